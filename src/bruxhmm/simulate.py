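"""Synthetic multi-subject EMG + cutaneous-sound recordings.

Generates reproducible datasets with the statistical structure the
classification pipeline assumes: ten stereotyped orofacial tasks (three
bruxism-with-tooth-contact movements, one bruxism-without-tooth-contact
movement, six non-bruxism movements), each performed as five 5-second
repetitions per subject, recorded on six EMG channels at 1000 Hz and one
skin-conducted sound channel at 44.1 kHz.

EMG is modelled as Gaussian noise shaped by per-task band-pass filters
and amplitude envelopes — no motor-unit-level simulation; the feature
extractor only sees spectral-temporal envelopes, so this is the level of
realism that matters downstream. Tooth-contact tasks add click or
friction transients to the sound channel. Channels are band-limited to
the 10–500 Hz hardware band and then contaminated with mains hum at the
configured line frequency and its odd harmonics.

Key confusability built in deliberately: bracing (forceful jaw-muscle
co-contraction without tooth contact) is spectrally and energetically
close to clenching on the masseter channels, distinguishable mainly by
stronger suprahyoid co-activation and by the absence of tooth-contact
sound (clenching emits only faint creaks, tapping and grinding loud
clicks and friction noise).
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .io_signals import (
    CHANNELS,
    SOUND_CHANNEL,
    TASKS,
    TASK_TO_CLASS,
    Recording,
    TaskSegment,
    cut_segments,
    write_csv_channel,
    write_wav,
)

__all__ = [
    "SubjectProfile",
    "Activity",
    "SoundEvent",
    "TaskModel",
    "TASK_MODELS",
    "GeneratorConfig",
    "subject_profile",
    "task_signature",
    "generate_recordings",
    "iter_subject_recordings",
    "generate_dataset",
]

# ---------------------------------------------------------------------------
# configuration and per-subject variability

#: Broadband resting-EMG noise floor, in a.u. before the subject gain.
BASELINE_LEVEL = 0.02
#: Band of the resting noise floor (Hz).
BASELINE_BAND = (20.0, 450.0)
#: Uniform noise floor RMS of the sound channel (a.u.).
SOUND_FLOOR_RMS = 0.003
#: Log-level anchor the task levels are pulled toward as separability -> 0.
EMG_LEVEL_ANCHOR = 0.2
SOUND_LEVEL_ANCHOR = 0.03
#: Lognormal sigma of the shared per-repetition effort jitter.
REP_JITTER_SIGMA = 0.25
#: Lognormal sigma of the per-channel level jitter inside a repetition.
CHANNEL_JITTER_SIGMA = 0.10


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject variability: overall EMG gain, a fractional shift of
    every channel's centre frequency, and the mains-hum contamination
    level of that subject's hookup."""

    subject_id: str
    emg_gain: float
    spectral_shift: float
    hum_amplitude: float
    rng_seed: int

    def __post_init__(self) -> None:
        if self.emg_gain <= 0:
            raise ValueError("emg_gain must be positive")
        if not -0.2 <= self.spectral_shift <= 0.2:
            raise ValueError("spectral_shift must lie in [-0.2, 0.2]")
        if self.hum_amplitude < 0:
            raise ValueError("hum_amplitude must be >= 0")


@dataclass(frozen=True)
class Activity:
    """One channel's activity during a task: envelope family, level in
    a.u. (before subject gain), and the EMG band as (centre, bandwidth)
    in Hz."""

    envelope: str  # sustained | periodic | single | irregular
    level: float
    band: tuple[float, float]
    rate: float | None = None  # burst rate in Hz (periodic)
    onset: float | None = None  # burst onset in s (single)
    duration: float | None = None  # burst duration in s (single)


@dataclass(frozen=True)
class SoundEvent:
    """Sound-channel event family for a task (none for silent tasks)."""

    kind: str  # none | click_train | friction | gulp | speech | snore
    level: float = 0.0
    rate: float | None = None


@dataclass(frozen=True)
class TaskModel:
    task_name: str
    class_label: str
    channels: dict[str, Activity]
    sound_event: SoundEvent


def _bilateral(task, cls, mass, infra, supra, chin, sound):
    """Helper: identical specs for left/right masseter and infrahyoid."""
    return TaskModel(
        task_name=task,
        class_label=cls,
        channels={
            "right_masseter": mass,
            "left_masseter": mass,
            "right_infrahyoid": infra,
            "left_infrahyoid": infra,
            "chin": chin,
            "suprahyoid": supra,
        },
        sound_event=sound,
    )


_QUIET = Activity("sustained", BASELINE_LEVEL, (100.0, 120.0))

#: The ten experimental tasks. Levels are in arbitrary units relative to
#: a 100% MVC clench of 1.0 on the masseter; bands chosen inside the
#: 10-500 Hz hardware passband with jaw-closer activity centred higher
#: than postural/movement artefact.
TASK_MODELS: dict[str, TaskModel] = {
    # Bracing deliberately shadows clenching: identical masseter band,
    # a level gap comparable to the effort jitter, identical infrahyoid
    # activity; only faint clenching creaks on the sound channel and a
    # modest suprahyoid level shift distinguish them -- the confusion
    # that caps BMwoTC accuracy. Tapping's 2 Hz burst train and
    # grinding's high-band noise are reliable masseter/sound signatures.
    "clenching": _bilateral(
        "clenching", "BMwTC",
        mass=Activity("sustained", 1.00, (120.0, 140.0)),
        infra=Activity("sustained", 0.16, (95.0, 90.0)),
        supra=Activity("sustained", 0.55, (90.0, 90.0)),
        chin=Activity("sustained", 0.15, (85.0, 80.0)),
        sound=SoundEvent("click_train", level=0.012, rate=0.5),
    ),
    "bracing": _bilateral(
        "bracing", "BMwoTC",
        mass=Activity("sustained", 0.70, (120.0, 140.0)),
        infra=Activity("sustained", 0.16, (95.0, 90.0)),
        supra=Activity("sustained", 0.70, (90.0, 90.0)),
        chin=Activity("sustained", 0.16, (85.0, 80.0)),
        sound=SoundEvent("none"),
    ),
    "tapping": _bilateral(
        "tapping", "BMwTC",
        mass=Activity("periodic", 0.80, (120.0, 140.0), rate=2.0),
        infra=Activity("periodic", 0.02, (95.0, 90.0), rate=2.0),
        supra=Activity("periodic", 0.12, (90.0, 90.0), rate=2.0),
        chin=Activity("periodic", 0.14, (85.0, 80.0), rate=2.0),
        sound=SoundEvent("click_train", level=0.45, rate=2.0),
    ),
    "grinding": _bilateral(
        "grinding", "BMwTC",
        mass=Activity("irregular", 0.90, (165.0, 190.0)),
        infra=Activity("irregular", 0.04, (85.0, 90.0)),
        supra=Activity("irregular", 0.15, (85.0, 90.0)),
        chin=Activity("irregular", 0.13, (70.0, 80.0)),
        sound=SoundEvent("friction", level=0.30, rate=1.2),
    ),
    "swallowing": _bilateral(
        "swallowing", "non-BM",
        mass=_QUIET,
        infra=Activity("single", 0.20, (70.0, 70.0), onset=2.0, duration=1.0),
        supra=Activity("single", 0.55, (70.0, 70.0), onset=2.0, duration=1.0),
        chin=Activity("single", 0.12, (70.0, 70.0), onset=2.0, duration=1.0),
        sound=SoundEvent("gulp", level=0.25),
    ),
    "yawning": _bilateral(
        "yawning", "non-BM",
        mass=Activity("sustained", 0.06, (60.0, 60.0)),
        infra=Activity("sustained", 0.11, (60.0, 60.0)),
        supra=Activity("sustained", 0.45, (60.0, 60.0)),
        chin=Activity("sustained", 0.12, (60.0, 60.0)),
        sound=SoundEvent("none"),
    ),
    "speaking": _bilateral(
        "speaking", "non-BM",
        mass=Activity("irregular", 0.13, (100.0, 110.0)),
        infra=Activity("irregular", 0.11, (80.0, 90.0)),
        supra=Activity("irregular", 0.38, (80.0, 90.0)),
        chin=Activity("irregular", 0.45, (90.0, 100.0)),
        sound=SoundEvent("speech", level=0.20),
    ),
    "scratching": _bilateral(
        "scratching", "non-BM",
        mass=Activity("irregular", 0.08, (60.0, 70.0)),
        infra=Activity("irregular", 0.04, (60.0, 70.0)),
        supra=Activity("irregular", 0.10, (60.0, 70.0)),
        chin=Activity("irregular", 0.35, (60.0, 80.0)),
        sound=SoundEvent("friction", level=0.07, rate=2.5),
    ),
    "head_body_motion": _bilateral(
        "head_body_motion", "non-BM",
        mass=Activity("irregular", 0.20, (45.0, 60.0)),
        infra=Activity("irregular", 0.08, (45.0, 60.0)),
        supra=Activity("irregular", 0.20, (45.0, 60.0)),
        chin=Activity("irregular", 0.15, (45.0, 60.0)),
        sound=SoundEvent("none"),
    ),
    "snoring": _bilateral(
        "snoring", "non-BM",
        mass=_QUIET,
        infra=Activity("periodic", 0.06, (40.0, 40.0), rate=0.3),
        supra=Activity("periodic", 0.25, (40.0, 40.0), rate=0.3),
        chin=_QUIET,
        sound=SoundEvent("snore", level=0.30, rate=0.35),
    ),
}


@dataclass
class GeneratorConfig:
    """Acquisition-protocol parameters of the synthetic study.

    Defaults mirror the emulated protocol: 12 subjects, 10 tasks of
    5 repetitions, 5 s per repetition with 5 s between repetitions and
    30 s between tasks; EMG at 1000 Hz, sound at 44100 Hz, 60 Hz mains.
    ``separability`` in (0, 1] scales the between-class contrast of the
    task amplitude levels (1 = the default, fully contrasted study).
    """

    n_subjects: int = 12
    reps_per_task: int = 5
    rep_duration: float = 5.0
    inter_rep_gap: float = 5.0
    inter_task_rest: float = 30.0
    emg_rate: float = 1000.0
    sound_rate: float = 44100.0
    mains_freq: float = 60.0
    master_seed: int = 0
    separability: float = 1.0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2 (leave-one-subject-out needs >= 2)")
        if self.reps_per_task < 1:
            raise ValueError("reps_per_task must be >= 1")
        for name in ("rep_duration", "inter_rep_gap", "inter_task_rest",
                     "emg_rate", "sound_rate", "mains_freq"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.separability <= 1:
            raise ValueError("separability must lie in (0, 1]")


# ---------------------------------------------------------------------------
# RNG plumbing: every (subject, task, rep, channel) gets its own stream so
# the dataset is deterministic and insensitive to generation order.

_PROFILE_TAG, _REP_TAG, _CHANNEL_TAG, _SESSION_TAG = 101, 202, 303, 404


def _rng(*entropy: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy))


def subject_profile(master_seed: int, subject_index: int) -> SubjectProfile:
    """Draw one subject's gain / spectral-shift / hum profile.

    Gain is lognormal (sigma 0.3), the centre-frequency shift uniform in
    +/-10%, and the hum amplitude uniform in [0.01, 0.05] a.u.
    """
    rng = _rng(master_seed, subject_index, _PROFILE_TAG)
    return SubjectProfile(
        subject_id=f"S{subject_index + 1:02d}",
        emg_gain=float(np.exp(rng.normal(0.0, 0.3))),
        spectral_shift=float(rng.uniform(-0.1, 0.1)),
        hum_amplitude=float(rng.uniform(0.01, 0.05)),
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# envelopes

def _ramp_window(n: int, rate: float, ramp_s: float = 0.3) -> np.ndarray:
    """Sustained-contraction window: raised-cosine on/off ramps."""
    w = np.ones(n)
    m = min(int(ramp_s * rate), n // 2)
    if m > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(m) / m))
        w[:m] = ramp
        w[n - m:] = ramp[::-1]
    return w


def _slow_noise(n: int, rate: float, cutoff: float, rng: np.random.Generator) -> np.ndarray:
    """Low-pass filtered unit-variance Gaussian noise (envelope wobble).

    Generated with padding and cropped to the settled interior so the
    filter's edge transients never leak into the envelope.
    """
    pad = int(2.0 * rate / cutoff)
    x = rng.standard_normal(n + 2 * pad)
    sos = butter(2, cutoff / (rate / 2), btype="low", output="sos")
    y = sosfiltfilt(sos, x)[pad : pad + n]
    s = y.std()
    return y / s if s > 0 else y


def _envelope(act: Activity, n: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / rate
    dur = n / rate
    if act.envelope == "sustained":
        env = _ramp_window(n, rate)
        env = env * (1.0 + 0.15 * _slow_noise(n, rate, 2.0, rng))
    elif act.envelope == "periodic":
        assert act.rate is not None
        env = np.zeros(n)
        width = 0.4 / act.rate  # 40% duty cycle
        k = 0
        while (tk := (k + 0.5) / act.rate) < dur:
            i0 = int((tk - width / 2) * rate)
            i1 = int((tk + width / 2) * rate)
            i0c, i1c = max(i0, 0), min(i1, n)
            m = i1 - i0
            if m > 1 and i1c > i0c:
                pulse = np.hanning(m)
                env[i0c:i1c] = np.maximum(env[i0c:i1c], pulse[i0c - i0 : i1c - i0])
            k += 1
    elif act.envelope == "single":
        onset = act.onset if act.onset is not None else 2.0
        width = act.duration if act.duration is not None else 1.0
        env = np.zeros(n)
        i0 = int(onset * rate)
        i1 = min(int((onset + width) * rate), n)
        if i1 > i0:
            env[i0:i1] = np.hanning(i1 - i0)
    elif act.envelope == "irregular":
        base = np.abs(_slow_noise(n, rate, 3.0, rng))
        peak = base.max()
        env = (base / peak if peak > 0 else base) * _ramp_window(n, rate)
    else:
        raise ValueError(f"unknown envelope kind {act.envelope!r}")
    return np.clip(env, 0.0, None)


def _effective_level(level: float, separability: float, anchor: float) -> float:
    """Pull task levels toward a common anchor (log-linearly) as the
    separability knob goes to 0, shrinking between-class contrast."""
    lv = max(level, BASELINE_LEVEL)
    return float(np.exp(separability * np.log(lv) + (1 - separability) * np.log(anchor)))


def _bandpass_noise(n: int, rate: float, lo: float, hi: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to [lo, hi] Hz."""
    hi = min(hi, 0.49 * rate)
    lo = max(lo, 1.0)
    sos = butter(4, [lo / (rate / 2), hi / (rate / 2)], btype="band", output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    s = x.std()
    return x / s if s > 0 else x


# ---------------------------------------------------------------------------
# sound events

def _click(rate: float, f0: float = 2500.0, tau: float = 0.004,
           length_s: float = 0.015, phase: float = 0.0) -> np.ndarray:
    t = np.arange(int(length_s * rate)) / rate
    return np.exp(-t / tau) * np.sin(2 * np.pi * f0 * t + phase)


def _sound_event(event: SoundEvent, n: int, rate: float, level: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Tooth-contact / orofacial sound for one repetition (no floor)."""
    t = np.arange(n) / rate
    dur = n / rate
    out = np.zeros(n)
    if event.kind == "none" or level <= 0:
        return out
    if event.kind == "click_train":
        assert event.rate is not None
        k = 0
        while (tk := (k + 0.5) / event.rate + rng.normal(0, 0.02)) < dur - 0.02:
            if tk < 0:
                k += 1
                continue
            c = _click(rate, f0=rng.uniform(2000, 3200), phase=rng.uniform(0, 2 * np.pi))
            i0 = int(tk * rate)
            amp = level * np.exp(rng.normal(0, 0.2))
            out[i0 : i0 + len(c)] += amp * c[: n - i0]
            k += 1
    elif event.kind == "friction":
        noise = _bandpass_noise(n, rate, 800.0, 4000.0, rng)
        am_rate = event.rate or 1.2
        am = 0.55 + 0.45 * np.sin(2 * np.pi * am_rate * t + rng.uniform(0, 2 * np.pi))
        out = level * noise * am * _ramp_window(n, rate)
    elif event.kind == "gulp":
        onset = 2.0 + rng.normal(0, 0.1)
        width = 0.3
        i0, i1 = int(onset * rate), min(int((onset + width) * rate), n)
        burst = _bandpass_noise(i1 - i0, rate, 100.0, 350.0, rng)
        out[i0:i1] = level * burst * np.hanning(i1 - i0)
    elif event.kind == "speech":
        noise = _bandpass_noise(n, rate, 300.0, 3400.0, rng)
        syll = np.clip(0.5 + 0.5 * np.sin(2 * np.pi * 4.0 * t + rng.uniform(0, 2 * np.pi))
                       + 0.3 * _slow_noise(n, rate, 3.0, rng), 0, None)
        out = level * noise * syll * _ramp_window(n, rate)
    elif event.kind == "snore":
        assert event.rate is not None
        breath = event.rate
        osc = np.sin(2 * np.pi * 90.0 * t) + 0.4 * np.sin(2 * np.pi * 180.0 * t)
        env = np.zeros(n)
        k = 0
        while (tk := (k + 0.3) / breath) < dur:
            i0 = int(tk * rate)
            i1 = min(int((tk + 1.4) * rate), n)
            if i1 > i0:
                env[i0:i1] = np.maximum(env[i0:i1], np.hanning(i1 - i0))
            k += 1
        out = level * osc * env
    else:
        raise ValueError(f"unknown sound event kind {event.kind!r}")
    return out


# ---------------------------------------------------------------------------
# public synthesis ops

def task_signature(
    task: str,
    channel: str,
    profile: SubjectProfile,
    rng: np.random.Generator,
    *,
    duration: float = 5.0,
    rate: float | None = None,
    separability: float = 1.0,
    include_baseline: bool = True,
) -> np.ndarray:
    """Sample one 5-s repetition of `task` on `channel`.

    EMG channels return band-shaped noise under the task envelope plus
    (optionally) the broadband resting floor; amplitudes scale linearly
    with ``profile.emg_gain``. The sound channel returns the task's
    tooth-contact / orofacial event over a low uniform noise floor and
    does not scale with the EMG gain.
    """
    if task not in TASK_MODELS:
        raise KeyError(f"unknown task {task!r}; valid tasks: {', '.join(TASKS)}")
    if channel not in CHANNELS:
        raise KeyError(f"unknown channel {channel!r}; valid channels: {', '.join(CHANNELS)}")
    model = TASK_MODELS[task]

    if channel == SOUND_CHANNEL:
        rate = rate if rate is not None else 44100.0
        n = int(round(duration * rate))
        level = _effective_level(model.sound_event.level, separability, SOUND_LEVEL_ANCHOR) \
            if model.sound_event.kind != "none" else 0.0
        out = _sound_event(model.sound_event, n, rate, level, rng)
        if include_baseline:
            half = SOUND_FLOOR_RMS * np.sqrt(3.0)
            out = out + rng.uniform(-half, half, size=n)
        return out

    rate = rate if rate is not None else 1000.0
    n = int(round(duration * rate))
    act = model.channels[channel]
    centre, bw = act.band
    centre *= 1.0 + profile.spectral_shift
    lo, hi = max(10.0, centre - bw / 2), min(480.0, centre + bw / 2)
    level = _effective_level(act.level, separability, EMG_LEVEL_ANCHOR)
    level *= float(np.exp(rng.normal(0.0, CHANNEL_JITTER_SIGMA)))
    carrier = _bandpass_noise(n, rate, lo, hi, rng)
    env = _envelope(act, n, rate, rng)
    out = profile.emg_gain * level * carrier * env
    if include_baseline:
        out = out + profile.emg_gain * BASELINE_LEVEL * _bandpass_noise(
            n, rate, *BASELINE_BAND, rng
        )
    return out


def _session_layout(config: GeneratorConfig) -> tuple[float, list[dict]]:
    """Rep start times (s) and the total session duration."""
    entries = []
    t = 0.0
    for ti, task in enumerate(TASKS):
        for rep in range(1, config.reps_per_task + 1):
            entries.append({"task": task, "rep": rep, "t0": t})
            t += config.rep_duration
            if rep < config.reps_per_task:
                t += config.inter_rep_gap
        if ti < len(TASKS) - 1:
            t += config.inter_task_rest
    return t, entries


def _hum(n: int, rate: float, mains: float, amplitude: float,
         rng: np.random.Generator) -> np.ndarray:
    """Mains contamination: fundamental plus odd harmonics below Nyquist,
    1/k amplitude roll-off, random phases."""
    t = np.arange(n) / rate
    out = np.zeros(n)
    k = 1
    while k * mains < 0.5 * rate and k <= 7:
        out += (amplitude / k) * np.sin(2 * np.pi * k * mains * t + rng.uniform(0, 2 * np.pi))
        k += 2
    return out


def generate_subject_recording(
    config: GeneratorConfig, subject_index: int
) -> tuple[SubjectProfile, Recording, list[dict]]:
    """Synthesize one subject's full session and its manifest entries."""
    config.validate()
    profile = subject_profile(config.master_seed, subject_index)
    total_s, layout = _session_layout(config)

    rec = Recording(subject_id=profile.subject_id)
    manifest_entries: list[dict] = []

    # shared per-repetition effort jitter (applies to all EMG channels)
    rep_scale = {
        (e["task"], e["rep"]): float(np.exp(
            _rng(config.master_seed, subject_index, ti_rep_key, _REP_TAG)
            .normal(0.0, REP_JITTER_SIGMA)))
        for ti_rep_key, e in enumerate(layout)
    }

    for ci, channel in enumerate(CHANNELS):
        rate = config.sound_rate if channel == SOUND_CHANNEL else config.emg_rate
        n_total = int(round(total_s * rate))
        sess_rng = _rng(config.master_seed, subject_index, ci, _SESSION_TAG)
        if channel == SOUND_CHANNEL:
            half = SOUND_FLOOR_RMS * np.sqrt(3.0)
            sig = sess_rng.uniform(-half, half, size=n_total)
        else:
            sig = profile.emg_gain * BASELINE_LEVEL * _bandpass_noise(
                n_total, rate, *BASELINE_BAND, sess_rng
            )
        for ei, e in enumerate(layout):
            rng = _rng(config.master_seed, subject_index, ei, ci, _CHANNEL_TAG)
            rep_sig = task_signature(
                e["task"], channel, profile, rng,
                duration=config.rep_duration, rate=rate,
                separability=config.separability, include_baseline=False,
            )
            if channel != SOUND_CHANNEL:
                rep_sig = rep_sig * rep_scale[(e["task"], e["rep"])]
            i0 = int(round(e["t0"] * rate))
            sig[i0 : i0 + len(rep_sig)] += rep_sig
        if channel != SOUND_CHANNEL:
            # emulated hardware acquisition band, then mains contamination
            nyq = rate / 2
            sos = butter(4, [10.0 / nyq, min(490.0, 0.98 * nyq) / nyq],
                         btype="band", output="sos")
            sig = sosfiltfilt(sos, sig)
            sig = sig + _hum(n_total, rate, config.mains_freq,
                             profile.hum_amplitude, sess_rng)
        rec.channels[channel] = (sig, rate)

    for e in layout:
        windows = {}
        for channel in CHANNELS:
            rate = rec.rate(channel)
            i0 = int(round(e["t0"] * rate))
            i1 = i0 + int(round(config.rep_duration * rate))
            windows[channel] = {"start_sample": i0, "end_sample": i1, "rate": rate}
        manifest_entries.append({
            "task": e["task"],
            "class": TASK_TO_CLASS[e["task"]],
            "rep": e["rep"],
            "windows": windows,
        })
    return profile, rec, manifest_entries


def iter_subject_recordings(config: GeneratorConfig):
    """Yield (profile, recording, manifest entries) per subject, streaming."""
    config.validate()
    for si in range(config.n_subjects):
        yield generate_subject_recording(config, si)


def generate_recordings(config: GeneratorConfig) -> list[TaskSegment]:
    """Generate the whole dataset in memory and return its segments."""
    segments: list[TaskSegment] = []
    for _, rec, entries in iter_subject_recordings(config):
        segs = cut_segments(rec, entries)
        # copy slices so the full-session arrays can be freed
        for s in segs:
            s.channels = {ch: (np.array(x), r) for ch, (x, r) in s.channels.items()}
        segments.extend(segs)
    return segments


def generate_dataset(config: GeneratorConfig, out_dir: str | Path) -> Path:
    """Write the dataset to disk: per subject one CSV per EMG channel and
    one WAV for sound, plus a JSON manifest. Returns the manifest path.

    Identical configs produce byte-identical output.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest = {
        "config": asdict(config),
        "subjects": [],
    }
    for profile, rec, entries in iter_subject_recordings(config):
        sid = rec.subject_id
        subj_dir = out_dir / sid
        subj_dir.mkdir(exist_ok=True)
        files: dict[str, str] = {}
        for channel in CHANNELS:
            x, rate = rec.channels[channel]
            if channel == SOUND_CHANNEL:
                fname = f"{sid}/{sid}_{channel}.wav"
                write_wav(out_dir / fname, x, int(rate))
            else:
                fname = f"{sid}/{sid}_{channel}.csv"
                write_csv_channel(out_dir / fname, x, rate)
            files[channel] = fname
        for e in entries:
            for channel, win in e["windows"].items():
                win["file"] = files[channel]
        manifest["subjects"].append({
            "subject_id": sid,
            "profile": asdict(profile),
            "segments": entries,
        })

    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest_path


def manifest_fingerprint(manifest_path: str | Path) -> str:
    """SHA-256 of the manifest file (determinism checks)."""
    return hashlib.sha256(Path(manifest_path).read_bytes()).hexdigest()
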