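"""Dataset file formats and labelled per-segment records.

The dataset layout mirrors a small polysomnography-style acquisition:
one CSV per EMG channel (``time_s,value``), one mono PCM16 WAV for the
cutaneous-sound channel, and a JSON manifest that lists every labelled
5-second task repetition with its sample window in each channel's own
sampling rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "EMG_CHANNELS",
    "SOUND_CHANNEL",
    "CHANNELS",
    "CLASSES",
    "TASKS",
    "TASK_TO_CLASS",
    "map_task_to_class",
    "Recording",
    "TaskSegment",
    "read_wav",
    "write_wav",
    "read_csv_channel",
    "write_csv_channel",
    "load_dataset",
    "cut_segments",
]

EMG_CHANNELS: tuple[str, ...] = (
    "right_masseter",
    "left_masseter",
    "right_infrahyoid",
    "left_infrahyoid",
    "chin",
    "suprahyoid",
)
SOUND_CHANNEL = "sound"
CHANNELS: tuple[str, ...] = EMG_CHANNELS + (SOUND_CHANNEL,)

#: Classification targets: bruxism movement with tooth contact, without
#: tooth contact, and non-bruxism movement.
CLASSES: tuple[str, ...] = ("BMwTC", "BMwoTC", "non-BM")

#: The ten experimental tasks and their class, in protocol order.
TASK_TO_CLASS: dict[str, str] = {
    "clenching": "BMwTC",
    "bracing": "BMwoTC",
    "tapping": "BMwTC",
    "grinding": "BMwTC",
    "swallowing": "non-BM",
    "yawning": "non-BM",
    "speaking": "non-BM",
    "scratching": "non-BM",
    "head_body_motion": "non-BM",
    "snoring": "non-BM",
}
TASKS: tuple[str, ...] = tuple(TASK_TO_CLASS)

#: PCM16 full scale used when writing float signals to WAV.
WAV_FULL_SCALE = 32767.0


def map_task_to_class(task: str) -> str:
    """Return the movement class for an experimental task.

    Clenching, tapping and grinding involve tooth contact (BMwTC);
    bracing is forceful co-contraction without tooth contact (BMwoTC);
    the remaining six everyday movements are non-bruxism (non-BM).
    """
    try:
        return TASK_TO_CLASS[task]
    except KeyError:
        raise KeyError(
            f"unknown task {task!r}; valid tasks: {', '.join(TASKS)}"
        ) from None


@dataclass
class Recording:
    """All channels of one subject's session, each at its own rate."""

    subject_id: str
    channels: dict[str, tuple[np.ndarray, float]] = field(default_factory=dict)

    def rate(self, channel: str) -> float:
        return self.channels[channel][1]

    def samples(self, channel: str) -> np.ndarray:
        return self.channels[channel][0]


@dataclass
class TaskSegment:
    """One labelled 5-s task repetition, the atomic classification unit.

    All channel slices cover the same time window; EMG channels are
    sampled at 1000 Hz and the sound channel at 44100 Hz, so the slices
    differ in length but not in duration.
    """

    subject_id: str
    task: str
    class_label: str
    rep: int
    channels: dict[str, tuple[np.ndarray, float]]

    def __post_init__(self) -> None:
        if self.class_label != map_task_to_class(self.task):
            raise ValueError(
                f"class_label {self.class_label!r} inconsistent with task "
                f"{self.task!r} ({map_task_to_class(self.task)})"
            )

    def samples(self, channel: str) -> np.ndarray:
        return self.channels[channel][0]

    def rate(self, channel: str) -> float:
        return self.channels[channel][1]

    @property
    def duration(self) -> float:
        ch = next(iter(self.channels))
        x, rate = self.channels[ch]
        return len(x) / rate


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a mono PCM16 WAV; returns float samples in [-1, 1] and rate."""
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: only mono WAV is supported, got shape {data.shape}")
    if data.dtype != np.int16:
        raise ValueError(f"{path}: only 16-bit PCM WAV is supported, got {data.dtype}")
    return data.astype(np.float64) / WAV_FULL_SCALE, int(rate)


def write_wav(path: str | Path, samples: np.ndarray, rate: int) -> None:
    """Write float samples (full scale 1.0) as mono PCM16 at `rate` Hz."""
    clipped = np.clip(np.asarray(samples, dtype=np.float64), -1.0, 1.0)
    pcm = np.round(clipped * WAV_FULL_SCALE).astype(np.int16)
    wavfile.write(path, int(rate), pcm)


def read_csv_channel(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a `time_s,value` channel CSV; returns (samples, rate).

    The rate is inferred from the first two time stamps; a file with a
    single row has an undefined rate and raises.
    """
    df = pd.read_csv(path)
    if list(df.columns) != ["time_s", "value"]:
        raise ValueError(f"{path}: expected header 'time_s,value', got {list(df.columns)}")
    bad = df.index[df.isna().any(axis=1)]
    if len(bad):
        # +2: one for the header row, one for 0-based index
        raise ValueError(f"{path}: malformed row at line {bad[0] + 2}")
    values = df["value"].to_numpy(dtype=np.float64)
    t = df["time_s"].to_numpy(dtype=np.float64)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least 2 rows to infer the sampling rate")
    rate = 1.0 / (t[1] - t[0])
    return values, float(round(rate, 6))


def write_csv_channel(path: str | Path, samples: np.ndarray, rate: float) -> None:
    samples = np.asarray(samples, dtype=np.float64)
    t = np.arange(len(samples)) / rate
    pd.DataFrame({"time_s": t, "value": samples}).to_csv(
        path, index=False, float_format="%.6f"
    )


def cut_segments(
    recording: Recording, entries: list[dict]
) -> list[TaskSegment]:
    """Materialize manifest segment entries from an in-memory recording.

    Each entry carries per-channel half-open [start_sample, end_sample)
    windows in that channel's own rate.
    """
    segments = []
    for e in entries:
        channels = {}
        for ch, win in e["windows"].items():
            x, rate = recording.channels[ch]
            channels[ch] = (x[win["start_sample"] : win["end_sample"]], rate)
        segments.append(
            TaskSegment(
                subject_id=recording.subject_id,
                task=e["task"],
                class_label=e["class"],
                rep=int(e["rep"]),
                channels=channels,
            )
        )
    return segments


def load_dataset(manifest_path: str | Path) -> list[TaskSegment]:
    """Load every labelled segment referenced by a dataset manifest.

    Segments are returned in (subject, task, rep) lexicographic order
    with task order as listed in the manifest entry order being ignored.
    Sampling rates found in the files must match the manifest; a
    mismatch raises rather than resampling.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    root = manifest_path.parent

    segments: list[TaskSegment] = []
    for subject in manifest["subjects"]:
        sid = subject["subject_id"]
        # read each referenced channel file once per subject
        cache: dict[str, tuple[np.ndarray, float]] = {}
        for seg in subject["segments"]:
            channels = {}
            for ch, win in seg["windows"].items():
                fname = win["file"]
                if fname not in cache:
                    fpath = root / fname
                    if not fpath.exists():
                        raise FileNotFoundError(f"channel file missing: {fpath}")
                    if fname.endswith(".wav"):
                        cache[fname] = tuple(read_wav(fpath))  # type: ignore[assignment]
                    else:
                        cache[fname] = read_csv_channel(fpath)
                x, rate = cache[fname]
                if abs(rate - win["rate"]) > 1e-6 * win["rate"]:
                    raise ValueError(
                        f"{fname}: rate {rate} Hz does not match manifest "
                        f"{win['rate']} Hz (refusing to resample)"
                    )
                channels[ch] = (x[win["start_sample"] : win["end_sample"]], rate)
            segments.append(
                TaskSegment(
                    subject_id=sid,
                    task=seg["task"],
                    class_label=seg["class"],
                    rep=int(seg["rep"]),
                    channels=channels,
                )
            )
    segments.sort(key=lambda s: (s.subject_id, s.task, s.rep))
    return segments
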