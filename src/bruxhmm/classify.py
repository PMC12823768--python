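"""Train the three class HMMs on a training split and classify segments.

A :class:`StreamSet` names the channels fused by a model: the seven
single-channel sets (each EMG channel and the cutaneous sound) and the
five multi-stream combinations MS-1..MS-5 (MS-1 = all six EMG channels;
MS-2 = bilateral masseter; MS-3 = MS-2 + sound; MS-4 = bilateral
masseter + bilateral infrahyoid; MS-5 = MS-4 + sound).

Classification assigns each 5-s segment to the class whose HMM attains
the highest Viterbi score on the segment's fused feature streams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import FrameSpec, MfccConfig, default_mfcc_config, extract_features
from .hmm import (
    ClassHMM,
    Observation,
    baum_welch,
    batch_scores,
    hmm_from_dict,
    hmm_to_dict,
    init_hmm,
)
from .io_signals import CLASSES, EMG_CHANNELS, SOUND_CHANNEL, TaskSegment

__all__ = [
    "StreamSet",
    "ClassifierBundle",
    "builtin_stream_sets",
    "segment_observation",
    "train_bundle",
    "train_bundle_from_observations",
    "classify_segment",
    "classify_observations",
    "save_bundle",
    "load_bundle",
]

#: Deterministic tie-break order for equal scores.
CLASS_ORDER: tuple[str, ...] = ("BMwTC", "BMwoTC", "non-BM")


@dataclass(frozen=True)
class StreamSet:
    """Named, ordered set of channels fused by one classifier."""

    name: str
    streams: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.streams:
            raise ValueError("stream set must be non-empty")
        if len(set(self.streams)) != len(self.streams):
            raise ValueError("duplicate channel in stream set")
        valid = set(EMG_CHANNELS) | {SOUND_CHANNEL}
        unknown = set(self.streams) - valid
        if unknown:
            raise ValueError(f"unknown channels {sorted(unknown)}")


def builtin_stream_sets() -> list[StreamSet]:
    """The 12 evaluated stream sets: 7 single channels plus MS-1..MS-5."""
    singles = [StreamSet(ch, (ch,)) for ch in EMG_CHANNELS + (SOUND_CHANNEL,)]
    masseter = ("right_masseter", "left_masseter")
    infrahyoid = ("right_infrahyoid", "left_infrahyoid")
    multis = [
        StreamSet("MS-1", EMG_CHANNELS),
        StreamSet("MS-2", masseter),
        StreamSet("MS-3", masseter + (SOUND_CHANNEL,)),
        StreamSet("MS-4", masseter + infrahyoid),
        StreamSet("MS-5", masseter + infrahyoid + (SOUND_CHANNEL,)),
    ]
    return singles + multis


@dataclass
class HmmConfig:
    """Topology / training hyperparameters shared by the three models."""

    n_states: int = 3
    n_mix: int = 10
    max_iter: int = 20
    rel_tol: float = 1e-4
    require_exit: bool = False
    statistic: str = "viterbi"  # classification score; "forward" available


@dataclass
class ClassifierBundle:
    """The three trained class HMMs for one stream set."""

    stream_set: StreamSet
    models: dict[str, ClassHMM]
    training_subjects: tuple[str, ...]
    training_counts: dict[str, int]
    feature_fingerprint: str
    hmm_config: HmmConfig = field(default_factory=HmmConfig)

    def __post_init__(self) -> None:
        if set(self.models) != set(CLASSES):
            raise ValueError(f"bundle must hold exactly the classes {CLASSES}")


def segment_observation(
    segment: TaskSegment,
    stream_set: StreamSet,
    frame_spec: FrameSpec | None = None,
    mfcc_configs: dict[str, MfccConfig] | None = None,
    *,
    mains_freq: float = 60.0,
) -> Observation:
    """Extract the per-stream feature matrices for one segment."""
    obs: Observation = {}
    for ch in stream_set.streams:
        cfg = (mfcc_configs or {}).get(ch) or default_mfcc_config(ch)
        fs = extract_features(segment, ch, frame_spec, cfg, mains_freq=mains_freq)
        obs[ch] = fs.values
    return obs


def _feature_fingerprint(frame_spec: FrameSpec | None,
                         mfcc_configs: dict[str, MfccConfig] | None) -> str:
    return json.dumps(
        {
            "frame": repr(frame_spec or FrameSpec()),
            "mfcc": {k: repr(v) for k, v in sorted((mfcc_configs or {}).items())},
        },
        sort_keys=True,
    )


def train_bundle_from_observations(
    observations: list[Observation],
    labels: list[str],
    subjects: list[str],
    stream_set: StreamSet,
    hmm_config: HmmConfig | None = None,
    seed: int = 0,
    feature_fingerprint: str = "",
) -> ClassifierBundle:
    """Fit one GMM-HMM per class on pre-extracted feature observations."""
    cfg = hmm_config or HmmConfig()
    present = set(labels)
    missing = [c for c in CLASSES if c not in present]
    if missing:
        raise ValueError(f"training data contains no segments of class: {', '.join(missing)}")
    models: dict[str, ClassHMM] = {}
    counts: dict[str, int] = {}
    for ci, cls in enumerate(CLASS_ORDER):
        seqs = [o for o, l in zip(observations, labels) if l == cls]
        counts[cls] = len(seqs)
        model = init_hmm(
            seqs, cls, n_states=cfg.n_states, n_mix=cfg.n_mix, seed=seed + ci
        )
        model.require_exit = cfg.require_exit
        model, _ = baum_welch(model, seqs, max_iter=cfg.max_iter, rel_tol=cfg.rel_tol)
        models[cls] = model
    return ClassifierBundle(
        stream_set=stream_set,
        models=models,
        training_subjects=tuple(sorted(set(subjects))),
        training_counts=counts,
        feature_fingerprint=feature_fingerprint,
        hmm_config=cfg,
    )


def train_bundle(
    train_segments: list[TaskSegment],
    stream_set: StreamSet,
    frame_spec: FrameSpec | None = None,
    mfcc_configs: dict[str, MfccConfig] | None = None,
    hmm_config: HmmConfig | None = None,
    seed: int = 0,
    *,
    mains_freq: float = 60.0,
) -> ClassifierBundle:
    """Extract features and fit the three class models.

    Each class HMM trains on every training segment of that class
    pooled across tasks (e.g. the BMwTC model on clenching + tapping +
    grinding segments of all training subjects).
    """
    observations = [
        segment_observation(s, stream_set, frame_spec, mfcc_configs, mains_freq=mains_freq)
        for s in train_segments
    ]
    return train_bundle_from_observations(
        observations,
        [s.class_label for s in train_segments],
        [s.subject_id for s in train_segments],
        stream_set,
        hmm_config,
        seed,
        _feature_fingerprint(frame_spec, mfcc_configs),
    )


def classify_observations(
    bundle: ClassifierBundle, observations: list[Observation]
) -> tuple[list[str], np.ndarray]:
    """Predicted class and the (n_obs x 3) per-class score matrix.

    The score is each model's Viterbi log score (or forward, per the
    bundle config); ties break deterministically in the order
    BMwTC < BMwoTC < non-BM.
    """
    stat = bundle.hmm_config.statistic
    scores = np.column_stack(
        [batch_scores(bundle.models[c], observations, statistic=stat) for c in CLASS_ORDER]
    )
    preds = [CLASS_ORDER[int(np.argmax(row))] for row in scores]
    return preds, scores


def classify_segment(
    bundle: ClassifierBundle,
    segment: TaskSegment,
    frame_spec: FrameSpec | None = None,
    mfcc_configs: dict[str, MfccConfig] | None = None,
    *,
    mains_freq: float = 60.0,
) -> tuple[str, dict[str, float]]:
    """Classify one segment; returns (predicted class, per-class scores)."""
    missing = [ch for ch in bundle.stream_set.streams if ch not in segment.channels]
    if missing:
        raise KeyError(f"segment lacks channels required by the bundle: {missing}")
    obs = segment_observation(
        segment, bundle.stream_set, frame_spec, mfcc_configs, mains_freq=mains_freq
    )
    preds, scores = classify_observations(bundle, [obs])
    return preds[0], {c: float(s) for c, s in zip(CLASS_ORDER, scores[0])}


# ---------------------------------------------------------------------------

def save_bundle(bundle: ClassifierBundle, path: str | Path) -> None:
    doc = {
        "stream_set": {"name": bundle.stream_set.name, "streams": list(bundle.stream_set.streams)},
        "training_subjects": list(bundle.training_subjects),
        "training_counts": bundle.training_counts,
        "feature_fingerprint": bundle.feature_fingerprint,
        "hmm_config": vars(bundle.hmm_config),
        "models": {c: hmm_to_dict(m) for c, m in bundle.models.items()},
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_bundle(path: str | Path) -> ClassifierBundle:
    doc = json.loads(Path(path).read_text())
    return ClassifierBundle(
        stream_set=StreamSet(doc["stream_set"]["name"], tuple(doc["stream_set"]["streams"])),
        models={c: hmm_from_dict(m) for c, m in doc["models"].items()},
        training_subjects=tuple(doc["training_subjects"]),
        training_counts={k: int(v) for k, v in doc["training_counts"].items()},
        feature_fingerprint=doc["feature_fingerprint"],
        hmm_config=HmmConfig(**doc["hmm_config"]),
    )
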