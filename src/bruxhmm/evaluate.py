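"""Leave-one-subject-out evaluation and study-level statistics.

Each of the N subjects serves once as the test set while the three
class HMMs train on the other N-1 subjects; per fold a 3x3 confusion
matrix yields one-vs-rest sensitivity, specificity, positive and
negative predictive values and the F-value (harmonic mean of PPV and
sensitivity) per class. Study summaries report mean +/- SD over folds,
and F-values are compared across stream sets with a one-way ANOVA and
Tukey's HSD post hoc test (alpha = 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .classify import (
    CLASS_ORDER,
    HmmConfig,
    StreamSet,
    builtin_stream_sets,
    classify_observations,
    segment_observation,
    train_bundle_from_observations,
)
from .features import FrameSpec, MfccConfig
from .io_signals import TaskSegment

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "FoldMetrics",
    "StudyReport",
    "confusion_matrix",
    "one_vs_rest_metrics",
    "f_value",
    "summarize",
    "anova_oneway",
    "tukey_hsd",
    "SegmentObservations",
    "extract_observations",
    "loso_cv",
    "run_study",
]

METRICS = ("sensitivity", "specificity", "ppv", "npv", "f_value")


@dataclass
class ConfusionMatrix:
    """3x3 counts; rows = true class, columns = predicted class, in the
    fixed order BMwTC, BMwoTC, non-BM."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (3, 3) or np.any(self.counts < 0):
            raise ValueError("confusion matrix must be 3x3 with non-negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(true_labels: list[str], pred_labels: list[str]) -> ConfusionMatrix:
    idx = {c: i for i, c in enumerate(CLASS_ORDER)}
    counts = np.zeros((3, 3), dtype=int)
    for t, p in zip(true_labels, pred_labels, strict=True):
        counts[idx[t], idx[p]] += 1
    return ConfusionMatrix(counts)


def one_vs_rest_metrics(cm: ConfusionMatrix, cls: str) -> dict[str, float | bool]:
    """Sensitivity, specificity, PPV, NPV for one class against the rest.

    A 0/0 ratio is reported as 0.0 with the corresponding
    ``*_undefined`` flag set, so degenerate folds stay visible instead
    of silently dropping out of the averages.
    """
    c = CLASS_ORDER.index(cls)
    m = cm.counts
    tp = int(m[c, c])
    fn = int(m[c].sum() - tp)
    fp = int(m[:, c].sum() - tp)
    tn = int(m.sum() - tp - fn - fp)

    out: dict[str, float | bool] = {}
    for name, num, den in (
        ("sensitivity", tp, tp + fn),
        ("specificity", tn, tn + fp),
        ("ppv", tp, tp + fp),
        ("npv", tn, tn + fn),
    ):
        if den == 0:
            out[name] = 0.0
            out[f"{name}_undefined"] = True
        else:
            out[name] = num / den
            out[f"{name}_undefined"] = False
    return out


def f_value(ppv: float, sensitivity: float) -> float:
    """Harmonic mean of PPV and sensitivity; 0 when both are 0."""
    if not (0 <= ppv <= 1 and 0 <= sensitivity <= 1):
        raise ValueError("ppv and sensitivity must lie in [0, 1]")
    if ppv + sensitivity == 0:
        return 0.0
    return 2.0 * ppv * sensitivity / (ppv + sensitivity)


@dataclass
class FoldMetrics:
    """One test subject's one-vs-rest metrics per class."""

    test_subject: str
    n_segments: int
    per_class: dict[str, dict[str, float | bool]]
    confusion: ConfusionMatrix

    @classmethod
    def from_predictions(
        cls, subject: str, true_labels: list[str], pred_labels: list[str]
    ) -> "FoldMetrics":
        cm = confusion_matrix(true_labels, pred_labels)
        per_class = {}
        for c in CLASS_ORDER:
            m = one_vs_rest_metrics(cm, c)
            m["f_value"] = f_value(float(m["ppv"]), float(m["sensitivity"]))
            per_class[c] = m
        return cls(subject, cm.total, per_class, cm)


def summarize(folds: list[FoldMetrics]) -> dict[str, dict[str, tuple[float, float]]]:
    """Per-class mean and sample SD (ddof=1) of each metric over folds.

    Averages per-fold values — never pooled counts — matching an
    evaluation that weights each test subject equally.
    """
    if not folds:
        raise ValueError("need at least one fold")
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for c in CLASS_ORDER:
        out[c] = {}
        for m in METRICS:
            vals = np.array([float(f.per_class[c][m]) for f in folds])
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            out[c][m] = (float(vals.mean()), sd)
    return out


# ---------------------------------------------------------------------------
# statistics

def anova_oneway(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA: F statistic and p-value.

    Standard between/within sum-of-squares decomposition with
    (k - 1, N - k) degrees of freedom. If both the between- and
    within-group variation vanish the statistic is undefined and
    (0.0, 1.0) is returned.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 values")
    k = len(groups)
    N = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, N - k
    if ssw == 0 and ssb == 0:
        return 0.0, 1.0
    if ssw == 0:
        return float("inf"), 0.0
    F = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return float(F), p


def tukey_hsd(
    groups: list[np.ndarray], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Tukey's honestly-significant-difference all-pairs comparison.

    Returns the symmetric pairwise p-value matrix (diagonal 1) and the
    boolean significance matrix at level ``alpha``. p-values come from
    the studentized-range distribution with the pooled within-group
    variance; unequal group sizes use the Tukey-Kramer standard error.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 values")
    k = len(groups)
    N = sum(len(g) for g in groups)
    df_w = N - k
    msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / df_w
    pmat = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(msw / 2.0 * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
            if se == 0:
                p = 1.0 if groups[i].mean() == groups[j].mean() else 0.0
            else:
                q = abs(groups[i].mean() - groups[j].mean()) / se
                p = float(stats.studentized_range.sf(q, k, df_w))
            pmat[i, j] = pmat[j, i] = p
    return pmat, pmat < alpha


# ---------------------------------------------------------------------------
# LOSO study

@dataclass
class SegmentObservations:
    """Pre-extracted per-channel features for one labelled segment."""

    subject_id: str
    task: str
    class_label: str
    rep: int
    features: dict[str, np.ndarray]  # channel -> (T, D)


def extract_observations(
    segments: list[TaskSegment],
    channels: tuple[str, ...] | None = None,
    frame_spec: FrameSpec | None = None,
    mfcc_configs: dict[str, MfccConfig] | None = None,
    *,
    mains_freq: float = 60.0,
) -> list[SegmentObservations]:
    """Extract features once per (segment, channel) for reuse across
    stream sets and folds."""
    out = []
    for s in segments:
        chans = channels if channels is not None else tuple(s.channels)
        obs = segment_observation(
            s, StreamSet("_all", chans), frame_spec, mfcc_configs, mains_freq=mains_freq
        )
        out.append(
            SegmentObservations(s.subject_id, s.task, s.class_label, s.rep, obs)
        )
    return out


def _project(seg: SegmentObservations, stream_set: StreamSet) -> dict[str, np.ndarray]:
    return {ch: seg.features[ch] for ch in stream_set.streams}


def loso_cv(
    dataset: list[SegmentObservations] | list[TaskSegment],
    stream_set: StreamSet,
    hmm_config: HmmConfig | None = None,
    seed: int = 0,
    frame_spec: FrameSpec | None = None,
    mfcc_configs: dict[str, MfccConfig] | None = None,
) -> list[FoldMetrics]:
    """Leave-one-subject-out cross-validation for one stream set.

    For each subject, the three class models train on all other
    subjects' segments and classify every segment of the held-out
    subject. Folds are ordered by subject id; a fold whose training
    split lacks a class is skipped with a warning.
    """
    if dataset and isinstance(dataset[0], TaskSegment):
        dataset = extract_observations(dataset)  # type: ignore[arg-type]
    segs: list[SegmentObservations] = list(dataset)  # type: ignore[assignment]
    subjects = sorted({s.subject_id for s in segs})
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")

    folds: list[FoldMetrics] = []
    for test_subject in subjects:
        train = [s for s in segs if s.subject_id != test_subject]
        test = [s for s in segs if s.subject_id == test_subject]
        try:
            bundle = train_bundle_from_observations(
                [_project(s, stream_set) for s in train],
                [s.class_label for s in train],
                [s.subject_id for s in train],
                stream_set,
                hmm_config,
                seed,
            )
        except ValueError as err:
            logger.warning("fold %s skipped: %s", test_subject, err)
            continue
        assert test_subject not in bundle.training_subjects  # no leakage
        preds, _ = classify_observations(bundle, [_project(s, stream_set) for s in test])
        folds.append(
            FoldMetrics.from_predictions(
                test_subject, [s.class_label for s in test], preds
            )
        )
    return folds


@dataclass
class StudyReport:
    """Cross-fold summary for one stream set plus study-wide statistics."""

    stream_set: str
    n_folds: int
    summary: dict[str, dict[str, tuple[float, float]]]
    fold_f_values: dict[str, list[float]]  # class -> per-fold F


def run_study(
    dataset: list[SegmentObservations] | list[TaskSegment],
    stream_sets: list[StreamSet] | None = None,
    hmm_config: HmmConfig | None = None,
    seed: int = 0,
    alpha: float = 0.05,
    progress: bool = False,
) -> dict:
    """Full study: LOSO for every stream set, then per-class one-way
    ANOVA + Tukey HSD on the per-fold F-values, separately across the
    single-channel sets and across the multi-stream (MS) sets.

    Returns a JSON-serializable report dictionary.
    """
    if dataset and isinstance(dataset[0], TaskSegment):
        dataset = extract_observations(dataset)  # type: ignore[arg-type]
    stream_sets = stream_sets if stream_sets is not None else builtin_stream_sets()

    reports: list[StudyReport] = []
    for ss in stream_sets:
        if progress:
            logger.info("LOSO for stream set %s", ss.name)
        folds = loso_cv(dataset, ss, hmm_config, seed)
        reports.append(
            StudyReport(
                stream_set=ss.name,
                n_folds=len(folds),
                summary=summarize(folds),
                fold_f_values={
                    c: [float(f.per_class[c]["f_value"]) for f in folds]
                    for c in CLASS_ORDER
                },
            )
        )

    def _anova_block(selected: list[StudyReport]) -> dict:
        block: dict = {}
        if len(selected) >= 2:
            for c in CLASS_ORDER:
                groups = [np.array(r.fold_f_values[c]) for r in selected]
                F, p = anova_oneway(groups)
                pmat, sig = tukey_hsd(groups, alpha=alpha)
                block[c] = {
                    "anova_F": F,
                    "anova_p": p,
                    "groups": [r.stream_set for r in selected],
                    "tukey_p": pmat.tolist(),
                    "tukey_significant": sig.tolist(),
                }
        return block

    single = [r for r in reports if not r.stream_set.startswith("MS-")]
    multi = [r for r in reports if r.stream_set.startswith("MS-")]
    return {
        "seed": seed,
        "alpha": alpha,
        "stream_sets": {
            r.stream_set: {
                "n_folds": r.n_folds,
                "summary": {
                    c: {m: {"mean": mv[0], "sd": mv[1]} for m, mv in d.items()}
                    for c, d in r.summary.items()
                },
                "fold_f_values": r.fold_f_values,
            }
            for r in reports
        },
        "anova_single_stream": _anova_block(single),
        "anova_multi_stream": _anova_block(multi),
    }
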