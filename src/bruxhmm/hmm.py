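"""Left-to-right GMM-HMMs with multi-stream emissions.

Each movement class is modelled by a 3-state left-to-right hidden Markov
model: every state may stay or advance to the next state, entry is
forced into the first state, and an optional non-emitting exit state is
reachable from the last emitting state. Emission densities are diagonal
Gaussian mixtures (10 components by default), one mixture per state and
per feature stream; a multi-stream model fuses synchronized streams by
a weighted sum of per-stream log-densities at every frame
(state-synchronous log-linear fusion with unit weights by default).

All probability arithmetic is carried out in the natural-log domain with
log-sum-exp; there is no scaling-coefficient variant. Training is
Baum-Welch (EM), batched over sequences of equal length for speed.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = [
    "GaussianMixture",
    "ClassHMM",
    "Observation",
    "log_emission",
    "forward_loglik",
    "viterbi",
    "init_hmm",
    "baum_welch",
    "sample",
    "save_hmm",
    "load_hmm",
]

LOG0 = -np.inf
#: Mixture-weight floor (renormalized after flooring).
WEIGHT_FLOOR = 1e-5
#: Variance floor as a fraction of the pooled per-dimension variance.
VAR_FLOOR_FRACTION = 1e-3

#: An observation is a mapping stream name -> (T x D_s) feature matrix;
#: all streams must share the frame count T.
Observation = dict[str, np.ndarray]


def _obs_T(obs: Observation) -> int:
    lengths = {name: mat.shape[0] for name, mat in obs.items()}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"streams disagree on frame count: {lengths}")
    return next(iter(lengths.values()))


@dataclass
class GaussianMixture:
    """Diagonal-covariance Gaussian mixture over one feature stream."""

    weights: np.ndarray  # (K,)
    means: np.ndarray    # (K, D)
    variances: np.ndarray  # (K, D), all > 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=np.float64))
        self.variances = np.atleast_2d(np.asarray(self.variances, dtype=np.float64))
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be strictly positive")

    @property
    def n_mix(self) -> int:
        return len(self.weights)

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def component_log_density(self, X: np.ndarray, Xsq: np.ndarray | None = None) -> np.ndarray:
        """Per-component log N(x | mu_k, diag sigma_k^2): (N, K).

        ``Xsq`` (elementwise X**2) may be passed to avoid recomputation
        in tight training loops.
        """
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if Xsq is None:
            Xsq = X * X
        inv = 1.0 / self.variances                     # (K, D)
        const = -0.5 * (self.dim * np.log(2 * np.pi) + np.log(self.variances).sum(axis=1))
        quad = (
            Xsq @ (0.5 * inv).T
            - X @ (self.means * inv).T
            + 0.5 * np.sum(self.means * self.means * inv, axis=1)
        )
        return const[None, :] - quad

    def weighted_component_log_density(
        self, X: np.ndarray, Xsq: np.ndarray | None = None
    ) -> np.ndarray:
        """log(w_k) + per-component log-density: (N, K)."""
        return self.component_log_density(X, Xsq) + np.log(self.weights)[None, :]

    def log_density(self, X: np.ndarray) -> np.ndarray:
        """Mixture log-density per row of X: (N,)."""
        return _logsumexp_rows(self.weighted_component_log_density(X))


def _logsumexp_rows(a: np.ndarray) -> np.ndarray:
    """logsumexp over the last axis (row-wise), faster than the scipy
    generic for the 2-d case used throughout training."""
    m = a.max(axis=-1)
    safe = np.where(np.isfinite(m), m, 0.0)
    with np.errstate(divide="ignore"):
        return safe + np.log(np.exp(a - safe[..., None]).sum(axis=-1))


@dataclass
class ClassHMM:
    """Left-to-right HMM for one movement class.

    ``transition`` is (S+1) x (S+1) row-stochastic over the S emitting
    states plus the non-emitting exit; nonzero entries lie on the
    diagonal and first superdiagonal only. Entry is a point mass on
    state 0. ``emissions[stream][state]`` is a GaussianMixture.
    """

    class_label: str
    n_states: int
    transition: np.ndarray
    emissions: dict[str, list[GaussianMixture]]
    stream_weights: dict[str, float] = field(default_factory=dict)
    require_exit: bool = False
    var_floor: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=np.float64)
        S = self.n_states
        if self.transition.shape != (S + 1, S + 1):
            raise ValueError(f"transition must be ({S + 1}, {S + 1})")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        lower = np.tril(self.transition, -1)
        upper = np.triu(self.transition, 2)
        if np.any(lower != 0) or np.any(upper != 0):
            raise ValueError("left-to-right topology violated (only self/next allowed)")
        for stream, gmms in self.emissions.items():
            if len(gmms) != S:
                raise ValueError(f"stream {stream!r} needs {S} state mixtures")
            self.stream_weights.setdefault(stream, 1.0)

    @property
    def streams(self) -> list[str]:
        return list(self.emissions)

    def log_transition(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.transition)

    def check_streams(self, obs: Observation) -> None:
        missing = set(obs) - set(self.emissions)
        if missing:
            raise KeyError(
                f"observation streams {sorted(missing)} absent from model "
                f"(model streams: {sorted(self.emissions)})"
            )


def frame_log_emissions(hmm: ClassHMM, obs: Observation) -> np.ndarray:
    """Fused per-frame, per-state emission log-density: (T, S).

    For each frame t and emitting state j this is
    sum_s w_s * log p_s(o_{t,s} | state j).
    """
    hmm.check_streams(obs)
    T = _obs_T(obs)
    out = np.zeros((T, hmm.n_states))
    for stream, mats in obs.items():
        w = hmm.stream_weights.get(stream, 1.0)
        if w == 0.0:
            continue
        for j, gmm in enumerate(hmm.emissions[stream]):
            out[:, j] += w * gmm.log_density(mats)
    return out


def log_emission(hmm: ClassHMM, state: int, obs: Observation, t: int) -> float:
    """Fused emission log-density of frame ``t`` (0-based) in ``state``."""
    if not 0 <= state < hmm.n_states:
        raise IndexError(f"state {state} out of range 0..{hmm.n_states - 1}")
    T = _obs_T(obs)
    if not 0 <= t < T:
        raise IndexError(f"frame {t} out of range 0..{T - 1}")
    hmm.check_streams(obs)
    total = 0.0
    for stream, mats in obs.items():
        w = hmm.stream_weights.get(stream, 1.0)
        if w == 0.0:
            continue
        total += w * float(hmm.emissions[stream][state].log_density(mats[t : t + 1])[0])
    return total


def _forward_lattice(hmm: ClassHMM, logB: np.ndarray) -> np.ndarray:
    """Log-alpha over emitting states, (T, S); entry in state 0."""
    T, S = logB.shape
    logA = hmm.log_transition()
    alpha = np.full((T, S), LOG0)
    alpha[0, 0] = logB[0, 0]
    for t in range(1, T):
        stay = alpha[t - 1] + np.diag(logA)[:S]
        move = np.full(S, LOG0)
        move[1:] = alpha[t - 1, :-1] + np.array([logA[i, i + 1] for i in range(S - 1)])
        alpha[t] = np.logaddexp(stay, move) + logB[t]
    return alpha


def forward_loglik(hmm: ClassHMM, obs: Observation) -> float:
    """Total log-likelihood log sum_paths P(path, obs).

    With ``require_exit`` the sum runs only over paths that leave the
    last emitting state into the exit after the final frame.
    """
    T = _obs_T(obs)
    if T == 0:
        raise ValueError("empty observation (T = 0)")
    logB = frame_log_emissions(hmm, obs)
    alpha = _forward_lattice(hmm, logB)
    if hmm.require_exit:
        logA = hmm.log_transition()
        return float(alpha[-1, -1] + logA[hmm.n_states - 1, hmm.n_states])
    return float(logsumexp(alpha[-1]))


def viterbi(hmm: ClassHMM, obs: Observation) -> tuple[np.ndarray, float]:
    """Best monotone state path and its log score.

    Ties in the argmax are broken toward the lower state index, which
    makes decoding deterministic.
    """
    T = _obs_T(obs)
    if T == 0:
        raise ValueError("empty observation (T = 0)")
    logB = frame_log_emissions(hmm, obs)
    S = hmm.n_states
    logA = hmm.log_transition()
    diag = np.array([logA[i, i] for i in range(S)])
    off = np.array([logA[i, i + 1] for i in range(S - 1)])

    delta_ = np.full((T, S), LOG0)
    psi = np.zeros((T, S), dtype=int)
    delta_[0, 0] = logB[0, 0]
    for t in range(1, T):
        stay = delta_[t - 1] + diag
        move = np.full(S, LOG0)
        move[1:] = delta_[t - 1, :-1] + off
        # lower predecessor index wins ties: prefer `move` (from j-1) only
        # when strictly greater than `stay` (from j)... move comes from a
        # lower index, so prefer move on ties.
        take_move = move >= stay
        delta_[t] = np.where(take_move, move, stay) + logB[t]
        psi[t] = np.where(take_move, np.arange(S) - 1, np.arange(S))
        psi[t, 0] = 0
    if hmm.require_exit:
        end_scores = np.full(S, LOG0)
        end_scores[S - 1] = delta_[-1, S - 1] + logA[S - 1, S]
    else:
        end_scores = delta_[-1]
    last = int(np.argmax(end_scores))  # np.argmax takes the lowest index on ties
    score = float(end_scores[last])
    path = np.empty(T, dtype=int)
    path[-1] = last
    for t in range(T - 1, 0, -1):
        path[t - 1] = psi[t, path[t]]
    return path, score


# ---------------------------------------------------------------------------
# initialization

def _default_transition(n_states: int, self_prob: float = 0.6) -> np.ndarray:
    S = n_states
    A = np.zeros((S + 1, S + 1))
    for i in range(S):
        A[i, i] = self_prob
        A[i, i + 1] = 1.0 - self_prob
    A[S, S] = 1.0
    return A


def init_hmm(
    sequences: list[Observation],
    class_label: str,
    n_states: int = 3,
    n_mix: int = 10,
    seed: int = 0,
    stream_weights: dict[str, float] | None = None,
) -> ClassHMM:
    """Segmental k-means initialization.

    Every sequence is split into ``n_states`` contiguous blocks; the
    pooled block-b frames of all sequences initialize state b's mixture
    via k-means (k-means++ start, fixed seed). Transitions start at
    self 0.6 / advance 0.4.
    """
    if not sequences:
        raise ValueError("need at least one training sequence")
    streams = list(sequences[0])
    for seq in sequences:
        if list(seq) != streams:
            raise ValueError("all sequences must carry the same streams")
        if _obs_T(seq) < n_states:
            raise ValueError(f"sequence too short: T must be >= n_states ({n_states})")

    emissions: dict[str, list[GaussianMixture]] = {}
    var_floor: dict[str, np.ndarray] = {}
    for stream in streams:
        pooled_all = np.vstack([seq[stream] for seq in sequences])
        floor = VAR_FLOOR_FRACTION * np.maximum(pooled_all.var(axis=0), 1e-12)
        var_floor[stream] = floor
        gmms = []
        for b in range(n_states):
            block = np.vstack(
                [np.array_split(seq[stream], n_states, axis=0)[b] for seq in sequences]
            )
            # canonical frame order: initialization (and hence training)
            # is invariant to the order of the training sequences
            block = block[np.lexsort(block.T)]
            k = n_mix
            if len(block) < n_mix:
                k = max(1, len(block))
                warnings.warn(
                    f"state {b}, stream {stream!r}: {len(block)} frames < "
                    f"{n_mix} mixtures, reducing to {k}",
                    stacklevel=2,
                )
            if k == 1:
                means = block.mean(axis=0, keepdims=True)
                variances = np.maximum(block.var(axis=0, keepdims=True), floor)
                weights = np.ones(1)
            else:
                # a deterministic subsample is plenty for initial centroids
                if len(block) > 2048:
                    sub_rng = np.random.default_rng(seed)
                    block = block[sub_rng.choice(len(block), 2048, replace=False)]
                km = KMeans(n_clusters=k, n_init=1, max_iter=25, random_state=seed).fit(block)
                labels = km.labels_
                weights = np.array([(labels == c).sum() for c in range(k)], dtype=float)
                weights = np.maximum(weights, 1.0)
                weights /= weights.sum()
                means = km.cluster_centers_
                variances = np.empty_like(means)
                for c in range(k):
                    members = block[labels == c]
                    v = members.var(axis=0) if len(members) > 1 else np.zeros(block.shape[1])
                    variances[c] = np.maximum(v, floor)
            gmms.append(GaussianMixture(weights, means, variances))
        emissions[stream] = gmms

    return ClassHMM(
        class_label=class_label,
        n_states=n_states,
        transition=_default_transition(n_states),
        emissions=emissions,
        stream_weights=dict(stream_weights or {}),
        var_floor=var_floor,
    )


# ---------------------------------------------------------------------------
# Baum-Welch

def _backward_lattice(hmm: ClassHMM, logB: np.ndarray) -> np.ndarray:
    T, S = logB.shape
    logA = hmm.log_transition()
    diag = np.array([logA[i, i] for i in range(S)])
    off = np.array([logA[i, i + 1] for i in range(S - 1)])
    beta = np.full((T, S), 0.0)
    if hmm.require_exit:
        beta[-1] = LOG0
        beta[-1, S - 1] = logA[S - 1, S]
    for t in range(T - 2, -1, -1):
        stay = diag + logB[t + 1] + beta[t + 1]
        move = np.full(S, LOG0)
        move[:-1] = off + logB[t + 1, 1:] + beta[t + 1, 1:]
        beta[t] = np.logaddexp(stay, move)
    return beta


def _group_by_length(sequences: list[Observation]) -> dict[int, list[int]]:
    groups: dict[int, list[int]] = {}
    for i, seq in enumerate(sequences):
        groups.setdefault(_obs_T(seq), []).append(i)
    return groups


def _batch_logB(hmm: ClassHMM, stacked: dict[str, np.ndarray]) -> np.ndarray:
    """Fused emissions for N stacked equal-length sequences: (N, T, S)."""
    first = next(iter(stacked.values()))
    N, T = first.shape[:2]
    out = np.zeros((N, T, hmm.n_states))
    for stream, mats in stacked.items():
        w = hmm.stream_weights.get(stream, 1.0)
        if w == 0.0:
            continue
        flat = mats.reshape(N * T, -1)
        flat_sq = flat * flat
        for j, gmm in enumerate(hmm.emissions[stream]):
            dens = _logsumexp_rows(gmm.weighted_component_log_density(flat, flat_sq))
            out[:, :, j] += w * dens.reshape(N, T)
    return out


def _batch_forward(logA: np.ndarray, logB: np.ndarray) -> np.ndarray:
    """Batched forward lattice: logB (N, T, S) -> log-alpha (N, T, S)."""
    N, T, S = logB.shape
    diag = np.diag(logA)[:S]
    off = np.array([logA[i, i + 1] for i in range(S - 1)])
    alpha = np.full((N, T, S), LOG0)
    alpha[:, 0, 0] = logB[:, 0, 0]
    for t in range(1, T):
        stay = alpha[:, t - 1] + diag
        move = np.full((N, S), LOG0)
        move[:, 1:] = alpha[:, t - 1, :-1] + off
        alpha[:, t] = np.logaddexp(stay, move) + logB[:, t]
    return alpha


def _batch_backward(logA: np.ndarray, logB: np.ndarray, require_exit: bool) -> np.ndarray:
    N, T, S = logB.shape
    diag = np.diag(logA)[:S]
    off = np.array([logA[i, i + 1] for i in range(S - 1)])
    beta = np.zeros((N, T, S))
    if require_exit:
        beta[:, -1] = LOG0
        beta[:, -1, S - 1] = logA[S - 1, S]
    for t in range(T - 2, -1, -1):
        stay = diag + logB[:, t + 1] + beta[:, t + 1]
        move = np.full((N, S), LOG0)
        move[:, :-1] = off + logB[:, t + 1, 1:] + beta[:, t + 1, 1:]
        beta[:, t] = np.logaddexp(stay, move)
    return beta


def baum_welch(
    hmm: ClassHMM,
    sequences: list[Observation],
    max_iter: int = 20,
    rel_tol: float = 1e-4,
) -> tuple[ClassHMM, list[float]]:
    """EM training; returns the trained model and the per-iteration
    total log-likelihood trace (evaluated before each update, plus a
    final evaluation), which is non-decreasing up to numerical slack.

    The left-to-right zero pattern of the transition matrix is
    preserved, and mixture-weight / variance floors are enforced after
    every M-step. Sufficient statistics are pooled over sequences, so
    training is invariant to the order of the training set; the E-step
    is vectorized across sequences of equal length.
    """
    if not sequences:
        raise ValueError("need at least one training sequence")
    streams = hmm.streams
    S = hmm.n_states
    trace: list[float] = []
    groups = _group_by_length(sequences)
    stacked_groups = {
        T: {s: np.stack([sequences[i][s] for i in idx]) for s in streams}
        for T, idx in groups.items()
    }
    # frame matrices are constant across iterations: flatten + square once
    flats = {
        T: {s: stacked[s].reshape(-1, stacked[s].shape[-1]) for s in streams}
        for T, stacked in stacked_groups.items()
    }
    flats_sq = {T: {s: f * f for s, f in fs.items()} for T, fs in flats.items()}

    for iteration in range(max_iter):
        # E-step ----------------------------------------------------------
        total_ll = 0.0
        trans_num = np.zeros((S + 1, S + 1))
        gamma_flat: dict[int, np.ndarray] = {}  # per group: (N*T, S)
        comp_cache: dict[int, dict[str, list[np.ndarray]]] = {}
        logA = hmm.log_transition()
        for T, stacked in stacked_groups.items():
            N = next(iter(stacked.values())).shape[0]
            comp_cache[T] = {}
            logB = np.zeros((N, T, S))
            for stream in streams:
                w = hmm.stream_weights.get(stream, 1.0)
                comps = []
                for j, gmm in enumerate(hmm.emissions[stream]):
                    c = gmm.weighted_component_log_density(
                        flats[T][stream], flats_sq[T][stream]
                    )  # (N*T, K)
                    comps.append(c)
                    if w != 0.0:
                        logB[:, :, j] += w * _logsumexp_rows(c).reshape(N, T)
                comp_cache[T][stream] = comps
            alpha = _batch_forward(logA, logB)
            beta = _batch_backward(logA, logB, hmm.require_exit)
            if hmm.require_exit:
                ll = alpha[:, -1, -1] + logA[S - 1, S]
            else:
                ll = logsumexp(alpha[:, -1], axis=1)
            if not np.all(np.isfinite(ll)):
                raise FloatingPointError(f"non-finite log-likelihood at iteration {iteration}")
            total_ll += float(ll.sum())
            gamma = np.exp(alpha + beta - ll[:, None, None])
            gamma /= np.maximum(gamma.sum(axis=2, keepdims=True), 1e-300)
            gamma_flat[T] = gamma.reshape(-1, S)
            if T > 1:
                for i in range(S):
                    stay = (alpha[:, :-1, i] + logA[i, i] + logB[:, 1:, i]
                            + beta[:, 1:, i] - ll[:, None])
                    trans_num[i, i] += float(np.exp(stay).sum())
                    if i + 1 < S:
                        adv = (alpha[:, :-1, i] + logA[i, i + 1] + logB[:, 1:, i + 1]
                               + beta[:, 1:, i + 1] - ll[:, None])
                        trans_num[i, i + 1] += float(np.exp(adv).sum())
            if hmm.require_exit:
                trans_num[S - 1, S] += logB.shape[0]  # every sequence exits once
        trace.append(total_ll)

        # M-step ----------------------------------------------------------
        newA = np.zeros_like(hmm.transition)
        for i in range(S):
            row = trans_num[i]
            tot = row.sum()
            if tot > 0:
                newA[i] = row / tot
            else:
                newA[i] = hmm.transition[i]
        newA[S, S] = 1.0
        # keep the final emitting state stochastic when no exit is modelled
        if not hmm.require_exit and newA[S - 1].sum() == 0:
            newA[S - 1, S - 1] = 1.0

        new_emissions: dict[str, list[GaussianMixture]] = {s: [] for s in streams}
        group_order = list(stacked_groups)

        def _cat(parts):
            return parts[0] if len(parts) == 1 else np.vstack(parts)

        gamma_cat = _cat([gamma_flat[T] for T in group_order])  # (Nframes, S)
        for stream in streams:
            X = _cat([flats[T][stream] for T in group_order])  # (Nframes, D)
            Xsq = _cat([flats_sq[T][stream] for T in group_order])
            floor = hmm.var_floor.get(
                stream, VAR_FLOOR_FRACTION * np.maximum(X.var(axis=0), 1e-12)
            )
            for j in range(S):
                g_j = gamma_cat[:, j]  # (Nframes,)
                gmm = hmm.emissions[stream][j]
                comp = _cat([comp_cache[T][stream][j] for T in group_order])
                comp = comp - _logsumexp_rows(comp)[:, None]
                resp = np.exp(comp) * g_j[:, None]  # (N, K)
                occ = resp.sum(axis=0)  # (K,)
                occ_safe = np.maximum(occ, 1e-300)
                means = (resp.T @ X) / occ_safe[:, None]
                sq = (resp.T @ Xsq) / occ_safe[:, None]
                variances = np.maximum(sq - means**2, floor)
                weights = np.maximum(occ / max(occ.sum(), 1e-300), WEIGHT_FLOOR)
                weights /= weights.sum()
                # keep parameters of starved components
                dead = occ < 1e-8
                if dead.any():
                    means[dead] = gmm.means[dead]
                    variances[dead] = gmm.variances[dead]
                new_emissions[stream].append(GaussianMixture(weights, means, variances))

        hmm = ClassHMM(
            class_label=hmm.class_label,
            n_states=S,
            transition=newA,
            emissions=new_emissions,
            stream_weights=dict(hmm.stream_weights),
            require_exit=hmm.require_exit,
            var_floor=dict(hmm.var_floor),
        )
        if len(trace) >= 2:
            prev, cur = trace[-2], trace[-1]
            if abs(cur - prev) < rel_tol * max(abs(prev), 1.0):
                break

    # final likelihood under the last parameter set
    trace.append(float(batch_scores(hmm, sequences, statistic="forward").sum()))
    return hmm, trace


def batch_scores(
    hmm: ClassHMM, sequences: list[Observation], statistic: str = "viterbi"
) -> np.ndarray:
    """Viterbi or forward log scores for many sequences at once.

    Equivalent to calling :func:`viterbi` / :func:`forward_loglik` per
    sequence, but vectorized across sequences of equal length.
    """
    if statistic not in ("viterbi", "forward"):
        raise ValueError("statistic must be 'viterbi' or 'forward'")
    S = hmm.n_states
    logA = hmm.log_transition()
    diag = np.diag(logA)[:S]
    off = np.array([logA[i, i + 1] for i in range(S - 1)])
    out = np.empty(len(sequences))
    for T, idx in _group_by_length(sequences).items():
        hmm.check_streams(sequences[idx[0]])
        stacked = {s: np.stack([sequences[i][s] for i in idx]) for s in sequences[idx[0]]}
        logB = _batch_logB(hmm, stacked)
        N = logB.shape[0]
        cur = np.full((N, S), LOG0)
        cur[:, 0] = logB[:, 0, 0]
        for t in range(1, T):
            stay = cur + diag
            move = np.full((N, S), LOG0)
            move[:, 1:] = cur[:, :-1] + off
            if statistic == "viterbi":
                cur = np.maximum(stay, move) + logB[:, t]
            else:
                cur = np.logaddexp(stay, move) + logB[:, t]
        if hmm.require_exit:
            scores = cur[:, S - 1] + logA[S - 1, S]
        elif statistic == "viterbi":
            scores = cur.max(axis=1)
        else:
            scores = logsumexp(cur, axis=1)
        out[idx] = scores
    return out


# ---------------------------------------------------------------------------
# sampling (used by parameter-recovery tests)

def sample(
    hmm: ClassHMM, T_max: int, rng: np.random.Generator
) -> tuple[Observation, np.ndarray]:
    """Draw a state path and per-stream emissions from the model.

    The path starts in state 0 and follows the left-to-right chain until
    the exit is taken or ``T_max`` frames are emitted.
    """
    S = hmm.n_states
    states = []
    s = 0
    for _ in range(T_max):
        states.append(s)
        p = hmm.transition[s, : S + 1]
        s = int(rng.choice(S + 1, p=p))
        if s == S:  # exit
            break
    path = np.array(states, dtype=int)
    obs: Observation = {}
    for stream, gmms in hmm.emissions.items():
        dim = gmms[0].dim
        X = np.empty((len(path), dim))
        for t, st in enumerate(path):
            g = gmms[st]
            k = int(rng.choice(g.n_mix, p=g.weights))
            X[t] = g.means[k] + np.sqrt(g.variances[k]) * rng.standard_normal(dim)
        obs[stream] = X
    return obs, path


# ---------------------------------------------------------------------------
# serialization

_FORMAT_VERSION = 1


def hmm_to_dict(hmm: ClassHMM) -> dict:
    return {
        "format_version": _FORMAT_VERSION,
        "class_label": hmm.class_label,
        "n_states": hmm.n_states,
        "transition": hmm.transition.tolist(),
        "require_exit": hmm.require_exit,
        "stream_weights": hmm.stream_weights,
        "var_floor": {s: v.tolist() for s, v in hmm.var_floor.items()},
        "emissions": {
            stream: [
                {
                    "weights": g.weights.tolist(),
                    "means": g.means.tolist(),
                    "variances": g.variances.tolist(),
                }
                for g in gmms
            ]
            for stream, gmms in hmm.emissions.items()
        },
    }


def hmm_from_dict(doc: dict) -> ClassHMM:
    if doc.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {doc.get('format_version')}")
    emissions = {
        stream: [
            GaussianMixture(
                np.array(g["weights"]), np.array(g["means"]), np.array(g["variances"])
            )
            for g in gmms
        ]
        for stream, gmms in doc["emissions"].items()
    }
    return ClassHMM(
        class_label=doc["class_label"],
        n_states=doc["n_states"],
        transition=np.array(doc["transition"]),
        emissions=emissions,
        stream_weights=dict(doc["stream_weights"]),
        require_exit=doc["require_exit"],
        var_floor={s: np.array(v) for s, v in doc.get("var_floor", {}).items()},
    )


def save_hmm(hmm: ClassHMM, path: str | Path) -> None:
    Path(path).write_text(json.dumps(hmm_to_dict(hmm), indent=1))


def load_hmm(path: str | Path) -> ClassHMM:
    return hmm_from_dict(json.loads(Path(path).read_text()))
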