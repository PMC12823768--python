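"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — explicit loops, direct DFT sums,
exhaustive path enumeration — and shares no code with the package
implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# MFCC: naive DFT loop + explicit filter triangles + explicit DCT sum

def naive_mfcc_frame(
    frame: np.ndarray,
    rate: float,
    n_mel: int,
    n_ceps: int,
    fft_size: int,
    f_min: float,
    f_max: float,
    log_floor: float,
) -> np.ndarray:
    """MFCC of one already-windowed frame, computed from first principles."""
    n = len(frame)
    # naive DFT: per-bin direct correlation with cos/sin (no FFT)
    padded = np.zeros(fft_size)
    padded[:n] = frame
    n_bins = fft_size // 2 + 1
    power = np.zeros(n_bins)
    t_idx = np.arange(fft_size)
    for k in range(n_bins):
        ang = -2.0 * math.pi * k * t_idx / fft_size
        re = float(np.dot(padded, np.cos(ang)))
        im = float(np.dot(padded, np.sin(ang)))
        power[k] = re * re + im * im

    def mel(f):
        return 2595.0 * math.log10(1.0 + f / 700.0)

    def mel_inv(m):
        return 700.0 * (10.0 ** (m / 2595.0) - 1.0)

    pts = [mel_inv(mel(f_min) + i * (mel(f_max) - mel(f_min)) / (n_mel + 1))
           for i in range(n_mel + 2)]
    freqs = np.arange(n_bins) * rate / fft_size
    log_mel = np.zeros(n_mel)
    for m in range(n_mel):
        lo, mid, hi = pts[m], pts[m + 1], pts[m + 2]
        rising = (freqs - lo) / (mid - lo)
        falling = (hi - freqs) / (hi - mid)
        tri = np.clip(np.minimum(rising, falling), 0.0, None)
        log_mel[m] = math.log(max(float(np.dot(tri, power)), log_floor))

    ceps = np.zeros(n_ceps)
    for c in range(n_ceps):
        s = 0.0
        for m in range(n_mel):
            s += log_mel[m] * math.cos(math.pi * c * (2 * m + 1) / (2 * n_mel))
        scale = math.sqrt(1.0 / n_mel) if c == 0 else math.sqrt(2.0 / n_mel)
        ceps[c] = scale * s
    return ceps


def sliding_window_count(n_samples: int, window: int, shift: int) -> int:
    """Count full windows by explicitly sliding (loop, no formula)."""
    count = 0
    start = 0
    while start + window <= n_samples:
        count += 1
        start += shift
    return count


# ---------------------------------------------------------------------------
# HMM: exhaustive enumeration over monotone left-to-right paths

def monotone_paths(n_states: int, T: int):
    """All state paths of length T starting in state 0 with steps in {0, +1}."""
    def rec(path):
        if len(path) == T:
            yield tuple(path)
            return
        s = path[-1]
        nxts = [s] if s == n_states - 1 else [s, s + 1]
        for nxt in nxts:
            yield from rec(path + [nxt])
    yield from rec([0])


def gmm_logpdf(x: np.ndarray, weights, means, variances) -> float:
    """Diagonal-GMM log-density of one vector, direct summation."""
    total = 0.0
    for w, mu, var in zip(weights, means, variances):
        expo = -0.5 * np.sum((x - mu) ** 2 / var)
        norm = np.prod(1.0 / np.sqrt(2.0 * math.pi * var))
        total += w * norm * math.exp(expo)
    return math.log(total)


def path_log_prob(path, trans, logB) -> float:
    lp = 0.0
    for i in range(len(path) - 1):
        a = trans[path[i], path[i + 1]]
        if a == 0:
            return -math.inf
        lp += math.log(a)
    for t, s in enumerate(path):
        lp += logB[t, s]
    return lp


def enum_forward(trans, logB, n_states, require_exit=False) -> float:
    """log sum over all monotone paths of P(path, obs)."""
    T = logB.shape[0]
    total = -math.inf
    for path in monotone_paths(n_states, T):
        lp = path_log_prob(path, trans, logB)
        if require_exit:
            if path[-1] != n_states - 1 or trans[n_states - 1, n_states] == 0:
                continue
            lp += math.log(trans[n_states - 1, n_states])
        total = np.logaddexp(total, lp)
    return float(total)


def enum_viterbi(trans, logB, n_states, require_exit=False):
    """(best path, best log score) by exhaustive search."""
    T = logB.shape[0]
    best, best_path = -math.inf, None
    for path in monotone_paths(n_states, T):
        lp = path_log_prob(path, trans, logB)
        if require_exit:
            if path[-1] != n_states - 1 or trans[n_states - 1, n_states] == 0:
                continue
            lp += math.log(trans[n_states - 1, n_states])
        if lp > best:
            best, best_path = lp, path
    return best_path, float(best)


def random_lr_hmm(rng, n_states, n_mix, dim, n_streams=1):
    """A random left-to-right GMM-HMM in plain-arrays form:
    (trans, {stream: [(weights, means, vars)] per state})."""
    trans = np.zeros((n_states + 1, n_states + 1))
    for i in range(n_states):
        p = rng.uniform(0.2, 0.9)
        trans[i, i] = p
        trans[i, i + 1] = 1.0 - p
    trans[n_states, n_states] = 1.0
    streams = {}
    for s in range(n_streams):
        per_state = []
        for _ in range(n_states):
            w = rng.dirichlet(np.ones(n_mix))
            mu = rng.normal(0.0, 2.0, (n_mix, dim))
            var = rng.uniform(0.3, 2.0, (n_mix, dim))
            per_state.append((w, mu, var))
        streams[f"s{s}"] = per_state
    return trans, streams
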