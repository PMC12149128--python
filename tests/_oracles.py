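"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive (direct summation, exhaustive
enumeration) and shares no code with the package internals.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def rms_envelope_naive(x: np.ndarray, n: int) -> np.ndarray:
    """Direct-summation centred RMS with edge truncation."""
    x = np.asarray(x, dtype=float)
    N = len(x)
    h = n // 2
    out = np.empty(N)
    for i in range(N):
        w = x[max(0, i - h) : min(N - 1, i + h) + 1]
        out[i] = math.sqrt(sum(v * v for v in w) / len(w))
    return out


def window_energy_naive(x: np.ndarray, n: int) -> np.ndarray:
    """Direct-summation centred window sum of squares."""
    x = np.asarray(x, dtype=float)
    N = len(x)
    h = n // 2
    return np.array(
        [sum(v * v for v in x[max(0, i - h) : min(N - 1, i + h) + 1]) for i in range(N)]
    )


def moments_naive(e: np.ndarray) -> tuple[float, float]:
    """Two-pass population skewness and kurtosis."""
    e = np.asarray(e, dtype=float)
    m = sum(e) / len(e)
    var = sum((v - m) ** 2 for v in e) / len(e)
    sd = math.sqrt(var)
    skew = sum(((v - m) / sd) ** 3 for v in e) / len(e)
    kurt = sum(((v - m) / sd) ** 4 for v in e) / len(e)
    return skew, kurt


def auc_rank_naive(scores: np.ndarray, labels: np.ndarray) -> float:
    """Pairwise-comparison AUC (ties count half). O(n_pos * n_neg)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return float(wins) / (len(pos) * len(neg))


def hull_vertices_naive(pts: np.ndarray) -> set[int]:
    """Extreme points of a 2-D set by exhaustive edge test, O(n^3).

    A directed pair (i, j) is a hull edge iff every other point lies
    strictly to one side; assumes general position (no 3 collinear).
    """
    n = len(pts)
    verts: set[int] = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = pts[j] - pts[i]
            others = np.delete(np.arange(n), [i, j])
            cross = d[0] * (pts[others, 1] - pts[i, 1]) - d[1] * (pts[others, 0] - pts[i, 0])
            if (cross > 0).all() or (cross < 0).all():
                verts.update((i, j))
    return verts


def hull_distance_naive(pts2: np.ndarray) -> float:
    """Mean hull-vertex-to-centroid distance via the exhaustive hull."""
    idx = sorted(hull_vertices_naive(pts2))
    v = pts2[idx]
    c = v.mean(axis=0)
    return float(np.mean(np.hypot(v[:, 0] - c[0], v[:, 1] - c[1])))


def wilcoxon_exact_naive(diffs: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank p by enumerating all sign patterns.

    Zero differences must already be removed; tied |d| get average ranks.
    Returns (W_plus_observed, p).
    """
    d = np.asarray(diffs, dtype=float)
    n = len(d)
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    ws = []
    for signs in itertools.product((0, 1), repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws, dtype=float)
    m = len(ws)
    p_low = np.sum(ws <= w_obs) / m
    p_high = np.sum(ws >= w_obs) / m
    return w_obs, min(1.0, 2.0 * min(p_low, p_high))


def mask_from_intervals_naive(
    intervals, fs: float, duration_s: float
) -> np.ndarray:
    """Per-sample membership test: sample i is 1 iff floor/ceil-quantised
    half-open interval covers index i."""
    n = int(round(duration_s * fs))
    out = np.zeros(n, dtype=int)
    for i in range(n):
        for s, e in intervals:
            if math.floor(s * fs) <= i < math.ceil(e * fs):
                out[i] = 1
    return out
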