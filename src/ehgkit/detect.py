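"""Energy-threshold contraction detection and ROC evaluation against TOCO.

A sample is called "contraction" when its windowed energy strictly exceeds a
threshold. Thresholds are swept over a z-score grid built from the energy
series itself -- mu + k * 0.05 * sigma for k = -60..60 (121 thresholds from
mu - 3 sigma to mu + 3 sigma) -- and each threshold's prediction mask is
scored per sample against the tocodynamometer-derived binary mask, giving a
(FPR, TPR) point. The curve is anchored at (0,0) and (1,1) and integrated by
the trapezoid rule for the AUC. The operating threshold is the one
maximising Youden's J = TPR - FPR (ties resolved toward the lower threshold,
i.e. higher sensitivity).

``rank_auc`` provides the threshold-free Mann-Whitney AUC of the same
energies; the grid AUC converges to it as the grid refines and is used as a
cross-check in tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enhance import DEFAULT_WINDOW
from .io import BinaryMask, ElectrodeLayout, Recording
from .metrics import window_energy

__all__ = [
    "detect_mask",
    "ThresholdGrid",
    "build_threshold_grid",
    "RocResult",
    "roc_against_mask",
    "rank_auc",
    "channel_auc_map",
]

GRID_HALF_STEPS = 60  # +-3 sigma in 0.05 sigma steps


def detect_mask(e: np.ndarray, thr: float, fs: float | None = None) -> BinaryMask:
    """Binary contraction mask: 1 where energy strictly exceeds ``thr``."""
    if not np.isfinite(thr):
        raise ValueError(f"threshold must be finite, got {thr}")
    e = np.asarray(e, dtype=float)
    return BinaryMask((e > thr).astype(np.uint8), fs if fs is not None else 1.0)


@dataclass(frozen=True)
class ThresholdGrid:
    """z-score threshold grid mu + k*0.05*sd, k = -60..60."""

    mu: float
    sd: float
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


def build_threshold_grid(e: np.ndarray) -> ThresholdGrid:
    """121 strictly increasing thresholds spanning mu +- 3 sigma.

    mu and sigma are the mean and sample standard deviation of the *full*
    (untrimmed) energy series.
    """
    e = np.asarray(e, dtype=float)
    mu = float(e.mean())
    sd = float(e.std(ddof=1))
    if sd == 0:
        raise ValueError("zero energy variance: threshold grid undefined")
    k = np.arange(-GRID_HALF_STEPS, GRID_HALF_STEPS + 1)
    return ThresholdGrid(mu, sd, mu + k * 0.05 * sd)


@dataclass
class RocResult:
    """Threshold sweep of an energy detector against a reference mask."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    optimal_threshold: float
    youden_j: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "tpr": self.tpr, "fpr": self.fpr}
        )


def _counts(e: np.ndarray, truth: np.ndarray, thresholds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pos = truth == 1
    pred = e[None, :] > thresholds[:, None]
    tp = (pred & pos[None, :]).sum(axis=1)
    fp = (pred & ~pos[None, :]).sum(axis=1)
    return tp, fp


def roc_against_mask(
    e: np.ndarray,
    truth: BinaryMask | np.ndarray,
    grid: ThresholdGrid | None = None,
) -> RocResult:
    """Grid ROC of windowed energies against a per-sample binary mask.

    TPR and FPR are counted per sample at the mask's rate; the curve is
    integrated with (0,0)/(1,1) anchors. Raises if the mask holds a single
    class (rates would be undefined).
    """
    e = np.asarray(e, dtype=float)
    t = truth.values if isinstance(truth, BinaryMask) else np.asarray(truth)
    if e.shape != t.shape:
        raise ValueError(f"energy/mask length mismatch: {e.shape} vs {t.shape}")
    if t.min() == t.max():
        raise ValueError("reference mask contains a single class; ROC undefined")
    if grid is None:
        grid = build_threshold_grid(e)
    n_pos = int((t == 1).sum())
    n_neg = int((t == 0).sum())
    tp, fp = _counts(e, t, grid.values)
    tpr, fpr = tp / n_pos, fp / n_neg
    order = np.lexsort((tp, fp))  # ascending fpr, ties by ascending tpr
    # trapezoid rule in integer counts (exact), anchored at (0,0) and (1,1)
    fpx = np.concatenate(([0], fp[order], [n_neg]))
    tpy = np.concatenate(([0], tp[order], [n_pos]))
    area2 = int(np.sum(np.diff(fpx) * (tpy[1:] + tpy[:-1])))
    auc = area2 / (2 * n_pos * n_neg)
    j = tpr - fpr
    best = int(np.argmax(j))  # thresholds ascend, argmax -> lowest threshold on ties
    return RocResult(grid.values, tpr, fpr, auc, float(grid.values[best]), float(j[best]))


def rank_auc(e: np.ndarray, truth: BinaryMask | np.ndarray) -> float:
    """Exact (threshold-free) AUC via the Mann-Whitney U statistic.

    Equals the probability that a randomly chosen contraction-sample energy
    exceeds a randomly chosen baseline one, ties counted half.
    """
    e = np.asarray(e, dtype=float)
    t = truth.values if isinstance(truth, BinaryMask) else np.asarray(truth)
    if t.min() == t.max():
        raise ValueError("reference mask contains a single class; AUC undefined")
    pos = e[t == 1]
    neg = e[t == 0]
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u / (len(pos) * len(neg)))


def channel_auc_map(
    rec: Recording,
    truth: BinaryMask,
    layout: ElectrodeLayout | None = None,
    n: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Grid AUC of every channel of a recording against the reference mask.

    Returns one row per channel (channel_id, auc, optimal_threshold,
    youden_j), joined to electrode coordinates when a layout is given.
    Channels should already have passed quality screening.
    """
    if len(truth) != rec.n_samples:
        raise ValueError(
            f"mask length {len(truth)} does not match recording length {rec.n_samples}"
        )
    rows = []
    for cid in rec.channel_ids:
        roc = roc_against_mask(window_energy(rec.channel(cid), n), truth)
        rows.append(
            {
                "channel_id": cid,
                "auc": roc.auc,
                "optimal_threshold": roc.optimal_threshold,
                "youden_j": roc.youden_j,
            }
        )
    table = pd.DataFrame(rows)
    if layout is not None:
        table = table.merge(layout.table, on="channel_id", how="left", validate="1:1")
    return table
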