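"""Windowed-energy signal-quality metrics: skewness, kurtosis and PAER.

The channel signal is scanned with the same centred, edge-truncated sliding
window used for the RMS envelope; each window contributes one energy value
(sum of squared samples). The histogram of these energies has two modes --
baseline noise and contraction bursts -- and the three metrics quantify how
separable they are:

* skewness (standardised third central moment, population form): grows as
  the baseline mass concentrates near zero;
* kurtosis (standardised fourth central moment, NOT excess): heavier
  contraction tail, larger value;
* PAER, peak-to-average-energy ratio, 10*log10(max(e)^2 / mean(e)^2) in dB:
  contrast between the strongest window and the average.

Spike artifacts inflate all three, so energies above the empirical 0.95
quantile are discarded before the metrics are computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enhance import DEFAULT_WINDOW, sliding_window_sums
from .io import Recording

__all__ = [
    "window_energy",
    "trim_energies",
    "skewness",
    "kurtosis",
    "paer",
    "QualityMetrics",
    "channel_metrics",
    "recording_metrics",
]


def window_energy(x: np.ndarray, n: int = DEFAULT_WINDOW) -> np.ndarray:
    """Per-index sum of squares over centred edge-truncated windows.

    Stride is one sample, so the output aligns with (and has the length of)
    the input. Interior windows hold ``n//2 * 2 + 1`` samples.
    """
    sums, _ = sliding_window_sums(np.asarray(x, dtype=float) ** 2, n)
    return np.maximum(sums, 0.0)


def trim_energies(e: np.ndarray, q: float = 0.95) -> np.ndarray:
    """Drop energies above the empirical ``q``-quantile (spike-artifact guard).

    Uses the linear-interpolation quantile; values equal to the quantile are
    retained. Discarding (rather than clipping) bounds artifact influence on
    all three metrics, including PAER's maximum.
    """
    if not 0 < q < 1:
        raise ValueError(f"quantile must be in (0, 1), got {q}")
    e = np.asarray(e, dtype=float)
    if e.size == 0:
        raise ValueError("empty energy series")
    thr = np.quantile(e, q)
    return e[e <= thr]


def _standardised_moment(e: np.ndarray, k: int) -> float:
    e = np.asarray(e, dtype=float)
    m = e.mean()
    sd = np.sqrt(np.mean((e - m) ** 2))  # population sd
    if sd == 0:
        raise ValueError("zero variance: standardised moment undefined")
    return float(np.mean(((e - m) / sd) ** k))


def skewness(e: np.ndarray) -> float:
    """Standardised third central moment (population, divisor N)."""
    e = np.asarray(e, dtype=float)
    if e.size < 3:
        raise ValueError("need at least 3 energy values for skewness")
    return _standardised_moment(e, 3)


def kurtosis(e: np.ndarray) -> float:
    """Standardised fourth central moment (population; 3 for a Gaussian)."""
    e = np.asarray(e, dtype=float)
    if e.size < 4:
        raise ValueError("need at least 4 energy values for kurtosis")
    return _standardised_moment(e, 4)


def paer(e: np.ndarray) -> float:
    """Peak-to-average-energy ratio, 20*log10(max(e)/mean(e)) dB."""
    e = np.asarray(e, dtype=float)
    if e.size == 0:
        raise ValueError("empty energy series")
    m = e.mean()
    if m <= 0:
        raise ValueError("PAER undefined for non-positive mean energy")
    return float(20.0 * np.log10(e.max() / m))


@dataclass(frozen=True)
class QualityMetrics:
    """Channel-level metric triple after quantile trimming."""

    skewness: float
    kurtosis: float
    paer: float
    n_used: int


def channel_metrics(x: np.ndarray, n: int = DEFAULT_WINDOW, q: float = 0.95) -> QualityMetrics:
    """window_energy -> trim_energies -> (skewness, kurtosis, PAER)."""
    x = np.asarray(x, dtype=float)
    if x.size and np.ptp(x) == 0:
        raise ValueError("constant channel: quality metrics undefined")
    e = trim_energies(window_energy(x, n), q)
    return QualityMetrics(skewness(e), kurtosis(e), paer(e), int(e.size))


def recording_metrics(
    rec: Recording, n: int = DEFAULT_WINDOW, q: float = 0.95
) -> pd.DataFrame:
    """One metric row per channel; columns channel_id, band, skewness, kurtosis, paer, n_used."""
    rows = []
    for cid in rec.channel_ids:
        m = channel_metrics(rec.channel(cid), n, q)
        rows.append(
            {
                "channel_id": cid,
                "band": rec.band,
                "skewness": m.skewness,
                "kurtosis": m.kurtosis,
                "paer": m.paer,
                "n_used": m.n_used,
            }
        )
    return pd.DataFrame(rows)
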