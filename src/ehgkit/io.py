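"""Readers/writers for recordings, electrode layouts and contraction masks.

On-disk conventions
-------------------
* Recordings: delimited CSV. First line is a comment header
  ``# fs=<Hz> band=<tag>``, second line the channel ids, then one row per
  sample (channels in columns). Diff-able and round-trip exact. EDF input is
  supported through :mod:`mne` when it is installed.
* Electrode layouts: CSV with columns ``channel_id,x,y,z`` (millimetres,
  y = anterior -> posterior).
* Contraction masks: either a per-sample 0/1 column (with a ``# fs=`` header)
  or an interval list with columns ``start_s,end_s``; intervals are half-open
  ``[start, end)`` in seconds.

Sample indexing is 0-based everywhere; a sample index i corresponds to time
i / fs seconds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "BinaryMask",
    "ElectrodeLayout",
    "read_recording",
    "write_recording",
    "read_mask",
    "write_mask",
    "mask_from_intervals",
    "read_layout",
    "write_layout",
]

VALID_BANDS = ("raw", "slow", "fast", "enhanced")


@dataclass
class Recording:
    """Multi-channel voltage recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Voltage samples in millivolts.
    fs : float
        Sampling rate in Hz.
    channel_ids : sequence of str
        Unique channel labels, one per row of ``data``.
    band : str
        One of ``raw``, ``slow``, ``fast``, ``enhanced``. Enhanced-band
        samples are in mV^2 (product of a voltage and an RMS envelope).
    meta : dict
        Free-form provenance (band edges, edge-transient extent, ...).
    """

    data: np.ndarray
    fs: float
    channel_ids: Sequence[str]
    band: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.channel_ids = [str(c) for c in self.channel_ids]
        if len(self.channel_ids) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_ids)} channel ids for {self.data.shape[0]} rows"
            )
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel ids must be unique")
        if self.band not in VALID_BANDS:
            raise ValueError(f"band must be one of {VALID_BANDS}, got {self.band!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, channel_id: str) -> np.ndarray:
        """Return the sample vector for one channel."""
        try:
            idx = self.channel_ids.index(str(channel_id))
        except ValueError:
            raise KeyError(f"no channel {channel_id!r}") from None
        return self.data[idx]

    def select(self, channel_ids: Iterable[str]) -> "Recording":
        """Sub-recording restricted to ``channel_ids`` (kept in given order)."""
        ids = [str(c) for c in channel_ids]
        idx = [self.channel_ids.index(c) for c in ids]
        return Recording(self.data[idx].copy(), self.fs, ids, self.band, dict(self.meta))

    def validate_finite(self) -> None:
        """Raise naming the first offending channel if any sample is NaN/Inf."""
        bad = ~np.isfinite(self.data)
        if bad.any():
            ch = self.channel_ids[int(np.argmax(bad.any(axis=1)))]
            raise ValueError(f"non-finite samples in channel {ch!r}")


@dataclass
class BinaryMask:
    """Per-sample 0/1 contraction mask at sampling rate ``fs``."""

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if not np.isin(v, (0, 1)).all():
            raise ValueError("mask entries must be 0 or 1")
        self.values = v.astype(np.uint8)
        if self.fs <= 0:
            raise ValueError("mask sampling rate must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def positive_fraction(self) -> float:
        return float(self.values.mean()) if len(self.values) else 0.0


@dataclass
class ElectrodeLayout:
    """Mapping channel_id -> (x, y, z) electrode coordinates in mm."""

    table: pd.DataFrame  # columns: channel_id, x, y, z

    def __post_init__(self) -> None:
        required = ["channel_id", "x", "y", "z"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"layout missing columns {missing}")
        t = self.table[required].copy()
        t["channel_id"] = t["channel_id"].astype(str)
        if t["channel_id"].duplicated().any():
            dup = t.loc[t["channel_id"].duplicated(), "channel_id"].iloc[0]
            raise ValueError(f"duplicate channel id {dup!r} in layout")
        coords = t[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.isfinite(coords).all():
            bad_rows = np.nonzero(~np.isfinite(coords).all(axis=1))[0]
            raise ValueError(f"non-finite coordinate in layout row {int(bad_rows[0])}")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def channel_ids(self) -> list[str]:
        return self.table["channel_id"].tolist()

    def coords(self, channel_ids: Iterable[str] | None = None) -> np.ndarray:
        """(n, 3) coordinate array for the given channels (all if None)."""
        if channel_ids is None:
            return self.table[["x", "y", "z"]].to_numpy(dtype=float)
        lookup = self.table.set_index("channel_id")
        ids = [str(c) for c in channel_ids]
        missing = [c for c in ids if c not in lookup.index]
        if missing:
            raise KeyError(f"layout lacks coordinates for channels {missing}")
        return lookup.loc[ids, ["x", "y", "z"]].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Recordings
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording in the delimited dialect (samples in rows)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={rec.fs!r} band={rec.band}\n")
        fh.write(",".join(rec.channel_ids) + "\n")
        np.savetxt(fh, rec.data.T, delimiter=",", fmt="%.17g")


def _read_delimited(path: Path) -> Recording:
    with path.open() as fh:
        header = fh.readline().strip()
        if not header.startswith("# fs="):
            raise ValueError(f"{path}: malformed header (expected '# fs=<Hz> ...')")
        fields = dict(
            tok.split("=", 1) for tok in header[2:].split() if "=" in tok
        )
        try:
            fs = float(fields["fs"])
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{path}: malformed fs in header") from exc
        band = fields.get("band", "raw")
        ids = [c.strip() for c in fh.readline().strip().split(",")]
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    return Recording(data.T, fs, ids, band)


def _read_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise ImportError(
            "reading EDF requires the optional 'mne' dependency; "
            "install ehgkit[edf] or convert to the delimited format"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data()  # volts
    return Recording(data * 1e3, float(raw.info["sfreq"]), list(raw.ch_names), "raw")


def read_recording(path: str | Path, format: str = "delimited") -> Recording:
    """Load a recording and validate that every sample is finite.

    ``format`` is ``"delimited"`` (the package's CSV dialect) or ``"edf"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "delimited":
        rec = _read_delimited(path)
    elif format == "edf":
        rec = _read_edf(path)
    else:
        raise ValueError(f"unknown recording format {format!r}")
    rec.validate_finite()
    return rec


# ---------------------------------------------------------------------------
# Masks
# ---------------------------------------------------------------------------

def mask_from_intervals(
    intervals: Sequence[tuple[float, float]],
    fs: float,
    duration_s: float,
) -> BinaryMask:
    """Rasterise half-open ``[start, end)`` second intervals to a 0/1 series.

    Start times are floored and end times ceiled to sample indices, so a
    contraction is never shortened by quantisation. Overlapping intervals are
    merged with a warning; negative times are an error.
    """
    n = int(round(duration_s * fs))
    values = np.zeros(n, dtype=np.uint8)
    prev_end = None
    for start, end in sorted(intervals):
        if start < 0 or end < 0:
            raise ValueError(f"negative interval time ({start}, {end})")
        if end < start:
            raise ValueError(f"interval end before start ({start}, {end})")
        if prev_end is not None and start < prev_end:
            warnings.warn(
                f"overlapping mask intervals merged at t={start:g}s", stacklevel=2
            )
        prev_end = max(prev_end, end) if prev_end is not None else end
        i0 = int(math.floor(start * fs))
        i1 = int(math.ceil(end * fs))
        values[i0 : min(i1, n)] = 1
    return BinaryMask(values, fs)


def read_mask(path: str | Path, fs_target: float, duration_s: float | None = None) -> BinaryMask:
    """Read a contraction mask, as intervals or as a per-sample series.

    Interval files need columns ``start_s,end_s`` and require ``duration_s``.
    Per-sample files carry their own ``# fs=`` header; ``fs_target`` must
    match it (resampling a 0/1 series is ambiguous, so it is not attempted).
    """
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().strip()
    if first.startswith("# fs="):
        with path.open() as fh:
            header = fh.readline().strip()
            fs = float(header[2:].split()[0].split("=", 1)[1])
            values = np.loadtxt(fh, delimiter=",", ndmin=1)
        if not math.isclose(fs, fs_target, rel_tol=1e-9):
            raise ValueError(
                f"per-sample mask stored at {fs} Hz, requested {fs_target} Hz"
            )
        return BinaryMask(values, fs)
    table = pd.read_csv(path)
    if not {"start_s", "end_s"} <= set(table.columns):
        raise ValueError(f"{path}: expected 'start_s,end_s' columns or '# fs=' header")
    intervals = list(zip(table["start_s"], table["end_s"]))
    if duration_s is None:
        duration_s = float(table["end_s"].max()) if len(table) else 0.0
    return mask_from_intervals(intervals, fs_target, duration_s)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a per-sample mask with its ``# fs=`` header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={mask.fs!r}\n")
        np.savetxt(fh, mask.values, fmt="%d")


def write_intervals(intervals: Sequence[tuple[float, float]], path: str | Path) -> None:
    """Write an interval-list mask (columns start_s,end_s)."""
    pd.DataFrame(intervals, columns=["start_s", "end_s"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Layouts
# ---------------------------------------------------------------------------

def read_layout(path: str | Path) -> ElectrodeLayout:
    """Read a ``channel_id,x,y,z`` CSV layout (mm)."""
    table = pd.read_csv(path)
    required = ["channel_id", "x", "y", "z"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: layout missing columns {missing}")
    for col in ("x", "y", "z"):
        bad = table[col].isna()
        if bad.any():
            raise ValueError(f"{path}: missing coordinate {col} in row {int(bad.idxmax())}")
    return ElectrodeLayout(table)


def write_layout(layout: ElectrodeLayout, path: str | Path) -> None:
    layout.table.to_csv(path, index=False, float_format="%.9f")
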