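"""Spatial consistency and signaling-distance analysis over electrode arrays.

Channels whose detector AUC against the TOCO mask reaches 0.8 are called
"high-consistency": their energy time course tracks the mechanically
recorded contractions. How far such channels spread over the abdomen is a
proxy for how far the detectable contraction signal propagates.

The signaling distance collapses the anterior-posterior (y) axis, takes the
2-D convex hull of the remaining (x, z) electrode positions, and averages
the Euclidean distance from each hull vertex to the vertex centroid. The
alternative reading -- measuring in full 3-D coordinates at the hull
vertices found in projection -- is available with ``projected=False``.

Growth ratios compare a quantity between the fast-wave and the enhanced
signal: r = (v_enhanced - v_fast) / v_fast.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .io import ElectrodeLayout

__all__ = [
    "ConsistencySet",
    "high_consistency",
    "channel_growth_ratio",
    "HullDistance",
    "signaling_distance",
    "distance_growth_ratio",
    "spatial_comparison",
]

DEFAULT_AUC_THRESHOLD = 0.8


@dataclass
class ConsistencySet:
    """Channels whose AUC reaches the consistency threshold (inclusive)."""

    channel_ids: list[str]
    auc_threshold: float

    @property
    def count(self) -> int:
        return len(self.channel_ids)


def high_consistency(
    auc_map: pd.DataFrame | Mapping[str, float],
    threshold: float = DEFAULT_AUC_THRESHOLD,
) -> ConsistencySet:
    """Select channels with AUC >= threshold from an AUC table or mapping."""
    if isinstance(auc_map, pd.DataFrame):
        items = list(zip(auc_map["channel_id"].astype(str), auc_map["auc"]))
    else:
        items = [(str(k), v) for k, v in auc_map.items()]
    ids = [cid for cid, auc in items if auc >= threshold]
    return ConsistencySet(ids, threshold)


def channel_growth_ratio(ch_f: int, ch_e: int) -> float:
    """Growth ratio of high-consistency channel count, (ch_e - ch_f) / ch_f."""
    if ch_f == 0:
        raise ZeroDivisionError("growth ratio undefined: no fast-wave channels")
    return (ch_e - ch_f) / ch_f


def distance_growth_ratio(d_f: float, d_e: float) -> float:
    """Growth ratio of signaling distance, (d_e - d_f) / d_f."""
    if d_f == 0:
        raise ZeroDivisionError("growth ratio undefined: zero fast-wave distance")
    return (d_e - d_f) / d_f


@dataclass
class HullDistance:
    """Convex-hull signaling-distance result.

    ``distance`` is the mean distance of hull vertices to their centroid
    (mm); vertices are listed counterclockwise starting from the
    lexicographically smallest projected point. Collinear boundary
    electrodes are not vertices (strict hull).
    """

    vertex_ids: list[str]
    centroid: np.ndarray
    distance: float


def _segment_extremes(pts: np.ndarray) -> tuple[int, int]:
    # extreme points of a (possibly degenerate) collinear set
    centred = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    proj = centred @ vt[0]
    return int(np.argmin(proj)), int(np.argmax(proj))


def _order_ccw(pts2: np.ndarray, vert_idx: np.ndarray) -> np.ndarray:
    # scipy returns CCW order already; rotate to start at lexicographic min
    coords = pts2[vert_idx]
    start = np.lexsort((coords[:, 1], coords[:, 0]))[0]
    return np.roll(vert_idx, -start)


def signaling_distance(
    channels: ConsistencySet | Sequence[str],
    layout: ElectrodeLayout,
    projected: bool = True,
) -> HullDistance:
    """Mean hull-vertex-to-centroid distance of high-consistency electrodes.

    With ``projected=True`` (default) coordinates are first projected along
    the anterior-posterior axis (y set to 0) and everything -- hull,
    centroid, distances -- lives in the x-z plane. With ``projected=False``
    the hull vertices are still found in projection but the centroid and
    distances use their full 3-D coordinates.

    Degenerate sets: a single electrode gives d = 0; two electrodes or a
    collinear set reduce to the segment extremes, giving d = half the
    segment length.
    """
    ids = list(channels.channel_ids if isinstance(channels, ConsistencySet) else channels)
    ids = [str(c) for c in ids]
    if not ids:
        raise ValueError("empty channel set: signaling distance undefined")
    xyz = layout.coords(ids)
    pts2 = xyz[:, [0, 2]]  # collapse y (anterior -> posterior)

    uniq = np.unique(pts2, axis=0)
    if len(uniq) == 1:
        return HullDistance([ids[0]], _vertex_centroid(xyz, [0], projected), 0.0)
    if len(uniq) == 2:
        vert_idx = np.array(_segment_extremes(pts2))
    else:
        try:
            hull = ConvexHull(pts2)
            vert_idx = _order_ccw(pts2, hull.vertices)
        except QhullError:  # collinear set
            vert_idx = np.array(_segment_extremes(pts2))

    verts = xyz[vert_idx] if not projected else np.column_stack(
        [pts2[vert_idx][:, 0], np.zeros(len(vert_idx)), pts2[vert_idx][:, 1]]
    )
    centroid = verts.mean(axis=0)
    d = float(np.linalg.norm(verts - centroid, axis=1).mean())
    return HullDistance([ids[i] for i in vert_idx], centroid, d)


def _vertex_centroid(xyz: np.ndarray, idx: Iterable[int], projected: bool) -> np.ndarray:
    v = xyz[list(idx)].astype(float).copy()
    if projected:
        v[:, 1] = 0.0
    return v.mean(axis=0)


def spatial_comparison(
    auc_fast: pd.DataFrame,
    auc_enhanced: pd.DataFrame,
    layout: ElectrodeLayout,
    threshold: float = DEFAULT_AUC_THRESHOLD,
    projected: bool = True,
) -> pd.DataFrame:
    """Fast vs enhanced consistency/hull summary (one row per band + ratios).

    Columns: band, ch (high-consistency count), d_mm (signaling distance),
    r_c and r_d on the ratio row, hull_vertices.
    """
    rows = []
    sets = {}
    dists = {}
    for band, table in (("fast", auc_fast), ("enhanced", auc_enhanced)):
        cs = high_consistency(table, threshold)
        sets[band] = cs
        if cs.count:
            hd = signaling_distance(cs, layout, projected)
            dists[band] = hd.distance
            verts = ";".join(hd.vertex_ids)
        else:
            dists[band] = np.nan
            verts = ""
        rows.append(
            {"band": band, "ch": cs.count, "d_mm": dists[band], "r_c": np.nan,
             "r_d": np.nan, "hull_vertices": verts}
        )
    r_c = (
        channel_growth_ratio(sets["fast"].count, sets["enhanced"].count)
        if sets["fast"].count
        else np.nan
    )
    r_d = (
        distance_growth_ratio(dists["fast"], dists["enhanced"])
        if dists["fast"] and np.isfinite(dists["fast"])
        else np.nan
    )
    rows.append(
        {"band": "ratio", "ch": np.nan, "d_mm": np.nan, "r_c": r_c, "r_d": r_d,
         "hull_vertices": ""}
    )
    return pd.DataFrame(rows)
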