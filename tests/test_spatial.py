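import numpy as np
import pandas as pd
import pytest

from ehgkit import (
    ElectrodeLayout,
    channel_growth_ratio,
    distance_growth_ratio,
    high_consistency,
    signaling_distance,
)
from ehgkit.spatial import spatial_comparison

import _oracles


def layout_from(coords, ids=None):
    coords = np.asarray(coords, dtype=float)
    ids = ids or [f"ch{i}" for i in range(len(coords))]
    return ElectrodeLayout(
        pd.DataFrame({"channel_id": ids, "x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2]})
    )


class TestHighConsistency:
    def test_threshold_is_inclusive(self):
        cs = high_consistency({"a": 0.79, "b": 0.80, "c": 0.95})
        assert sorted(cs.channel_ids) == ["b", "c"]

    def test_empty_map(self):
        assert high_consistency({}).count == 0

    def test_zero_threshold_keeps_all(self):
        assert high_consistency({"a": 0.1, "b": 0.2}, threshold=0.0).count == 2


class TestGrowthRatios:
    def test_channel_ratio_examples(self):
        assert round(channel_growth_ratio(50, 55), 2) == 0.1
        assert round(channel_growth_ratio(7, 13), 2) == 0.86

    def test_no_growth(self):
        assert channel_growth_ratio(31, 31) == 0.0
        assert distance_growth_ratio(120.0, 120.0) == 0.0

    def test_distance_ratio_examples(self):
        assert round(distance_growth_ratio(77.0, 110.0), 2) == 0.43
        assert round(distance_growth_ratio(166.0, 174.0), 2) == 0.05

    def test_zero_baseline_rejected(self):
        with pytest.raises(ZeroDivisionError):
            channel_growth_ratio(0, 5)
        with pytest.raises(ZeroDivisionError):
            distance_growth_ratio(0.0, 5.0)


class TestSignalingDistance:
    def test_unit_square_in_xz_plane(self):
        # y varies but is projected away
        coords = [(1, 5, 1), (1, -3, -1), (-1, 7, 1), (-1, 0, -1)]
        hd = signaling_distance([f"ch{i}" for i in range(4)], layout_from(coords))
        np.testing.assert_allclose(hd.centroid, [0, 0, 0], atol=1e-12)
        assert hd.distance == pytest.approx(np.sqrt(2.0))
        assert len(hd.vertex_ids) == 4

    def test_single_channel_gives_zero(self):
        hd = signaling_distance(["ch0"], layout_from([(3, 4, 5)]))
        assert hd.distance == 0.0

    def test_two_channels_give_half_segment_length(self):
        hd = signaling_distance(["ch0", "ch1"], layout_from([(0, 0, 0), (6, 9, 8)]))
        assert hd.distance == pytest.approx(5.0)  # xz distance 10, half = 5

    def test_collinear_set_reduces_to_segment_extremes(self):
        coords = [(t, 0.0, 2 * t) for t in (0.0, 1.0, 2.5, 4.0)]
        hd = signaling_distance([f"ch{i}" for i in range(4)], layout_from(coords))
        assert hd.distance == pytest.approx(2.0 * np.sqrt(5.0))
        assert len(hd.vertex_ids) == 2

    def test_interior_channel_leaves_distance_unchanged(self):
        square = [(2, 0, 2), (2, 0, -2), (-2, 0, -2), (-2, 0, 2)]
        with_interior = square + [(0.3, 0, 0.1)]
        d1 = signaling_distance([f"ch{i}" for i in range(4)], layout_from(square)).distance
        d2 = signaling_distance(
            [f"ch{i}" for i in range(5)], layout_from(with_interior)
        ).distance
        assert d1 == pytest.approx(d2)

    def test_matches_brute_force_hull_oracle(self, rng):
        for _ in range(100):
            m = int(rng.integers(4, 30))
            pts = rng.normal(size=(m, 3)) * 50
            lay = layout_from(pts)
            hd = signaling_distance(lay.channel_ids, lay)
            pts2 = pts[:, [0, 2]]
            expected_vertices = _oracles.hull_vertices_naive(pts2)
            got_vertices = {lay.channel_ids.index(c) for c in hd.vertex_ids}
            assert got_vertices == expected_vertices
            assert hd.distance == pytest.approx(_oracles.hull_distance_naive(pts2), rel=1e-9)

    def test_rigid_invariance_and_linear_scaling(self, rng):
        pts = rng.normal(size=(15, 3)) * 40
        lay = layout_from(pts)
        d0 = signaling_distance(lay.channel_ids, lay).distance
        # translation
        d_t = signaling_distance(lay.channel_ids, layout_from(pts + [7, -3, 11])).distance
        assert d_t == pytest.approx(d0)
        # rotation about the y (projection) axis
        th = 0.73
        rot = np.array(
            [[np.cos(th), 0, -np.sin(th)], [0, 1, 0], [np.sin(th), 0, np.cos(th)]]
        )
        d_r = signaling_distance(lay.channel_ids, layout_from(pts @ rot.T)).distance
        assert d_r == pytest.approx(d0)
        # isotropic scaling
        d_s = signaling_distance(lay.channel_ids, layout_from(2.5 * pts)).distance
        assert d_s == pytest.approx(2.5 * d0)

    def test_empty_set_rejected(self, rng):
        lay = layout_from(rng.normal(size=(5, 3)))
        with pytest.raises(ValueError, match="empty"):
            signaling_distance([], lay)

    def test_unprojected_mode_uses_3d_coordinates(self):
        coords = [(1, 5, 1), (1, -3, -1), (-1, 7, 1), (-1, 0, -1)]
        lay = layout_from(coords)
        ids = lay.channel_ids
        d2 = signaling_distance(ids, lay, projected=True).distance
        d3 = signaling_distance(ids, lay, projected=False).distance
        assert d3 > d2  # y spread adds distance in 3-D


def test_spatial_comparison_table(low_snr_run):
    table = spatial_comparison(
        low_snr_run["auc_fast"], low_snr_run["auc_enhanced"], low_snr_run["layout"]
    )
    assert list(table["band"]) == ["fast", "enhanced", "ratio"]
    ratio = table[table["band"] == "ratio"].iloc[0]
    ch_f = int(table[table["band"] == "fast"]["ch"].iloc[0])
    ch_e = int(table[table["band"] == "enhanced"]["ch"].iloc[0])
    if ch_f:
        assert ratio["r_c"] == pytest.approx((ch_e - ch_f) / ch_f)
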