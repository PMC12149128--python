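import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from ehgkit import (
    BinaryMask,
    Recording,
    build_threshold_grid,
    channel_auc_map,
    detect_mask,
    rank_auc,
    roc_against_mask,
)
from ehgkit.metrics import window_energy

import _oracles


class TestDetectMask:
    def test_strict_threshold_comparison(self):
        mask = detect_mask(np.array([0.0, 1, 2, 3]), 1.5)
        np.testing.assert_array_equal(mask.values, [0, 0, 1, 1])

    def test_threshold_below_min_gives_all_ones(self):
        e = np.array([2.0, 3, 4])
        assert detect_mask(e, 1.0).values.all()

    def test_threshold_at_max_gives_all_zeros(self):
        e = np.array([2.0, 3, 4])
        assert not detect_mask(e, 4.0).values.any()

    def test_nonfinite_threshold_rejected(self):
        with pytest.raises(ValueError):
            detect_mask(np.arange(5.0), np.nan)


class TestThresholdGrid:
    def test_grid_span_and_count(self, rng):
        e = rng.normal(size=400)
        grid = build_threshold_grid(e)
        mu, sd = e.mean(), e.std(ddof=1)
        assert len(grid) == 121
        assert grid.values[0] == pytest.approx(mu - 3 * sd)
        assert grid.values[-1] == pytest.approx(mu + 3 * sd)
        assert grid.values[60] == pytest.approx(mu)  # symmetric about the mean
        steps = np.diff(grid.values)
        np.testing.assert_allclose(steps, 0.05 * sd, rtol=1e-9)
        assert (steps > 0).all()

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            build_threshold_grid(np.full(50, 2.0))


class TestRocAgainstMask:
    def test_perfect_separation_gives_auc_one(self, rng):
        truth = np.array([0] * 50 + [1] * 50)
        e = np.concatenate([rng.uniform(0, 1, 50), rng.uniform(2, 3, 50)])
        assert roc_against_mask(e, truth).auc == pytest.approx(1.0)

    def test_independent_energies_give_chance_auc(self, rng):
        aucs = []
        for _ in range(200):
            truth = np.array([0] * 30 + [1] * 30)
            e = rng.normal(size=60)
            aucs.append(roc_against_mask(e, truth).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_small_instance_matches_rank_auc_on_dense_grid(self):
        # 12 energies spread wider than a grid step: every pair is resolved
        truth = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1])
        e = np.array([1.0, 2, 3, 4, 5, 6, 4.5, 5.5, 6.5, 7.5, 8.5, 9.5])
        roc = roc_against_mask(e, truth)
        assert roc.auc == pytest.approx(rank_auc(e, truth), abs=1e-12)
        assert roc.auc == pytest.approx(_oracles.auc_rank_naive(e, truth), abs=1e-12)

    def test_grid_auc_close_to_exact_rank_auc(self, rng):
        for _ in range(50):
            truth = (rng.uniform(size=200) < 0.3).astype(int)
            if truth.min() == truth.max():
                continue
            e = rng.gamma(2.0, size=200) + truth * rng.uniform(0, 2)
            grid_auc = roc_against_mask(e, truth).auc
            assert abs(grid_auc - rank_auc(e, truth)) <= 0.02

    def test_rank_auc_matches_sklearn(self, rng):
        truth = (rng.uniform(size=300) < 0.4).astype(int)
        e = rng.normal(size=300) + truth
        assert rank_auc(e, truth) == pytest.approx(roc_auc_score(truth, e), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        truth = (rng.uniform(size=150) < 0.3).astype(int)
        e = rng.gamma(2.0, size=150) + truth
        warped = np.expm1(e / e.max() * 3)  # strictly increasing
        assert rank_auc(warped, truth) == pytest.approx(rank_auc(e, truth), abs=1e-12)
        assert abs(roc_against_mask(warped, truth).auc - roc_against_mask(e, truth).auc) <= 0.02

    def test_optimal_threshold_maximises_youden_j(self, rng):
        truth = np.array([0] * 100 + [1] * 100)
        e = np.concatenate([rng.normal(0, 1, 100), rng.normal(2, 1, 100)])
        roc = roc_against_mask(e, truth)
        j = roc.tpr - roc.fpr
        assert roc.youden_j == pytest.approx(j.max())
        best = np.flatnonzero(j == j.max())
        assert roc.optimal_threshold == roc.thresholds[best[0]]  # lowest on ties

    def test_single_class_mask_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            roc_against_mask(np.arange(10.0), np.zeros(10, dtype=int))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            roc_against_mask(np.arange(10.0), np.array([0, 1]))


class TestChannelAucMap:
    def test_origin_channel_beats_farthest(self, low_snr_run):
        table = low_snr_run["auc_fast"]
        truth = low_snr_run["truth"]
        att = truth.attenuation
        origin = truth.origin_channel
        farthest = min(att, key=att.get)
        by_channel = table.set_index("channel_id")["auc"]
        assert by_channel[origin] > by_channel[farthest]

    def test_pure_noise_channels_stay_near_chance(self, rng):
        data = rng.normal(size=(40, 3000))
        rec = Recording(data, 5.0, [f"c{i}" for i in range(40)], "fast")
        truth = BinaryMask((rng.uniform(size=3000) < 0.25).astype(int), 5.0)
        table = channel_auc_map(rec, truth)
        inside = ((table["auc"] >= 0.35) & (table["auc"] <= 0.65)).mean()
        assert inside >= 0.95

    def test_duplicated_channel_gets_identical_auc(self, rng):
        x = rng.normal(size=2000)
        truth = BinaryMask((rng.uniform(size=2000) < 0.3).astype(int), 5.0)
        rec = Recording(np.vstack([x, x]), 5.0, ["a", "b"], "fast")
        table = channel_auc_map(rec, truth)
        assert table["auc"].iloc[0] == table["auc"].iloc[1]


def test_roc_invariant_to_constant_envelope(rng):
    """Scaling a signal by a constant leaves the threshold-swept ROC unchanged."""
    truth = (rng.uniform(size=500) < 0.3).astype(int)
    x = rng.normal(size=500) + truth
    e1 = window_energy(x)
    e2 = window_energy(4.2 * x)
    r1, r2 = roc_against_mask(e1, truth), roc_against_mask(e2, truth)
    assert r1.auc == pytest.approx(r2.auc, abs=1e-12)
    np.testing.assert_allclose(r1.tpr, r2.tpr)
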