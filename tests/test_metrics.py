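"""Metric suite vs independently coded brute-force oracles."""

import numpy as np
import pytest

import poseload as pl
from poseload.metrics import EvalReport, torso_diagonal


# -- brute-force oracles (deliberately naive loops) -------------------------

def _mae_oracle(p, t):
    return sum(abs(a - b) for a, b in zip(p, t)) / len(p)


def _rmse_oracle(p, t):
    return (sum((a - b) ** 2 for a, b in zip(p, t)) / len(p)) ** 0.5


def _mpjpe_oracle(p, g):
    total, count = 0.0, 0
    for i in range(p.shape[0]):
        for k in range(p.shape[1]):
            total += float(np.sqrt(((p[i, k] - g[i, k]) ** 2).sum()))
            count += 1
    return total / count


def _pck_oracle(p, g, ls, tau):
    hits, count = 0, 0
    for i in range(p.shape[0]):
        for k in range(p.shape[1]):
            d = float(np.sqrt(((p[i, k] - g[i, k]) ** 2).sum()))
            hits += d / ls[i] <= tau
            count += 1
    return 100.0 * hits / count


def _auc_oracle(pred, truth):
    hi = [p for p, t in zip(pred, truth) if t >= 70]
    lo = [p for p, t in zip(pred, truth) if t < 30]
    if not hi or not lo:
        return None
    wins = sum(1 for a in hi for b in lo if a > b)
    return wins / (len(hi) * len(lo))


def _frc_oracle(x):
    m = x.shape[1]
    total = 0.0
    for j in range(m):
        for k in range(j + 1, m):
            sj, sk = x[:, j].std(), x[:, k].std()
            if sj == 0 or sk == 0:
                continue
            total += abs(np.corrcoef(x[:, j], x[:, k])[0, 1])
    return total / m ** 2


class TestMaeRmse:
    def test_perfect_prediction(self):
        assert pl.mae_rmse([1.0, 2.0], [1.0, 2.0]) == (0.0, 0.0)

    def test_hand_arithmetic(self):
        mae, rmse = pl.mae_rmse([0.0, 0.0], [3.0, 4.0])
        assert np.isclose(mae, 3.5)
        assert np.isclose(rmse, np.sqrt(12.5))
        assert np.isclose(rmse, 3.5355339, atol=1e-6)

    def test_rmse_dominates_mae(self, rng):
        for _ in range(200):
            p, t = rng.normal(size=(2, 10))
            mae, rmse = pl.mae_rmse(p, t)
            assert rmse >= mae - 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pl.mae_rmse([], [])


class TestMpjpe:
    def test_identical_arrays(self, rng):
        x = rng.normal(size=(4, 25, 3))
        assert pl.mpjpe(x, x) == 0.0

    def test_three_four_five_translation(self, rng):
        gt = rng.normal(size=(6, 25, 3))
        pred = gt + np.array([0.03, 0.0, 0.04])
        assert np.isclose(pl.mpjpe(pred, gt), 0.05)

    def test_joint_permutation_invariance(self, rng):
        gt = rng.normal(size=(5, 25, 3))
        pred = gt + rng.normal(scale=0.01, size=gt.shape)
        perm = rng.permutation(25)
        assert np.isclose(pl.mpjpe(pred, gt), pl.mpjpe(pred[:, perm], gt[:, perm]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pl.mpjpe(np.zeros((2, 25, 3)), np.zeros((3, 25, 3)))


class TestPck:
    def test_perfect_is_100(self, rng):
        x = rng.normal(size=(3, 25, 3))
        assert pl.pck(x, x, np.ones(3)) == 100.0

    def test_boundary_deviation_counts_as_correct(self):
        gt = np.zeros((1, 2, 3))
        pred = np.zeros((1, 2, 3))
        pred[0, 0, 0] = 0.1  # d/L exactly tau with L=1
        assert pl.pck(pred, gt, np.ones(1), tau=0.1) == 100.0
        pred[0, 0, 0] = 0.1000001
        assert pl.pck(pred, gt, np.ones(1), tau=0.1) == 50.0

    def test_monotone_in_threshold(self, rng):
        gt = rng.normal(size=(10, 25, 3))
        pred = gt + rng.normal(scale=0.05, size=gt.shape)
        ls = np.full(10, 0.5)
        values = [pl.pck(pred, gt, ls, tau) for tau in (0.05, 0.1, 0.2, 0.5)]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_nonpositive_torso_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            pl.pck(np.zeros((1, 2, 3)), np.zeros((1, 2, 3)), np.zeros(1))

    def test_torso_diagonal_uses_shoulder_hip(self):
        from poseload.features import rest_pose, DEFAULT_TOPOLOGY
        pose = rest_pose()
        ls = DEFAULT_TOPOLOGY.names.index("left_shoulder")
        rh = DEFAULT_TOPOLOGY.names.index("right_hip")
        assert np.isclose(torso_diagonal(pose),
                          np.linalg.norm(pose[ls] - pose[rh]))


class TestAuc:
    def test_perfect_separation(self):
        truth = np.array([80.0, 90.0, 10.0, 20.0])
        assert pl.auc([0.9, 0.8, 0.1, 0.2], truth) == 1.0
        assert pl.auc([0.1, 0.2, 0.9, 0.8], truth) == 0.0

    def test_midrange_samples_excluded(self):
        truth = np.array([80.0, 50.0, 10.0])
        # the mid sample's wild prediction must not matter
        assert pl.auc([0.9, -5.0, 0.1], truth) == 1.0

    def test_random_scores_near_half(self):
        values = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            truth = np.concatenate([np.full(200, 80.0), np.full(200, 10.0)])
            values.append(pl.auc(rng.normal(size=400), truth))
        assert abs(np.mean(values) - 0.5) < 0.06

    def test_undefined_without_both_classes(self):
        assert pl.auc([1.0, 2.0], [80.0, 90.0]) is None

    def test_tie_handling(self):
        truth = np.array([80.0, 10.0])
        assert pl.auc([0.5, 0.5], truth) == 0.0
        assert pl.auc([0.5, 0.5], truth, ties="half") == 0.5

    def test_matches_rank_formulation_on_tie_free_data(self, rng):
        from scipy.stats import rankdata
        for _ in range(100):
            n_hi, n_lo = rng.integers(2, 20), rng.integers(2, 20)
            truth = np.concatenate([np.full(n_hi, 85.0), np.full(n_lo, 5.0)])
            pred = rng.normal(size=n_hi + n_lo)
            ranks = rankdata(pred)
            rank_auc = (ranks[:n_hi].sum() - n_hi * (n_hi + 1) / 2) / (n_hi * n_lo)
            assert np.isclose(pl.auc(pred, truth), rank_auc, atol=1e-12)


class TestEvaluateAssembly:
    def test_oracle_equivalence_on_random_instances(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 15))
            pred = rng.uniform(0, 100, size=n)
            truth = rng.uniform(0, 100, size=n)
            coords_gt = rng.normal(size=(n, 25, 3))
            coords_pred = coords_gt + rng.normal(scale=0.05,
                                                 size=coords_gt.shape)
            feats = rng.normal(size=(n, 6))
            report = pl.evaluate(pred, truth, pred_coords=coords_pred,
                                 gt_coords=coords_gt, feature_matrix=feats)
            assert np.isclose(report.mae, _mae_oracle(pred, truth))
            assert np.isclose(report.rmse, _rmse_oracle(pred, truth))
            assert np.isclose(report.mpjpe,
                              _mpjpe_oracle(coords_pred, coords_gt))
            ls = [torso_diagonal(c) for c in coords_gt]
            assert np.isclose(report.pck,
                              _pck_oracle(coords_pred, coords_gt, ls, 0.1))
            want_auc = _auc_oracle(pred, truth)
            if want_auc is None:
                assert report.auc is None
            else:
                assert np.isclose(report.auc, want_auc)
            assert np.isclose(report.frc, _frc_oracle(feats))

    def test_sample_reordering_invariance(self, rng):
        n = 30
        pred = rng.uniform(0, 100, size=n)
        truth = rng.uniform(0, 100, size=n)
        perm = rng.permutation(n)
        r1 = pl.evaluate(pred, truth)
        r2 = pl.evaluate(pred[perm], truth[perm])
        assert np.isclose(r1.mae, r2.mae)
        assert np.isclose(r1.rmse, r2.rmse)
        assert (r1.auc is None and r2.auc is None) or np.isclose(r1.auc, r2.auc)

    def test_report_schema_and_serialization(self, rng):
        report = pl.evaluate(rng.uniform(0, 100, 10), rng.uniform(0, 100, 10))
        d = report.to_dict()
        assert set(d) == {"mae", "rmse", "mpjpe", "pck", "auc", "frc", "n"}
        assert "mae" in report.to_json()

    def test_inconsistent_mae_rmse_rejected(self):
        with pytest.raises(ValueError, match="RMSE"):
            EvalReport(mae=5.0, rmse=1.0, mpjpe=None, pck=None, auc=None,
                       frc=None, n=3)
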