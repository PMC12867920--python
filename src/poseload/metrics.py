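"""Evaluation metric suite: MAE, RMSE, MPJPE, PCK, pairwise AUC, FRC.

MAE/RMSE score the load predictions on the [0, 100] scale.  MPJPE is the
mean Euclidean distance (metres) between predicted and reference 3D joint
positions; PCK the percentage of joints within a torso-normalized threshold
tau of the reference.  AUC is the pairwise statistic over (high, low) load
pairs -- high means true load >= 70, low means < 30, mid-range samples are
excluded -- counting strictly ordered pairs (ties score 0 by default;
half-credit mode matches the conventional rank AUC).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .features import DEFAULT_TOPOLOGY, SkeletonTopology

HIGH_LOAD = 70.0
LOW_LOAD = 30.0
PCK_TAU = 0.1


def mae_rmse(pred, truth) -> tuple[float, float]:
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.size == 0 or pred.shape != truth.shape:
        raise ValueError("pred and truth must be equal-length and non-empty")
    err = pred - truth
    return float(np.mean(np.abs(err))), float(np.sqrt(np.mean(err ** 2)))


def mpjpe(pred: np.ndarray, gt: np.ndarray) -> float:
    """Mean per-joint position error in metres over N x K x 3 arrays."""
    pred = np.asarray(pred, dtype=float)
    gt = np.asarray(gt, dtype=float)
    if pred.shape != gt.shape or pred.ndim != 3 or pred.shape[-1] != 3:
        raise ValueError("pred/gt must be matching N x K x 3 arrays")
    return float(np.linalg.norm(pred - gt, axis=-1).mean())


def torso_diagonal(coords: np.ndarray,
                   topo: SkeletonTopology = DEFAULT_TOPOLOGY) -> float:
    """Torso diagonal of a (T, J, 3) or (J, 3) pose: the left-shoulder to
    right-hip distance (averaged over frames), the scale used to normalize
    joint deviations."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    ls = topo.names.index("left_shoulder")
    rh = topo.names.index("right_hip")
    return float(np.linalg.norm(coords[:, ls] - coords[:, rh], axis=-1).mean())


def pck(pred: np.ndarray, gt: np.ndarray, torso_diag: np.ndarray,
        tau: float = PCK_TAU) -> float:
    """Percentage of joints with d_{i,k} / L_i <= tau (boundary counts)."""
    pred = np.asarray(pred, dtype=float)
    gt = np.asarray(gt, dtype=float)
    li = np.asarray(torso_diag, dtype=float).reshape(-1)
    if pred.shape != gt.shape:
        raise ValueError("pred/gt shape mismatch")
    if np.any(li <= 0):
        raise ValueError("torso diagonals must be positive")
    d = np.linalg.norm(pred - gt, axis=-1)  # (N, K)
    return float((d / li[:, None] <= tau).mean() * 100.0)


def auc(pred, truth, high: float = HIGH_LOAD, low: float = LOW_LOAD,
        ties: str = "zero") -> float | None:
    """Pairwise high/low separability of the predicted scores.

    Fraction of (high, low) pairs with pred_high > pred_low.  Returns None
    when either class is empty (the statistic is undefined).  `ties='half'`
    gives tied pairs half credit (the conventional rank-based AUC).
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    hi = pred[truth >= high]
    lo = pred[truth < low]
    if hi.size == 0 or lo.size == 0:
        return None
    diff = hi[:, None] - lo[None, :]
    wins = (diff > 0).sum()
    if ties == "half":
        wins = wins + 0.5 * (diff == 0).sum()
    return float(wins / (hi.size * lo.size))


@dataclass
class EvalReport:
    mae: float
    rmse: float
    mpjpe: float | None
    pck: float | None
    auc: float | None
    frc: float | None
    n: int

    def __post_init__(self):
        if self.rmse < self.mae - 1e-9:
            raise ValueError("RMSE cannot be below MAE")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate(pred_scores, true_scores, pred_coords=None, gt_coords=None,
             feature_matrix=None,
             topo: SkeletonTopology = DEFAULT_TOPOLOGY) -> EvalReport:
    """Assemble the full metric report for one model/dataset pairing.

    Pose metrics (MPJPE, PCK) are computed only when coordinate arrays are
    supplied; FRC only when a selected-feature matrix is supplied.  Missing
    metrics are reported as null rather than fabricated.
    """
    mae, rmse = mae_rmse(pred_scores, true_scores)
    mpjpe_v = pck_v = frc_v = None
    if pred_coords is not None and gt_coords is not None:
        pred_coords = np.asarray(pred_coords, dtype=float)
        gt_coords = np.asarray(gt_coords, dtype=float)
        flat_pred = pred_coords.reshape(-1, *pred_coords.shape[-2:])
        flat_gt = gt_coords.reshape(-1, *gt_coords.shape[-2:])
        mpjpe_v = mpjpe(flat_pred, flat_gt)
        diag = np.array([torso_diagonal(c, topo) for c in flat_gt])
        pck_v = pck(flat_pred, flat_gt, diag)
    if feature_matrix is not None:
        from .woa import frc
        frc_v = frc(feature_matrix)
    return EvalReport(mae=mae, rmse=rmse, mpjpe=mpjpe_v, pck=pck_v,
                      auc=auc(pred_scores, true_scores), frc=frc_v,
                      n=len(np.asarray(pred_scores).reshape(-1)))
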