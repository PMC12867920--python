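"""Objective cognitive-load label construction.

A sequence's load label is built from four factors: choreographic difficulty
D (1-5), coordination entropy E (bits) of the per-joint motion distribution,
the LF/HF heart-rate-variability ratio, and the EEG alpha-power change rate
(delta_alpha).  The composite is the fixed weighted sum

    y_raw = 0.4*D + 0.3*E + 0.2*(LF/HF) + 0.1*delta_alpha

and the corpus of raw scores is min-max scaled to [0, 100].  An intraclass
correlation check (ICC(2,1): two-way random effects, absolute agreement,
single rater) validates rater reliability of a label set.

Coordination entropy treats the share of total path length travelled by each
of the 25 joints as a probability distribution: synchronized, single-joint
motion has low entropy; load spread evenly over every joint attains the
maximum log2(25) ~ 4.644 bits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

COMPOSITE_WEIGHTS = (0.4, 0.3, 0.2, 0.1)  # D, E, LF/HF, delta_alpha
N_JOINTS = 25
MAX_ENTROPY_BITS = float(np.log2(N_JOINTS))


@dataclass
class LoadLabel:
    D: int
    E: float
    lfhf: float
    delta_alpha: float
    y_raw: float
    y: float  # in [0, 100]


def joint_path_lengths(coords: np.ndarray) -> np.ndarray:
    """Total Euclidean path length per joint over the sequence, shape (J,)."""
    coords = np.asarray(coords, dtype=float)
    steps = np.linalg.norm(np.diff(coords, axis=0), axis=-1)  # (T-1, J)
    return steps.sum(axis=0)


def coordination_entropy(seq) -> float:
    """Shannon entropy (bits) of the per-joint share of total path length.

    p_i = path_i / sum_j path_j;  E = -sum p_i log2 p_i with 0 log 0 := 0.
    A motionless sequence carries no coordination demand and returns 0.
    """
    coords = np.asarray(seq.coords if hasattr(seq, "coords") else seq, dtype=float)
    if coords.shape[0] < 2:
        raise ValueError("entropy needs at least 2 frames")
    path = joint_path_lengths(coords)
    total = path.sum()
    if total <= 0.0:
        return 0.0
    p = path / total
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def composite_load(D: float, E: float, lfhf: float, delta_alpha: float) -> float:
    """The fixed-weight composite raw load score."""
    if not 1 <= D <= 5:
        raise ValueError(f"difficulty D must be in [1, 5], got {D}")
    w = COMPOSITE_WEIGHTS
    return w[0] * D + w[1] * E + w[2] * lfhf + w[3] * delta_alpha


def scale_labels(y_raw: np.ndarray) -> np.ndarray:
    """Min-max scale a corpus of raw scores to [0, 100].

    The corpus minimum maps to 0 and the maximum to 100; a degenerate corpus
    (all values equal) maps to all zeros, mirroring the degenerate min-max
    rule used for coordinates.
    """
    y_raw = np.asarray(y_raw, dtype=float)
    lo, hi = y_raw.min(), y_raw.max()
    if hi == lo:
        return np.zeros_like(y_raw)
    return 100.0 * (y_raw - lo) / (hi - lo)


def build_labels(records: pd.DataFrame, zscore_components: bool = False) -> pd.DataFrame:
    """Build the label table from per-sequence factor records.

    `records` needs columns sequence_id, D, E, lfhf, delta_alpha.  With
    `zscore_components` each factor is standardized before weighting (the
    composite is otherwise applied literally, E in raw bits).
    """
    df = records.copy()
    comps = df[["D", "E", "lfhf", "delta_alpha"]].to_numpy(float)
    if zscore_components:
        sd = comps.std(axis=0)
        sd[sd == 0] = 1.0
        comps = (comps - comps.mean(axis=0)) / sd
    df["y_raw"] = comps @ np.asarray(COMPOSITE_WEIGHTS)
    df["y"] = scale_labels(df["y_raw"].to_numpy())
    return df[["sequence_id", "D", "E", "lfhf", "delta_alpha", "y_raw", "y"]]


def icc_reliability(ratings: np.ndarray) -> float:
    """ICC(2,1) of an items x raters matrix: two-way random effects,
    absolute agreement, single rater -- the standard form for a panel of
    raters each scoring every item.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2:
        raise ValueError("ratings must be a 2-D items x raters matrix")
    n, k = ratings.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 items and 2 raters")
    if not np.all(np.isfinite(ratings)):
        raise ValueError("ratings contain missing or non-finite cells")

    if np.allclose(ratings, ratings[:, :1]):
        # zero residual and rater variance: perfect absolute agreement
        # (degenerate for the ANOVA F ratios, so handled directly)
        return 1.0 if np.ptp(ratings[:, 0]) > 0 else 0.0

    import pingouin as pg

    long = pd.DataFrame({
        "item": np.repeat(np.arange(n), k),
        "rater": np.tile(np.arange(k), n),
        "score": ratings.reshape(-1),
    })
    table = pg.intraclass_corr(data=long, targets="item", raters="rater",
                               ratings="score")
    # the two-way-random absolute-agreement single-rater row is labelled
    # ICC2 or ICC(A,1) depending on the pingouin release
    mask = table["Type"].isin(["ICC2", "ICC(A,1)"])
    return float(table.loc[mask, "ICC"].iloc[0])
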