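"""Whale-optimization dual search over hyperparameters and feature subsets.

A whale's position concatenates a continuous hyperparameter block (decoded
into declared ranges, log-scale for learning rates, half-up rounding for
integers) and a relaxed [0, 1] block of 512 feature-mask logits decoded by
a top-300 rule.  Fitness = alpha * MAE + (1 - alpha) * FRC with alpha 0.7:
prediction error traded against the redundancy of the selected features.

Position updates follow the canonical whale dynamics: with probability 0.5
a logarithmic-spiral ("bubble-net") move around the best whale; otherwise
A = 2 a r - a with a(t) = 2 (1 - t / max_iter) decides between encircling
the best (|A| < 1) and a random-peer search (|A| >= 1).  A 10 % exploration
floor forces the random-search branch regardless of |A|.  Elitism keeps the
best-ever candidate; a fixed-capacity FIFO taboo list of quantized
positions (entries expiring after 10 iterations) forces re-sampling of
already-failed regions.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Callable

import numpy as np


# -- fitness components -------------------------------------------------------

def frc(features: np.ndarray, use_abs: bool = True) -> float:
    """Feature redundancy coefficient of an n x M feature matrix.

    (1/M^2) * sum_{j<k} Corr(f_j, f_k); by default the absolute Pearson
    correlation, so oppositely-signed redundancy cannot cancel.  Constant
    columns contribute zero.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise ValueError("features must be an n x M matrix")
    n, m = x.shape
    if n < 2:
        raise ValueError("need at least 2 rows to correlate")
    if m < 2:
        return 0.0
    sd = x.std(axis=0)
    live = sd > 0
    if live.sum() < 2:
        return 0.0
    corr = np.corrcoef(x[:, live], rowvar=False)
    if use_abs:
        corr = np.abs(corr)
    upper = corr[np.triu_indices_from(corr, k=1)]
    return float(upper.sum() / (m * m))


def fitness(mae: float, frc_value: float, alpha: float = 0.7) -> float:
    """alpha * MAE + (1 - alpha) * FRC."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return alpha * mae + (1.0 - alpha) * frc_value


# -- search space and candidates ---------------------------------------------

@dataclass(frozen=True)
class SearchSpace:
    """Declared hyperparameter bounds plus an optional feature-mask block.

    `bounds` maps name -> (low, high, kind) with kind one of 'float',
    'int', 'log'.  The mask block has `n_features` logits in [0, 1] decoded
    to the `n_select` largest (ties to the lowest index).
    """

    bounds: dict[str, tuple[float, float, str]] = field(default_factory=dict)
    n_features: int = 0
    n_select: int = 300

    @property
    def n_hyper(self) -> int:
        return len(self.bounds)

    @property
    def dim(self) -> int:
        return self.n_hyper + self.n_features

    def lows(self) -> np.ndarray:
        hyper = [lo for lo, _, _ in self.bounds.values()]
        return np.concatenate([np.array(hyper, float),
                               np.zeros(self.n_features)])

    def highs(self) -> np.ndarray:
        hyper = [hi for _, hi, _ in self.bounds.values()]
        return np.concatenate([np.array(hyper, float),
                               np.ones(self.n_features)])


def default_search_space(n_features: int = 512,
                         n_select: int = 300) -> SearchSpace:
    """The dual space the model search explores by default."""
    return SearchSpace(
        bounds={
            "kernel_size": (2.0, 3.0, "int"),
            "dilation_base": (1.0, 2.0, "int"),
            "heads": (4.0, 8.0, "int"),
            "dropout": (0.0, 0.3, "float"),
            "learning_rate": (1e-5, 1e-2, "log"),
        },
        n_features=n_features, n_select=n_select,
    )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def decode(position: np.ndarray, space: SearchSpace):
    """Map a position vector to (hyperparameter dict, feature index array)."""
    position = np.asarray(position, dtype=float)
    hypers: dict[str, float | int] = {}
    for i, (name, (lo, hi, kind)) in enumerate(space.bounds.items()):
        v = float(np.clip(position[i], lo, hi))
        if kind == "int":
            hypers[name] = _round_half_up(v)
        elif kind == "log":
            # position is carried on the log10 scale between the bounds
            lg = np.log10(lo) + (v - lo) / (hi - lo) * (np.log10(hi) - np.log10(lo))
            hypers[name] = float(10.0 ** lg)
        else:
            hypers[name] = v
    if space.n_features:
        logits = position[space.n_hyper:]
        # argsort of -logits is stable, so ties break to the lowest index
        order = np.argsort(-logits, kind="stable")
        selected = np.sort(order[:space.n_select])
    else:
        selected = np.array([], dtype=int)
    return hypers, selected


@dataclass
class WhaleCandidate:
    position: np.ndarray
    fitness: float = np.inf

    def decoded(self, space: SearchSpace):
        return decode(self.position, space)


@dataclass(frozen=True)
class WoaConfig:
    population: int = 30
    max_iter: int = 50
    spiral_b: float = 1.0
    random_search_prob: float = 0.10
    alpha: float = 0.7
    seed: int = 0
    taboo_capacity: int = 50
    taboo_expiry: int = 10       # iterations until a taboo entry is relaxed
    taboo_quantum: float = 0.05  # position quantization for taboo keys

    def __post_init__(self):
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def a_schedule(t: int, max_iter: int) -> float:
    """Exploration coefficient a(t) = 2 (1 - t / max_iter), linear 2 -> 0."""
    return 2.0 * (1.0 - t / max_iter)


def whale_step(positions: np.ndarray, best: np.ndarray, t: int,
               cfg: WoaConfig, space: SearchSpace,
               rng: np.random.Generator) -> np.ndarray:
    """One synchronous position update of the whole population."""
    if positions.shape[0] == 0:
        raise ValueError("population is empty")
    a = a_schedule(t, cfg.max_iter)
    lows, highs = space.lows(), space.highs()
    new = np.empty_like(positions)
    n = positions.shape[0]
    for i in range(n):
        x = positions[i]
        if rng.random() < 0.5:
            # bubble-net spiral around the best whale
            l = rng.uniform(-1.0, 1.0)
            dist = np.abs(best - x)
            new[i] = dist * np.exp(cfg.spiral_b * l) * np.cos(2.0 * np.pi * l) + best
        else:
            big_a = 2.0 * a * rng.random() - a  # scalar coefficient
            big_c = 2.0 * rng.random(x.shape)
            forced = rng.random() < cfg.random_search_prob
            if forced or abs(big_a) >= 1.0:
                peer = positions[rng.integers(n)]
                new[i] = peer - big_a * np.abs(big_c * peer - x)
            else:
                new[i] = best - big_a * np.abs(big_c * best - x)
    return np.clip(new, lows, highs)


@dataclass
class WoaResult:
    best: WhaleCandidate
    hyperparameters: dict
    selected_features: np.ndarray
    trace: np.ndarray  # best-so-far fitness per iteration


def _taboo_key(position: np.ndarray, quantum: float) -> tuple:
    return tuple(np.round(position / quantum).astype(int))


def optimize(evaluate: Callable[[dict, np.ndarray], tuple[float, float]],
             space: SearchSpace, cfg: WoaConfig) -> WoaResult:
    """Run the whale search; `evaluate(hypers, feature_idx) -> (mae, frc)`.

    Failed evaluations receive +inf fitness and their position enters the
    taboo list; candidates matching a live taboo entry are re-sampled
    uniformly.  The best-ever candidate is kept (elitism) so the fitness
    trace is non-increasing.
    """
    rng = np.random.default_rng(cfg.seed)
    lows, highs = space.lows(), space.highs()
    positions = rng.uniform(lows, highs, size=(cfg.population, space.dim))
    taboo: deque[tuple[tuple, int]] = deque(maxlen=cfg.taboo_capacity)

    def taboo_hit(pos: np.ndarray, t: int) -> bool:
        key = _taboo_key(pos, cfg.taboo_quantum)
        return any(k == key and t - born < cfg.taboo_expiry for k, born in taboo)

    def score(pos: np.ndarray, t: int) -> float:
        hypers, feats = decode(pos, space)
        try:
            mae, frc_value = evaluate(hypers, feats)
            return fitness(mae, frc_value, cfg.alpha)
        except Exception:
            taboo.append((_taboo_key(pos, cfg.taboo_quantum), t))
            return np.inf

    fits = np.array([score(p, 0) for p in positions])
    best_i = int(np.argmin(fits))
    best = WhaleCandidate(positions[best_i].copy(), float(fits[best_i]))
    trace = [best.fitness]

    for t in range(1, cfg.max_iter + 1):
        positions = whale_step(positions, best.position, t, cfg, space, rng)
        for i in range(cfg.population):
            if taboo_hit(positions[i], t):
                positions[i] = rng.uniform(lows, highs)
            fits[i] = score(positions[i], t)
        i = int(np.argmin(fits))
        if fits[i] < best.fitness:
            best = WhaleCandidate(positions[i].copy(), float(fits[i]))
        trace.append(best.fitness)

    hypers, feats = best.decoded(space)
    return WoaResult(best=best, hyperparameters=hypers,
                     selected_features=feats, trace=np.array(trace))


# -- proxy evaluator for the dual search --------------------------------------

def ridge_proxy_evaluator(x_train: np.ndarray, y_train: np.ndarray,
                          x_val: np.ndarray, y_val: np.ndarray,
                          ridge_alpha: float = 1.0):
    """Cheap candidate scorer: ridge fit on the selected feature columns.

    Returns an `evaluate(hypers, feature_idx) -> (val MAE, FRC)` closure,
    the short proxy run that stands behind each whale's fitness.
    """
    from sklearn.linear_model import Ridge

    def evaluate(hypers: dict, feature_idx: np.ndarray) -> tuple[float, float]:
        cols = np.asarray(feature_idx, dtype=int)
        model = Ridge(alpha=ridge_alpha)
        model.fit(x_train[:, cols], y_train)
        mae = float(np.mean(np.abs(model.predict(x_val[:, cols]) - y_val)))
        return mae, frc(x_train[:, cols])

    return evaluate
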