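"""Cognitive-load output head and the weighted-MSE training loop.

The head maps the masked pooled encoder features through a 3-layer fully
connected stack (300 -> 128 -> 64 -> 1 by default) and a sigmoid scaled to
[0, 100]:

    score = 100 * sigmoid(W3 relu(W2 relu(W1 x + b1) + b2) + b3)

Training minimizes a weighted mean squared error in which samples with a
true load of at least 70 (the high-load regime, where assessment errors
matter most) carry weight 1.5 instead of 1.0.  The regimen: AdamW with
learning rate 1e-4 and weight decay 1e-4, batch size 32, up to 100 epochs,
early stopping after 5 epochs without validation improvement.  The loss is
reduced per-batch by the mean of the weighted terms so the learning rate is
batch-size invariant; the plain sum is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attention import Encoder, EncoderConfig
from .autodiff import AdamW, Linear, Module, Tensor
from .features import BranchFeatures, branch_features
from .tcn import TcnConfig, TcnFusion

HIGH_LOAD_THRESHOLD = 70.0
HIGH_LOAD_WEIGHT = 1.5


def weighted_mse(pred: np.ndarray, truth: np.ndarray,
                 threshold: float = HIGH_LOAD_THRESHOLD,
                 high_weight: float = HIGH_LOAD_WEIGHT,
                 reduction: str = "sum") -> float:
    """sum_i w_i (pred_i - truth_i)^2 with w_i = 1.5 iff truth_i >= 70.

    `reduction` 'sum' is the literal form; 'mean' divides by N.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.size == 0:
        raise ValueError("empty input")
    w = np.where(truth >= threshold, high_weight, 1.0)
    terms = w * (pred - truth) ** 2
    return float(terms.mean() if reduction == "mean" else terms.sum())


class ScoreHead(Module):
    """300 -> 128 -> 64 -> 1 fully connected head, sigmoid scaled to [0,100]."""

    def __init__(self, rng: np.random.Generator, in_dim: int = 300,
                 hidden: tuple[int, int] = (128, 64)):
        super().__init__()
        self.fc1 = Linear(in_dim, hidden[0], rng)
        self.fc2 = Linear(hidden[0], hidden[1], rng)
        self.fc3 = Linear(hidden[1], 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.fc1(x).relu()
        h = self.fc2(h).relu()
        return self.fc3(h).sigmoid() * 100.0


def score_head(x: np.ndarray, weights: dict[str, np.ndarray]) -> np.ndarray:
    """Reference forward pass of the head from explicit parameter arrays.

    weights: W1 (300x128), W2 (128x64), W3 (64x1), b1, b2, b3.
    """
    x = np.asarray(x, dtype=float)
    w1, w2, w3 = weights["W1"], weights["W2"], weights["W3"]
    b1, b2, b3 = weights["b1"], weights["b2"], weights["b3"]
    if x.shape[-1] != w1.shape[0]:
        raise ValueError("input dimension does not match W1")
    h = np.maximum(x @ w1 + b1, 0.0)
    h = np.maximum(h @ w2 + b2, 0.0)
    z = (h @ w3 + b3)[..., 0]
    return 100.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    weight_decay: float = 1e-4
    batch_size: int = 32
    epochs: int = 100
    patience: int = 5
    high_load_threshold: float = HIGH_LOAD_THRESHOLD
    high_load_weight: float = HIGH_LOAD_WEIGHT
    reduction: str = "mean"
    seed: int = 0

    def __post_init__(self):
        if self.patience > self.epochs:
            raise ValueError("patience must not exceed epochs")


@dataclass(frozen=True)
class ModelConfig:
    tcn: TcnConfig = field(default_factory=TcnConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    head_in: int = 300
    head_hidden: tuple[int, int] = (128, 64)

    def __post_init__(self):
        if self.tcn.out_dim != self.encoder.input_dim:
            raise ValueError("TCN output dim must equal encoder input dim")


def small_model_config() -> ModelConfig:
    """A width-reduced configuration for desk-scale experiments: the same
    architecture (three causal dilated branches, attention encoder, sigmoid
    head) at channel widths that train in seconds on one CPU."""
    return ModelConfig(
        tcn=TcnConfig(branch_channels=8, out_dim=16),
        encoder=EncoderConfig(n_layers=1, input_dim=16, model_dim=32,
                              ffn_dim=64, heads=4, dropout=0.0),
        head_in=24, head_hidden=(32, 16),
    )


class CogLoadModel(Module):
    """Full assembly: branch TCNs -> encoder -> feature mask -> score head.

    `feature_mask` holds the selected indices of the pooled encoder output
    (the whale search's 300-set at full width); without a search the first
    `head_in` indices are used.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator,
                 feature_mask: np.ndarray | None = None):
        super().__init__()
        self.cfg = cfg
        self.tcn = TcnFusion(cfg.tcn, rng)
        self.encoder = Encoder(cfg.encoder, rng)
        if feature_mask is None:
            feature_mask = np.arange(cfg.head_in)
        self.feature_mask = np.asarray(feature_mask, dtype=int)
        if len(self.feature_mask) != cfg.head_in:
            raise ValueError("feature mask size must match head input dim")
        self.head = ScoreHead(rng, in_dim=cfg.head_in, hidden=cfg.head_hidden)

    def __call__(self, joint: Tensor, bone: Tensor, velocity: Tensor,
                 rng: np.random.Generator | None = None) -> Tensor:
        local = self.tcn(joint, bone, velocity)
        _, pooled = self.encoder(local, rng)
        masked = pooled.take_last(self.feature_mask)
        return self.head(masked).reshape(-1)

    def predict(self, batch: dict[str, np.ndarray]) -> np.ndarray:
        was_training = self.training
        self.eval()
        out = self(Tensor(batch["joint"]), Tensor(batch["bone"]),
                   Tensor(batch["velocity"])).data
        if was_training:
            self.train()
        return out


def stack_branches(sequences) -> dict[str, np.ndarray]:
    """Batch the three branch streams of a list of sequences."""
    feats = [branch_features(s) if not isinstance(s, BranchFeatures) else s
             for s in sequences]
    return {
        "joint": np.stack([f.joint_stream for f in feats]),
        "bone": np.stack([f.bone_stream for f in feats]),
        "velocity": np.stack([f.velocity_stream for f in feats]),
    }


@dataclass
class TrainResult:
    train_losses: list[float]
    val_losses: list[float]
    best_epoch: int
    best_state: dict[str, np.ndarray]
    val_mae: float


def _loss_tensor(pred: Tensor, truth: np.ndarray, cfg: TrainConfig) -> Tensor:
    w = np.where(truth >= cfg.high_load_threshold, cfg.high_load_weight, 1.0)
    diff = pred - Tensor(truth)
    terms = Tensor(w) * diff * diff
    return terms.mean() if cfg.reduction == "mean" else terms.sum()


def train(model: CogLoadModel, train_batch: dict[str, np.ndarray],
          y_train: np.ndarray, val_batch: dict[str, np.ndarray],
          y_val: np.ndarray, cfg: TrainConfig) -> TrainResult:
    """Fit the assembly with the stated regimen; early-stops on validation.

    Inputs are pre-stacked branch batches (see `stack_branches`).  Training
    is fully seeded: shuffling and dropout draw from one generator, so two
    runs with the same seed produce identical loss traces.
    """
    if y_train.size == 0 or y_val.size == 0:
        raise ValueError("train/val splits must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    n = y_train.size
    train_losses, val_losses = [], []
    best_val, best_epoch, best_state = np.inf, -1, model.state_dict()
    stale = 0

    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            pred = model(Tensor(train_batch["joint"][idx]),
                         Tensor(train_batch["bone"][idx]),
                         Tensor(train_batch["velocity"][idx]), rng)
            loss = _loss_tensor(pred, y_train[idx], cfg)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        train_losses.append(epoch_loss / n_batches)

        val_pred = model.predict(val_batch)
        val_loss = weighted_mse(val_pred, y_val, cfg.high_load_threshold,
                                cfg.high_load_weight, cfg.reduction)
        val_losses.append(val_loss)

        if val_loss < best_val - 1e-12:
            best_val, best_epoch, stale = val_loss, epoch, 0
            best_state = model.state_dict()
        else:
            stale += 1
            if stale >= cfg.patience:
                break

    model.load_state_dict(best_state)
    val_mae = float(np.mean(np.abs(model.predict(val_batch) - y_val)))
    return TrainResult(train_losses=train_losses, val_losses=val_losses,
                       best_epoch=best_epoch, best_state=best_state,
                       val_mae=val_mae)
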