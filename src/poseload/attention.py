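"""Multi-head self-attention encoder (the long-range temporal model).

A post-norm encoder stack: the 256-d local features from the convolutional
stage are linearly lifted to 512 dimensions, fixed sinusoidal positional
encodings are added (sequence order carries movement-segment structure),
and each of the 3 layers applies 8-head scaled dot-product attention and a
GELU feed-forward block (512 -> 2048 -> 512), both wrapped in residual
Add & Norm with dropout.  The sequence output is mean-pooled over time into
a single 512-d summary feeding the load head.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .autodiff import Linear, Module, Tensor, dropout
from .tcn import LayerNorm


@dataclass(frozen=True)
class AttentionSpec:
    heads: int = 8
    model_dim: int = 512
    dropout: float = 0.1

    def __post_init__(self):
        if self.model_dim % self.heads != 0:
            raise ValueError("model_dim must be divisible by heads")

    @property
    def head_dim(self) -> int:
        return self.model_dim // self.heads


@dataclass(frozen=True)
class EncoderConfig:
    n_layers: int = 3
    input_dim: int = 256
    model_dim: int = 512
    ffn_dim: int = 2048
    heads: int = 8
    dropout: float = 0.1
    positional: bool = True

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("need at least one encoder layer")
        if self.model_dim % self.heads != 0:
            raise ValueError("model_dim must be divisible by heads")


# -- reference functional ops -------------------------------------------------

def gelu(x):
    """x * Phi(x), Phi the standard normal CDF."""
    x = np.asarray(x, dtype=float)
    out = x * ndtr(x)
    return out if out.ndim else float(out)


def scaled_attention(q: np.ndarray, k: np.ndarray, v: np.ndarray):
    """Scaled dot-product attention: softmax(QK^T / sqrt(d_k)) V.

    Returns (output, weights); every weight row sums to 1.
    """
    q, k, v = (np.asarray(a, dtype=float) for a in (q, k, v))
    d_k = q.shape[-1]
    if d_k == 0:
        raise ValueError("d_k must be positive")
    logits = q @ np.swapaxes(k, -1, -2) / np.sqrt(d_k)
    logits -= logits.max(axis=-1, keepdims=True)
    e = np.exp(logits)
    weights = e / e.sum(axis=-1, keepdims=True)
    return weights @ v, weights


def sinusoidal_encoding(n_positions: int, dim: int) -> np.ndarray:
    """Fixed sinusoidal positional encodings, shape (n_positions, dim)."""
    pos = np.arange(n_positions)[:, None]
    i = np.arange(dim // 2)[None, :]
    angles = pos / (10000.0 ** (2.0 * i / dim))
    enc = np.zeros((n_positions, dim))
    enc[:, 0::2] = np.sin(angles)
    enc[:, 1::2] = np.cos(angles)
    return enc


# -- differentiable modules ---------------------------------------------------

class MultiHeadAttention(Module):
    """h parallel scaled-attention maps over learned projections."""

    def __init__(self, spec: AttentionSpec, rng: np.random.Generator,
                 zero_out: bool = False):
        super().__init__()
        d = spec.model_dim
        self.spec = spec
        self.w_q = Linear(d, d, rng)
        self.w_k = Linear(d, d, rng)
        self.w_v = Linear(d, d, rng)
        self.w_o = Linear(d, d, rng, zero_init=zero_out)

    def __call__(self, x: Tensor) -> Tensor:
        b, t, d = x.shape
        h, hd = self.spec.heads, self.spec.head_dim

        def split(z: Tensor) -> Tensor:  # (B,T,D) -> (B,h,T,hd)
            return z.reshape(b, t, h, hd).transpose((0, 2, 1, 3))

        q, k, v = split(self.w_q(x)), split(self.w_k(x)), split(self.w_v(x))
        logits = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(hd))
        weights = logits.softmax(axis=-1)
        out = weights @ v                                  # (B,h,T,hd)
        out = out.transpose((0, 2, 1, 3)).reshape(b, t, d)
        return self.w_o(out)


class FeedForward(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator,
                 zero_out: bool = False):
        super().__init__()
        self.lift = Linear(dim, hidden, rng)
        self.proj = Linear(hidden, dim, rng, zero_init=zero_out)

    def __call__(self, x: Tensor) -> Tensor:
        return self.proj(self.lift(x).gelu())


class EncoderLayer(Module):
    """Post-norm transformer layer: Add & Norm around attention and FFN."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator,
                 zero_blocks: bool = False):
        super().__init__()
        spec = AttentionSpec(heads=cfg.heads, model_dim=cfg.model_dim,
                             dropout=cfg.dropout)
        self.attn = MultiHeadAttention(spec, rng, zero_out=zero_blocks)
        self.ffn = FeedForward(cfg.model_dim, cfg.ffn_dim, rng,
                               zero_out=zero_blocks)
        self.norm1 = LayerNorm(cfg.model_dim)
        self.norm2 = LayerNorm(cfg.model_dim)
        self.p_drop = cfg.dropout

    def __call__(self, x: Tensor, rng: np.random.Generator) -> Tensor:
        x = self.norm1(x + dropout(self.attn(x), self.p_drop, rng, self.training))
        x = self.norm2(x + dropout(self.ffn(x), self.p_drop, rng, self.training))
        return x


class Encoder(Module):
    """256 -> 512 lift, positional encoding, stacked layers, mean pooling."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.lift = Linear(cfg.input_dim, cfg.model_dim, rng)
        self.layers = [EncoderLayer(cfg, rng) for _ in range(cfg.n_layers)]

    def __call__(self, x: Tensor,
                 rng: np.random.Generator | None = None) -> tuple[Tensor, Tensor]:
        """Returns (sequence features (B, T, model_dim), pooled (B, model_dim))."""
        if rng is None:
            rng = np.random.default_rng(0)
        h = self.lift(x)
        if self.cfg.positional:
            h = h + Tensor(sinusoidal_encoding(h.shape[-2], self.cfg.model_dim))
        for layer in self.layers:
            h = layer(h, rng)
        pooled = h.mean(axis=-2)
        return h, pooled


def encoder_forward(local_feats: np.ndarray, cfg: EncoderConfig,
                    seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Convenience eval-mode pass: (T, input_dim) -> ((T, 512), (512,))."""
    rng = np.random.default_rng(seed)
    enc = Encoder(cfg, rng).eval()
    seq, pooled = enc(Tensor(np.asarray(local_feats)[None]))
    return seq.data[0], pooled.data[0]
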