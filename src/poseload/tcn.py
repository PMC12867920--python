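"""Causal dilated temporal convolution stacks (the local-feature extractor).

Three independent 5-layer stacks -- one per input branch (joints, bones,
velocities) -- each layer being causal dilated convolution -> LeakyReLU
(slope 0.1) -> LayerNorm, with the dilation schedule [1, 2, 4, 8, 16].
Branch outputs are concatenated and linearly fused into a 256-dimensional
local feature vector per frame.

Layer l computes y_t = sum_{k=0}^{K-1} w_k . x_{t - d_l k} with zero past
padding, so outputs at time t never depend on later frames.  The default
kernel size is 2, under which the cumulative receptive field of the stack
is 1 + (K-1) * sum(d) = 32 frames (2 frames after the first layer); the
kernel size is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Linear, Module, Tensor
from .features import BranchFeatures

DEFAULT_DILATIONS = (1, 2, 4, 8, 16)


@dataclass(frozen=True)
class TcnConfig:
    n_layers: int = 5
    dilations: tuple[int, ...] = DEFAULT_DILATIONS
    kernel_size: int = 2
    branch_channels: int = 128
    out_dim: int = 256
    leaky_slope: float = 0.1

    def __post_init__(self):
        if len(self.dilations) != self.n_layers:
            raise ValueError("need one dilation per layer")
        if any(d <= 0 for d in self.dilations):
            raise ValueError("dilations must be positive")
        if self.kernel_size < 1:
            raise ValueError("kernel_size must be >= 1")
        if not 0.0 < self.leaky_slope < 1.0:
            raise ValueError("leaky_slope must be in (0, 1)")


def receptive_field(cfg: TcnConfig) -> int:
    """Frames of input influencing one output frame of the full stack."""
    return 1 + (cfg.kernel_size - 1) * sum(cfg.dilations)


def receptive_field_per_layer(cfg: TcnConfig) -> list[int]:
    """Cumulative receptive field after each layer (strictly growing)."""
    rf, out = 1, []
    for d in cfg.dilations:
        rf += (cfg.kernel_size - 1) * d
        out.append(rf)
    return out


# -- reference functional ops (NumPy, used directly and as oracles) ---------

def causal_dilated_conv(x: np.ndarray, weights: np.ndarray,
                        dilation: int) -> np.ndarray:
    """Single-channel causal dilated convolution with zero past padding.

    y_t = sum_k weights[k] * x[t - dilation*k]; x may be (T,) or (T, C)
    with the same kernel applied per channel.
    """
    if dilation <= 0:
        raise ValueError("dilation must be positive")
    x = np.asarray(x, dtype=float)
    weights = np.asarray(weights, dtype=float)
    y = np.zeros_like(x)
    for k, w in enumerate(weights):
        shift = dilation * k
        if shift == 0:
            y += w * x
        elif shift < x.shape[0]:
            y[shift:] += w * x[:-shift]
    return y


def leaky_relu(x, slope: float = 0.1):
    """x for x >= 0, slope*x otherwise."""
    x = np.asarray(x, dtype=float)
    out = np.where(x >= 0.0, x, slope * x)
    return out if out.ndim else float(out)


def layer_norm(x: np.ndarray, gamma=1.0, beta=0.0, eps: float = 1e-5) -> np.ndarray:
    """gamma * (x - mu) / sqrt(var + eps) + beta over the channel axis."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    return gamma * (x - mu) / np.sqrt(var + eps) + beta


# -- differentiable layers ---------------------------------------------------

class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centred = x - mu
        var = (centred * centred).mean(axis=-1, keepdims=True)
        return centred * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class CausalConv1d(Module):
    """Multi-channel causal dilated convolution over (B, T, C) tensors."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 dilation: int, rng: np.random.Generator):
        super().__init__()
        if dilation <= 0:
            raise ValueError("dilation must be positive")
        scale = np.sqrt(2.0 / (in_channels * kernel_size + out_channels))
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(kernel_size, in_channels, out_channels)),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)
        self.kernel_size = kernel_size
        self.dilation = dilation

    def __call__(self, x: Tensor) -> Tensor:
        out = None
        for k in range(self.kernel_size):
            wk = _slice_kernel(self.weight, k)
            term = x.time_shift(self.dilation * k) @ wk
            out = term if out is None else out + term
        return out + self.bias


def _slice_kernel(weight: Tensor, k: int) -> Tensor:
    """Select tap k of a (K, Cin, Cout) kernel as a (Cin, Cout) tensor."""
    data = weight.data[k]

    def backward(g):
        if weight._in_graph():
            gg = np.zeros_like(weight.data)
            gg[k] = g
            weight._accum(gg)

    return Tensor._make(data, (weight,), backward)


class TcnBranch(Module):
    """One 5-layer stack: conv -> LeakyReLU -> LayerNorm per layer."""

    def __init__(self, in_dim: int, cfg: TcnConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.layers = []
        channels = in_dim
        for d in cfg.dilations:
            conv = CausalConv1d(channels, cfg.branch_channels, cfg.kernel_size,
                                d, rng)
            norm = LayerNorm(cfg.branch_channels)
            self.layers.append((conv, norm))
            channels = cfg.branch_channels
        # flat attribute so Module.parameters finds them
        self._flat = [m for pair in self.layers for m in pair]

    def __call__(self, x: Tensor) -> Tensor:
        for conv, norm in self.layers:
            x = norm(conv(x).leaky_relu(self.cfg.leaky_slope))
        return x


class TcnFusion(Module):
    """Three branch stacks fused into a 256-d per-frame local feature."""

    def __init__(self, cfg: TcnConfig, rng: np.random.Generator,
                 in_dims: tuple[int, int, int] = (75, 72, 75)):
        super().__init__()
        self.cfg = cfg
        self.joint_branch = TcnBranch(in_dims[0], cfg, rng)
        self.bone_branch = TcnBranch(in_dims[1], cfg, rng)
        self.velocity_branch = TcnBranch(in_dims[2], cfg, rng)
        self.fuse = Linear(3 * cfg.branch_channels, cfg.out_dim, rng)

    def __call__(self, joint: Tensor, bone: Tensor, velocity: Tensor) -> Tensor:
        if not (joint.shape[-2] == bone.shape[-2] == velocity.shape[-2]):
            raise ValueError("branch streams must share the frame count")
        from .autodiff import concat
        parts = [self.joint_branch(joint), self.bone_branch(bone),
                 self.velocity_branch(velocity)]
        return self.fuse(concat(parts, axis=-1))


def tcn_forward(branches: BranchFeatures, cfg: TcnConfig,
                seed: int = 0) -> np.ndarray:
    """Convenience forward pass: branch streams -> (T, out_dim) features."""
    rng = np.random.default_rng(seed)
    model = TcnFusion(cfg, rng)
    out = model(Tensor(branches.joint_stream[None]),
                Tensor(branches.bone_stream[None]),
                Tensor(branches.velocity_stream[None]))
    return out.data[0]
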