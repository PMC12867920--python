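"""Standardization chain for pose sequences.

Order of the pipeline: optional gray-variance frame filtering (video input
only), per-joint per-axis min-max normalization to [0, 1], length
standardization to a fixed 100 frames (linear interpolation of short
sequences, beat-aligned segmentation of long ones), 5-frame Gaussian
smoothing (sigma 0.8, reflected edges), and three seeded augmentation
operators: temporal scaling (+/-10 % rate), spatial noise (+/-5 % of axis
range) and per-frame joint-angle jitter (+/-3 degrees).  The augmentation
operators double as the interference scenarios of robustness experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d
from scipy.spatial.transform import Rotation

from .features import DEFAULT_TOPOLOGY, SkeletonTopology
from .synth import PoseSequence


# -- frame-quality filter ---------------------------------------------------

def gray_variance_filter(frames, threshold: float = 50.0) -> list[int]:
    """Indices of frames whose pixel-intensity variance is >= threshold.

    Frames below the threshold are considered blurry and dropped; order is
    preserved.  Each frame must be a 2-D intensity array.
    """
    kept = []
    for i, frame in enumerate(frames):
        arr = np.asarray(frame, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"frame {i} is not a 2-D intensity image")
        if arr.var() >= threshold:
            kept.append(i)
    return kept


# -- min-max normalization --------------------------------------------------

@dataclass
class NormalizationStats:
    """Per-joint per-axis coordinate extrema, shape (25, 3) each."""

    x_min: np.ndarray
    x_max: np.ndarray

    def __post_init__(self):
        self.x_min = np.asarray(self.x_min, dtype=float)
        self.x_max = np.asarray(self.x_max, dtype=float)
        if np.any(self.x_max < self.x_min):
            raise ValueError("x_max must be >= x_min elementwise")

    @classmethod
    def from_sequences(cls, sequences) -> "NormalizationStats":
        stacked = np.concatenate([np.asarray(s.coords) for s in sequences], axis=0)
        return cls(x_min=stacked.min(axis=0), x_max=stacked.max(axis=0))

    def to_json(self) -> str:
        return json.dumps({"x_min": self.x_min.tolist(),
                           "x_max": self.x_max.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "NormalizationStats":
        d = json.loads(text)
        return cls(x_min=np.array(d["x_min"]), x_max=np.array(d["x_max"]))


def minmax_normalize(seq: PoseSequence, stats: NormalizationStats) -> PoseSequence:
    """Map each coordinate to (x - x_min) / (x_max - x_min).

    Eliminates dancer height and body-type scale differences.  A degenerate
    axis (x_max == x_min, a static channel) maps to 0 rather than erroring.
    """
    span = stats.x_max - stats.x_min
    safe = np.where(span == 0.0, 1.0, span)
    out = (seq.coords - stats.x_min) / safe
    out = np.where(span == 0.0, 0.0, out)
    return seq.with_coords(out)


# -- length standardization ---------------------------------------------------

def _resample(coords: np.ndarray, target: int) -> np.ndarray:
    """Linear time resampling of a (T, ...) array to `target` frames."""
    t = coords.shape[0]
    if t == target:
        return coords.copy()
    old = np.linspace(0.0, 1.0, t)
    new = np.linspace(0.0, 1.0, target)
    flat = coords.reshape(t, -1)
    out = np.empty((target, flat.shape[1]))
    for c in range(flat.shape[1]):
        out[:, c] = np.interp(new, old, flat[:, c])
    return out.reshape((target,) + coords.shape[1:])


def standardize_length(seq: PoseSequence, target: int = 100) -> list[PoseSequence]:
    """Standardize a sequence to exactly `target` frames.

    Short sequences are linearly interpolated up to `target`.  Long
    sequences are cut at the music-beat frame nearest each multiple of
    `target` (uniform cut points when no beats are annotated), then each
    segment is linearly resampled to `target` frames.
    """
    t = seq.n_frames
    if t < 2:
        raise ValueError("need at least 2 frames")
    if t == target:
        return [seq.with_coords(seq.coords.copy())]
    if t < target:
        return [seq.with_coords(_resample(seq.coords, target),
                                beat_frames=_rescale_beats(seq.beat_frames, t, target))]

    n_seg = int(np.ceil(t / target))
    cuts = [0]
    for m in range(1, n_seg):
        ideal = m * target
        if seq.beat_frames.size:
            beats = seq.beat_frames
            cut = int(beats[np.argmin(np.abs(beats - ideal))])
        else:  # uniform fallback
            cut = int(round(m * t / n_seg))
        if cut <= cuts[-1]:
            cut = cuts[-1] + 2  # keep segments at least 2 frames
        cuts.append(min(cut, t - 2 * (n_seg - m)))
    cuts.append(t)

    out = []
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        segment = seq.coords[lo:hi]
        beats = seq.beat_frames[(seq.beat_frames >= lo) & (seq.beat_frames < hi)] - lo
        out.append(seq.with_coords(
            _resample(segment, target),
            beat_frames=_rescale_beats(beats, hi - lo, target)))
    return out


def _rescale_beats(beats: np.ndarray, old_t: int, new_t: int) -> np.ndarray:
    if beats.size == 0:
        return beats.copy()
    scaled = np.unique(np.clip(np.round(beats * (new_t - 1) / max(old_t - 1, 1)),
                               0, new_t - 1).astype(int))
    return scaled


# -- Gaussian smoothing -------------------------------------------------------

def gaussian_kernel(window: int = 5, sigma: float = 0.8) -> np.ndarray:
    """Discrete Gaussian weights over a centred odd window, normalized to 1."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    half = window // 2
    x = np.arange(-half, half + 1, dtype=float)
    w = np.exp(-0.5 * (x / sigma) ** 2)
    return w / w.sum()


def gaussian_smooth(seq: PoseSequence, window: int = 5,
                    sigma: float = 0.8) -> PoseSequence:
    """Sliding-window Gaussian filter along time, reflected edges."""
    kernel = gaussian_kernel(window, sigma)
    t = seq.coords.shape[0]
    flat = seq.coords.reshape(t, -1)
    smoothed = convolve1d(flat, kernel, axis=0, mode="reflect")
    return seq.with_coords(smoothed.reshape(seq.coords.shape))


# -- augmentation -------------------------------------------------------------

@dataclass
class AugmentSpec:
    temporal_scale_pct: float = 10.0
    spatial_noise_pct: float = 5.0
    angle_jitter_deg: float = 3.0
    seed: int = 0

    def __post_init__(self):
        for name in ("temporal_scale_pct", "spatial_noise_pct", "angle_jitter_deg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def draw_temporal_factor(rng: np.random.Generator, scale_pct: float) -> float:
    """Resampling factor for temporal scaling, uniform in [1-s, 1+s]."""
    s = scale_pct / 100.0
    return float(rng.uniform(1.0 - s, 1.0 + s))


def _angle_jitter(coords: np.ndarray, max_deg: float, rng: np.random.Generator,
                  topo: SkeletonTopology) -> np.ndarray:
    """Rotate each bone about a random axis by at most `max_deg` per frame,
    rebuilding joints from the root so bone lengths are preserved."""
    t = coords.shape[0]
    order = topo.topological_order()
    out = coords.copy()
    angles = np.deg2rad(rng.uniform(-max_deg, max_deg, size=(t, topo.n_joints)))
    axes = rng.normal(size=(t, topo.n_joints, 3))
    axes /= np.linalg.norm(axes, axis=-1, keepdims=True)
    for j in order:
        p = topo.parents[j]
        if p == -1:
            continue
        bone = coords[:, j, :] - coords[:, p, :]
        rot = Rotation.from_rotvec(axes[:, j, :] * angles[:, j, None])
        out[:, j, :] = out[:, p, :] + rot.apply(bone)
    return out


def augment(seq: PoseSequence, spec: AugmentSpec,
            topo: SkeletonTopology = DEFAULT_TOPOLOGY) -> PoseSequence:
    """Apply the three seeded perturbation operators to a standardized sequence.

    (a) temporal resampling by a factor drawn from [1-s, 1+s], re-interpolated
    back to the original frame count; (b) additive coordinate noise bounded by
    spatial_noise_pct/100 of each axis range; (c) per-frame joint-angle jitter
    bounded by angle_jitter_deg about random axes.  Any operator with zero
    magnitude is the identity.
    """
    rng = np.random.default_rng(spec.seed)
    t = seq.n_frames
    coords = seq.coords

    if spec.temporal_scale_pct > 0:
        factor = draw_temporal_factor(rng, spec.temporal_scale_pct)
        scaled_t = max(2, int(round(t * factor)))
        coords = _resample(_resample(coords, scaled_t), t)

    if spec.angle_jitter_deg > 0:
        coords = _angle_jitter(coords, spec.angle_jitter_deg, rng, topo)

    if spec.spatial_noise_pct > 0:
        axis_range = coords.reshape(-1, 3).max(axis=0) - coords.reshape(-1, 3).min(axis=0)
        bound = spec.spatial_noise_pct / 100.0 * axis_range
        coords = coords + rng.uniform(-1.0, 1.0, size=coords.shape) * bound

    return seq.with_coords(coords)
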