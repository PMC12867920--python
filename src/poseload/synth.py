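"""Seeded generator of dance-like 25-joint 3D pose sequences.

Each sequence is a sum of per-joint sinusoids around a shared rest skeleton.
Difficulty (1-5) drives the generative factors monotonically:

* per-joint activity follows a Gibbs profile w_j ~ exp(-lam(D) * j / 24);
  lam decreases linearly with difficulty, so easy sequences concentrate
  motion in a few joints (low coordination entropy) while hard ones spread
  it evenly (entropy approaching log2 25),
* oscillation amplitude and frequency grow with difficulty,
* inter-joint phase dispersion grows with difficulty,
* physiological proxies follow lfhf = 1 + 0.5 D and delta_alpha = 0.2 D,
  plus seeded noise proportional to the coordinate noise level.

Sequences carry genre tags, music-beat frames and a dancer-height scale in
[1.55, 1.85] m.  The dataset builder computes every true load with the
label-construction chain (entropy -> composite -> min-max to [0, 100]) and
records which of the 512 encoder feature slots are wired to the load, so
feature-recovery experiments have ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import labels as labelkit
from .features import DEFAULT_TOPOLOGY, rest_pose

N_FEATURE_SLOTS = 512
N_INFORMATIVE = 40
SPLIT_FRACTIONS = {"train": 0.7, "val": 0.2, "test": 0.1}


@dataclass(frozen=True)
class GenConfig:
    n_sequences: int = 500
    frames_per_seq: int = 100
    fps: float = 25.0
    n_joints: int = 25
    difficulty_range: tuple[int, int] = (1, 5)
    genre_count: int = 10
    noise_sd: float = 0.002  # metres; matches ~2 mm annotation accuracy
    seed: int = 0

    def __post_init__(self):
        if self.n_joints != 25:
            raise ValueError("generator is defined for exactly 25 joints")
        if self.frames_per_seq < 2:
            raise ValueError("frames_per_seq must be >= 2")
        lo, hi = self.difficulty_range
        if not (1 <= lo <= hi <= 5):
            raise ValueError("difficulty_range must lie within [1, 5]")


@dataclass
class PoseSequence:
    coords: np.ndarray          # (T, 25, 3) metres
    fps: float
    genre: int
    difficulty: int
    lfhf: float
    delta_alpha: float
    beat_frames: np.ndarray     # strictly increasing, in [0, T)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        self.beat_frames = np.asarray(self.beat_frames, dtype=int)
        t = self.coords.shape[0]
        if self.beat_frames.size:
            if np.any(np.diff(self.beat_frames) <= 0):
                raise ValueError("beat_frames must be strictly increasing")
            if self.beat_frames[0] < 0 or self.beat_frames[-1] >= t:
                raise ValueError("beat_frames must lie within [0, T)")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def with_coords(self, coords: np.ndarray, beat_frames=None) -> "PoseSequence":
        return PoseSequence(
            coords=coords, fps=self.fps, genre=self.genre,
            difficulty=self.difficulty, lfhf=self.lfhf,
            delta_alpha=self.delta_alpha,
            beat_frames=self.beat_frames if beat_frames is None else beat_frames,
        )


@dataclass(frozen=True)
class GroundTruth:
    informative_feature_ids: frozenset[int]
    true_load: float  # in [0, 100]


# difficulty -> generative factor maps (monotone by construction)

def _activity_weights(difficulty: int) -> np.ndarray:
    lam = 6.0 * (5 - difficulty) / 4.0  # 6 at D=1 -> 0 at D=5 (uniform)
    w = np.exp(-lam * np.arange(25) / 24.0)
    return w / w.sum()


def _amplitude(difficulty: int) -> float:
    return 0.05 * (1.0 + 0.25 * (difficulty - 1))  # metres


def _base_freq(difficulty: int) -> float:
    return 0.8 + 0.25 * (difficulty - 1)  # Hz


def generate_sequence(cfg: GenConfig, difficulty: int, seed: int,
                      genre: int | None = None) -> PoseSequence:
    """One seeded dance-like sequence at the given difficulty."""
    if not 1 <= difficulty <= 5:
        raise ValueError(f"difficulty must be in [1, 5], got {difficulty}")
    rng = np.random.default_rng(seed)
    t_frames = cfg.frames_per_seq
    if genre is None:
        genre = int(rng.integers(cfg.genre_count))

    height = rng.uniform(1.55, 1.85)
    scale = height / 1.70
    base = rest_pose(DEFAULT_TOPOLOGY) * scale  # (25, 3)

    w = _activity_weights(difficulty)           # per-joint path-length share
    amp = _amplitude(difficulty) * 25.0 * w     # mean amplitude ~ amplitude(D)
    freq = _base_freq(difficulty)
    dispersion = (difficulty - 1) / 4.0
    phase = dispersion * rng.uniform(0.0, 2.0 * np.pi, size=25)
    axis_gain = np.array([0.8, 1.0, 0.5])       # anisotropic but joint-uniform
    axis_freq = freq * np.array([1.0, 1.0, 1.0])

    t = np.arange(t_frames) / cfg.fps           # seconds
    # coords[t, j, a] = base + amp_j * gain_a * sin(2 pi f_a t + phase_j + a)
    arg = (2.0 * np.pi * axis_freq[None, None, :] * t[:, None, None]
           + phase[None, :, None] + np.array([0.0, np.pi / 2, np.pi])[None, None, :])
    motion = amp[None, :, None] * axis_gain[None, None, :] * np.sin(arg)
    coords = base[None, :, :] + motion
    if cfg.noise_sd > 0:
        coords = coords + rng.normal(0.0, cfg.noise_sd, size=coords.shape)

    bpm = 88.0 + 6.0 * (genre % cfg.genre_count)
    step = max(2, int(round(60.0 / bpm * cfg.fps)))
    beat_frames = np.arange(0, t_frames, step)

    lfhf = max(0.01, 1.0 + 0.5 * difficulty + rng.normal(0.0, 50.0 * cfg.noise_sd))
    delta_alpha = 0.2 * difficulty + rng.normal(0.0, 25.0 * cfg.noise_sd)

    return PoseSequence(coords=coords, fps=cfg.fps, genre=genre,
                        difficulty=difficulty, lfhf=lfhf,
                        delta_alpha=delta_alpha, beat_frames=beat_frames)


def informative_feature_ids(cfg: GenConfig,
                            k: int = N_INFORMATIVE) -> frozenset[int]:
    """The fixed seeded set of encoder feature slots wired to the load."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x1F]))
    return frozenset(int(i) for i in
                     rng.choice(N_FEATURE_SLOTS, size=k, replace=False))


def generate_dataset(cfg: GenConfig):
    """Generate sequences, ground truths and a stratified split.

    Returns (sequences, truths, splits) where splits maps
    'train'/'val'/'test' to disjoint, exhaustive index arrays with genre
    distribution approximately equal across splits (70/20/10).
    """
    if cfg.n_sequences < 10:
        raise ValueError("need at least 10 sequences to stratify the split")
    lo, hi = cfg.difficulty_range
    rng = np.random.default_rng(cfg.seed)

    sequences: list[PoseSequence] = []
    for i in range(cfg.n_sequences):
        difficulty = lo + i % (hi - lo + 1)
        genre = i % cfg.genre_count
        seq_seed = int((cfg.seed * 1_000_003 + i * 7_919 + 1) % (2 ** 31))
        sequences.append(generate_sequence(cfg, difficulty, seq_seed, genre=genre))

    # true load via the label chain, min-max scaled over this corpus
    records = pd.DataFrame({
        "sequence_id": np.arange(cfg.n_sequences),
        "D": [s.difficulty for s in sequences],
        "E": [labelkit.coordination_entropy(s) for s in sequences],
        "lfhf": [s.lfhf for s in sequences],
        "delta_alpha": [s.delta_alpha for s in sequences],
    })
    table = labelkit.build_labels(records)
    info = informative_feature_ids(cfg)
    truths = [GroundTruth(informative_feature_ids=info, true_load=float(y))
              for y in table["y"]]

    # stratified 70/20/10 split: globally exact quotas (largest remainder)
    # with per-genre allocations rounded as close to proportional as the
    # quotas allow (controlled matrix rounding)
    names = list(SPLIT_FRACTIONS)
    fracs = np.array([SPLIT_FRACTIONS[k] for k in names])
    quotas = _largest_remainder(cfg.n_sequences * fracs)
    by_genre = []
    for g in range(cfg.genre_count):
        idx = np.array([i for i, s in enumerate(sequences) if s.genre == g])
        rng.shuffle(idx)
        by_genre.append(list(idx))

    counts = np.floor(np.outer([len(b) for b in by_genre], fracs)).astype(int)
    need = np.array([len(b) for b in by_genre]) - counts.sum(axis=1)
    slack = quotas - counts.sum(axis=0)
    rema = np.outer([len(b) for b in by_genre], fracs) - counts
    for g, k in sorted(np.ndindex(counts.shape),
                       key=lambda gk: -rema[gk]):
        take = min(need[g], slack[k])
        if take > 0:
            counts[g, k] += take
            need[g] -= take
            slack[k] -= take

    splits = {name: [] for name in names}
    for g, bucket in enumerate(by_genre):
        pos = 0
        for k, name in enumerate(names):
            splits[name].extend(bucket[pos:pos + counts[g, k]])
            pos += counts[g, k]
    splits = {k: np.sort(np.array(v, dtype=int)) for k, v in splits.items()}
    return sequences, truths, splits


def _largest_remainder(raw: np.ndarray) -> np.ndarray:
    counts = np.floor(raw).astype(int)
    rema = raw - counts
    for _ in range(int(round(raw.sum())) - counts.sum()):
        j = int(np.argmax(rema))
        counts[j] += 1
        rema[j] = -1.0
    return counts


def encode_proxy_features(sequences: list[PoseSequence],
                          truths: list[GroundTruth],
                          seed: int) -> np.ndarray:
    """Per-sequence 512-d global feature vectors with known informative slots.

    The informative slots carry seeded linear mixes of the standardized
    generative factors (D, E, LF/HF, delta_alpha) plus observation noise;
    every other slot is pure standard-normal noise.  This emulates the
    pooled encoder output for feature-selection experiments where the
    wiring must be known exactly.
    """
    rng = np.random.default_rng(seed)
    factors = np.column_stack([
        [s.difficulty for s in sequences],
        [labelkit.coordination_entropy(s) for s in sequences],
        [s.lfhf for s in sequences],
        [s.delta_alpha for s in sequences],
    ]).astype(float)
    sd = factors.std(axis=0)
    sd[sd == 0] = 1.0
    z = (factors - factors.mean(axis=0)) / sd

    info = sorted(truths[0].informative_feature_ids)
    x = rng.standard_normal((len(sequences), N_FEATURE_SLOTS))
    mix_rng = np.random.default_rng(np.random.SeedSequence([seed, 0x2F]))
    for col in info:
        coef = mix_rng.normal(0.0, 1.0, size=z.shape[1])
        coef /= np.linalg.norm(coef)
        x[:, col] = z @ coef + 0.3 * rng.standard_normal(len(sequences))
    return x


# -- on-disk dialects ------------------------------------------------------

def sequence_to_frame_csv(seq: PoseSequence) -> pd.DataFrame:
    """Flat dialect: one row per frame, columns frame, j00_x ... j24_z."""
    t, j, _ = seq.coords.shape
    cols = [f"j{k:02d}_{a}" for k in range(j) for a in "xyz"]
    df = pd.DataFrame(seq.coords.reshape(t, -1), columns=cols)
    df.insert(0, "frame", np.arange(t))
    return df


def save_dataset(out_dir: str | Path, sequences: list[PoseSequence],
                 truths: list[GroundTruth], splits: dict[str, np.ndarray],
                 cfg: GenConfig) -> None:
    """One NPZ per split plus a JSON manifest with per-sequence metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, idx in splits.items():
        np.savez(
            out / f"{name}.npz",
            coords=np.stack([sequences[i].coords for i in idx]),
            true_load=np.array([truths[i].true_load for i in idx]),
            indices=idx,
        )
    manifest = {
        "generator": "poseload.synth",
        "config": {
            "n_sequences": cfg.n_sequences, "frames_per_seq": cfg.frames_per_seq,
            "fps": cfg.fps, "genre_count": cfg.genre_count,
            "noise_sd": cfg.noise_sd, "seed": cfg.seed,
        },
        "informative_feature_ids": sorted(truths[0].informative_feature_ids),
        "sequences": [
            {"id": i, "genre": s.genre, "difficulty": s.difficulty,
             "lfhf": s.lfhf, "delta_alpha": s.delta_alpha,
             "n_frames": s.n_frames, "true_load": truths[i].true_load}
            for i, s in enumerate(sequences)
        ],
        "splits": {k: v.tolist() for k, v in splits.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_split(out_dir: str | Path, name: str):
    data = np.load(Path(out_dir) / f"{name}.npz")
    return data["coords"], data["true_load"], data["indices"]
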