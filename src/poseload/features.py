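"""Three-branch decomposition of a pose sequence: joints, bones, velocities.

A 25-joint 3D sequence is split into the parallel streams a temporal model
consumes: raw joint positions (T x 75), parent-relative bone vectors
(T x 72, 24 bones), and finite-difference joint velocities (T x 75).
The skeleton tree is configuration, not a constant of the maths: every
operator here works for any valid tree over 25 joints.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

N_JOINTS = 25

# Default 25-node tree: a COCO-style skeleton extended with spine, hands,
# heels/toes and head-top so that 25 joints form a single connected tree.
DEFAULT_JOINT_NAMES = [
    "pelvis", "spine", "chest", "neck", "head",            # 0-4
    "nose", "left_shoulder", "left_elbow", "left_wrist",   # 5-8
    "left_hand", "right_shoulder", "right_elbow",          # 9-11
    "right_wrist", "right_hand", "left_hip", "left_knee",  # 12-15
    "left_ankle", "left_heel", "left_toe", "right_hip",    # 16-19
    "right_knee", "right_ankle", "right_heel", "right_toe",  # 20-23
    "head_top",                                            # 24
]
DEFAULT_PARENTS = [
    -1, 0, 1, 2, 3,
    4, 2, 6, 7,
    8, 2, 10,
    11, 12, 0, 14,
    15, 16, 16, 0,
    19, 20, 21, 21,
    4,
]

# Rest-pose offsets (metres) of each joint from its parent, for a ~1.70 m
# figure; the root offset is the pelvis height above ground.
DEFAULT_OFFSETS = np.array([
    [0.00, 0.00, 0.95],    # pelvis
    [0.00, 0.00, 0.20],    # spine
    [0.00, 0.00, 0.20],    # chest
    [0.00, 0.00, 0.15],    # neck
    [0.00, 0.00, 0.10],    # head
    [0.00, 0.10, 0.03],    # nose
    [0.18, 0.00, 0.00],    # left_shoulder
    [0.28, 0.00, -0.02],   # left_elbow
    [0.25, 0.00, -0.02],   # left_wrist
    [0.09, 0.00, 0.00],    # left_hand
    [-0.18, 0.00, 0.00],   # right_shoulder
    [-0.28, 0.00, -0.02],  # right_elbow
    [-0.25, 0.00, -0.02],  # right_wrist
    [-0.09, 0.00, 0.00],   # right_hand
    [0.10, 0.00, -0.05],   # left_hip
    [0.00, 0.00, -0.42],   # left_knee
    [0.00, 0.00, -0.40],   # left_ankle
    [0.00, -0.06, -0.06],  # left_heel
    [0.00, 0.14, -0.06],   # left_toe
    [-0.10, 0.00, -0.05],  # right_hip
    [0.00, 0.00, -0.42],   # right_knee
    [0.00, 0.00, -0.40],   # right_ankle
    [0.00, -0.06, -0.06],  # right_heel
    [0.00, 0.14, -0.06],   # right_toe
    [0.00, 0.00, 0.12],    # head_top
])


@dataclass(frozen=True)
class SkeletonTopology:
    """Parent map over 25 joints; exactly one root (parent -1)."""

    parents: tuple[int, ...]
    names: tuple[str, ...] = field(default=tuple(DEFAULT_JOINT_NAMES))

    def __post_init__(self):
        parents = tuple(int(p) for p in self.parents)
        object.__setattr__(self, "parents", parents)
        n = len(parents)
        roots = [j for j, p in enumerate(parents) if p == -1]
        if len(roots) != 1:
            raise ValueError(f"topology must have exactly one root, found {len(roots)}")
        for j, p in enumerate(parents):
            if p != -1 and not (0 <= p < n):
                raise ValueError(f"joint {j} has out-of-range parent {p}")
        # cycle / connectivity check: walk each joint up to the root
        for j in range(n):
            seen = set()
            cur = j
            while cur != -1:
                if cur in seen:
                    raise ValueError("topology contains a cycle")
                seen.add(cur)
                cur = parents[cur]

    @property
    def root(self) -> int:
        return self.parents.index(-1)

    @property
    def n_joints(self) -> int:
        return len(self.parents)

    def non_root_joints(self) -> list[int]:
        return [j for j in range(self.n_joints) if j != self.root]

    def topological_order(self) -> list[int]:
        """Joints ordered parent-before-child (root first)."""
        order, placed = [], set()
        pending = list(range(self.n_joints))
        while pending:
            for j in list(pending):
                p = self.parents[j]
                if p == -1 or p in placed:
                    order.append(j)
                    placed.add(j)
                    pending.remove(j)
        return order

    def to_json(self) -> str:
        return json.dumps({"names": list(self.names), "parents": list(self.parents)})

    @classmethod
    def from_json(cls, text: str) -> "SkeletonTopology":
        d = json.loads(text)
        return cls(parents=tuple(d["parents"]), names=tuple(d["names"]))


DEFAULT_TOPOLOGY = SkeletonTopology(parents=tuple(DEFAULT_PARENTS))


def rest_pose(topo: SkeletonTopology = DEFAULT_TOPOLOGY,
              offsets: np.ndarray = DEFAULT_OFFSETS) -> np.ndarray:
    """Absolute rest-pose joint positions from per-bone offsets, shape (25, 3)."""
    pos = np.zeros((topo.n_joints, 3))
    for j in topo.topological_order():
        p = topo.parents[j]
        pos[j] = offsets[j] if p == -1 else pos[p] + offsets[j]
    return pos


@dataclass
class BranchFeatures:
    """Flattened per-frame streams feeding the three TCN branches."""

    joint_stream: np.ndarray     # (T, 75)
    bone_stream: np.ndarray      # (T, 72)
    velocity_stream: np.ndarray  # (T, 75)

    def __post_init__(self):
        t = self.joint_stream.shape[0]
        if self.bone_stream.shape[0] != t or self.velocity_stream.shape[0] != t:
            raise ValueError("branch streams must share the frame count")
        for s in (self.joint_stream, self.bone_stream, self.velocity_stream):
            if not np.all(np.isfinite(s)):
                raise ValueError("branch streams must be finite")


def _coords_of(seq) -> tuple[np.ndarray, float]:
    if hasattr(seq, "coords"):
        return np.asarray(seq.coords, dtype=float), float(seq.fps)
    return np.asarray(seq, dtype=float), 25.0


def bone_vectors(seq, topo: SkeletonTopology = DEFAULT_TOPOLOGY) -> np.ndarray:
    """Parent-relative bone vectors, shape (T, 24, 3), ordered by child joint id.

    bone_j(t) = coords_j(t) - coords_parent(j)(t); translation-invariant by
    construction, capturing the spatial structure between body segments.
    """
    coords, _ = _coords_of(seq)
    children = topo.non_root_joints()
    parents = [topo.parents[j] for j in children]
    return coords[:, children, :] - coords[:, parents, :]


def velocities(seq) -> np.ndarray:
    """First-difference joint velocities in m/s, shape (T, 25, 3).

    v(t) = (x(t) - x(t-1)) * fps, with v(0) = v(1) so all streams keep T.
    """
    coords, fps = _coords_of(seq)
    if coords.shape[0] < 2:
        raise ValueError("velocity needs at least 2 frames")
    v = np.empty_like(coords)
    v[1:] = (coords[1:] - coords[:-1]) * fps
    v[0] = v[1]
    return v


def branch_features(seq, topo: SkeletonTopology = DEFAULT_TOPOLOGY) -> BranchFeatures:
    """Decompose a sequence into the joint / bone / velocity streams."""
    coords, _ = _coords_of(seq)
    t = coords.shape[0]
    return BranchFeatures(
        joint_stream=coords.reshape(t, -1),
        bone_stream=bone_vectors(seq, topo).reshape(t, -1),
        velocity_stream=velocities(seq).reshape(t, -1),
    )
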