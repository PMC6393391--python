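"""Synthetic tubular phantoms with known ground truth.

Emulates how a fluorescently labelled neurite appears in a light-microscopy
stack: a 1-voxel-wide binary centreline, blurred by a 3-D Gaussian kernel
standing in for the point-spread function, rescaled to an 8-bit-like maximum
of 255, and corrupted by additive Gaussian white noise (clipped below at 0 so
intensities stay physical).  Two phantom families are provided:

* a *fold line* — two straight legs meeting at a corner of prescribed angle,
  the canonical tortuous structure for exercising the L1 skeleton optimizer;
* a *Y-junction* — three straight arms with per-arm blur width and peak
  intensity, the fixture for the branch-point optimizer.

Every generator is a pure function of its spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import (
    DegenerateInputError,
    NeuronTree,
    SkeletonPath,
    VolumeImage,
)

__all__ = [
    "FoldLineSpec",
    "BranchPhantomSpec",
    "rasterize_polyline",
    "convolve_normalize",
    "add_noise",
    "make_fold_line_stack",
    "perturb_polyline",
    "make_branch_phantom",
    "sample_polyline",
]

DEFAULT_SHAPE = (156, 156, 57)


def _angle_at(a: np.ndarray, corner: np.ndarray, b: np.ndarray) -> float:
    u = a - corner
    v = b - corner
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass
class FoldLineSpec:
    """Two straight legs joined at a corner of prescribed angle, plus imaging noise.

    The corner angle is the angle *between the two legs*: 30 degrees is a
    sharp, strongly tortuous turn; 90 degrees a milder one.
    """

    shape: tuple[int, int, int] = DEFAULT_SHAPE
    endpoint_a: Sequence[float] = (62.5, 52.0, 28.5)
    corner: Sequence[float] = (78.0, 110.0, 28.5)
    endpoint_b: Sequence[float] = (93.5, 52.0, 28.5)
    corner_angle_deg: float = 30.0
    kernel_width: float = 1.73
    noise_sd: float = 50.0
    noise_mean: float = 0.0
    seed: int = 0
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.endpoint_a = np.asarray(self.endpoint_a, dtype=float)
        self.endpoint_b = np.asarray(self.endpoint_b, dtype=float)
        self.corner = np.asarray(self.corner, dtype=float)
        if not (0.0 < self.corner_angle_deg < 180.0):
            raise ValueError("corner_angle_deg must lie in (0, 180)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        actual = _angle_at(self.endpoint_a, self.corner, self.endpoint_b)
        if abs(actual - self.corner_angle_deg) > 0.5:
            raise ValueError(
                f"corner geometry implies {actual:.2f} deg, spec says {self.corner_angle_deg} deg")

    @classmethod
    def from_angle(cls, corner_angle_deg: float, *, shape=DEFAULT_SHAPE,
                   leg_length: float = 60.0, noise_sd: float = 50.0,
                   seed: int = 0, **kw) -> "FoldLineSpec":
        """Symmetric x-monotone fold line: corner top-middle, legs descending.

        Each leg makes ``angle/2`` with the -y axis, so the polyline from
        ``endpoint_a`` through the corner to ``endpoint_b`` is strictly
        x-monotone — convenient for x-resampling-based consistency metrics.
        """
        nx, ny, nz = shape
        corner = np.array([nx / 2.0, ny * 0.705, nz / 2.0])
        phi = np.radians(corner_angle_deg / 2.0)
        da = np.array([-np.sin(phi), -np.cos(phi), 0.0]) * leg_length
        db = np.array([np.sin(phi), -np.cos(phi), 0.0]) * leg_length
        return cls(shape=shape, endpoint_a=corner + da, corner=corner,
                   endpoint_b=corner + db, corner_angle_deg=corner_angle_deg,
                   noise_sd=noise_sd, seed=seed, **kw)


@dataclass
class BranchPhantomSpec:
    """Three straight arms radiating from a junction, each with its own blur
    width (a proxy for neurite radius) and peak intensity."""

    shape: tuple[int, int, int] = (64, 64, 32)
    junction: Sequence[float] = (32.0, 32.0, 16.0)
    arm_directions: Sequence[Sequence[float]] = (
        (1.0, 0.0, 0.0), (-0.5, np.sqrt(3) / 2, 0.0), (-0.5, -np.sqrt(3) / 2, 0.0))
    arm_lengths: Sequence[float] = (25.0, 25.0, 25.0)
    arm_intensities: Sequence[float] = (255.0, 255.0, 255.0)
    arm_kernel_widths: Sequence[float] = (1.73, 1.73, 1.73)
    noise_sd: float = 0.0
    seed: int = 0
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.junction = np.asarray(self.junction, dtype=float)
        dirs = np.asarray(self.arm_directions, dtype=float)
        dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
        for i in range(3):
            for j in range(i + 1, 3):
                if abs(np.dot(dirs[i], dirs[j])) > 1 - 1e-9:
                    raise ValueError(f"arm directions {i} and {j} are parallel")
        self.arm_directions = dirs
        ext = np.asarray(self.shape, dtype=float) * np.asarray(self.voxel_size)
        for d, L in zip(dirs, self.arm_lengths):
            tip = self.junction + d * L
            if np.any(tip < 0) or np.any(tip >= ext):
                raise ValueError(f"arm tip {tip} leaves the volume {ext}")


# ---------------------------------------------------------------------------
# Primitive generators
# ---------------------------------------------------------------------------

def sample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Sample a polyline densely: each original segment subdivided so sample
    spacing is <= ``step``; all original vertices are kept."""
    pts = np.asarray(points, dtype=float)
    out = [pts[0]]
    for a, b in zip(pts[:-1], pts[1:]):
        L = np.linalg.norm(b - a)
        n = max(1, int(np.ceil(L / step)))
        for k in range(1, n + 1):
            out.append(a + (b - a) * (k / n))
    return np.asarray(out)


def _point_segment_dist(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distances of many points to one closed segment ab."""
    ab = b - a
    denom = float(np.dot(ab, ab))
    if denom == 0.0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def rasterize_polyline(path: SkeletonPath, shape: tuple[int, int, int],
                       voxel_size: Sequence[float] = (1.0, 1.0, 1.0)) -> VolumeImage:
    """Binary volume: a voxel is 1 iff its centre lies within half a voxel
    diagonal of the polyline.

    The tolerance (half the diagonal of one voxel) guarantees 26-connectivity
    of the marked set along the line without thickening axis-aligned runs.
    """
    vs = np.asarray(voxel_size, dtype=float)
    ext = np.asarray(shape) * vs
    pts = path.points
    if np.any(pts < 0) or np.any(pts >= ext):
        raise ValueError(f"polyline leaves the volume (extent {ext})")
    tol = 0.5 * float(np.linalg.norm(vs))
    data = np.zeros(shape)
    segs = list(zip(pts[:-1], pts[1:])) if len(pts) > 1 else [(pts[0], pts[0])]
    for a, b in segs:
        lo = np.maximum(np.floor((np.minimum(a, b) - tol) / vs).astype(int), 0)
        hi = np.minimum(np.ceil((np.maximum(a, b) + tol) / vs).astype(int) + 1,
                        np.asarray(shape))
        grids = np.meshgrid(*(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij")
        idx = np.stack([g.ravel() for g in grids], axis=1)
        if idx.size == 0:
            continue
        centers = (idx + 0.5) * vs
        hit = _point_segment_dist(centers, np.asarray(a), np.asarray(b)) <= tol
        sel = idx[hit]
        data[sel[:, 0], sel[:, 1], sel[:, 2]] = 1.0
    return VolumeImage(data, tuple(vs))


def convolve_normalize(binary: VolumeImage, kernel_width: float) -> VolumeImage:
    """Gaussian-blur (sigma = ``kernel_width`` voxels per axis, truncated at
    4 sigma) and rescale linearly so the maximum is exactly 255."""
    if not np.any(binary.data):
        raise DegenerateInputError("cannot normalize an all-zero volume")
    blurred = gaussian_filter(binary.data, sigma=kernel_width, truncate=4.0, mode="constant")
    blurred *= 255.0 / blurred.max()
    np.clip(blurred, 0.0, None, out=blurred)
    return VolumeImage(blurred, binary.voxel_size)


def add_noise(image: VolumeImage, mean: float, sd: float, seed: int) -> VolumeImage:
    """Add i.i.d. Gaussian(mean, sd) to every voxel, clipping below at 0."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0 and mean == 0:
        return VolumeImage(image.data.copy(), image.voxel_size)
    rng = np.random.default_rng(seed)
    noisy = image.data + rng.normal(mean, sd, size=image.data.shape)
    return VolumeImage(np.clip(noisy, 0.0, None), image.voxel_size)


# ---------------------------------------------------------------------------
# Composite phantoms
# ---------------------------------------------------------------------------

def make_fold_line_stack(spec: FoldLineSpec) -> tuple[VolumeImage, SkeletonPath]:
    """Rasterize -> blur -> normalize -> noise, plus dense ground truth.

    The ground truth is the fold line sampled at <= 0.5 um so that
    distance-to-truth metrics are not resolution-limited; the corner vertex is
    always one of the samples.
    """
    fold = np.asarray([spec.endpoint_a, spec.corner, spec.endpoint_b])
    truth = SkeletonPath(sample_polyline(fold, 0.5))
    binary = rasterize_polyline(SkeletonPath(fold), spec.shape, spec.voxel_size)
    clean = convolve_normalize(binary, spec.kernel_width)
    noisy = add_noise(clean, spec.noise_mean, spec.noise_sd, spec.seed)
    return noisy, truth


def perturb_polyline(path: SkeletonPath, magnitude: float, seed: int,
                     fix_ends: bool = True) -> SkeletonPath:
    """Displace points by i.i.d. uniform offsets in [-magnitude, magnitude]
    per axis; endpoints left untouched when ``fix_ends`` is set."""
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    pts = path.points.copy()
    if magnitude == 0:
        return SkeletonPath(pts)
    rng = np.random.default_rng(seed)
    offsets = rng.uniform(-magnitude, magnitude, size=pts.shape)
    if fix_ends:
        offsets[0] = 0.0
        offsets[-1] = 0.0
    return SkeletonPath(pts + offsets)


def make_branch_phantom(spec: BranchPhantomSpec) -> tuple[VolumeImage, NeuronTree]:
    """Three straight arms, each rasterized and blurred with its own kernel
    width and scaled to its own peak intensity before summation and noise.

    The ground-truth tree runs from the tip of arm 0 to the junction, which
    forks into arms 1 and 2 (exactly one node with two children); nodes are
    spaced ~1 um along each arm.
    """
    vs = np.asarray(spec.voxel_size, dtype=float)
    data = np.zeros(spec.shape)
    for d, L, peak, kw in zip(spec.arm_directions, spec.arm_lengths,
                              spec.arm_intensities, spec.arm_kernel_widths):
        arm = SkeletonPath(np.asarray([spec.junction, spec.junction + d * L]))
        binary = rasterize_polyline(arm, spec.shape, spec.voxel_size)
        blurred = gaussian_filter(binary.data, sigma=kw, truncate=4.0, mode="constant")
        data += blurred * (peak / blurred.max())
    image = add_noise(VolumeImage(data, tuple(vs)), 0.0, spec.noise_sd, spec.seed)

    def arm_nodes(arm_idx: int) -> np.ndarray:
        d = spec.arm_directions[arm_idx]
        L = spec.arm_lengths[arm_idx]
        n = int(np.floor(L))
        return np.asarray([spec.junction + d * t for t in np.arange(1.0, n + 1.0)])

    a0, a1, a2 = (arm_nodes(i) for i in range(3))
    # tip of arm 0 -> junction -> forks into arms 1 and 2
    positions = np.vstack([a0[::-1], spec.junction, a1, a2])
    n0, n1 = len(a0), len(a1)
    ids = np.arange(1, len(positions) + 1)
    parents = np.empty(len(positions), dtype=int)
    parents[0] = -1
    parents[1:n0 + 1] = ids[:n0]                     # chain down arm 0 to junction
    junction_id = ids[n0]
    parents[n0 + 1] = junction_id                    # first node of arm 1
    for k in range(n0 + 2, n0 + 1 + n1):
        parents[k] = ids[k - 1]
    parents[n0 + 1 + n1] = junction_id               # first node of arm 2
    for k in range(n0 + 2 + n1, len(positions)):
        parents[k] = ids[k - 1]
    tree = NeuronTree(ids, np.full(len(ids), 3), positions,
                      np.full(len(ids), 1.0), parents)
    return image, tree
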