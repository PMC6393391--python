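"""Domain types, coordinate conventions and I/O for skeleton optimization.

Conventions
-----------
* All skeleton coordinates are physical micrometres (um), continuous.
* Image volumes are indexed ``(ix, iy, iz)``; the voxel containing a point is
  ``floor(coord / voxel_size)`` (0-based) and its physical centre is
  ``(index + 0.5) * voxel_size``.  This single mapping makes rules phrased in
  "voxel sizes" well defined on anisotropic data.
* A multi-page TIFF stores z-planes of shape ``(ny, nx)``; readers/writers
  transpose between that layout and the ``(nx, ny, nz)`` in-memory layout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SkelassoError",
    "SwcParseError",
    "SwcStructureError",
    "StackFormatError",
    "DegenerateInputError",
    "DivergenceError",
    "DegenerateBranchError",
    "FrameMismatchError",
    "MetricInapplicableError",
    "BranchSkip",
    "VolumeImage",
    "SkeletonPath",
    "NeuronTree",
    "BranchTriplet",
    "SolverConfig",
    "read_swc",
    "write_swc",
    "read_stack",
    "write_stack",
    "sample_neighborhood",
]


class SkelassoError(Exception):
    """Base class for all package errors."""


class SwcParseError(SkelassoError):
    """Malformed SWC line (message names the 1-based line number)."""


class SwcStructureError(SkelassoError):
    """SWC violates tree structure (dangling parent, cycle, duplicate id)."""


class StackFormatError(SkelassoError):
    """Image stack on disk is inconsistent with its declared layout."""


class DegenerateInputError(SkelassoError):
    """Input is degenerate for the requested operation (e.g. all-zero image)."""


class DivergenceError(SkelassoError):
    """Split-Bregman iteration produced a non-finite objective."""


class DegenerateBranchError(SkelassoError):
    """Branch-frame construction failed (segments too short / too close)."""


class FrameMismatchError(SkelassoError):
    """Skeleton and image do not share a coordinate frame."""


class MetricInapplicableError(SkelassoError):
    """A metric's preconditions (e.g. x-monotonicity) do not hold."""


class BranchSkip(SkelassoError):
    """Signal that a branch point cannot be optimized (arm too short)."""


def as_point(p: Sequence[float]) -> np.ndarray:
    """Coerce to a finite float64 3-vector (physical um)."""
    a = np.asarray(p, dtype=float).reshape(3)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"non-finite point coordinates: {a}")
    return a


# ---------------------------------------------------------------------------
# Volume image
# ---------------------------------------------------------------------------

@dataclass
class VolumeImage:
    """A 3-D intensity grid with per-axis physical voxel size.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Non-negative voxel intensities.
    voxel_size : triple of float
        Physical size of one voxel per axis, in um.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume must be 3-D with all dims >= 1, got {self.data.shape}")
        vs = np.asarray(self.voxel_size, dtype=float).reshape(3)
        if np.any(vs <= 0):
            raise ValueError(f"voxel_size must be positive, got {vs}")
        self.voxel_size = tuple(vs)
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def physical_extent(self) -> np.ndarray:
        """Physical size of the volume per axis (um)."""
        return np.asarray(self.shape) * np.asarray(self.voxel_size)

    def voxel_index(self, point: Sequence[float]) -> np.ndarray:
        """0-based voxel index containing a physical point (may be out of bounds)."""
        p = np.asarray(point, dtype=float)
        return np.floor(p / np.asarray(self.voxel_size)).astype(int)

    def voxel_center(self, index: Sequence[int]) -> np.ndarray:
        """Physical um coordinate of a voxel centre."""
        return (np.asarray(index, dtype=float) + 0.5) * np.asarray(self.voxel_size)

    def contains_index(self, index: np.ndarray) -> bool:
        idx = np.asarray(index)
        return bool(np.all(idx >= 0) and np.all(idx < np.asarray(self.shape)))


# ---------------------------------------------------------------------------
# Skeleton path
# ---------------------------------------------------------------------------

class SkeletonPath:
    """Ordered sequence of 3-D points (physical um) along one neurite.

    Consecutive points must be distinct; point order is preserved by every
    operation in the package.  Single-point paths are allowed as degenerate
    carriers (e.g. an isolated blob to rasterize).
    """

    __slots__ = ("points",)

    def __init__(self, points: Iterable[Sequence[float]]):
        pts = np.atleast_2d(np.asarray(list(points) if not isinstance(points, np.ndarray) else points, dtype=float))
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 1:
            raise ValueError(f"path must be an (n, 3) array with n >= 1, got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("path contains non-finite coordinates")
        if pts.shape[0] > 1:
            gaps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            if np.any(gaps == 0):
                raise ValueError("consecutive path points must be distinct")
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]

    def __getitem__(self, i):
        return self.points[i]

    def __repr__(self) -> str:
        return f"SkeletonPath(n={len(self)}, length={self.arc_length():.2f} um)"

    def arc_length(self) -> float:
        if len(self) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    def reversed(self) -> "SkeletonPath":
        return SkeletonPath(self.points[::-1].copy())

    def copy(self) -> "SkeletonPath":
        return SkeletonPath(self.points.copy())

    @staticmethod
    def concat(*paths: "SkeletonPath") -> "SkeletonPath":
        """Join paths sharing endpoints, dropping the duplicated joints."""
        pts = [paths[0].points]
        for prev, nxt in zip(paths, paths[1:]):
            seg = nxt.points
            if np.allclose(prev.points[-1], seg[0]):
                seg = seg[1:]
            pts.append(seg)
        return SkeletonPath(np.vstack(pts))

    def dedupe(self, tol: float = 1e-6) -> "SkeletonPath":
        """Drop interior points closer than ``tol`` to their predecessor."""
        pts = self.points
        if len(pts) <= 2:
            return self.copy()
        keep = [0]
        for i in range(1, len(pts) - 1):
            if np.linalg.norm(pts[i] - pts[keep[-1]]) > tol:
                keep.append(i)
        keep.append(len(pts) - 1)
        return SkeletonPath(pts[keep])


# ---------------------------------------------------------------------------
# Neuron tree (SWC semantics)
# ---------------------------------------------------------------------------

@dataclass
class NeuronTree:
    """Rooted tree (or forest) of skeleton nodes with SWC semantics.

    Nodes carry ``(id, type_code, position, radius, parent_id)``; a parent id
    of -1 marks a root.  Node order is the file order and is preserved.
    """

    ids: np.ndarray
    type_codes: np.ndarray
    xyz: np.ndarray
    radii: np.ndarray
    parent_ids: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.type_codes = np.asarray(self.type_codes, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float)
        self.parent_ids = np.asarray(self.parent_ids, dtype=int)
        self._validate()

    def _validate(self) -> None:
        n = len(self.ids)
        if not (len(self.type_codes) == n == self.xyz.shape[0] == len(self.radii) == len(self.parent_ids)):
            raise SwcStructureError("inconsistent node array lengths")
        if len(np.unique(self.ids)) != n:
            raise SwcStructureError("duplicate node ids")
        if np.any(self.radii < 0):
            raise SwcStructureError("negative radius")
        self._index = {int(i): k for k, i in enumerate(self.ids)}
        for pid in self.parent_ids:
            if pid != -1 and int(pid) not in self._index:
                raise SwcStructureError(f"dangling parent id {int(pid)}")
        # cycle check by walking parent chains
        state = {}
        for nid in self.ids:
            nid = int(nid)
            chain = []
            cur = nid
            while cur != -1 and state.get(cur) is None:
                state[cur] = "visiting"
                chain.append(cur)
                cur = int(self.parent_ids[self._index[cur]])
                if cur in chain:
                    raise SwcStructureError(f"cyclic parent chain at node {cur}")
            for c in chain:
                state[c] = "done"

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, node_id: int) -> int:
        return self._index[int(node_id)]

    def position(self, node_id: int) -> np.ndarray:
        return self.xyz[self.index_of(node_id)]

    def parent_of(self, node_id: int) -> int | None:
        pid = int(self.parent_ids[self.index_of(node_id)])
        return None if pid == -1 else pid

    def children_map(self) -> dict[int, list[int]]:
        """Map node id -> child ids, in node (file) order."""
        kids: dict[int, list[int]] = {int(i): [] for i in self.ids}
        for nid, pid in zip(self.ids, self.parent_ids):
            if pid != -1:
                kids[int(pid)].append(int(nid))
        return kids

    def roots(self) -> list[int]:
        return [int(i) for i, p in zip(self.ids, self.parent_ids) if p == -1]

    def copy(self) -> "NeuronTree":
        return NeuronTree(self.ids.copy(), self.type_codes.copy(), self.xyz.copy(),
                          self.radii.copy(), self.parent_ids.copy())


@dataclass
class BranchTriplet:
    """Local branch structure: S1 through the branch point, S2 the third arm.

    ``S1`` is split at ``branch_index`` into ``S11`` (ending at the branch
    point) and ``S12`` (starting there); ``S2`` starts at the branch point.

    ``arms``, when present, holds the three *untruncated* local walks away
    from the branch point (S11's arm, S12's arm, S2's arm, each starting at
    the branch point).  The recombination passes re-extract their local
    structure from these walks with the same point budgets that shaped S1
    and S2, so each pairing of segments gets a full-length side arm.
    """

    S1: SkeletonPath
    S11: SkeletonPath
    S12: SkeletonPath
    S2: SkeletonPath
    branch_index: int
    arms: tuple["SkeletonPath", "SkeletonPath", "SkeletonPath"] | None = None

    def __post_init__(self) -> None:
        bp = self.S1[self.branch_index]
        for name, path, idx in (("S11", self.S11, -1), ("S12", self.S12, 0), ("S2", self.S2, 0)):
            if not np.allclose(path[idx], bp):
                raise ValueError(f"{name} does not meet S1 at the branch point")

    @property
    def branch_point(self) -> np.ndarray:
        return self.S1[self.branch_index]


# ---------------------------------------------------------------------------
# Solver configuration
# ---------------------------------------------------------------------------

@dataclass
class SolverConfig:
    """All scalar knobs of the skeleton and branch optimizers.

    The iteration counts and the local-structure sizes (five outer
    split-Bregman sweeps; 21/16 extraction points; 1-um resampling; 1.73-voxel
    Gaussian template) are the published operating point of the method.  The
    penalty weights and gradient-descent schedule have no published values;
    the defaults here were fixed once on the synthetic fold-line phantoms
    (see docs/methods.md) and every one is overridable.
    """

    lam: float = 1000.0                 # L1 sparsity weight on second differences
    mu: float = 0.001                   # augmented-Lagrangian penalty scale
    sigma: float = 1.73                 # Gaussian width of the intensity score, voxels
    neighborhood_halfwidth: int = 6     # half-extent of the score neighborhood, voxels
    outer_iters: int = 5                # split-Bregman sweeps
    inner_grad_steps: int = 20          # gradient steps per position update
    step_size: float = 5e-5             # gradient step length
    p_update_includes_quadratic: bool = True
    m_points: int = 21                  # traced points extracted along S2
    n_points: int = 16                  # traced points extracted along S1
    resample_spacing: float = 1.0       # um between resampled skeleton points
    template_sigma: float = 1.73        # Gaussian width of the skeleton template, voxels
    branch_lam: float = 1.0             # weight of the orientation term (branch objective)
    branch_tol: float = 0.1             # um; branch-point convergence threshold
    branch_max_iters: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lam", "mu", "sigma", "step_size", "resample_spacing",
                     "template_sigma", "branch_lam", "branch_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("neighborhood_halfwidth", "outer_iters", "inner_grad_steps",
                     "branch_max_iters"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive integer")

    def replace(self, **kw) -> "SolverConfig":
        return replace(self, **kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SolverConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def read_swc(path: str | Path) -> NeuronTree:
    """Read a whitespace-delimited 7-column SWC file into a :class:`NeuronTree`.

    Comment lines start with '#'.  Coordinates are interpreted in the file's
    units (assumed um); node order is preserved; multiple roots (a forest) are
    allowed; type codes are passed through untouched.
    """
    ids, types, xyz, radii, parents = [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            if len(fields) != 7:
                raise SwcParseError(f"{path}: line {lineno}: expected 7 columns, got {len(fields)}")
            try:
                nid = int(fields[0]); tc = int(fields[1])
                x, y, z, r = (float(v) for v in fields[2:6])
                pid = int(fields[6])
            except ValueError as exc:
                raise SwcParseError(f"{path}: line {lineno}: {exc}") from exc
            ids.append(nid); types.append(tc); xyz.append((x, y, z))
            radii.append(r); parents.append(pid)
    if not ids:
        return NeuronTree(np.empty(0, int), np.empty(0, int), np.empty((0, 3)),
                          np.empty(0), np.empty(0, int))
    return NeuronTree(np.array(ids), np.array(types), np.array(xyz),
                      np.array(radii), np.array(parents))


def write_swc(tree: NeuronTree, path: str | Path) -> None:
    """Write a :class:`NeuronTree` to SWC (coordinates at um precision 1e-6)."""
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for k in range(len(tree)):
            x, y, z = tree.xyz[k]
            fh.write(f"{int(tree.ids[k])} {int(tree.type_codes[k])} "
                     f"{x:.6f} {y:.6f} {z:.6f} {tree.radii[k]:.6f} "
                     f"{int(tree.parent_ids[k])}\n")


# ---------------------------------------------------------------------------
# Image stack I/O
# ---------------------------------------------------------------------------

def _from_zyx(pages: np.ndarray) -> np.ndarray:
    """(nz, ny, nx) page stack -> (nx, ny, nz) volume."""
    return np.ascontiguousarray(np.transpose(pages, (2, 1, 0))).astype(float)


def read_stack(path: str | Path, voxel_size: Sequence[float] = (1.0, 1.0, 1.0)) -> VolumeImage:
    """Read a 3-D grayscale stack.

    Accepts a multi-page TIFF, a directory of single-page TIFFs (sorted by
    name), or a raw binary file with a plain-text YAML sidecar ``<path>.meta``
    declaring ``shape`` (nx, ny, nz), ``dtype`` and optionally ``voxel_size``.
    """
    import tifffile

    path = Path(path)
    if path.is_dir():
        pages = []
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise StackFormatError(f"{path}: no TIFF pages found")
        for f in files:
            page = tifffile.imread(f)
            if page.ndim != 2:
                raise StackFormatError(f"{f}: expected a single 2-D page")
            if pages and page.shape != pages[0].shape:
                raise StackFormatError(f"{f}: page size {page.shape} != {pages[0].shape}")
            pages.append(page)
        return VolumeImage(_from_zyx(np.stack(pages)), tuple(voxel_size))
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise StackFormatError(f"{path}: expected 2-D pages or a 3-D stack, got ndim={arr.ndim}")
        return VolumeImage(_from_zyx(arr), tuple(voxel_size))
    return _read_raw(path, voxel_size)


def _read_raw(path: Path, voxel_size: Sequence[float]) -> VolumeImage:
    import yaml

    sidecar = path.with_suffix(path.suffix + ".meta")
    if not sidecar.exists():
        raise SkelassoError(f"{path}: raw stack requires a sidecar metadata file {sidecar}")
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    shape = tuple(int(v) for v in meta["shape"])
    dtype = np.dtype(meta.get("dtype", "uint8"))
    vs = tuple(meta.get("voxel_size", voxel_size))
    raw = np.fromfile(path, dtype=dtype)
    expected = int(np.prod(shape))
    if raw.size != expected:
        raise StackFormatError(f"{path}: raw file holds {raw.size} voxels, sidecar declares {expected}")
    # raw layout is x-fastest (Fortran-style for (nx, ny, nz))
    return VolumeImage(raw.reshape(shape[::-1]).transpose(2, 1, 0).astype(float), vs)


def write_stack(image: VolumeImage, path: str | Path, dtype: str = "float32") -> None:
    """Write a volume to a multi-page grayscale TIFF (pages are z-planes)."""
    import tifffile

    pages = np.transpose(image.data, (2, 1, 0)).astype(dtype)
    tifffile.imwrite(Path(path), pages, photometric="minisblack")


# ---------------------------------------------------------------------------
# Neighborhood sampling
# ---------------------------------------------------------------------------

def neighborhood_offsets(halfwidth: int) -> np.ndarray:
    """All integer offsets of the +-halfwidth cube, shape ((2h+1)**3, 3)."""
    r = np.arange(-halfwidth, halfwidth + 1)
    return np.stack(np.meshgrid(r, r, r, indexing="ij"), axis=-1).reshape(-1, 3)


def sample_neighborhood(image: VolumeImage, center: Sequence[float],
                        halfwidth: int) -> tuple[np.ndarray, np.ndarray]:
    """Voxels of the axis-aligned cube around the voxel containing ``center``.

    Returns ``(centers, intensities)`` where ``centers`` is an (k, 3) array of
    physical voxel-centre coordinates (um) and ``intensities`` the matching
    intensities, for every voxel whose 0-based index lies within
    ``+-halfwidth`` per axis of the voxel containing ``center``, clipped to
    the image bounds.  A centre farther than ``halfwidth`` voxels outside the
    volume yields empty arrays (callers treat the intensity score as 0).
    """
    if halfwidth < 1:
        raise ValueError("halfwidth must be >= 1")
    idx = image.voxel_index(center)
    vox = idx[None, :] + neighborhood_offsets(halfwidth)
    shape = np.asarray(image.shape)
    valid = np.all((vox >= 0) & (vox < shape), axis=1)
    vox = vox[valid]
    if vox.size == 0:
        return np.empty((0, 3)), np.empty(0)
    centers = (vox + 0.5) * np.asarray(image.voxel_size)
    vals = image.data[vox[:, 0], vox[:, 1], vox[:, 2]]
    return centers, vals
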