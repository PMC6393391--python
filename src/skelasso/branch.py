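"""Branch-point optimization by segment recombination.

A bifurcation joins three neurite segments.  Locally they are modelled as a
through-path ``S1`` (containing the branch point at index ``s``, split into
``S11`` and ``S12``) and a side arm ``S2`` whose first point is the branch
point.  The optimizer:

1. L1-optimizes ``S1`` on the real image and resamples it at 1 um;
2. synthesizes a *skeleton template* — the resampled path blurred with a 3-D
   Gaussian (sigma = 1.73 voxels) and normalized to 255 — so every point of
   ``S1`` is equally bright and brighter than any off-path point;
3. repositions the branch point as the minimizer, over the resampled points
   of ``S1``, of the template intensity score plus a quadratic penalty on the
   perpendicular offset from the line carried by the side arm's direction;
4. re-optimizes ``S2`` from the new branch point and loops 3-4 to a fixed
   point.

The whole procedure is run three times, once per way of pairing the three
segments into (through-path, side arm), and the three converged points are
averaged — the recombination suppresses the bias any single pairing inherits
from intensity or radius changes across the junction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    BranchTriplet,
    DegenerateBranchError,
    SkeletonPath,
    SolverConfig,
    VolumeImage,
)
from .lasso import _batch_score, optimize_segment
from .synthgen import convolve_normalize, rasterize_polyline

__all__ = [
    "FrameObjective",
    "resample_path",
    "skeleton_template_image",
    "build_frame",
    "branch_objective",
    "optimize_attachment",
    "optimize_branch_point",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_path(path: SkeletonPath, spacing: float) -> SkeletonPath:
    """Resample so consecutive *Euclidean* (chord) gaps equal ``spacing``.

    The sampler marches a sphere of radius ``spacing`` along the polyline:
    from the current output point it finds the first forward intersection of
    the polyline with that sphere, so gaps are exact chords even across
    corners.  The first input point is kept exactly; the last input point is
    always appended (its gap may be shorter).  A path shorter than one
    spacing collapses to its two endpoints with a warning.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    pts = path.points
    if path.arc_length() < spacing:
        warnings.warn("path shorter than one spacing; returning endpoints")
        if len(pts) == 1:
            return path.copy()
        return SkeletonPath(np.vstack([pts[0], pts[-1]]))
    out = [pts[0].copy()]
    seg = 0                      # current segment index
    t = 0.0                      # parameter in [0, 1] along segment `seg`
    q = pts[0].copy()            # last emitted point
    while seg < len(pts) - 1:
        a, b = pts[seg], pts[seg + 1]
        ab = b - a
        # find first t' in (t, 1] with |a + t' ab - q| == spacing
        aa = float(ab @ ab)
        rel = a - q
        bq = float(rel @ ab)
        cq = float(rel @ rel) - spacing ** 2
        disc = bq * bq - aa * cq
        t_hit = None
        if aa > 0 and disc >= 0:
            root = (-bq + np.sqrt(disc)) / aa   # forward crossing (leaving the sphere)
            if t < root <= 1.0 + 1e-12:
                t_hit = min(root, 1.0)
        if t_hit is None:
            seg += 1
            t = 0.0
            continue
        q = a + t_hit * ab
        out.append(q.copy())
        t = t_hit
    last = pts[-1]
    if np.linalg.norm(last - out[-1]) > 1e-9:
        out.append(last.copy())
    elif len(out) >= 2:
        out[-1] = last.copy()
    return SkeletonPath(np.asarray(out))


# ---------------------------------------------------------------------------
# Skeleton template
# ---------------------------------------------------------------------------

def skeleton_template_image(path: SkeletonPath, sigma: float,
                            shape: tuple[int, int, int],
                            voxel_size=(1.0, 1.0, 1.0)) -> VolumeImage:
    """Synthetic volume in which the given skeleton is uniformly bright.

    Rasterizes the path, blurs with a Gaussian of width ``sigma`` voxels and
    normalizes the maximum to 255; along the path the intensity is nearly
    constant, and strictly larger than at laterally displaced points, so a
    branch point searched on this volume is drawn onto the skeleton without
    bias toward any particular position along it.
    """
    binary = rasterize_polyline(path, shape, voxel_size)
    return convolve_normalize(binary, sigma)


def _local_template(path: SkeletonPath, sigma: float,
                    voxel_size) -> tuple[VolumeImage, np.ndarray]:
    """Template over the path's bounding box padded by 4 sigma voxels.

    Returns (template, origin) where ``origin`` is the physical um offset of
    the template volume inside the parent frame.  Keeping the template local
    avoids allocating full-stack volumes for every branch.
    """
    vs = np.asarray(voxel_size, dtype=float)
    pad = 4.0 * sigma * vs + vs
    lo = path.points.min(axis=0) - pad
    hi = path.points.max(axis=0) + pad
    origin = np.floor(lo / vs) * vs
    shape = tuple(np.ceil((hi - origin) / vs).astype(int))
    shifted = SkeletonPath(path.points - origin)
    return skeleton_template_image(shifted, sigma, shape, tuple(vs)), origin


# ---------------------------------------------------------------------------
# Frame objective
# ---------------------------------------------------------------------------

@dataclass
class FrameObjective:
    """The branch-point objective: template attraction + orientation penalty.

    ``projector`` is ``I - dv1 dv1^T``, the orthogonal projector onto the
    plane normal to the side arm's direction ``dv1``; by the completeness
    relation it equals ``dv2 dv2^T + dv3 dv3^T`` for *any* orthonormal
    completion (dv2, dv3), which makes the objective well posed without ever
    choosing them.  ``g_scale`` rescales the template term onto the order of
    the quadratic term (the template maximum magnitude over the candidate
    set); callers that evaluate single points may leave it at 1.
    """

    p_fx: np.ndarray
    dv1: np.ndarray
    projector: np.ndarray
    lam: float
    template: VolumeImage | None = None
    template_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    g_scale: float = 1.0

    def __post_init__(self) -> None:
        self.p_fx = np.asarray(self.p_fx, dtype=float)
        self.dv1 = np.asarray(self.dv1, dtype=float)
        self.projector = np.asarray(self.projector, dtype=float)
        if abs(np.linalg.norm(self.dv1) - 1.0) > 1e-9:
            raise ValueError("dv1 must be a unit vector")
        if np.linalg.norm(self.projector @ self.projector - self.projector) > 1e-9:
            raise ValueError("projector must be idempotent")
        if np.linalg.norm(self.projector @ self.dv1) > 1e-9:
            raise ValueError("projector must annihilate dv1")


def build_frame(S2: SkeletonPath, voxel_size, S1: SkeletonPath,
                lam: float = 1.0) -> FrameObjective:
    """Reference point and direction frame from the side arm ``S2``.

    Walking ``S2`` from its branch end: ``p_fx`` is the first point whose
    distance to *every* point of ``S1`` exceeds three voxel sizes (the
    largest per-axis size, conservatively, on anisotropic grids); ``p_v1`` is
    the first later point farther than the same margin from ``p_fx``.  Then
    ``dv1 = (p_v1 - p_fx) / ||.||`` and the projector is ``I - dv1 dv1^T``.
    """
    margin = 3.0 * float(np.max(voxel_size))
    s1 = S1.points
    p_fx = None
    i_fx = None
    for i, q in enumerate(S2.points):
        if np.min(np.linalg.norm(s1 - q, axis=1)) > margin:
            p_fx = q
            i_fx = i
            break
    if p_fx is None:
        raise DegenerateBranchError("no S2 point clears the S1 margin (side arm too short)")
    p_v1 = None
    for q in S2.points[i_fx + 1:]:
        if np.linalg.norm(q - p_fx) > margin:
            p_v1 = q
            break
    if p_v1 is None:
        raise DegenerateBranchError("no S2 point clears the p_fx margin (side arm too short)")
    dv1 = (p_v1 - p_fx) / np.linalg.norm(p_v1 - p_fx)
    projector = np.eye(3) - np.outer(dv1, dv1)
    return FrameObjective(p_fx=p_fx, dv1=dv1, projector=projector, lam=lam)


def branch_objective(fo: FrameObjective, p, sigma: float, halfwidth: int) -> float:
    """Template intensity score (scaled by ``1/g_scale``) plus ``lam`` times
    the squared perpendicular distance of ``p`` from the line through
    ``p_fx`` along ``dv1``."""
    p = np.asarray(p, dtype=float)
    g = 0.0
    if fo.template is not None:
        g, _ = _batch_score(fo.template, p - fo.template_origin, sigma, halfwidth, False)
        g = float(g[0])
    rel = fo.p_fx - p
    quad = float(rel @ fo.projector @ rel)
    return g / fo.g_scale + fo.lam * quad


# ---------------------------------------------------------------------------
# Attachment fixed-point loop (Steps 1-5)
# ---------------------------------------------------------------------------

def optimize_attachment(S1: SkeletonPath, S2: SkeletonPath, image: VolumeImage,
                        cfg: SolverConfig) -> np.ndarray:
    """Reposition the attachment of side arm ``S2`` on through-path ``S1``.

    ``S2``'s first point must be the current branch point (a point of
    ``S1``).  Returns the converged branch point; if the side arm is too
    short to carry a direction frame, the input branch point is returned
    unchanged with a warning.
    """
    bp = np.asarray(S2.points[0], dtype=float).copy()
    s1_opt = optimize_segment(S1, image, cfg)
    s1_star = resample_path(s1_opt, cfg.resample_spacing)
    template, origin = _local_template(s1_star, cfg.template_sigma, image.voxel_size)
    s2_cur = S2.copy()
    for it in range(cfg.branch_max_iters):
        try:
            fo = build_frame(s2_cur, image.voxel_size, s1_star, lam=cfg.branch_lam)
        except DegenerateBranchError as exc:
            warnings.warn(f"branch frame degenerate ({exc}); keeping input branch point")
            return np.asarray(S2.points[0], dtype=float).copy()
        fo.template = template
        fo.template_origin = origin
        cand = s1_star.points
        g, _ = _batch_score(template, cand - origin, cfg.sigma, cfg.neighborhood_halfwidth, False)
        fo.g_scale = float(np.max(np.abs(g))) or 1.0
        rel = fo.p_fx[None, :] - cand
        quad = np.einsum("kj,jl,kl->k", rel, fo.projector, rel)
        scores = g / fo.g_scale + cfg.branch_lam * quad
        bp_new = cand[int(np.argmin(scores))].copy()   # argmin ties -> smaller index
        # re-anchor the side arm at the new branch point and re-optimize it
        s2_pts = s2_cur.points.copy()
        s2_pts[0] = bp_new
        s2_cur = SkeletonPath(s2_pts).dedupe()
        if len(s2_cur) >= 3:
            s2_cur = optimize_segment(s2_cur, image, cfg)
        moved = float(np.linalg.norm(bp_new - bp))
        bp = bp_new
        logger.debug("attachment iteration %d: moved %.4f um", it + 1, moved)
        if moved < cfg.branch_tol:
            break
    return bp


# ---------------------------------------------------------------------------
# Three-way recombination (Steps 6-7) and averaging
# ---------------------------------------------------------------------------

def _pair_through(first: SkeletonPath, second: SkeletonPath,
                  n_budget: int) -> SkeletonPath:
    """Through-path of up to ``n_budget`` points centred on the shared branch
    point: the first arm (reversed, ending at the branch point) joined to the
    second (starting there), each half truncated to its share of the budget."""
    avail_a, avail_b = len(first), len(second)
    k_a = min(avail_a, max(3, (n_budget + 1) // 2))
    k_b = min(avail_b, n_budget + 1 - k_a)
    k_a = min(avail_a, n_budget + 1 - k_b)
    half_a = SkeletonPath(first.points[:k_a]).reversed()
    half_b = SkeletonPath(second.points[:k_b])
    return SkeletonPath.concat(half_a, half_b)


def _recombinations(triplet: BranchTriplet,
                    cfg: SolverConfig) -> list[tuple[SkeletonPath, SkeletonPath]]:
    """The three (through-path, side-arm) pairings of the branch's segments.

    When the triplet carries its untruncated arm walks, each pairing is
    re-extracted with the standard budgets (through-path <= n points, side
    arm <= m points), mirroring how the original S1/S2 were cut; otherwise
    the stored S11/S12/S2 are recombined directly.
    """
    if triplet.arms is not None:
        U, C, W = triplet.arms          # S11's, S12's, S2's arm, each from the bp
        m, n = cfg.m_points, cfg.n_points
        side = lambda p: SkeletonPath(p.points[:m])
        return [
            (_pair_through(U, C, n), side(W)),
            (_pair_through(C, W, n), side(U)),
            (_pair_through(U, W, n), side(C)),
        ]
    S11, S12, S2 = triplet.S11, triplet.S12, triplet.S2
    return [
        (SkeletonPath.concat(S11, S12), S2),
        (SkeletonPath.concat(S12.reversed(), S2), S11.reversed()),
        (SkeletonPath.concat(S11, S2), S12),
    ]


def optimize_branch_point(triplet: BranchTriplet, image: VolumeImage,
                          cfg: SolverConfig) -> np.ndarray:
    """Optimize one bifurcation: three recombination passes, then average.

    Each pass runs the full attachment loop (segment optimization, template
    synthesis, frame objective, fixed point).  Passes that degenerate are
    dropped; if all three degenerate the input branch point is returned with
    a warning.
    """
    bp0 = np.asarray(triplet.branch_point, dtype=float).copy()
    results = []
    for k, (s1, s2) in enumerate(_recombinations(triplet, cfg)):
        try:
            pt = optimize_attachment(s1, s2, image, cfg)
            results.append(pt)
            logger.debug("recombination pass %d -> %s", k + 1, pt)
        except (DegenerateBranchError, ValueError) as exc:
            logger.warning("recombination pass %d failed: %s", k + 1, exc)
    if not results:
        warnings.warn("all recombination passes degenerate; branch point unchanged")
        return bp0
    return np.mean(np.asarray(results), axis=0)
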