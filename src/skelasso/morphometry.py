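"""Morphometric measurements and skeleton-consistency metrics.

Total neurite length, the local (10-um chord) branch angle, and the
matched-pair segment distance used to quantify how consistent two skeleton
estimates of the same neurite are: both skeletons are resampled at equal
x-coordinate steps, consecutive resampled points form segments, and each
segment of one skeleton is paired with its nearest segment (minimum
segment-to-segment distance) on the other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import MetricInapplicableError, NeuronTree, SkeletonPath

__all__ = [
    "MatchedPairResult",
    "total_length",
    "branch_angle",
    "resample_by_x",
    "matched_pair_distances",
    "segment_segment_distance",
]


def total_length(tree: NeuronTree) -> float:
    """Sum of Euclidean lengths of all parent-child edges, in um."""
    total = 0.0
    for k in range(len(tree)):
        pid = tree.parent_ids[k]
        if pid != -1:
            total += float(np.linalg.norm(tree.xyz[k] - tree.position(int(pid))))
    return total


def _walk_arc(points: np.ndarray, arm_length: float) -> np.ndarray:
    """Point at arc length ``arm_length`` along a polyline from its start
    (linear interpolation; the last point if the polyline is shorter)."""
    acc = 0.0
    for a, b in zip(points[:-1], points[1:]):
        L = float(np.linalg.norm(b - a))
        if acc + L >= arm_length:
            t = (arm_length - acc) / L
            return a + t * (b - a)
        acc += L
    return points[-1]


def branch_angle(tree: NeuronTree, node_id: int, arm_length: float = 10.0) -> float:
    """Local branch angle at a bifurcation, in degrees.

    For each of the two child arms, walk ``arm_length`` um of arc from the
    branch point along the traced polyline and form the chord from the
    branch point to the reached point; the angle between the two chords (in
    [0, 180]) is returned.  An arm shorter than ``arm_length`` is used in
    full, with a warning.
    """
    kids = tree.children_map()
    children = kids.get(int(node_id), [])
    if len(children) < 2:
        raise ValueError(f"node {node_id} is not a bifurcation")
    bp = tree.position(node_id)
    chords = []
    for child in children[:2]:
        ids = [node_id, child]
        cur = child
        acc = float(np.linalg.norm(tree.position(child) - bp))
        while acc < arm_length:
            ch = kids[cur]
            if not ch:
                warnings.warn(f"arm from node {node_id} via {child} shorter than "
                              f"{arm_length} um; using full arm")
                break
            nxt = ch[0]
            acc += float(np.linalg.norm(tree.position(nxt) - tree.position(cur)))
            ids.append(nxt)
            cur = nxt
        pts = np.asarray([tree.position(i) for i in ids])
        chords.append(_walk_arc(pts, arm_length) - bp)
    u, v = chords
    c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# x-resampling and matched-pair segment distances
# ---------------------------------------------------------------------------

def resample_by_x(path: SkeletonPath, dx: float = 1.0, count: int = 51) -> SkeletonPath:
    """``count`` points at x-coordinates ``start_x + k*dx`` interpolated on the polyline.

    Requires the path's x-coordinates to be strictly monotone over the
    sampled range; otherwise the protocol is inapplicable and an error is
    raised.
    """
    if dx <= 0 or count < 2:
        raise ValueError("dx must be positive and count >= 2")
    pts = path.points
    x = pts[:, 0]
    steps = np.diff(x)
    if np.all(steps > 0):
        xs, ps = x, pts
    elif np.all(steps < 0):
        xs, ps = x[::-1], pts[::-1]
    else:
        raise MetricInapplicableError("path is not x-monotone; x-resampling inapplicable")
    x0 = x[0]
    sign = 1.0 if steps[0] > 0 else -1.0
    targets = x0 + sign * dx * np.arange(count)
    lo, hi = min(xs[0], xs[-1]), max(xs[0], xs[-1])
    if np.any(targets < lo - 1e-9) or np.any(targets > hi + 1e-9):
        raise MetricInapplicableError(
            f"requested x-range exceeds the path ({count} points at dx={dx})")
    out = np.column_stack([
        targets,
        np.interp(targets, xs, ps[:, 1]),
        np.interp(targets, xs, ps[:, 2]),
    ])
    return SkeletonPath(out)


def segment_segment_distance(a0: np.ndarray, a1: np.ndarray,
                             b0: np.ndarray, b1: np.ndarray) -> float:
    """Minimum Euclidean distance between two closed 3-D line segments.

    The squared distance is a convex quadratic in the two segment parameters
    (s, t) over the unit box, so the minimizer is either the interior
    stationary point or lies on one of the four box edges; all candidates
    are evaluated and the best taken (exact, no iteration).
    """
    u = a1 - a0
    v = b1 - b0
    w = a0 - b0
    A = float(u @ u); B = float(u @ v); C = float(v @ v)
    D = float(u @ w); E = float(v @ w)

    def dist(s: float, t: float) -> float:
        return float(np.linalg.norm(w + s * u - t * v))

    candidates = []
    den = A * C - B * B
    if den > 1e-14:
        s0 = (B * E - C * D) / den
        t0 = (A * E - B * D) / den
        if 0.0 <= s0 <= 1.0 and 0.0 <= t0 <= 1.0:
            candidates.append((s0, t0))
    for t in (0.0, 1.0):   # edges t fixed: minimize over s
        s = np.clip((B * t - D) / A, 0.0, 1.0) if A > 1e-14 else 0.0
        candidates.append((s, t))
    for s in (0.0, 1.0):   # edges s fixed: minimize over t
        t = np.clip((B * s + E) / C, 0.0, 1.0) if C > 1e-14 else 0.0
        candidates.append((s, t))
    return min(dist(s, t) for s, t in candidates)


@dataclass
class MatchedPairResult:
    """Per-segment nearest-neighbor distances between two resampled skeletons."""

    distances: np.ndarray
    matched_indices: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.distances))

    @property
    def max(self) -> float:
        return float(np.max(self.distances))


def matched_pair_distances(a: SkeletonPath, b: SkeletonPath, dx: float = 1.0,
                           count: int = 51) -> MatchedPairResult:
    """Matched-pair segment distances between two skeletons.

    Both paths are x-resampled (``count`` points at step ``dx``); consecutive
    points form segments; each segment of ``a`` is matched with the segment
    of ``b`` minimizing the segment-to-segment distance (ties to the smaller
    index) and that distance is recorded.
    """
    ra = resample_by_x(a, dx, count).points
    rb = resample_by_x(b, dx, count).points
    seg_a = list(zip(ra[:-1], ra[1:]))
    seg_b = list(zip(rb[:-1], rb[1:]))
    dists = np.empty(len(seg_a))
    idx = np.empty(len(seg_a), dtype=int)
    for i, (p0, p1) in enumerate(seg_a):
        best = np.inf
        best_j = 0
        for j, (q0, q1) in enumerate(seg_b):
            dij = segment_segment_distance(p0, p1, q0, q1)
            if dij < best - 1e-15:
                best = dij
                best_j = j
        dists[i] = best
        idx[i] = best_j
    return MatchedPairResult(distances=dists, matched_indices=idx)
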