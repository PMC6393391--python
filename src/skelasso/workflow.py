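"""Whole-neuron optimization workflow over an SWC tree.

Pass 1 optimizes every branch point (bifurcations directly; multifurcations
decomposed into successive bifurcations and flagged); pass 2 re-optimizes
every maximal segment between branch/terminal nodes with its (possibly
moved) endpoints fixed.  Topology — ids, parent links, type codes — is never
touched; only node positions move.  Terminal points of the whole tree never
move.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .branch import optimize_branch_point
from .core import (
    BranchSkip,
    BranchTriplet,
    FrameMismatchError,
    NeuronTree,
    SkeletonPath,
    SolverConfig,
    VolumeImage,
)
from .lasso import objective_value, optimize_segment

__all__ = [
    "WorkflowReport",
    "find_branch_nodes",
    "extract_branch_triplet",
    "optimize_tree",
]

logger = logging.getLogger(__name__)


@dataclass
class WorkflowReport:
    """Audit record of one optimization run."""

    branch_records: list[dict] = field(default_factory=list)
    segment_records: list[dict] = field(default_factory=list)

    def branches(self) -> pd.DataFrame:
        return pd.DataFrame(self.branch_records)

    def segments(self) -> pd.DataFrame:
        return pd.DataFrame(self.segment_records)

    @property
    def totals(self) -> dict:
        nb = len(self.branch_records)
        done = [r for r in self.branch_records if r["status"] == "optimized"]
        return {
            "branches": nb,
            "branches_optimized": len(done),
            "mean_branch_displacement_um":
                float(np.mean([r["displacement_um"] for r in done])) if done else 0.0,
            "segments": len(self.segment_records),
        }

    def to_csv(self, path) -> None:
        frames = []
        if self.branch_records:
            b = self.branches()
            b.insert(0, "kind", "branch")
            frames.append(b)
        if self.segment_records:
            s = self.segments()
            s.insert(0, "kind", "segment")
            frames.append(s)
        (pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Tree traversal helpers
# ---------------------------------------------------------------------------

def find_branch_nodes(tree: NeuronTree) -> list[int]:
    """Ids of nodes with >= 2 children, in increasing id order."""
    kids = tree.children_map()
    return sorted(nid for nid, ch in kids.items() if len(ch) >= 2)


def multifurcation_nodes(tree: NeuronTree) -> list[int]:
    """Ids of nodes with >= 3 children (decomposed into bifurcations downstream)."""
    kids = tree.children_map()
    return sorted(nid for nid, ch in kids.items() if len(ch) >= 3)


def _walk_down(tree: NeuronTree, start: int, first_child: int, max_points: int,
               kids: dict[int, list[int]]) -> list[int]:
    """Node ids from ``start`` through ``first_child`` downstream, following
    the first child at any later fork, up to ``max_points`` ids (incl. start)."""
    out = [start, first_child]
    cur = first_child
    while len(out) < max_points:
        ch = kids[cur]
        if not ch:
            break
        cur = ch[0]
        out.append(cur)
    return out[:max_points]


def _walk_up(tree: NeuronTree, start: int, max_points: int) -> list[int]:
    """Node ids from ``start`` up the parent chain, up to ``max_points``."""
    out = [start]
    cur = start
    while len(out) < max_points:
        pid = tree.parent_of(cur)
        if pid is None:
            break
        out.append(pid)
        cur = pid
    return out


def _ids_to_path(tree: NeuronTree, ids: list[int], keep: str = "first") -> SkeletonPath:
    """Positions along a node-id chain, dropping consecutive coincident nodes
    (tracers occasionally emit duplicates).  ``keep`` says which end of the
    chain must survive deduplication ("first" or "last")."""
    pts = np.asarray([tree.position(i) for i in ids])
    if keep == "last":
        pts = pts[::-1]
    out = [pts[0]]
    for q in pts[1:]:
        if np.linalg.norm(q - out[-1]) > 1e-9:
            out.append(q)
    pts = np.asarray(out)
    if keep == "last":
        pts = pts[::-1]
    return SkeletonPath(pts)


def extract_branch_triplet(tree: NeuronTree, node_id: int, cfg: SolverConfig,
                           child_pair: tuple[int, int] | None = None) -> BranchTriplet:
    """Local structure around a bifurcation.

    ``S1`` spans up to ``cfg.n_points`` traced points through the branch
    point, along the parent path on one side and the longer child arm on the
    other; ``S2`` is up to ``cfg.m_points`` points along the other child,
    starting at the branch point.  At a branch with no parent (tree root) the
    two children form S1 and a third child, if present, forms S2.  Any arm
    with fewer than 3 points raises :class:`BranchSkip`.

    ``child_pair`` restricts the construction to two specific children (used
    when decomposing multifurcations).
    """
    kids = tree.children_map()
    children = kids.get(int(node_id), [])
    if len(children) < 2:
        raise BranchSkip(f"node {node_id} is not a branch point")
    c_pair = list(child_pair) if child_pair is not None else children[:2]
    up_ids = _walk_up(tree, node_id, cfg.m_points)      # includes node_id
    down = {c: _walk_down(tree, node_id, c, cfg.m_points, kids) for c in c_pair}
    has_parent = len(up_ids) >= 2

    if has_parent:
        # longer child continues S1; the other is the side arm S2
        a, b = c_pair
        c_s1, c_s2 = (a, b) if len(down[a]) >= len(down[b]) else (b, a)
        arm_u_ids, arm_c_ids, arm_w_ids = up_ids, down[c_s1], down[c_s2]
    else:
        third = [c for c in children if c not in c_pair]
        if not third:
            raise BranchSkip(f"root branch {node_id} has no third arm for S2")
        a, b = c_pair
        arm_u_ids, arm_c_ids = down[a], down[b]
        arm_w_ids = _walk_down(tree, node_id, third[0], cfg.m_points, kids)

    # each arm starts at the branch point and walks outward
    arm_u = _ids_to_path(tree, arm_u_ids, keep="first")
    arm_c = _ids_to_path(tree, arm_c_ids, keep="first")
    arm_w = _ids_to_path(tree, arm_w_ids, keep="first")
    for name, path in (("S11 arm", arm_u), ("S12 arm", arm_c), ("S2 arm", arm_w)):
        if len(path) < 3:
            raise BranchSkip(f"{name} of branch {node_id} has only {len(path)} points")
    # balance the S1 halves around the branch point within the n-point budget
    k_up = min(len(arm_u), max(3, (cfg.n_points + 1) // 2))
    k_dn = min(len(arm_c), cfg.n_points + 1 - k_up)
    k_up = min(len(arm_u), cfg.n_points + 1 - k_dn)
    S11 = SkeletonPath(arm_u.points[:k_up]).reversed()
    S12 = SkeletonPath(arm_c.points[:k_dn])
    S2 = SkeletonPath(arm_w.points[:cfg.m_points])
    S1 = SkeletonPath.concat(S11, S12)
    return BranchTriplet(S1=S1, S11=S11, S12=S12, S2=S2,
                         branch_index=len(S11) - 1, arms=(arm_u, arm_c, arm_w))


# ---------------------------------------------------------------------------
# Segment enumeration
# ---------------------------------------------------------------------------

def _maximal_segments(tree: NeuronTree) -> list[list[int]]:
    """Maximal node-id chains between branch/terminal/root nodes."""
    kids = tree.children_map()
    stops = set(find_branch_nodes(tree)) | set(tree.roots())
    segments = []
    for start in sorted(stops):
        for child in kids[start]:
            chain = [start, child]
            cur = child
            while len(kids[cur]) == 1 and cur not in stops:
                cur = kids[cur][0]
                chain.append(cur)
            segments.append(chain)
    return segments


# ---------------------------------------------------------------------------
# Whole-tree optimization
# ---------------------------------------------------------------------------

def optimize_tree(tree: NeuronTree, image: VolumeImage,
                  cfg: SolverConfig) -> tuple[NeuronTree, WorkflowReport]:
    """Branch pass then segment pass over a whole reconstruction.

    Raises :class:`FrameMismatchError` before any mutation if any node lies
    more than 10 um outside the volume (skeleton and image almost certainly
    do not share a frame).
    """
    ext = image.physical_extent
    over = np.maximum(tree.xyz - ext, -tree.xyz).max() if len(tree) else 0.0
    if over > 10.0:
        raise FrameMismatchError(
            f"nodes up to {over:.1f} um outside the volume; check coordinate frames")

    out = tree.copy()
    report = WorkflowReport()

    kids = tree.children_map()
    for nid in find_branch_nodes(tree):
        children = kids[nid]
        pairs = [tuple(children[:2])]
        is_multi = len(children) >= 3
        if is_multi:
            pairs += [(children[0], c) for c in children[2:]]
        initial = out.position(nid).copy()
        results = []
        status = "optimized"
        for pair in pairs:
            try:
                triplet = extract_branch_triplet(out, nid, cfg, child_pair=pair)
                results.append(optimize_branch_point(triplet, image, cfg))
            except BranchSkip as exc:
                logger.info("branch %d pair %s skipped: %s", nid, pair, exc)
        if results:
            new_pos = np.mean(np.asarray(results), axis=0)
            out.xyz[out.index_of(nid)] = new_pos
        else:
            new_pos = initial
            status = "skipped"
        report.branch_records.append({
            "node_id": nid,
            "initial": tuple(np.round(initial, 4)),
            "optimized": tuple(np.round(new_pos, 4)),
            "displacement_um": float(np.linalg.norm(new_pos - initial)),
            "multifurcation": is_multi,
            "status": status,
        })

    for chain in _maximal_segments(out):
        pts = np.asarray([out.position(i) for i in chain])
        if len(chain) < 3:
            continue
        path = SkeletonPath(pts)
        obj_before = objective_value(pts, image, cfg)
        optimized = optimize_segment(path, image, cfg)
        obj_after = objective_value(optimized.points, image, cfg)
        if len(optimized) == len(chain):
            for nid, pos in zip(chain[1:-1], optimized.points[1:-1]):
                out.xyz[out.index_of(nid)] = pos
        report.segment_records.append({
            "start_id": chain[0],
            "end_id": chain[-1],
            "n_points": len(chain),
            "objective_before": obj_before,
            "objective_after": obj_after,
        })
    return out, report
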