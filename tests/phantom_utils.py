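"""Helpers shared between fixtures and tests: phantom experiments and metrics."""

from __future__ import annotations

import numpy as np

import skelasso as sk


def lateral_perturb(path: sk.SkeletonPath, magnitude: float, seed: int) -> sk.SkeletonPath:
    """Perturb y and z only, keeping x (preserves x-monotonicity)."""
    p = sk.perturb_polyline(path, magnitude, seed)
    pts = p.points.copy()
    pts[:, 0] = path.points[:, 0]
    return sk.SkeletonPath(pts)


def distance_to_polyline(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Distance of each point to the nearest point of a polyline."""
    d = np.full(len(points), np.inf)
    for a, b in zip(poly[:-1], poly[1:]):
        ab = b - a
        t = np.clip((points - a) @ ab / (ab @ ab), 0.0, 1.0)
        proj = a + t[:, None] * ab
        d = np.minimum(d, np.linalg.norm(points - proj, axis=1))
    return d


class FoldExperiment:
    """One corner-recovery run: phantom, perturbed initial, L1 and L2 outputs."""

    def __init__(self, angle: float, noise_sd: float, seed: int,
                 cfg: sk.SolverConfig):
        self.spec = sk.FoldLineSpec.from_angle(angle, noise_sd=noise_sd, seed=seed)
        self.image, self.truth = sk.make_fold_line_stack(self.spec)
        self.initial = sk.resample_path(self.truth, cfg.resample_spacing)
        self.perturbed = sk.perturb_polyline(self.initial, 2.0, seed=seed + 1000)
        self.history: list[float] = []
        self.l1_out = sk.optimize_segment(self.perturbed, self.image, cfg,
                                          history=self.history)
        self.l2_out = sk.l2_comparator(self.perturbed, self.image, cfg)

    def mean_dist(self, path: sk.SkeletonPath) -> float:
        return float(distance_to_polyline(path.points, self.truth.points).mean())

    @staticmethod
    def max_sd(path: sk.SkeletonPath) -> float:
        return float(np.linalg.norm(sk.second_differences(path.points), axis=1).max())
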