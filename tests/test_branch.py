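"""Branch-point optimizer: resampling, template, frame objective, recombination."""

import numpy as np
import pytest

import skelasso as sk
from skelasso.branch import _local_template
from skelasso.core import DegenerateBranchError
from skelasso.workflow import extract_branch_triplet


# ---------------------------------------------------------------------------
# resample_path
# ---------------------------------------------------------------------------

def test_resample_straight_segment():
    p = sk.SkeletonPath([[0, 0, 0], [20, 0, 0]])
    out = sk.resample_path(p, 1.0)
    assert len(out) == 21
    assert np.allclose(out.segment_lengths(), 1.0)


def test_resample_across_right_angle_corner():
    """Chord gaps stay 1 um even across the corner of a 10+10 um fold."""
    p = sk.SkeletonPath([[0, 0, 0], [10, 0, 0], [10, 10, 0]])
    out = sk.resample_path(p, 1.0)
    gaps = out.segment_lengths()
    assert np.all(np.abs(gaps[:-1] - 1.0) <= 1e-6)   # last gap may be short
    assert np.allclose(out.points[0], p.points[0])
    assert np.allclose(out.points[-1], p.points[-1])


def test_resample_spacing_longer_than_path():
    p = sk.SkeletonPath([[0, 0, 0], [0.3, 0, 0], [0.6, 0, 0]])
    with pytest.warns(UserWarning, match="spacing"):
        out = sk.resample_path(p, 5.0)
    assert len(out) == 2
    assert np.allclose(out.points, [[0, 0, 0], [0.6, 0, 0]])


def test_resample_random_polylines_gap_contract():
    """Interior chord gaps equal the spacing to 1e-6 on 50 random polylines."""
    rng = np.random.default_rng(11)
    for _ in range(50):
        n = rng.integers(4, 15)
        pts = np.cumsum(rng.uniform(0.5, 3.0, (n, 3)) * rng.choice([-1, 1], (n, 3)),
                        axis=0)
        path = sk.SkeletonPath(pts)
        if path.arc_length() < 1.0:
            continue
        out = sk.resample_path(path, 1.0)
        gaps = out.segment_lengths()
        assert np.all(np.abs(gaps[:-1] - 1.0) <= 1e-6)
        assert gaps[-1] <= 1.0 + 1e-6


# ---------------------------------------------------------------------------
# skeleton template
# ---------------------------------------------------------------------------

def test_template_uniform_along_straight_path():
    path = sk.SkeletonPath([[5.5, 15.5, 15.5], [25.5, 15.5, 15.5]])
    tpl = sk.skeleton_template_image(sk.resample_path(path, 1.0), 1.73, (31, 31, 31))
    vals = [tpl.data[tuple(tpl.voxel_index(p))] for p in np.linspace(8, 23, 10)[:, None]
            * [1, 0, 0] + [0, 15.5, 15.5]]
    assert min(vals) >= 0.85 * 255.0


def test_template_on_path_brighter_than_lateral():
    path = sk.SkeletonPath([[5.5, 15.5, 15.5], [25.5, 15.5, 15.5]])
    tpl = sk.skeleton_template_image(sk.resample_path(path, 1.0), 1.73, (31, 31, 31))
    for x in np.arange(7.5, 24.0, 2.0):
        on = tpl.data[tuple(tpl.voxel_index((x, 15.5, 15.5)))]
        off = tpl.data[tuple(tpl.voxel_index((x, 15.5 + 3 * 1.73, 15.5)))]
        assert on > off


def test_template_single_point_blob():
    tpl = sk.skeleton_template_image(sk.SkeletonPath([[7.5, 7.5, 7.5]]), 1.73, (15, 15, 15))
    assert tpl.data.max() == pytest.approx(255.0)
    assert tpl.data[7, 7, 7] == pytest.approx(255.0)


# ---------------------------------------------------------------------------
# build_frame / branch_objective
# ---------------------------------------------------------------------------

def straight_frame_paths():
    s1 = sk.SkeletonPath(np.column_stack([np.arange(0.0, 16), np.zeros(16), np.zeros(16)]))
    s2 = sk.SkeletonPath(np.column_stack([np.full(21, 8.0), np.arange(0.0, 21), np.zeros(21)]))
    return s1, s2


def test_build_frame_direction_and_projector():
    s1, s2 = straight_frame_paths()
    fo = sk.build_frame(s2, (1, 1, 1), s1)
    assert np.allclose(fo.dv1, [0, 1, 0])               # S2 runs along +y
    assert np.linalg.norm(fo.projector @ fo.dv1) <= 1e-9
    assert np.allclose(fo.projector @ fo.projector, fo.projector, atol=1e-12)
    # p_fx is the first S2 point clearing 3 voxel sizes from every S1 point
    assert fo.p_fx[1] > 3.0


def test_build_frame_margins_use_largest_voxel_size():
    s1, s2 = straight_frame_paths()
    fo = sk.build_frame(s2, (1, 1, 2), s1)   # margin becomes 6 um
    assert fo.p_fx[1] > 6.0


def test_build_frame_short_arm_degenerates():
    s1, _ = straight_frame_paths()
    short = sk.SkeletonPath([[8.0, 0, 0], [8.0, 1, 0], [8.0, 2, 0]])
    with pytest.raises(DegenerateBranchError):
        sk.build_frame(short, (1, 1, 1), s1)


def test_gram_schmidt_completeness_relation():
    """dv2 dv2^T + dv3 dv3^T from any orthonormal completion equals
    I - dv1 dv1^T: the objective never depends on the choice of dv2, dv3."""
    rng = np.random.default_rng(0)
    for _ in range(100):
        dv1 = rng.normal(size=3)
        dv1 /= np.linalg.norm(dv1)
        aux = rng.normal(size=3)
        dv2 = aux - (aux @ dv1) * dv1
        dv2 /= np.linalg.norm(dv2)
        dv3 = np.cross(dv1, dv2)
        explicit = np.outer(dv2, dv2) + np.outer(dv3, dv3)
        assert np.abs(explicit - (np.eye(3) - np.outer(dv1, dv1))).max() <= 1e-9


def test_branch_objective_perpendicular_offset():
    fo = sk.FrameObjective(p_fx=np.zeros(3), dv1=np.array([1.0, 0, 0]),
                           projector=np.eye(3) - np.outer([1.0, 0, 0], [1.0, 0, 0]),
                           lam=1.0)
    assert sk.branch_objective(fo, (5.0, 2.0, 0.0), 1.73, 6) == pytest.approx(4.0)
    assert sk.branch_objective(fo, (7.0, 0.0, 0.0), 1.73, 6) == pytest.approx(0.0)


def test_branch_objective_matches_matrix_identity():
    rng = np.random.default_rng(5)
    for _ in range(20):
        dv1 = rng.normal(size=3)
        dv1 /= np.linalg.norm(dv1)
        P = np.eye(3) - np.outer(dv1, dv1)
        p_fx = rng.uniform(-5, 5, 3)
        p = rng.uniform(-5, 5, 3)
        fo = sk.FrameObjective(p_fx=p_fx, dv1=dv1, projector=P, lam=2.5)
        expected = 2.5 * np.linalg.norm(P @ (p_fx - p)) ** 2
        assert sk.branch_objective(fo, p, 1.73, 6) == pytest.approx(expected, rel=1e-9)


def test_frame_objective_validates_unit_dv1():
    with pytest.raises(ValueError, match="unit"):
        sk.FrameObjective(p_fx=np.zeros(3), dv1=np.array([2.0, 0, 0]),
                          projector=np.eye(3) - np.outer([1.0, 0, 0], [1.0, 0, 0]),
                          lam=1.0)


# ---------------------------------------------------------------------------
# optimize_attachment / optimize_branch_point
# ---------------------------------------------------------------------------

def t_junction_fixture():
    """Noiseless T: through-path along x, side arm along +y, junction at center."""
    shape = (48, 48, 24)
    c = np.array([24.0, 12.0, 12.0])
    s1_path = sk.SkeletonPath([c - [20, 0, 0], c + [20, 0, 0]])
    s2_path = sk.SkeletonPath([c, c + [0, 20, 0]])
    img_data = np.zeros(shape)
    for p in (s1_path, s2_path):
        binary = sk.rasterize_polyline(p, shape)
        from scipy.ndimage import gaussian_filter
        img_data += gaussian_filter(binary.data, 1.73, truncate=4.0)
    img_data *= 255.0 / img_data.max()
    return sk.VolumeImage(img_data), c


def test_attachment_recovers_displaced_junction():
    img, c = t_junction_fixture()
    s1 = sk.SkeletonPath(np.column_stack([np.arange(c[0] - 8, c[0] + 9),
                                          np.full(17, c[1]), np.full(17, c[2])]))
    bp0 = c + np.array([5.0, 0, 0])       # displaced 5 um along S1
    s2_pts = np.vstack([bp0, [c + [0, t, 0] for t in np.arange(2.0, 21.0)]])
    s2 = sk.SkeletonPath(s2_pts)
    cfg = sk.SolverConfig()
    bp = sk.optimize_attachment(s1, s2, img, cfg)
    assert np.linalg.norm(bp - c) <= cfg.resample_spacing


def test_attachment_started_at_truth_stays_near_truth():
    """Starting at the true junction, the loop converges within one resample
    spacing of it (the side arm's intensity bows the through-path slightly
    toward itself, which is what the three-way recombination averages out)."""
    img, c = t_junction_fixture()
    s1 = sk.SkeletonPath(np.column_stack([np.arange(c[0] - 8, c[0] + 9),
                                          np.full(17, c[1]), np.full(17, c[2])]))
    s2 = sk.SkeletonPath(np.vstack([[c], [c + [0, t, 0] for t in np.arange(1.0, 21.0)]]))
    cfg = sk.SolverConfig()
    bp = sk.optimize_attachment(s1, s2, img, cfg)
    assert np.linalg.norm(bp - c) <= cfg.resample_spacing


def test_attachment_short_side_arm_warns_and_keeps_input():
    img, c = t_junction_fixture()
    s1 = sk.SkeletonPath(np.column_stack([np.arange(c[0] - 8, c[0] + 9),
                                          np.full(17, c[1]), np.full(17, c[2])]))
    s2 = sk.SkeletonPath([c, c + [0, 1.0, 0], c + [0, 2.0, 0]])
    with pytest.warns(UserWarning, match="degenerate"):
        bp = sk.optimize_attachment(s1, s2, img, sk.SolverConfig())
    assert np.array_equal(bp, c)


def test_branch_point_average_of_three_passes(monkeypatch):
    """The optimized branch point is the arithmetic mean of the three
    recombination passes' results."""
    candidates = iter([np.array([0.0, 0, 0]), np.array([3.0, 0, 0]),
                       np.array([0.0, 3, 0])])
    import skelasso.branch as br
    monkeypatch.setattr(br, "optimize_attachment", lambda *a, **k: next(candidates))
    arm = lambda d: sk.SkeletonPath([[0, 0, 0], d, np.multiply(d, 2)])
    trip = sk.BranchTriplet(
        S1=sk.SkeletonPath([[-2, 0, 0], [-1, 0, 0], [0, 0, 0], [1, 0, 0], [2, 0, 0]]),
        S11=sk.SkeletonPath([[-2, 0, 0], [-1, 0, 0], [0, 0, 0]]),
        S12=sk.SkeletonPath([[0, 0, 0], [1, 0, 0], [2, 0, 0]]),
        S2=sk.SkeletonPath([[0, 0, 0], [0, 1, 0], [0, 2, 0]]),
        branch_index=2)
    out = br.optimize_branch_point(trip, sk.VolumeImage(np.zeros((5, 5, 5))),
                                   sk.SolverConfig())
    assert np.allclose(out, [1.0, 1.0, 0.0])


@pytest.mark.parametrize("arm", [0, 1, 2])
def test_branch_point_recovery_on_y_phantom(y_phantom, arm, default_cfg):
    """A branch point displaced 5 voxels along any arm returns to within
    2 voxels of the true junction on the noiseless Y phantom."""
    spec, image, tree = y_phantom
    J = np.asarray(spec.junction)
    bid = sk.find_branch_nodes(tree)[0]
    displaced = tree.copy()
    displaced.xyz[displaced.index_of(bid)] = J + spec.arm_directions[arm] * 5.0
    triplet = extract_branch_triplet(displaced, bid, default_cfg)
    out = sk.optimize_branch_point(triplet, image, default_cfg)
    assert np.linalg.norm(out - J) <= 2.0


def test_local_template_covers_path():
    path = sk.SkeletonPath([[30.0, 40.0, 10.0], [50.0, 40.0, 10.0]])
    tpl, origin = _local_template(path, 1.73, (1.0, 1.0, 1.0))
    assert np.all(origin <= path.points.min(axis=0))
    assert tpl.data.max() == pytest.approx(255.0)
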