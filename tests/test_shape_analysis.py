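import numpy as np
import pytest

from helpers import circle_points, ellipse_points, procrustes_oracle, random_blob

from fasworm.attractor import cycle_frequency
from fasworm.fixtures import analytic_trajectory
from fasworm.shape_analysis import (
    PDCurve,
    Shape,
    ShapeError,
    extract_period,
    normalize_and_average,
    pd_curve,
    phase_aligned_pd,
    procrustes,
    resample_closed_curve,
)


def _similarity(points, b, theta, c, rng=None):
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    return b * points @ R.T + np.asarray(c)


# ---------------------------------------------------------------------------
# procrustes core


def test_shape_against_itself_is_exact_zero():
    S = Shape(random_blob(np.random.default_rng(0)))
    res = procrustes(S, S)
    assert res.pd == pytest.approx(0.0, abs=1e-14)
    assert res.b == pytest.approx(1.0)
    assert np.allclose(res.R, np.eye(2), atol=1e-12)
    assert np.allclose(res.c, 0.0, atol=1e-10)


def test_similarity_transforms_are_invisible_to_pd():
    rng = np.random.default_rng(42)
    for _ in range(100):
        A = random_blob(rng, N=int(rng.integers(5, 30)))
        b = float(rng.uniform(0.2, 5.0))
        theta = float(rng.uniform(0, 2 * np.pi))
        c = rng.normal(scale=10, size=2)
        B = _similarity(A, b, theta, c)
        res = procrustes(Shape(A), Shape(B))
        assert res.pd < 1e-10
        assert res.b == pytest.approx(b, rel=1e-8)


def test_pd_matches_brute_force_optimizer_on_random_pairs():
    rng = np.random.default_rng(2024)
    for _ in range(50):
        A = random_blob(rng, N=10)
        B = random_blob(rng, N=10)
        ours = procrustes(Shape(A), Shape(B)).pd
        brute = procrustes_oracle(A, B)
        assert ours == pytest.approx(brute, abs=1e-4)


def test_pd_is_symmetric_and_rotation_is_proper():
    rng = np.random.default_rng(5)
    A, B = random_blob(rng), random_blob(rng)
    r1 = procrustes(Shape(A), Shape(B))
    r2 = procrustes(Shape(B), Shape(A))
    assert r1.pd == pytest.approx(r2.pd, rel=1e-10)
    assert np.linalg.det(r1.R) == pytest.approx(1.0)


def test_reflected_shape_is_not_matched_by_proper_rotations():
    rng = np.random.default_rng(9)
    A = random_blob(rng, N=12)
    B = A @ np.diag([1.0, -1.0])   # mirror image
    res = procrustes(Shape(A), Shape(B))
    assert res.pd > 1e-3   # reflections are excluded from R
    assert np.linalg.det(res.R) == pytest.approx(1.0)


def test_zero_variance_shape_raises():
    flat = Shape(np.zeros((8, 2)))
    blob = Shape(random_blob(np.random.default_rng(1), N=8))
    with pytest.raises(ShapeError):
        procrustes(flat, blob)
    with pytest.raises(ShapeError):
        procrustes(Shape(random_blob(np.random.default_rng(2), N=5)), Shape(np.zeros((8, 2))))


def test_agreement_with_scipy_when_reflection_not_needed():
    # scipy.spatial.procrustes allows improper rotations; when the optimal
    # unconstrained alignment is proper the two must agree exactly
    from scipy.spatial import procrustes as scipy_procrustes

    rng = np.random.default_rng(17)
    checked = 0
    while checked < 20:
        A, B = random_blob(rng, N=15), random_blob(rng, N=15)
        Ac = A - A.mean(0)
        Bc = B - B.mean(0)
        if np.linalg.det(Ac.T @ Bc) <= 0:
            continue
        _, _, disparity = scipy_procrustes(A, B)
        assert procrustes(Shape(A), Shape(B)).pd == pytest.approx(disparity, rel=1e-9)
        checked += 1


# ---------------------------------------------------------------------------
# phase alignment


def test_quarter_phase_offset_circles_align_to_zero():
    A = Shape(circle_points(100))
    B = Shape(circle_points(100, phase=np.pi / 2))
    res = phase_aligned_pd(A, B)
    assert res.pd < 1e-12


def test_phase_alignment_never_exceeds_unaligned_pd():
    rng = np.random.default_rng(31)
    for _ in range(10):
        A = Shape(random_blob(rng, N=20))
        B = Shape(random_blob(rng, N=20))
        assert phase_aligned_pd(A, B).pd <= procrustes(A, B).pd + 1e-15


def test_phase_alignment_matches_exhaustive_shift_search():
    rng = np.random.default_rng(77)
    A = Shape(random_blob(rng, N=16))
    B = Shape(random_blob(rng, N=16))
    best = min(
        procrustes(A, Shape(np.roll(pts, -s, axis=0))).pd
        for pts in (B.points, B.points[::-1])
        for s in range(16)
    )
    assert phase_aligned_pd(A, B).pd == pytest.approx(best, rel=1e-12)


def test_reversed_traversal_is_recovered():
    A = Shape(ellipse_points(60, 2.0, 1.0))
    B = Shape(A.points[::-1].copy())
    assert phase_aligned_pd(A, B).pd < 1e-12
    assert phase_aligned_pd(A, B, try_reversal=False).pd > 1e-6


# ---------------------------------------------------------------------------
# resampling and period extraction


def test_resampling_a_circle_stays_on_the_circle():
    pts = circle_points(73, r=2.5)
    shp = resample_closed_curve(pts, 200)
    radii = np.linalg.norm(shp.points, axis=1)
    assert np.abs(radii / 2.5 - 1.0).max() < 1e-6


def test_resampling_at_input_length_is_near_identity():
    pts = circle_points(50)
    shp = resample_closed_curve(pts, 50)
    assert np.abs(shp.points - pts).max() < 1e-6


def test_arclength_preserved_for_smooth_curves():
    pts = ellipse_points(400, 2.0, 1.0)
    shp = resample_closed_curve(pts, 200)

    def arclength(p):
        closed = np.vstack([p, p[:1]])
        return np.linalg.norm(np.diff(closed, axis=0), axis=1).sum()

    assert arclength(shp.points) == pytest.approx(arclength(pts), rel=1e-3)


def test_degenerate_curve_raises():
    with pytest.raises(ShapeError):
        resample_closed_curve(np.zeros((10, 2)), 50)
    with pytest.raises(ShapeError):
        resample_closed_curve(circle_points(3), 50)


def test_extracted_period_length_matches_cycle_frequency():
    pt = analytic_trajectory("circle", radius=1.0, frequency=0.5, T=20.0, dt=1e-3)
    pts = extract_period(pt, transient=2.0)
    freq = cycle_frequency(pt)
    assert pts.shape[0] == pytest.approx(1.0 / freq / 1e-3, rel=0.01)
    # closure: first and last points of one period nearly coincide
    assert np.linalg.norm(pts[0] - pts[-1]) < 0.02 * 2 * np.pi


def test_three_cycle_input_yields_single_cycle():
    pt = analytic_trajectory("circle", radius=1.0, frequency=0.5, T=6.0, dt=1e-3)
    pts = extract_period(pt, transient=0.0)

    def arclength(p):
        return np.linalg.norm(np.diff(p, axis=0), axis=1).sum()

    total = arclength(pt.xy)
    assert arclength(pts) == pytest.approx(total / 3.0, rel=0.02)


def test_nonperiodic_input_is_rejected():
    from fasworm.attractor import FIXED_POINT, AttractorResult

    pt = analytic_trajectory("fixed_point", T=12.0)
    res = AttractorResult(FIXED_POINT, endpoint=np.zeros(2))
    with pytest.raises(ShapeError):
        extract_period(pt, result=res)


# ---------------------------------------------------------------------------
# PD curves


def test_uniformly_shrinking_cycles_have_zero_pd_and_falling_scale():
    healthy = Shape(circle_points(200))

    def traj_at(mu):
        return analytic_trajectory("circle", radius=1.0 / (1.0 + mu), frequency=0.5,
                                   T=20.0, dt=1e-3)

    schedule = np.array([0.5, 1.0, 2.0])
    curve = pd_curve(traj_at, schedule, healthy, mu_star=3.0, transient=2.0,
                     healthy_frequency=0.5)
    assert curve.gaps == []
    assert np.all(curve.pd_values < 1e-4)
    assert np.all(np.diff(curve.scaling_values) < 0)


def test_morphing_circle_to_ellipse_increases_pd():
    healthy = Shape(circle_points(200))

    def traj_at(mu):
        return analytic_trajectory("ellipse", radius=1.0, radius_b=1.0 / (1.0 + mu),
                                   frequency=0.5, T=20.0, dt=1e-3)

    schedule = np.array([0.5, 1.0, 2.0])
    curve = pd_curve(traj_at, schedule, healthy, mu_star=3.0, transient=2.0)
    assert curve.pd_values[0] == 0.0
    assert np.all(np.diff(curve.pd_values) > 0)


def test_failures_become_gaps_not_aborts():
    healthy = Shape(circle_points(200))

    def traj_at(mu):
        if mu == 1.0:
            return None
        return analytic_trajectory("circle", radius=1.0, frequency=0.5, T=20.0, dt=1e-3)

    curve = pd_curve(traj_at, np.array([0.5, 1.0, 2.0]), healthy, mu_star=3.0, transient=2.0)
    assert curve.gaps == [1.0]
    assert len(curve.mu_values) == 3   # mu=0 entry plus the two successes


def test_normalize_and_average_single_and_duplicated():
    curve = PDCurve(
        np.array([0.0, 1.0, 2.0]), np.array([0.0, 0.2, 0.4]),
        np.array([1.0, 0.8, 0.6]), np.array([0.0, 0.1, 0.2]),
        np.array([1.0, 0.9, 0.8]), mu_star=2.0,
    )
    grid, mean, std = normalize_and_average([curve], which="pd")
    assert np.allclose(std, 0.0)
    assert mean[-1] == pytest.approx(1.0)   # PD normalized to max 1
    grid2, mean2, std2 = normalize_and_average([curve, curve], which="pd")
    assert np.allclose(mean, mean2) and np.allclose(std2, 0.0)


def test_average_of_two_linear_curves_is_hand_mean():
    def mk(slope):
        mu = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
        return PDCurve(mu, slope * mu, np.ones(5), np.zeros(5), np.ones(5), mu_star=2.0)

    # after value normalization both are the identity ramp; scaling curves differ
    c1, c2 = mk(0.1), mk(0.4)
    grid, mean, std = normalize_and_average([c1, c2], which="pd")
    assert np.allclose(mean, grid, atol=1e-8)
    assert np.allclose(std, 0.0, atol=1e-8)
    # translation untouched (raw scale)
    _, tmean, _ = normalize_and_average([c1, c2], which="translation")
    assert np.allclose(tmean, 0.0)
    with pytest.raises(ShapeError):
        normalize_and_average([], which="pd")


def test_healthy_fixture_shape_is_closed_and_reproducible(oscillator_baseline):
    *_, shape, freq = oscillator_baseline[6:8]
    shape = oscillator_baseline[6]
    assert shape.n_points == 200
    res = phase_aligned_pd(shape, shape)
    assert res.pd < 1e-12
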