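"""Fiber tracing, per-fiber theta/l/epsilon, TACS-3 core features."""

import numpy as np
import pytest

from cslim import fibers as fib
from cslim import normalize, phantom
from cslim.diagnosis import ECBoundary


def _straight_fiber(fid, p0, p1, n=30, px=0.5):
    line = np.array(p0) + np.linspace(0, 1, n)[:, None] * (
        np.array(p1) - np.array(p0)
    )
    return fib.Fiber(fiber_id=fid, centerline=line, pixel_size_um=px)


def _square_boundary(x0, y0, size, pts_per_side=30):
    """Axis-aligned square polygon (top edge along +x at y = y0)."""
    t = np.linspace(0, 1, pts_per_side, endpoint=False)
    top = np.column_stack([x0 + size * t, np.full(pts_per_side, y0)])
    right = np.column_stack([np.full(pts_per_side, x0 + size), y0 + size * t])
    bottom = np.column_stack([x0 + size * (1 - t), np.full(pts_per_side, y0 + size)])
    left = np.column_stack([np.full(pts_per_side, x0), y0 + size * (1 - t)])
    return ECBoundary(np.vstack([top, right, bottom, left]), ec_id=1)


def _circle_boundary(cx, cy, r, n=360):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return ECBoundary(
        np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)]), ec_id=1
    )


def test_tls_orientation_and_fold():
    pts = np.array([[0, 0], [1, -1], [2, -2]])  # 45 deg CCW (y down)
    assert fib.tls_orientation(pts) == pytest.approx(45.0)
    assert fib.fold_angle(170.0) == pytest.approx(10.0)
    assert fib.fold_angle(-30.0) == pytest.approx(30.0)
    assert fib.fold_angle(90.0) == pytest.approx(90.0)


def test_perpendicular_and_parallel_theta_exact():
    square = _square_boundary(50, 100, 200)
    # vertical fiber approaching the horizontal top edge from above
    perp = _straight_fiber(0, (150, 40), (150, 90))
    par = _straight_fiber(1, (100, 80), (200, 80))
    assert fib.relative_angle(perp, [square], max_dist_um=100) == pytest.approx(
        90.0, abs=1e-6
    )
    assert fib.relative_angle(par, [square], max_dist_um=100) == pytest.approx(
        0.0, abs=1e-6
    )


def test_theta_30_degrees_to_circle_tangent():
    circle = _circle_boundary(200, 200, 100)
    # place fiber end near the top of the circle (tangent horizontal);
    # orient the fiber 30 deg from the tangent
    ang = np.deg2rad(30.0)
    start = np.array([200.0, 200.0 - 110.0])
    direction = np.array([np.cos(ang), -np.sin(ang)])
    fiber = _straight_fiber(0, start + direction * 60, start)
    theta = fib.relative_angle(fiber, [circle], max_dist_um=100)
    assert theta == pytest.approx(30.0, abs=2.0)


def test_fiber_beyond_max_distance_excluded():
    square = _square_boundary(50, 200, 100)
    far = _straight_fiber(0, (10, 10), (60, 10))
    assert fib.relative_angle(far, [square], max_dist_um=10.0) is None


def test_boundary_distance_geometry():
    square = _square_boundary(50, 100, 200)  # top edge y = 100
    touching = _straight_fiber(0, (150, 50), (150, 100))
    assert fib.boundary_distance(touching, [square]) == pytest.approx(0.0, abs=1e-9)
    parallel = _straight_fiber(1, (100, 0), (200, 0))  # 100 px above edge
    assert fib.boundary_distance(parallel, [square]) == pytest.approx(
        50.0, abs=0.5
    )  # 100 px * 0.5 um/px
    assert fib.boundary_distance(parallel, []) is None


def test_epsilon_perfectly_aligned_field_is_one():
    fibers = [
        _straight_fiber(i, (10 + 15 * i, 10), (10 + 15 * i, 60)) for i in range(6)
    ]
    for i in range(len(fibers)):
        assert fib.nearest_alignment(fibers, i) == pytest.approx(1.0, abs=1e-12)


def test_epsilon_orthogonal_pair_with_self():
    """Self + one parallel + one orthogonal: |1 + 1 - 1| / 3 = 1/3."""
    fibers = [
        _straight_fiber(0, (0, 0), (0, 30)),
        _straight_fiber(1, (5, 0), (5, 30)),
        _straight_fiber(2, (0, 35), (30, 35)),
    ]
    eps = fib.nearest_alignment(fibers, 0, neighborhood_sizes=(2,))
    assert eps == pytest.approx(1.0 / 3.0, abs=1e-9)


def test_epsilon_uniform_orientations_matches_monte_carlo():
    """Random axial field: mean epsilon matches the phasor-resultant oracle."""
    n, reps = 60, 24
    per_realization = []
    for seed in range(reps):
        r = np.random.default_rng(seed)
        angles = r.uniform(0, 180, n)
        fibers = []
        for i, a in enumerate(angles):
            c = r.uniform(50, 450, 2)
            u = np.array([np.cos(np.deg2rad(a)), -np.sin(np.deg2rad(a))]) * 20
            fibers.append(_straight_fiber(i, c - u, c + u))
        per_realization.append(
            np.mean([fib.nearest_alignment(fibers, i) for i in range(n)])
        )
    measured = np.mean(per_realization)
    # independent oracle: mean resultant of m+1 uniform axial phasors
    oracle_rng = np.random.default_rng(123)
    sims = []
    for _ in range(8000):
        vals = [
            np.abs(np.exp(2j * np.deg2rad(oracle_rng.uniform(0, 180, m + 1))).mean())
            for m in (2, 4, 8, 16)
        ]
        sims.append(np.mean(vals))
    assert measured == pytest.approx(np.mean(sims), abs=0.02)


def test_epsilon_decreases_with_orientation_dispersion(rng):
    means = []
    for kappa_sd in (2.0, 15.0, 60.0):
        fibers = []
        for i in range(40):
            a = rng.normal(90, kappa_sd) % 180
            c = rng.uniform(50, 450, 2)
            u = np.array([np.cos(np.deg2rad(a)), -np.sin(np.deg2rad(a))]) * 20
            fibers.append(_straight_fiber(i, c - u, c + u))
        means.append(np.mean([fib.nearest_alignment(fibers, i) for i in range(40)]))
    assert means[0] > means[1] > means[2]


def test_epsilon_undefined_for_tiny_fields():
    fibers = [_straight_fiber(0, (0, 0), (0, 30)), _straight_fiber(1, (5, 0), (5, 30))]
    assert fib.nearest_alignment(fibers, 0) is None


# --- tracing ---------------------------------------------------------------


def test_tracer_recovers_phantom_fibers():
    spec = phantom.PhantomSpec(
        seed=5, n_glands=2, n_fibers=20, fiber_policy="random",
        background_noise_sd_rad=0.0,
    )
    truth = phantom.make_phase_phantom(spec)
    z = normalize.z_normalize(truth.phase, truth.tissue_mask)
    traced = fib.extract_fibers(z.z, truth.pixel_size_um, ec_mask=truth.ec_mask())
    detected, errors = 0, []
    for tf in truth.fibers:
        tc = tf.centerline.mean(axis=0)
        best = min(traced, key=lambda f: np.hypot(*(f.centroid - tc)))
        if np.hypot(*(best.centroid - tc)) < 8:
            err = fib.fold_angle(best.orientation_deg - tf.orientation_deg)
            if err < 5:
                detected += 1
                errors.append(err)
    assert detected >= 19
    assert max(errors) < 3.0


def test_tracing_scale_invariance():
    spec = phantom.PhantomSpec(seed=9, n_glands=1, n_fibers=10,
                               background_noise_sd_rad=0.005)
    truth = phantom.make_phase_phantom(spec)
    z = normalize.z_normalize(truth.phase, truth.tissue_mask)
    a = fib.extract_fibers(z.z, 0.5, ec_mask=truth.ec_mask())
    b = fib.extract_fibers(3.0 * z.z + 1.0, 0.5, ec_mask=truth.ec_mask())
    assert len(a) == len(b)
    for fa, fb in zip(a, b):
        np.testing.assert_array_equal(fa.centerline, fb.centerline)


def test_fiber_crossing_ec_only_stromal_part_traced(rng):
    img = 0.01 * rng.standard_normal((200, 200))
    # horizontal ridge through the whole image
    img[98:102, :] += 1.0
    ec_mask = np.zeros((200, 200), dtype=bool)
    ec_mask[60:140, 80:120] = True  # EC blocking the middle
    traced = fib.extract_fibers(img, 0.5, ec_mask=ec_mask)
    assert len(traced) >= 1
    from scipy.ndimage import binary_dilation

    grown = binary_dilation(ec_mask, iterations=2)
    for f in traced:
        cols = np.round(f.centerline[:, 0]).astype(int)
        rows = np.round(f.centerline[:, 1]).astype(int)
        assert not grown[rows, cols].any()


def test_pure_noise_yields_few_spurious_fibers():
    rates = []
    for seed in range(3):
        img = np.random.default_rng(seed).normal(0, 1.0, (512, 512))
        traced = fib.extract_fibers(img, 0.5)
        rates.append(len(traced) / (512 * 0.5e-3) ** 2)
    assert max(rates) <= 2.0  # fibers per mm^2


def test_rotation_equivariance():
    spec = phantom.PhantomSpec(seed=13, n_glands=1, n_fibers=12,
                               background_noise_sd_rad=0.0)
    truth = phantom.make_phase_phantom(spec)
    z = normalize.z_normalize(truth.phase, truth.tissue_mask)
    ecm = truth.ec_mask()
    a = fib.extract_fibers(z.z, 0.5, ec_mask=ecm)
    b = fib.extract_fibers(np.rot90(z.z), 0.5, ec_mask=np.rot90(ecm))
    assert abs(len(a) - len(b)) <= 1
    ors_a = np.sort([(f.orientation_deg + 90.0) % 180.0 for f in a])
    ors_b = np.sort([f.orientation_deg for f in b])
    n = min(len(ors_a), len(ors_b))
    diffs = [fib.fold_angle(x - y) for x, y in zip(ors_a[:n], ors_b[:n])]
    assert np.median(diffs) < 3.0


def test_feature_ranges_on_phantom(small_truth, small_zmap):
    traced = fib.extract_fibers(small_zmap.z, 0.5, ec_mask=small_truth.ec_mask())
    assert traced, "tracer found no fibers on the phantom"
    for i, f in enumerate(traced):
        assert 0.0 <= f.orientation_deg < 180.0
        theta = fib.relative_angle(f, small_truth.ec_boundaries, max_dist_um=1e6)
        assert theta is None or 0.0 <= theta <= 90.0
        l_um = fib.boundary_distance(f, small_truth.ec_boundaries)
        assert l_um >= 0.0
        eps = fib.nearest_alignment(traced, i)
        assert eps is None or 0.0 <= eps <= 1.0


# --- core features and SVM -------------------------------------------------


def test_skewness_conventions():
    assert fib.sample_skewness(np.array([5.0, 5.0, 5.0])) == 0.0
    # hand-computed g1 for {10, 10, 80}
    v = np.array([10.0, 10.0, 80.0])
    m = v.mean()
    g1 = np.mean((v - m) ** 3) / np.mean((v - m) ** 2) ** 1.5
    assert fib.sample_skewness(v) == pytest.approx(g1, abs=1e-12)
    assert g1 == pytest.approx(np.sqrt(2) / 2, abs=1e-12)


def test_core_features_direction_positive_vs_negative():
    """TACS-3-like cores: higher epsilon, lower l, more positive theta skew."""
    from cslim import studies

    pos = [studies.tacs_core_features("positive", 1000 + s, through_optics=False)
           for s in range(4)]
    neg = [studies.tacs_core_features("negative", 2000 + s, through_optics=False)
           for s in range(4)]
    pos_mean = np.mean([c.as_array() for c in pos], axis=0)
    neg_mean = np.mean([c.as_array() for c in neg], axis=0)
    assert pos_mean[0] > neg_mean[0]  # mean epsilon
    assert pos_mean[1] < neg_mean[1]  # mean l
    assert pos_mean[2] > neg_mean[2]  # skew theta


def test_core_flagged_with_too_few_eligible_fibers():
    square = _square_boundary(50, 100, 100)
    fibers = [_straight_fiber(0, (60, 80), (100, 80))]
    assert fib.core_tacs_features(fibers, [square]) is None


def test_svm_separable_and_scaling_invariant(rng):
    x = np.vstack([rng.normal(0, 0.3, (12, 3)) + [0.6, 10, 1.0],
                   rng.normal(0, 0.3, (12, 3)) + [0.3, 40, 0.0]])
    y = np.repeat([1, 0], 12)
    clf = fib.train_tacs_svm(x, y)
    calls, _ = fib.classify_cores(clf, x)
    assert (calls == y).all()
    # standardization makes constant per-feature scaling irrelevant
    scale = np.array([100.0, 0.01, 7.0])
    clf2 = fib.train_tacs_svm(x * scale, y)
    calls2, _ = fib.classify_cores(clf2, x * scale)
    np.testing.assert_array_equal(calls, calls2)
    with pytest.raises(ValueError, match="both"):
        fib.train_tacs_svm(x, np.ones(24))
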