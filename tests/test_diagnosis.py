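"""EC diagnostic features: curvature, scattering length, textons, LDA."""

import numpy as np
import pytest

from cslim import diagnosis as dx


def _circle(radius_px: float, n: int = 180, center=(150.0, 150.0)) -> dx.ECBoundary:
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    poly = np.column_stack(
        [center[0] + radius_px * np.cos(t), center[1] + radius_px * np.sin(t)]
    )
    return dx.ECBoundary(polygon=poly, ec_id=1)


# --- curvature -------------------------------------------------------------


def test_circle_curvature_closed_form():
    """R = 50 um circle at 0.5 um/px -> median |kappa| = 1/50 per um."""
    ec = _circle(radius_px=100.0)
    _, c_med = dx.boundary_curvature(ec, pixel_size_um=0.5)
    assert c_med == pytest.approx(1.0 / 50.0, rel=0.02)


def test_curvature_resampling_invariance():
    a = dx.boundary_curvature(_circle(100.0, n=120), 0.5)[1]
    b = dx.boundary_curvature(_circle(100.0, n=240), 0.5)[1]
    assert b == pytest.approx(a, rel=0.005)


def test_star_polygon_curvature_exceeds_circle():
    t = np.linspace(0, 2 * np.pi, 240, endpoint=False)
    r = 100.0 * (1 + 0.15 * np.cos(8 * t))
    star = dx.ECBoundary(
        np.column_stack([150 + r * np.cos(t), 150 + r * np.sin(t)]), ec_id=2
    )
    c_star = dx.boundary_curvature(star, 0.5)[1]
    c_circle = dx.boundary_curvature(_circle(100.0), 0.5)[1]
    assert c_star > c_circle


def test_curvature_scale_equivariance():
    base = dx.boundary_curvature(_circle(80.0), 0.5)[1]
    scaled = dx.boundary_curvature(_circle(160.0), 0.5)[1]
    assert scaled == pytest.approx(base / 2.0, rel=0.01)


def test_polygon_validation():
    with pytest.raises(ValueError, match="8 vertices"):
        dx.ECBoundary(np.zeros((4, 2)), ec_id=1)
    with pytest.raises(ValueError, match="label"):
        dx.ECBoundary(np.random.default_rng(0).random((10, 2)), ec_id=1, label="odd")


# --- scattering length -----------------------------------------------------


def test_constant_phase_hits_cap():
    ls = dx.scattering_length_map(np.full((64, 64), 0.7), thickness_um=5.0)
    assert np.all(ls == dx.LS_CAP_UM)


def test_ls_additive_constant_invariance(rng):
    phi = rng.standard_normal((64, 64))
    a = dx.scattering_length_map(phi, 5.0)
    b = dx.scattering_length_map(phi + 3.0, 5.0)
    np.testing.assert_allclose(a, b, rtol=1e-9)


def test_ls_linear_in_thickness(rng):
    phi = rng.standard_normal((64, 64))
    np.testing.assert_allclose(
        dx.scattering_length_map(phi, 10.0),
        2.0 * dx.scattering_length_map(phi, 5.0),
        rtol=1e-12,
    )


def test_ls_iid_noise_limit():
    """i.i.d. phase noise sd s: l_s -> t/s^2 (window 31, within 5%)."""
    rng = np.random.default_rng(3)
    s, t = 0.3, 5.0
    phi = rng.normal(0, s, (256, 256))
    ls = dx.scattering_length_map(phi, t, window_px=31)
    interior = ls[32:-32, 32:-32]
    assert np.median(interior) == pytest.approx(t / s**2, rel=0.05)


def test_ls_window_validation():
    with pytest.raises(ValueError, match="odd"):
        dx.scattering_length_map(np.zeros((32, 32)), 5.0, window_px=8)
    with pytest.raises(ValueError, match="larger"):
        dx.scattering_length_map(np.zeros((8, 8)), 5.0, window_px=15)


# --- textons ---------------------------------------------------------------


def _two_texture_image(rng, shape=(128, 128)):
    # stripe period ~12.6 px sits inside the bank's derivative passband
    img = 0.02 * rng.standard_normal(shape)
    stripes = 0.8 * np.sin(np.arange(shape[1]) * 0.5)
    img[:, shape[1] // 2 :] += stripes[shape[1] // 2 :]
    truth = np.zeros(shape, dtype=int)
    truth[:, shape[1] // 2 :] = 1
    return img, truth


def test_bank_is_fixed_18_filters():
    bank = dx.filter_bank()
    assert len(bank) == 18
    # derivative/LoG filters are zero-mean
    assert all(abs(k.sum()) < 1e-10 for k in bank[3:])


def test_two_texture_image_recovered(rng):
    img, truth = _two_texture_image(rng)
    d = dx.build_texton_dictionary([img], k=2, seed=0, samples_per_image=3000)
    labels = d.assign(img)
    interior = (slice(16, -16), slice(16, -16))
    a, b = labels[interior], truth[interior]
    agreement = max((a == b).mean(), (a == 1 - b).mean())
    assert agreement > 0.95


def test_dictionary_deterministic(rng):
    img, _ = _two_texture_image(rng)
    d1 = dx.build_texton_dictionary([img], k=5, seed=3)
    d2 = dx.build_texton_dictionary([img], k=5, seed=3)
    np.testing.assert_array_equal(d1.centroids, d2.centroids)


def test_dictionary_size_and_sample_guard(rng):
    img, _ = _two_texture_image(rng)
    d = dx.build_texton_dictionary([img], k=30, seed=0, samples_per_image=2000)
    assert d.k == 30 and d.centroids.shape == (30, 18)
    with pytest.raises(ValueError, match="fewer samples"):
        dx.build_texton_dictionary([img[:2, :2]], k=30, seed=0)
    with pytest.raises(ValueError, match="k must be"):
        dx.build_texton_dictionary([img], k=1, seed=0)


def test_texture_vector_simplex_properties(rng):
    img, truth = _two_texture_image(rng)
    d = dx.build_texton_dictionary([img], k=3, seed=0)
    t_maps, t_med = dx.texture_vector(img, d, window_px=15, ec_mask=truth == 0)
    sums = t_maps.sum(axis=0)
    np.testing.assert_allclose(sums, 1.0, atol=1e-9)
    assert np.all(t_maps >= 0)
    # elementwise median of simplex vectors: entries >= 0, sum in (0, 1]
    assert np.all(t_med >= 0)
    assert 0 < t_med.sum() <= 1.0 + 1e-9
    with pytest.raises(ValueError, match="empty EC"):
        dx.texture_vector(img, d, ec_mask=np.zeros_like(truth, dtype=bool))


def test_uniform_texture_gives_constant_t(rng):
    img = 0.01 * rng.standard_normal((96, 96))
    d = dx.build_texton_dictionary([img], k=2, seed=0)
    t_maps, t_med = dx.texture_vector(
        img, d, window_px=25, ec_mask=np.ones_like(img, dtype=bool)
    )
    interior = t_maps[:, 24:-24, 24:-24]
    assert np.all(interior.std(axis=(1, 2)) < 0.2)


# --- feature vector --------------------------------------------------------


def test_feature_vector_lengths():
    t30, t50 = np.full(30, 1 / 30), np.full(50, 1 / 50)
    assert dx.ec_feature_vector(0.02, 5.0, t30, k=30).size == 32
    assert dx.ec_feature_vector(0.02, 5.0, t50, k=50).size == 52
    with pytest.raises(ValueError):
        dx.ec_feature_vector(0.02, None, t30)
    with pytest.raises(ValueError, match="length"):
        dx.ec_feature_vector(0.02, 5.0, t30, k=50)


# --- LDA and cross-validation ---------------------------------------------


def test_lda_separates_gaussian_clouds(rng):
    x = np.vstack([rng.normal(0, 1, (40, 5)), rng.normal(4, 1, (40, 5))])
    y = np.repeat([0, 1], 40)
    clf = dx.train_lda(x, y)
    assert (clf.predict(x) == y).all()
    s = clf.score(x)
    assert np.all((s >= 0) & (s <= 1))


def test_lda_duplicate_column_same_scores(rng):
    x = np.vstack([rng.normal(0, 1, (30, 4)), rng.normal(2, 1, (30, 4))])
    y = np.repeat([0, 1], 30)
    x_dup = np.hstack([x, x[:, :1]])
    s1 = dx.train_lda(x, y).score(x)
    s2 = dx.train_lda(x_dup, y).score(x_dup)
    np.testing.assert_allclose(s1, s2, atol=1e-4)


def test_lda_singular_covariance_warns(rng):
    # p = 16 > n - 2 = 10 degrees of freedom: pooled covariance singular
    x = np.vstack([rng.normal(0, 1, (6, 16)), rng.normal(2, 1, (6, 16))])
    y = np.repeat([0, 1], 6)
    with pytest.warns(UserWarning, match="singular"):
        dx.train_lda(x, y)


def test_lda_requires_both_classes(rng):
    with pytest.raises(ValueError, match="both classes"):
        dx.train_lda(rng.random((10, 3)), np.zeros(10))


def test_crossvalidation_scores_each_ec_once(rng):
    x = np.vstack([rng.normal(0, 1, (3, 4)), rng.normal(5, 1, (3, 4))])
    y = np.repeat([0, 1], 3)
    roc = dx.crossvalidate_roc(x, y, folds=3, seed=0)
    # partition property: every EC held out and scored exactly once
    assert roc.pooled_scores.size == 6
    assert np.all(np.isfinite(roc.pooled_scores))
    assert roc.auc > 0.8  # pooled calibration across tiny folds is not exact


def test_pooled_roc_contract(rng):
    """The reported AUC comes from pooled held-out scores, not fold means."""
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold

    x = np.vstack([rng.normal(0, 2, (24, 3)), rng.normal(1.0, 2, (24, 3))])
    y = np.repeat([0, 1], 24)
    roc = dx.crossvalidate_roc(x, y, folds=3, seed=1)
    pooled = roc_auc_score(roc.pooled_labels, roc.pooled_scores)
    assert roc.auc == pytest.approx(pooled, abs=1e-12)
    fold_aucs = []
    for tr, te in StratifiedKFold(3, shuffle=True, random_state=1).split(x, y):
        clf = dx.train_lda(x[tr], y[tr])
        fold_aucs.append(roc_auc_score(y[te], clf.score(x[te])))
    assert roc.auc != pytest.approx(np.mean(fold_aucs), abs=1e-6)
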