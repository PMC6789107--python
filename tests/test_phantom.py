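"""Phantom generator: determinism, geometry, stain and survival models."""

import numpy as np
import pytest
from scipy import stats

from cslim import fibers as fib
from cslim import interferometry as itf
from cslim import normalize, phantom


def test_same_seed_bitwise_identical():
    spec = phantom.PhantomSpec(
        seed=7, shape=(192, 192), n_glands=2, gland_radius_um=(10.0, 14.0),
        n_fibers=6,
    )
    a = phantom.make_phase_phantom(spec)
    b = phantom.make_phase_phantom(spec)
    np.testing.assert_array_equal(a.phase, b.phase)
    np.testing.assert_array_equal(a.tissue_mask, b.tissue_mask)
    for fa, fb in zip(a.fibers, b.fibers):
        np.testing.assert_array_equal(fa.centerline, fb.centerline)
        assert fa.orientation_deg == fb.orientation_deg


def test_empty_stroma_single_ec_disk():
    spec = phantom.PhantomSpec(
        seed=1, shape=(192, 192), n_glands=1, n_fibers=0,
        gland_aspect_range=(1.0, 1.0), malignant_fraction=0.0,
        background_noise_sd_rad=0.0,
    )
    truth = phantom.make_phase_phantom(spec)
    ec_mask = truth.ec_boundaries[0].mask(truth.phase.shape)
    assert np.all(truth.phase[~ec_mask] == 0.0)
    assert truth.phase[ec_mask].max() > 0


def test_fibers_stay_outside_ec_masks(small_truth):
    ec_mask = small_truth.ec_mask()
    for f in small_truth.fibers:
        cols = np.round(f.centerline[:, 0]).astype(int)
        rows = np.round(f.centerline[:, 1]).astype(int)
        assert not ec_mask[rows, cols].any()


def test_geometry_that_cannot_fit_raises():
    spec = phantom.PhantomSpec(
        seed=0, shape=(96, 96), n_glands=5, gland_radius_um=(20.0, 22.0)
    )
    with pytest.raises(ValueError, match="fit|too large"):
        phantom.make_phase_phantom(spec)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"fiber_target_angle_deg": 120.0},
        {"fiber_policy": "spiral"},
        {"pixel_size_um": -1.0},
        {"background_noise_sd_rad": -0.1},
    ],
)
def test_invalid_spec_rejected(kwargs):
    with pytest.raises(ValueError):
        phantom.PhantomSpec(seed=0, **kwargs)


def test_aligned_policy_records_near_perpendicular_theta():
    """Fibers placed at 90 deg to the boundary measure theta near 90."""
    devs = []
    for seed in (7, 8):
        spec = phantom.PhantomSpec(
            seed=seed, n_glands=1, n_fibers=10, fiber_policy="aligned",
            fiber_target_angle_deg=90.0, fiber_aligned_fraction=1.0,
            fiber_distance_um=(2.0, 15.0), malignant_fraction=0.0,
            gland_aspect_range=(0.9, 1.0), background_noise_sd_rad=0.0,
        )
        truth = phantom.make_phase_phantom(spec)
        z = normalize.z_normalize(truth.phase, truth.tissue_mask)
        traced = fib.extract_fibers(z.z, truth.pixel_size_um, ec_mask=truth.ec_mask())
        thetas = [
            fib.relative_angle(f, truth.ec_boundaries, max_dist_um=100.0)
            for f in traced
        ]
        devs += [90.0 - t for t in thetas if t is not None]
    assert len(devs) >= 15
    assert np.mean(devs) < 6.0  # tracing + boundary-curvature tolerance
    assert max(devs) < 20.0


# --- stain model -----------------------------------------------------------


def test_identity_stain_leaves_phase_unchanged(small_truth):
    stained = phantom.apply_stain_model(
        small_truth, phantom.StainParams(a=1.0, b=0.0, noise_sd_rad=0.0), seed=0
    )
    np.testing.assert_array_equal(stained.phase, small_truth.phase)


def test_stain_scales_masked_sd_and_leaves_background(small_truth):
    stained = phantom.apply_stain_model(
        small_truth, phantom.StainParams(a=0.5, b=0.1, noise_sd_rad=0.0), seed=0
    )
    m = small_truth.tissue_mask
    assert stained.phase[m].std() == pytest.approx(0.5 * small_truth.phase[m].std())
    np.testing.assert_array_equal(stained.phase[~m], small_truth.phase[~m])
    assert np.all(stained.absorbance[:, ~m] == 0.0)


def test_stain_commutes_with_z_normalization(small_truth):
    """Z(a*phi + b) = Z(phi) over the tissue mask, noiseless."""
    stained = phantom.apply_stain_model(
        small_truth, phantom.StainParams(a=0.5, b=0.3, noise_sd_rad=0.0), seed=0
    )
    m = small_truth.tissue_mask
    z_u = normalize.z_normalize(small_truth.phase, m)
    z_s = normalize.z_normalize(stained.phase, m)
    np.testing.assert_allclose(z_u.z[m], z_s.z[m], atol=1e-12)


def test_invalid_stain_params():
    with pytest.raises(ValueError):
        phantom.StainParams(a=0.0)
    with pytest.raises(ValueError):
        phantom.StainParams(absorbance_rgb=(-0.1, 0, 0))


# --- interferometric rendering --------------------------------------------


def test_flat_zero_phase_gives_constant_frames():
    truth = phantom.GroundTruth(
        phase=np.zeros((32, 32)),
        tissue_mask=np.zeros((32, 32), dtype=bool),
        ec_boundaries=[], fibers=[], pixel_size_um=0.5, thickness_um=5.0,
    )
    acq = phantom.render_interferograms(truth, phantom.OpticsModel(), seed=0)
    for c in range(3):
        for k in range(4):
            frame = acq.frames[c, k]
            assert np.ptp(frame) < 1e-12 * max(frame.max(), 1.0)


def test_noiseless_roundtrip_recovers_phase(small_truth):
    acq = phantom.render_interferograms(small_truth, phantom.OpticsModel(), seed=0)
    pm = itf.reconstruct_phase(itf.combine_channels(acq), alpha=3.4)
    rmse = np.sqrt(np.mean((pm.phi.astype(float) - small_truth.phase) ** 2))
    assert rmse < 1e-6


def test_shot_noise_keeps_phase_unbiased():
    """1% shot noise adds error but no systematic phase bias (<1e-3 rad)."""
    spec = phantom.PhantomSpec(seed=3, shape=(96, 96), n_glands=1, n_fibers=3,
                               background_noise_sd_rad=0.0)
    truth = phantom.make_phase_phantom(spec)
    optics = phantom.OpticsModel(shot_noise_sd=0.01)
    biases = []
    for seed in range(100):
        acq = phantom.render_interferograms(truth, optics, seed=seed)
        pm = itf.reconstruct_phase(itf.combine_channels(acq), alpha=3.4)
        biases.append(np.mean(pm.phi.astype(float) - truth.phase))
    assert abs(np.mean(biases)) < 1e-3


# --- survival simulation ---------------------------------------------------


def test_simulate_survival_columns_and_no_censoring():
    t = phantom.simulate_survival(50, 2.0, baseline_rate=0.02, censor_rate=0.0, seed=0)
    assert list(t.columns) == ["time", "event", "group"]
    assert (t["event"] == 1).all()
    assert (t["time"] > 0).all()
    assert set(t["group"]) == {0, 1}


def test_simulate_survival_rejects_tiny_groups():
    with pytest.raises(ValueError):
        phantom.simulate_survival(1, 2.0, seed=0)


def test_null_hazard_ratio_gives_uniform_logrank_p():
    from cslim import survival

    pvals = []
    for seed in range(40):
        t = phantom.simulate_survival(60, 1.0, 0.02, 0.0, seed=seed)
        _, p = survival.logrank_test(t[t.group == 0], t[t.group == 1])
        pvals.append(p)
    # uniform null: KS test should not reject
    assert stats.kstest(pvals, "uniform").pvalue > 0.01
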