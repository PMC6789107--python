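"""Reproducible phantom studies exercising the full cSLIM pipeline.

Each function runs a self-contained, seeded experiment on synthetic
phantoms and returns summary statistics:

* interferometric round trip — render 12-frame acquisitions and verify
  the reconstruction inverts the forward model;
* stain normalization — stained/unstained Z-map agreement (histogram
  Pearson rho) against the raw-phase baseline, at full histology phase
  scale;
* diagnosis — EC feature extraction, pooled 3-fold cross-validated ROC,
  and its label-permutation null;
* TACS-3 prognosis — fiber tracing on simulated cores from positive and
  negative stromal regimes, SVM classification, and downstream survival
  analysis;
* survival recovery — Cox hazard-ratio and log-rank power calibration on
  simulated cohorts.

Problem sizes default to desk-scale runs (a few minutes in total); every
study is deterministic for a given seed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from cslim import diagnosis as dx
from cslim import fibers as fib
from cslim import interferometry as itf
from cslim import normalize, phantom, survival

# ---------------------------------------------------------------------------
# interferometric round trip


def optical_roundtrip_study(n_phantoms: int = 20, seed: int = 0) -> dict:
    """Noiseless simulate -> combine -> reconstruct across seeded phantoms.

    Returns per-phantom RMSE (rad) between reconstructed and true phase.
    """
    rmses = []
    for i in range(n_phantoms):
        spec = phantom.PhantomSpec(seed=seed + i, background_noise_sd_rad=0.01)
        truth = phantom.make_phase_phantom(spec)
        acq = phantom.render_interferograms(truth, phantom.OpticsModel(), seed=seed + i)
        gray = itf.combine_channels(acq, itf.ChannelWeights())
        pm = itf.reconstruct_phase(gray, alpha=3.4, pixel_size_um=spec.pixel_size_um)
        err = pm.phi.astype(float) - truth.phase
        rmses.append(float(np.sqrt(np.mean(err**2))))
    return {"rmse_rad": rmses, "max_rmse_rad": max(rmses)}


# ---------------------------------------------------------------------------
# stain normalization


def stain_phantom_spec(seed: int) -> phantom.PhantomSpec:
    """Phantom emulating a full stained-core comparison.

    Histology-scale phase amplitudes (5 um sections reach ~1.5 rad) and a
    measurement-scale phase noise floor; sized like a core scan so the
    256-bin histograms are well populated.  This study compares phase
    maps directly (it does not pass through the interferometric render,
    which operates in the weak-scattering regime).
    """
    return phantom.PhantomSpec(
        seed=seed,
        shape=(1024, 1024),
        n_glands=10,
        n_fibers=60,
        gland_radius_um=(18.0, 35.0),
        epithelial_phase_rad=1.5,
        fiber_phase_rad=1.0,
        background_noise_sd_rad=0.08,
        fiber_distance_um=(2.0, 60.0),
    )


def stain_normalization_study(
    n_seeds: int = 50,
    seed: int = 0,
    stain: phantom.StainParams | None = None,
) -> pd.DataFrame:
    """Histogram correlation of stained vs unstained maps, raw and Z.

    For each seed: generate a phantom, stain it (default a = 0.6,
    b = 0.2, stain noise sd 0.01 rad), and compute the histogram Pearson
    rho between stained and unstained values over the tissue mask, for
    the raw phase and for the Z maps.  Also reports the pixelwise RMS
    difference of the two Z maps.
    """
    stain = stain or phantom.StainParams(a=0.6, b=0.2, noise_sd_rad=0.01)
    rows = []
    for i in range(n_seeds):
        truth = phantom.make_phase_phantom(stain_phantom_spec(seed + i))
        stained = phantom.apply_stain_model(truth, stain, seed=seed + i + 10_000)
        m = truth.tissue_mask
        z_u = normalize.z_normalize(truth.phase, m)
        z_s = normalize.z_normalize(stained.phase, m)
        rows.append(
            {
                "rho_z": normalize.histogram_correlation(z_u.z[m], z_s.z[m]),
                "rho_raw": normalize.histogram_correlation(
                    truth.phase[m], stained.phase[m]
                ),
                "z_rms_diff": float(np.sqrt(np.mean((z_u.z[m] - z_s.z[m]) ** 2))),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# diagnosis


def diagnosis_phantom_spec(seed: int) -> phantom.PhantomSpec:
    """One diagnosis-study tile: 4 ECs (half malignant) plus sparse stroma."""
    return phantom.PhantomSpec(
        seed=seed,
        shape=(320, 320),
        n_glands=4,
        gland_radius_um=(12.0, 20.0),
        n_fibers=8,
        background_noise_sd_rad=0.01,
    )


def diagnosis_cohort(
    n_images: int = 24, seed: int = 0, n_textons: int = 30
) -> tuple[np.ndarray, np.ndarray]:
    """EC feature matrix (n_ecs, 2 + n_textons) and 0/1 labels.

    Z maps are computed per tile; the texton dictionary is trained
    (unsupervised) on all tiles; per EC the median curvature, median
    scattering length and median texton-frequency vector are
    concatenated.
    """
    images, ec_lists = [], []
    for i in range(n_images):
        truth = phantom.make_phase_phantom(diagnosis_phantom_spec(seed + i))
        z = normalize.z_normalize(truth.phase, truth.tissue_mask)
        images.append(z.z)
        ec_lists.append(truth.ec_boundaries)
    dictionary = dx.build_texton_dictionary(
        images, k=n_textons, seed=seed, samples_per_image=1500
    )
    feats, labels = [], []
    for img, ecs in zip(images, ec_lists):
        t_maps, _ = dx.texture_vector(img, dictionary, window_px=25)
        ls_map = dx.scattering_length_map(img, thickness_um=5.0, window_px=15)
        for ec in ecs:
            mask = ec.mask(img.shape)
            _, c_med = dx.boundary_curvature(ec, pixel_size_um=0.5)
            ls_med = dx.ec_median(ls_map, mask)
            t_med = np.median(t_maps[:, mask], axis=1)
            feats.append(dx.ec_feature_vector(c_med, ls_med, t_med, k=n_textons))
            labels.append(1 if ec.label == "malignant" else 0)
    return np.array(feats), np.array(labels)


def diagnosis_study(
    seed: int = 0, n_images: int = 24, n_permutation_seeds: int = 50
) -> dict:
    """Pooled 3-fold CV AUC on phantom ECs and its permutation null."""
    feats, labels = diagnosis_cohort(n_images=n_images, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # n < p folds: ridge handles it
        auc = dx.crossvalidate_roc(feats, labels, folds=3, seed=seed).auc
        rng = np.random.default_rng(seed + 1)
        perm_aucs = [
            dx.crossvalidate_roc(feats, rng.permutation(labels), folds=3, seed=s).auc
            for s in range(n_permutation_seeds)
        ]
    return {
        "auc": auc,
        "n_ecs": int(labels.size),
        "perm_aucs": perm_aucs,
        "perm_mean": float(np.mean(perm_aucs)),
    }


# ---------------------------------------------------------------------------
# TACS-3 prognosis


def tacs_core_spec(regime: str, seed: int) -> phantom.PhantomSpec:
    """Generative stromal regimes for TACS-3 cores.

    ``positive``: a radial (boundary-terminating, near-perpendicular)
    fiber subpopulation mixed into a wrapped parallel background, all
    close to the tumor edge — high alignment, low edge distance, theta
    bulk low with a high tail (positive skew).
    ``negative``: uniformly oriented fibers farther from the edge.
    """
    if regime == "positive":
        return phantom.PhantomSpec(
            seed=seed,
            n_glands=2,
            n_fibers=16,
            fiber_policy="aligned",
            fiber_target_angle_deg=90.0,
            fiber_aligned_fraction=0.3,
            fiber_distance_um=(1.0, 20.0),
            background_noise_sd_rad=0.01,
        )
    if regime == "negative":
        return phantom.PhantomSpec(
            seed=seed,
            n_glands=2,
            n_fibers=16,
            fiber_policy="random",
            fiber_distance_um=(25.0, 60.0),
            background_noise_sd_rad=0.01,
        )
    raise ValueError("regime must be 'positive' or 'negative'")


def tacs_core_features(
    regime: str, seed: int, through_optics: bool = True
) -> fib.CoreFeatures | None:
    """Simulate one core and measure its TACS-3 feature triple.

    With ``through_optics`` the core passes through the full pipeline
    (12-frame render with 0.5% shot noise -> channel combination ->
    phase reconstruction -> segmentation -> Z map) before fiber tracing;
    otherwise fibers are traced on the Z map of the true phase.
    """
    truth = phantom.make_phase_phantom(tacs_core_spec(regime, seed))
    if through_optics:
        optics = phantom.OpticsModel(shot_noise_sd=0.005)
        acq = phantom.render_interferograms(truth, optics, seed=seed + 50_000)
        gray = itf.combine_channels(acq, itf.ChannelWeights())
        pm = itf.reconstruct_phase(gray, alpha=optics.alpha)
        phase = pm.phi.astype(float)
        mask = normalize.segment_background(phase)
    else:
        phase, mask = truth.phase, truth.tissue_mask
    z = normalize.z_normalize(phase, mask)
    traced = fib.extract_fibers(
        z.z, truth.pixel_size_um, ec_mask=truth.ec_mask()
    )
    return fib.core_tacs_features(traced, truth.ec_boundaries, max_dist_um=100.0)


def tacs_cohort(
    n_per_class: int, seed: int, through_optics: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix (n, 3) and labels (1 = positive) for simulated cores."""
    feats, labels = [], []
    for i in range(n_per_class):
        for regime, lab in (("positive", 1), ("negative", 0)):
            cf = None
            for attempt in range(4):  # rare infeasible geometry: redraw core
                try:
                    cf = tacs_core_features(
                        regime, seed + 97 * i + lab + 31_337 * attempt, through_optics
                    )
                    break
                except ValueError:
                    continue
            if cf is None:  # unclassifiable core (too few eligible fibers)
                continue
            feats.append(cf.as_array())
            labels.append(lab)
    return np.array(feats), np.array(labels)


def tacs_prognosis_study(
    n_train_per_class: int = 10,
    n_test_per_class: int = 100,
    seed: int = 0,
    survival_hr: float = 2.0,
    baseline_rate: float = 0.02,
    censor_rate: float = 0.005,
    through_optics: bool = True,
) -> dict:
    """End-to-end prognosis: cores -> SVM calls -> survival analysis.

    A linear SVM is trained on ``n_train_per_class`` cores per regime and
    applied to an independent test cohort.  Survival times are simulated
    from each test core's *true* regime (hazard ratio ``survival_hr`` for
    true positives); Cox regression and the log-rank test then compare
    the groups defined by the *SVM calls*, as in a prospective use of the
    classifier.
    """
    x_train, y_train = tacs_cohort(n_train_per_class, seed=seed, through_optics=through_optics)
    x_test, y_test = tacs_cohort(
        n_test_per_class, seed=seed + 1_000_000, through_optics=through_optics
    )
    clf = fib.train_tacs_svm(x_train, y_train)
    calls, decision = fib.classify_cores(clf, x_test)
    accuracy = float(np.mean(calls == y_test))

    rng_seed = seed + 77
    rate = baseline_rate * np.where(y_test == 1, survival_hr, 1.0)
    rng = np.random.default_rng(rng_seed)
    t_event = rng.exponential(1.0 / rate)
    t_cens = (
        rng.exponential(1.0 / censor_rate, size=y_test.size)
        if censor_rate > 0
        else np.full(y_test.size, np.inf)
    )
    table = pd.DataFrame(
        {
            "time": np.minimum(t_event, t_cens),
            "event": (t_event <= t_cens).astype(int),
            "group": calls,
        }
    )
    cox = survival.cox_univariate(table, covariate="group")
    chi2, p_logrank = survival.logrank_test(
        table[table["group"] == 0], table[table["group"] == 1]
    )
    return {
        "test_accuracy": accuracy,
        "n_test": int(y_test.size),
        "cox_hr": cox.hr,
        "cox_p": cox.p,
        "logrank_chi2": chi2,
        "logrank_p": p_logrank,
        "decision_values": decision,
    }


# ---------------------------------------------------------------------------
# survival calibration


def cox_recovery_study(
    n_sims: int = 100,
    true_hr: float = 2.0,
    n_per_group: int = 500,
    seed: int = 0,
    hr_band: tuple[float, float] = (1.7, 2.3),
) -> dict:
    """Fraction of simulations whose Cox HR falls within ``hr_band``."""
    hrs = []
    for i in range(n_sims):
        table = phantom.simulate_survival(
            n_per_group, true_hr, baseline_rate=0.02, censor_rate=0.0, seed=seed + i
        )
        hrs.append(survival.cox_univariate(table).hr)
    hrs = np.array(hrs)
    within = float(np.mean((hrs >= hr_band[0]) & (hrs <= hr_band[1])))
    return {"hrs": hrs, "fraction_within": within, "mean_hr": float(hrs.mean())}


def logrank_power_study(
    n_sims: int = 100,
    true_hr: float = 3.0,
    n_per_group: int = 200,
    seed: int = 0,
    alpha: float = 1e-3,
) -> dict:
    """Fraction of simulations with two-sample log-rank p below ``alpha``."""
    hits = 0
    pvals = []
    for i in range(n_sims):
        table = phantom.simulate_survival(
            n_per_group, true_hr, baseline_rate=0.02, censor_rate=0.0, seed=seed + i
        )
        _, p = survival.logrank_test(table[table.group == 0], table[table.group == 1])
        pvals.append(p)
        hits += p < alpha
    return {"power": hits / n_sims, "pvals": pvals}
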