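"""Stage orchestration: run pipeline stages in dependency order.

Stages operate on files in ``config.out_dir`` and every run writes a JSON
manifest listing outputs with their SHA-256 hashes, the resolved
configuration and the seeds used, so identical (config, seed) pairs
reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from cslim import diagnosis as dx
from cslim import fibers as fib
from cslim import interferometry as itf
from cslim import io as cio
from cslim import normalize, phantom, studies, survival
from cslim.config import RunConfig

STAGE_ORDER = ["simulate", "reconstruct", "zmap", "fibers", "tacs3", "survival"]

#: files each stage needs from its upstream stage
STAGE_INPUTS = {
    "simulate": [],
    "reconstruct": ["stack.tif"],
    "zmap": ["phase.tif"],
    "fibers": ["z.tif", "ec_labels.tif"],
    "tacs3": ["core_features.csv"],
    "survival": [],
}


class DependencyError(RuntimeError):
    """A requested stage is missing its upstream artifact."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_simulate(config: RunConfig, out: Path, spec: phantom.PhantomSpec) -> list[Path]:
    truth = phantom.make_phase_phantom(spec)
    optics = phantom.OpticsModel(
        alpha=config.alpha, channel_weights=config.channel_weights
    )
    acq = phantom.render_interferograms(truth, optics, seed=config.seed)
    files = [cio.write_acquisition(out / "stack.tif", acq)]
    files += [Path(p) for p in cio.write_ground_truth(out, truth).values()]
    return files


def _stage_reconstruct(config: RunConfig, out: Path) -> list[Path]:
    acq = cio.read_acquisition(out / "stack.tif")
    gray = itf.combine_channels(acq, itf.ChannelWeights(*config.channel_weights))
    pm = itf.reconstruct_phase(
        gray,
        alpha=config.alpha,
        pixel_size_um=config.pixel_size_um,
        thickness_um=config.thickness_um,
    )
    files = [cio.write_phase(out / "phase.tif", pm)]
    bf = itf.extract_brightfield(acq)
    bf8 = np.clip(bf / max(bf.max(), 1e-12) * 255, 0, 255).astype(np.uint8)
    import tifffile

    tifffile.imwrite(out / "brightfield.tif", bf8)
    files.append(out / "brightfield.tif")
    return files


def _stage_zmap(config: RunConfig, out: Path) -> list[Path]:
    pm = cio.read_phase(out / "phase.tif")
    phase = pm.phi.astype(float)
    mask = normalize.segment_background(phase)
    zm = normalize.z_normalize(phase, mask)
    import tifffile

    tifffile.imwrite(out / "z.tif", zm.z.astype(np.float32))
    (out / "z.json").write_text(
        json.dumps({"mu": zm.mu, "sigma": zm.sigma, "mask_file": "z_mask.tif"}, indent=2)
    )
    cio.write_mask(out / "z_mask.tif", zm.mask)
    return [out / "z.tif", out / "z.json", out / "z_mask.tif"]


def _stage_fibers(config: RunConfig, out: Path) -> list[Path]:
    import tifffile

    z = tifffile.imread(out / "z.tif").astype(float)
    boundaries = cio.read_ec_boundaries(
        out / "ec_labels.tif",
        out / "ec_table.csv" if (out / "ec_table.csv").exists() else None,
    )
    ec_mask = tifffile.imread(out / "ec_labels.tif") > 0
    traced = fib.extract_fibers(z, config.pixel_size_um, ec_mask=ec_mask)
    features: dict[int, dict] = {}
    for i, f in enumerate(traced):
        features[f.fiber_id] = {
            "theta_deg": fib.relative_angle(f, boundaries, config.fiber_max_dist_um),
            "l_um": fib.boundary_distance(f, boundaries),
            "epsilon": fib.nearest_alignment(traced, i),
        }
    files = [cio.write_fiber_table(out / "fibers.csv", traced, features)]
    cf = fib.core_tacs_features(traced, boundaries, config.fiber_max_dist_um)
    row = (
        {
            "core_id": 0,
            "mean_epsilon": cf.mean_epsilon,
            "mean_l_um": cf.mean_l_um,
            "skew_theta": cf.skew_theta,
            "n_fibers": cf.n_fibers,
        }
        if cf is not None
        else {"core_id": 0, "mean_epsilon": np.nan, "mean_l_um": np.nan,
              "skew_theta": np.nan, "n_fibers": 0}
    )
    pd.DataFrame([row]).to_csv(out / "core_features.csv", index=False)
    files.append(out / "core_features.csv")
    return files


def _stage_tacs3(config: RunConfig, out: Path) -> list[Path]:
    cores = pd.read_csv(out / "core_features.csv")
    x_train, y_train = studies.tacs_cohort(5, seed=config.seed, through_optics=False)
    clf = fib.train_tacs_svm(x_train, y_train)
    x = cores[["mean_epsilon", "mean_l_um", "skew_theta"]].to_numpy()
    valid = np.all(np.isfinite(x), axis=1)
    calls = np.full(len(cores), -1)
    decision = np.full(len(cores), np.nan)
    if valid.any():
        calls[valid], decision[valid] = fib.classify_cores(clf, x[valid])
    result = pd.DataFrame(
        {"core_id": cores["core_id"], "call": calls, "decision_value": decision}
    )
    result.to_csv(out / "tacs3_calls.csv", index=False)
    return [out / "tacs3_calls.csv"]


def _stage_survival(config: RunConfig, out: Path) -> list[Path]:
    table_path = out / "survival.csv"
    if not table_path.exists():
        table = phantom.simulate_survival(
            100, true_hazard_ratio=2.0, baseline_rate=0.02, censor_rate=0.005,
            seed=config.seed,
        )
        cio.write_survival_table(table_path, table)
    table = cio.read_survival_table(table_path)
    km = {
        g: survival.kaplan_meier(t).to_dict(orient="list")
        for g, t in table.groupby("group")
    }
    chi2, p = survival.logrank_test(
        table[table["group"] == 0], table[table["group"] == 1]
    )
    cox = survival.cox_univariate(table)
    results = {
        "logrank_chi2": chi2,
        "logrank_p": p,
        "cox": dataclasses.asdict(cox),
    }
    (out / "survival_results.json").write_text(json.dumps(results, indent=2))
    pd.concat(
        [survival.kaplan_meier(t).assign(group=g) for g, t in table.groupby("group")]
    ).to_csv(out / "km_curves.csv", index=False)
    del km
    return [table_path, out / "survival_results.json", out / "km_curves.csv"]


def run_pipeline(
    config: RunConfig,
    stages: list[str],
    spec: phantom.PhantomSpec | None = None,
) -> dict:
    """Run the requested stages in dependency order; return the manifest.

    Raises :class:`DependencyError` when a stage's upstream artifact is
    neither produced by an earlier requested stage nor already on disk.
    """
    unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    ordered = [s for s in STAGE_ORDER if s in stages]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = spec or phantom.PhantomSpec(seed=config.seed)

    produced: list[Path] = []
    manifest: dict = {
        "config": {**dataclasses.asdict(config), "out_dir": str(config.out_dir)},
        "stages": ordered,
        "outputs": {},
    }
    for stage in ordered:
        for needed in STAGE_INPUTS[stage]:
            if not (out / needed).exists():
                raise DependencyError(
                    f"stage {stage!r} requires {needed!r}; run its upstream "
                    "stage first or include it in the stage list"
                )
        fn = {
            "simulate": lambda: _stage_simulate(config, out, spec),
            "reconstruct": lambda: _stage_reconstruct(config, out),
            "zmap": lambda: _stage_zmap(config, out),
            "fibers": lambda: _stage_fibers(config, out),
            "tacs3": lambda: _stage_tacs3(config, out),
            "survival": lambda: _stage_survival(config, out),
        }[stage]
        files = fn()
        produced.extend(files)
        manifest["outputs"][stage] = {str(f.name): _sha256(Path(f)) for f in files}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def diagnose_image(
    z: np.ndarray,
    boundaries: list[dx.ECBoundary],
    config: RunConfig,
) -> tuple[np.ndarray, np.ndarray, dx.ROCResult]:
    """Feature extraction + pooled CV ROC for the ECs of one Z map."""
    dictionary = dx.build_texton_dictionary(
        [z], k=config.n_textons, seed=config.seed
    )
    t_maps, _ = dx.texture_vector(z, dictionary, window_px=config.texton_window_px)
    ls_map = dx.scattering_length_map(
        z, thickness_um=config.thickness_um, window_px=config.ls_window_px
    )
    feats, labels = [], []
    for ec in boundaries:
        mask = ec.mask(z.shape)
        _, c_med = dx.boundary_curvature(
            ec, config.pixel_size_um, config.curvature_smoothing_px
        )
        feats.append(
            dx.ec_feature_vector(
                c_med,
                dx.ec_median(ls_map, mask),
                np.median(t_maps[:, mask], axis=1),
                k=config.n_textons,
            )
        )
        labels.append(1 if ec.label == "malignant" else 0)
    x, y = np.array(feats), np.array(labels)
    roc = dx.crossvalidate_roc(x, y, folds=3, seed=config.seed)
    return x, y, roc
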