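"""Readers and writers for the pipeline's file dialects.

Images travel as TIFF (12-page float32 acquisition stacks in
channel-major R, G, B / shift-minor 0, pi/2, pi, 3pi/2 order; single-page
float32 maps with JSON sidecars; uint8 label and mask images), tables as
CSV, metadata as JSON.  Float maps round-trip losslessly; label images
are preserved exactly.

Coordinate convention: arrays are indexed (row, col); polygons and fiber
vertices are stored as (x = col, y = row) in CSV.  Angles are measured
counterclockwise from +x, orientations mod 180 deg.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage import measure

from cslim.diagnosis import ECBoundary
from cslim.fibers import Fiber
from cslim.interferometry import PhaseMap, RawAcquisition
from cslim.phantom import GroundTruth, PhantomFiber


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


def write_acquisition(path: str | Path, acq: RawAcquisition) -> Path:
    """Write a RawAcquisition as a 12-page float32 TIFF."""
    path = Path(path)
    pages = acq.frames.reshape((12,) + acq.shape).astype(np.float32)
    tifffile.imwrite(
        path,
        pages,
        metadata=None,
        description=json.dumps(
            {"pixel_size_um": acq.pixel_size_um, "layout": "channel-major RGB, shifts 0,pi/2,pi,3pi/2"}
        ),
    )
    return path


def read_acquisition(path: str | Path) -> RawAcquisition:
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        n = len(tif.pages)
        if n != 12:
            raise FormatError(
                f"{path.name}: expected the 12-page layout (3 channels x 4 "
                f"shifts, channel-major R,G,B, shift-minor 0,pi/2,pi,3pi/2); "
                f"got {n} pages"
            )
        pages = tif.asarray()
        pixel_size = 0.5
        desc = tif.pages[0].description
        if desc:
            try:
                pixel_size = float(json.loads(desc).get("pixel_size_um", pixel_size))
            except (json.JSONDecodeError, TypeError, ValueError):
                pass
    frames = np.asarray(pages, dtype=float).reshape((3, 4) + pages.shape[1:])
    return RawAcquisition(frames=frames, pixel_size_um=pixel_size)


def write_phase(path: str | Path, pm: PhaseMap) -> Path:
    """Float32 TIFF plus a JSON sidecar (lambda_c, pixel size, t, alpha)."""
    path = Path(path)
    tifffile.imwrite(path, pm.phi.astype(np.float32))
    sidecar = {
        "lambda_c_nm": pm.lambda_c_nm,
        "pixel_size_um": pm.pixel_size_um,
        "thickness_um": pm.thickness_um,
        "alpha": pm.alpha,
        "n_beta_clamped": pm.n_beta_clamped,
        "n_out_of_range": pm.n_out_of_range,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_phase(path: str | Path) -> PhaseMap:
    path = Path(path)
    phi = tifffile.imread(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing JSON sidecar for {path.name}")
    meta = json.loads(sidecar_path.read_text())
    return PhaseMap(
        phi=phi,
        lambda_c_nm=meta["lambda_c_nm"],
        pixel_size_um=meta["pixel_size_um"],
        thickness_um=meta["thickness_um"],
        alpha=meta["alpha"],
        n_beta_clamped=meta.get("n_beta_clamped", 0),
        n_out_of_range=meta.get("n_out_of_range", 0),
    )


def write_mask(path: str | Path, mask: np.ndarray) -> Path:
    path = Path(path)
    tifffile.imwrite(path, mask.astype(np.uint8))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)) > 0


def write_labels(path: str | Path, labels: np.ndarray) -> Path:
    """uint8 label image: background 0, k-th EC = value k."""
    path = Path(path)
    tifffile.imwrite(path, labels.astype(np.uint8))
    return path


def read_ec_boundaries(
    label_path: str | Path, table_path: str | Path | None = None
) -> list[ECBoundary]:
    """EC boundaries from a label image (+ optional diagnosis CSV).

    Boundaries are extracted for exactly the label values present; the
    CSV table (columns ec_id, diagnosis) supplies the labels, defaulting
    to benign.
    """
    labels = tifffile.imread(Path(label_path))
    diagnoses: dict[int, str] = {}
    if table_path is not None:
        df = pd.read_csv(table_path)
        diagnoses = dict(zip(df["ec_id"].astype(int), df["diagnosis"].astype(str)))
    out = []
    for value in sorted(np.unique(labels)):
        if value == 0:
            continue
        mask = labels == value
        contours = measure.find_contours(mask.astype(float), 0.5)
        if not contours:
            continue
        contour = max(contours, key=len)  # (row, col) -> (x, y)
        poly = contour[:, ::-1]
        if poly.shape[0] > 8 and np.allclose(poly[0], poly[-1]):
            poly = poly[:-1]
        out.append(
            ECBoundary(
                polygon=poly,
                ec_id=int(value),
                label=diagnoses.get(int(value), "benign"),
            )
        )
    return out


def write_ec_table(path: str | Path, boundaries: list[ECBoundary]) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"ec_id": [b.ec_id for b in boundaries], "diagnosis": [b.label for b in boundaries]}
    ).to_csv(path, index=False)
    return path


def _pack_vertices(arr: np.ndarray) -> str:
    return ";".join(f"{x:.2f},{y:.2f}" for x, y in arr)


def _unpack_vertices(s: str) -> np.ndarray:
    return np.array([[float(v) for v in p.split(",")] for p in s.split(";")])


def write_fiber_table(
    path: str | Path,
    fibers: list[Fiber],
    features: dict[int, dict] | None = None,
) -> Path:
    """Fiber CSV: id, packed vertices, orientation, length and, when
    provided, the theta/l/epsilon features keyed by fiber id."""
    path = Path(path)
    rows = []
    for f in fibers:
        row = {
            "fiber_id": f.fiber_id,
            "vertices": _pack_vertices(f.centerline),
            "orientation_deg": f.orientation_deg,
            "length_um": f.length_um,
        }
        if features and f.fiber_id in features:
            row.update(features[f.fiber_id])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_fiber_table(path: str | Path, pixel_size_um: float = 0.5) -> list[Fiber]:
    df = pd.read_csv(path)
    return [
        Fiber(
            fiber_id=int(r.fiber_id),
            centerline=_unpack_vertices(r.vertices),
            pixel_size_um=pixel_size_um,
        )
        for r in df.itertuples()
    ]


def write_truth_fibers(path: str | Path, fibers: list[PhantomFiber]) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {
                "fiber_id": f.fiber_id,
                "vertices": _pack_vertices(f.centerline),
                "orientation_deg": f.orientation_deg,
                "width_um": f.width_um,
                "length_um": f.length_um,
            }
            for f in fibers
        ]
    ).to_csv(path, index=False)
    return path


def write_ground_truth(out_dir: str | Path, truth: GroundTruth) -> dict[str, str]:
    """Write phase (float32 TIFF), masks, EC labels/table, fiber CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "true_phase.tif", truth.phase.astype(np.float32))
    write_mask(out / "tissue_mask.tif", truth.tissue_mask)
    write_labels(out / "ec_labels.tif", truth.ec_label_image())
    write_ec_table(out / "ec_table.csv", truth.ec_boundaries)
    write_truth_fibers(out / "true_fibers.csv", truth.fibers)
    return {
        "true_phase": str(out / "true_phase.tif"),
        "tissue_mask": str(out / "tissue_mask.tif"),
        "ec_labels": str(out / "ec_labels.tif"),
        "ec_table": str(out / "ec_table.csv"),
        "true_fibers": str(out / "true_fibers.csv"),
    }


def write_survival_table(path: str | Path, table: pd.DataFrame) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_survival_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"time", "event"} - set(df.columns)
    if missing:
        raise FormatError(f"survival table missing columns: {sorted(missing)}")
    return df


def write_roc(path: str | Path, fpr, tpr, thresholds, auc_value: float) -> Path:
    path = Path(path)
    pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds}).to_csv(
        path, index=False
    )
    path.with_suffix(".json").write_text(json.dumps({"auc": auc_value}, indent=2))
    return path
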