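"""Stromal collagen-fiber tracing and TACS-3 prognostic features.

Fibers are traced in Z maps with the epithelial compartments masked out
(so cell edges do not interfere): multiscale ridge enhancement, hysteresis
thresholding, skeletonization, and branch tracing into centerline
polylines, split at junctions and at direction discontinuities > 45 deg.

Per fiber, three features are measured relative to the EC (tumor) edges:

* ``theta``  acute angle between the fiber and the boundary tangent at the
  nearest edge point, in [0, 90] deg;
* ``l``      distance to the nearest EC boundary (um);
* ``epsilon`` mean nearest alignment: the axial circular resultant length
  of the fiber with its nearest 2, 4, 8 and 16 neighbors, averaged over
  the neighborhood sizes.

Core-level TACS-3 predictors are mean(epsilon), mean(l) and skewness of
theta over fibers within an eligibility distance of the tumor edge
(100 um by default); TACS-3-positive cores carry aligned fibers (high
epsilon) terminating at or near the edge (low l) at near-perpendicular
angles (positively skewed theta).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import LinearRing, Point
from scipy.ndimage import binary_dilation
from skimage.filters import apply_hysteresis_threshold, sato
from skimage.morphology import skeletonize
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from cslim.diagnosis import ECBoundary


@dataclass
class Fiber:
    """Traced fiber centerline with orientation bookkeeping.

    Coordinates are (x, y) = (col, row) pixels.  Orientations are axial,
    in degrees mod 180, measured counterclockwise from +x.
    """

    fiber_id: int
    centerline: np.ndarray
    pixel_size_um: float
    local_orientation_deg: np.ndarray = field(default=None, repr=False)
    orientation_deg: float = None  # total-least-squares line fit
    width_um: float = float("nan")

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[1] != 2:
            raise ValueError("centerline must be an (n, 2) array of (x, y)")
        if self.local_orientation_deg is None:
            self.local_orientation_deg = _local_orientations(self.centerline)
        if self.orientation_deg is None:
            self.orientation_deg = tls_orientation(self.centerline)

    @property
    def length_um(self) -> float:
        seg = np.diff(self.centerline, axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum() * self.pixel_size_um)

    @property
    def centroid(self) -> np.ndarray:
        return self.centerline.mean(axis=0)

    def end_orientation_deg(self, end: int, n_vertices: int = 10, trim: int = 2) -> float:
        """Orientation of the end segment (``end`` 0 = first, 1 = last).

        The outermost ``trim`` vertices are dropped first: skeleton tips
        of thick ridges often hook and would bias a short segment fit.
        """
        n = self.centerline.shape[0]
        t = trim if n > 2 * (trim + 2) else 0
        pts = (
            self.centerline[t : t + n_vertices]
            if end == 0
            else self.centerline[n - t - n_vertices : n - t]
        )
        if pts.shape[0] < 2:
            return self.orientation_deg
        return tls_orientation(pts)


def tls_orientation(points: np.ndarray) -> float:
    """Axial orientation (deg, mod 180) of a total-least-squares line fit."""
    pts = np.asarray(points, dtype=float)
    c = pts - pts.mean(axis=0)
    cov = c.T @ c
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argmax(evals)]
    # image rows grow downward; negate y so angles are CCW from +x
    return float(np.degrees(np.arctan2(-v[1], v[0])) % 180.0)


def _local_orientations(centerline: np.ndarray, half_window: int = 3) -> np.ndarray:
    n = centerline.shape[0]
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half_window), min(n, i + half_window + 1)
        out[i] = tls_orientation(centerline[lo:hi]) if hi - lo >= 2 else 0.0
    return out


@dataclass
class FiberTraceParams:
    """Tuning of the ridge/skeleton fiber tracer.

    Hysteresis thresholds are the larger of (a) multiples (``low_k``,
    ``high_k``) of a robust (1.4826 * MAD) scale of the stromal ridge
    response — suppressing noise-driven detections — and (b) fractions
    (``low_frac``, ``high_frac``) of the peak response — governing clean
    images where the MAD scale collapses.  Both are relative, so tracing
    is invariant to affine intensity scaling of the input.
    """

    ridge_sigmas: tuple[float, ...] = (1.0, 2.0, 3.0)
    low_k: float = 4.0
    high_k: float = 10.0
    low_frac: float = 0.1
    high_frac: float = 0.3
    min_length_um: float = 10.0
    split_angle_deg: float = 45.0
    ec_dilate_px: int = 3


# 8-connected neighbor offsets
_NBRS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _skeleton_paths(skel: np.ndarray) -> list[list[tuple[int, int]]]:
    """Decompose a skeleton into simple paths, splitting at junctions."""
    coords = {tuple(rc) for rc in np.argwhere(skel)}
    degree = {
        rc: sum((rc[0] + dr, rc[1] + dc) in coords for dr, dc in _NBRS) for rc in coords
    }
    junctions = {rc for rc, d in degree.items() if d >= 3}
    simple = coords - junctions
    visited: set[tuple[int, int]] = set()
    paths: list[list[tuple[int, int]]] = []

    def neighbors(rc):
        return [
            (rc[0] + dr, rc[1] + dc)
            for dr, dc in _NBRS
            if (rc[0] + dr, rc[1] + dc) in simple
        ]

    # deterministic order: sorted endpoints first, then remaining (loops)
    endpoints = sorted(
        rc for rc in simple if sum(n in simple for n in neighbors(rc)) <= 1
    )
    seeds = endpoints + sorted(simple)
    for seed in seeds:
        if seed in visited:
            continue
        path = [seed]
        visited.add(seed)
        while True:
            nxt = [n for n in neighbors(path[-1]) if n not in visited]
            if not nxt:
                break
            nxt.sort()
            path.append(nxt[0])
            visited.add(nxt[0])
        if len(path) >= 2:
            paths.append(path)
    return paths


def _split_at_kinks(path: np.ndarray, angle_deg: float, step: int = 4) -> list[np.ndarray]:
    """Split a polyline where local direction turns by more than angle_deg."""
    if path.shape[0] <= 2 * step:
        return [path]
    pieces, start = [], 0
    for i in range(step, path.shape[0] - step):
        a = tls_orientation(path[i - step : i + 1])
        b = tls_orientation(path[i : i + step + 1])
        diff = abs(a - b)
        diff = min(diff, 180.0 - diff)
        if diff > angle_deg and i - start >= step:
            pieces.append(path[start : i + 1])
            start = i
    pieces.append(path[start:])
    return pieces


def extract_fibers(
    zmap: np.ndarray,
    pixel_size_um: float,
    ec_mask: np.ndarray | None = None,
    params: FiberTraceParams | None = None,
) -> list[Fiber]:
    """Trace fiber centerlines in a (Z-normalized) phase map.

    EC pixels (dilated by ``ec_dilate_px``) are replaced by the stromal
    median before ridge enhancement so cell edges do not seed fibers.
    Returns fibers longer than ``min_length_um``, deterministically
    ordered; an empty stromal region yields an empty list.
    """
    p = params or FiberTraceParams()
    img = np.asarray(zmap, dtype=float).copy()
    stromal = np.ones_like(img, dtype=bool)
    if ec_mask is not None:
        grown = binary_dilation(ec_mask.astype(bool), iterations=p.ec_dilate_px)
        stromal = ~grown
        if not stromal.any():
            return []
        img[grown] = np.median(img[stromal])

    ridge = sato(img, sigmas=p.ridge_sigmas, black_ridges=False)
    ridge[~stromal] = 0.0
    vals = ridge[stromal]
    peak = float(vals.max())
    if peak <= 0:
        return []
    scale = 1.4826 * float(np.median(np.abs(vals - np.median(vals))))
    low = max(p.low_k * scale, p.low_frac * peak)
    high = max(p.high_k * scale, p.high_frac * peak)
    mask = apply_hysteresis_threshold(ridge, low, high)
    mask &= stromal
    if not mask.any():
        return []
    skel = skeletonize(mask)

    min_len_px = p.min_length_um / pixel_size_um
    fibers: list[Fiber] = []
    fid = 0
    for path in _skeleton_paths(skel):
        arr = np.array([(c, r) for r, c in path], dtype=float)  # (x, y)
        for piece in _split_at_kinks(arr, p.split_angle_deg):
            seg = np.diff(piece, axis=0)
            if np.hypot(seg[:, 0], seg[:, 1]).sum() < min_len_px:
                continue
            fibers.append(Fiber(fiber_id=fid, centerline=piece, pixel_size_um=pixel_size_um))
            fid += 1
    return fibers


# ---------------------------------------------------------------------------
# per-fiber features


def _boundary_rings(boundaries: list[ECBoundary]) -> list[LinearRing]:
    return [LinearRing(ec.polygon) for ec in boundaries]


def fold_angle(angle_deg: float) -> float:
    """Fold an axial angle difference into the acute range [0, 90] deg."""
    a = abs(angle_deg) % 180.0
    return min(a, 180.0 - a)


def relative_angle(
    fiber: Fiber,
    boundaries: list[ECBoundary],
    max_dist_um: float,
    tangent_delta_px: float = 2.0,
) -> float | None:
    """Relative angle theta between a fiber and the nearest EC edge tangent.

    The boundary point nearest to the fiber's nearest endpoint defines the
    local tangent; theta is the acute angle between the orientation of the
    fiber's end segment there and that tangent, folded into [0, 90] deg.
    Fibers with no boundary within ``max_dist_um`` are excluded (None).
    """
    if not boundaries:
        return None
    rings = _boundary_rings(boundaries)
    ends = [Point(*fiber.centerline[0]), Point(*fiber.centerline[-1])]
    best = None
    for end_idx, pt in enumerate(ends):
        for ring in rings:
            d = ring.distance(pt)
            if best is None or d < best[0]:
                best = (d, end_idx, ring, pt)
    dist_um = best[0] * fiber.pixel_size_um
    if dist_um > max_dist_um:
        return None
    _, end_idx, ring, pt = best
    s = ring.project(pt)
    p0 = ring.interpolate((s - tangent_delta_px) % ring.length)
    p1 = ring.interpolate((s + tangent_delta_px) % ring.length)
    tangent = np.degrees(np.arctan2(-(p1.y - p0.y), p1.x - p0.x)) % 180.0
    fiber_angle = fiber.end_orientation_deg(end_idx)
    return fold_angle(fiber_angle - tangent)


def boundary_distance(fiber: Fiber, boundaries: list[ECBoundary]) -> float | None:
    """Minimum distance (um) from any fiber vertex to any EC boundary."""
    if not boundaries:
        return None
    pts = shapely.points(fiber.centerline)
    d = min(shapely.distance(pts, ring).min() for ring in _boundary_rings(boundaries))
    return float(d * fiber.pixel_size_um)


def nearest_alignment(
    fibers: list[Fiber],
    index: int,
    neighborhood_sizes: tuple[int, ...] = (2, 4, 8, 16),
) -> float | None:
    """Mean nearest alignment epsilon of fiber ``index``.

    For each neighborhood size m (those with m <= n-1 available), the m
    nearest fibers by centroid distance (ties broken by fiber id) are
    pooled with the fiber itself and the axial circular resultant length
    ``|mean exp(2i * orientation)|`` is computed; epsilon is the mean over
    the available sizes.  Undefined (None) for fields of fewer than 3
    fibers.
    """
    n = len(fibers)
    if n < 3:
        return None
    me = fibers[index]
    others = [f for f in fibers if f is not me]
    dists = [(float(np.hypot(*(f.centroid - me.centroid))), f.fiber_id, f) for f in others]
    dists.sort(key=lambda t: (t[0], t[1]))
    sizes = [m for m in neighborhood_sizes if m <= n - 1]
    if not sizes:
        return None
    vals = []
    for m in sizes:
        group = [me] + [t[2] for t in dists[:m]]
        phasors = np.exp(2j * np.deg2rad([f.orientation_deg for f in group]))
        vals.append(float(np.abs(phasors.mean())))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# core-level TACS-3 features and classification


@dataclass
class CoreFeatures:
    """Core-level TACS-3 predictors: mean epsilon, mean l (um), skew theta."""

    mean_epsilon: float
    mean_l_um: float
    skew_theta: float
    n_fibers: int

    def as_array(self) -> np.ndarray:
        return np.array([self.mean_epsilon, self.mean_l_um, self.skew_theta])


def sample_skewness(values: np.ndarray) -> float:
    """Biased moment skewness g1 = m3 / m2^{3/2}; 0 when m2 = 0."""
    v = np.asarray(values, dtype=float)
    m = v.mean()
    m2 = np.mean((v - m) ** 2)
    if m2 == 0:
        return 0.0
    m3 = np.mean((v - m) ** 3)
    return float(m3 / m2**1.5)


def core_tacs_features(
    fibers: list[Fiber],
    boundaries: list[ECBoundary],
    max_dist_um: float = 100.0,
) -> CoreFeatures | None:
    """TACS-3 feature triple for one core; None if < 3 eligible fibers.

    Eligibility: the fiber's nearest-boundary distance l is within
    ``max_dist_um`` of the tumor edge.  epsilon is computed within the
    eligible fiber field.
    """
    eligible, thetas, ls = [], [], []
    for fiber in fibers:
        l_um = boundary_distance(fiber, boundaries)
        if l_um is None or l_um > max_dist_um:
            continue
        theta = relative_angle(fiber, boundaries, max_dist_um=np.inf)
        if theta is None:
            continue
        eligible.append(fiber)
        thetas.append(theta)
        ls.append(l_um)
    if len(eligible) < 3:
        return None
    eps = [nearest_alignment(eligible, i) for i in range(len(eligible))]
    eps = [e for e in eps if e is not None]
    return CoreFeatures(
        mean_epsilon=float(np.mean(eps)),
        mean_l_um=float(np.mean(ls)),
        skew_theta=sample_skewness(np.array(thetas)),
        n_fibers=len(eligible),
    )


def train_tacs_svm(core_features: np.ndarray, labels: np.ndarray) -> Pipeline:
    """Linear SVM on standardized 3-dim core features (decision threshold 0).

    ``labels``: 1 = TACS-3 positive, 0 = negative; both classes required.
    """
    x = np.asarray(core_features, dtype=float)
    y = np.asarray(labels).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("both TACS-3 classes must be present in training data")
    clf = Pipeline(
        [("scale", StandardScaler()), ("svm", SVC(kernel="linear", C=1.0))]
    )
    return clf.fit(x, y)


def classify_cores(clf: Pipeline, core_features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """TACS-3 calls (1 = positive) and decision values for cores."""
    x = np.asarray(core_features, dtype=float)
    decision = clf.decision_function(x)
    return (decision > 0).astype(int), decision
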