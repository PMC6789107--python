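"""Epithelial-compartment diagnostic features and classification.

Each epithelial compartment (EC) — a gland-like group of epithelial cells
bounded by stroma — is described by three feature families computed on the
stain-independent Z map:

* ``<C>``  median boundary curvature (1/um): the magnitude of the rate of
  change of the tangent along the EC perimeter;
* ``<l_s>`` median scattering mean free path (um): from the
  scattering-phase relation ``l_s = t / var(phi)`` with the variance taken
  in a local sliding window;
* ``<T>``  elementwise median texton-frequency vector: local histograms of
  texton (filter-bank k-means centroid) assignments.

The concatenated vector ``[<C>, <l_s>, <T>_1..k]`` (length 2 + k; 32 for
the default 30-texton dictionary) feeds a two-class LDA classifier
evaluated by pooled 3-fold cross-validated ROC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon
from sklearn.cluster import KMeans
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

LABELS = ("benign", "malignant")


@dataclass
class ECBoundary:
    """Closed EC boundary polygon with its diagnosis label.

    ``polygon`` holds (x, y) = (col, row) pixel coordinates, ordered
    counterclockwise, not repeating the first vertex.
    """

    polygon: np.ndarray
    ec_id: int
    label: str = "benign"
    _mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2:
            raise ValueError("polygon must be an (n, 2) array of (x, y) vertices")
        if self.polygon.shape[0] < 8:
            raise ValueError("polygon must have >= 8 vertices")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")
        if _signed_area(self.polygon) < 0:  # enforce CCW orientation
            self.polygon = self.polygon[::-1]

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        if self._mask is None or self._mask.shape != shape:
            rr, cc = draw_polygon(self.polygon[:, 1], self.polygon[:, 0], shape)
            m = np.zeros(shape, dtype=bool)
            m[rr, cc] = True
            self._mask = m
        return self._mask


def _signed_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


# ---------------------------------------------------------------------------
# boundary curvature


def boundary_curvature(
    ec: ECBoundary, pixel_size_um: float, smoothing_px: float = 5.0
) -> tuple[np.ndarray, float]:
    """Per-vertex |curvature| (1/um) along the EC perimeter and its median.

    The perimeter is resampled at 1 px arc-length spacing, smoothed with a
    periodic Gaussian (sd ``smoothing_px``), and the curvature
    ``kappa = (x'y'' - y'x'') / (x'^2 + y'^2)^{3/2}`` is evaluated with
    periodic central differences.
    """
    poly = ec.polygon
    seg = np.diff(np.vstack([poly, poly[:1]]), axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    perimeter = float(seg_len.sum())
    if perimeter <= 0:
        raise ValueError("degenerate zero-length polygon")
    n = max(int(round(perimeter)), 16)  # ~1 px spacing
    s_nodes = np.concatenate([[0.0], np.cumsum(seg_len)])
    closed = np.vstack([poly, poly[:1]])
    s = np.linspace(0.0, perimeter, n, endpoint=False)
    x = np.interp(s, s_nodes, closed[:, 0])
    y = np.interp(s, s_nodes, closed[:, 1])
    if smoothing_px > 0:
        x = ndimage.gaussian_filter1d(x, smoothing_px, mode="wrap")
        y = ndimage.gaussian_filter1d(y, smoothing_px, mode="wrap")
    ds = perimeter / n
    xp = (np.roll(x, -1) - np.roll(x, 1)) / (2 * ds)
    yp = (np.roll(y, -1) - np.roll(y, 1)) / (2 * ds)
    xpp = (np.roll(x, -1) - 2 * x + np.roll(x, 1)) / ds**2
    ypp = (np.roll(y, -1) - 2 * y + np.roll(y, 1)) / ds**2
    speed2 = xp * xp + yp * yp
    kappa_px = np.abs(xp * ypp - yp * xpp) / np.maximum(speed2, 1e-12) ** 1.5
    kappa_um = kappa_px / pixel_size_um
    return kappa_um, float(np.median(kappa_um))


# ---------------------------------------------------------------------------
# scattering length

#: documented ceiling for l_s where the local variance vanishes (um)
LS_CAP_UM = 1e6


def scattering_length_map(
    phase: np.ndarray,
    thickness_um: float,
    window_px: int = 15,
    cap_um: float = LS_CAP_UM,
) -> np.ndarray:
    """Scattering mean free path map ``l_s = t / var_w(phi)`` (um).

    ``var_w`` is the local (population) variance of the phase in a sliding
    ``window_px`` square; where it vanishes the value is capped at
    ``cap_um`` (no scattering).  Adding a constant to the phase leaves the
    map unchanged; doubling ``t`` doubles it.
    """
    phase = np.asarray(phase, dtype=float)
    if thickness_um <= 0:
        raise ValueError("thickness must be > 0")
    if window_px < 1 or window_px % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window_px > min(phase.shape):
        raise ValueError("window larger than image")
    m1 = ndimage.uniform_filter(phase, window_px, mode="reflect")
    m2 = ndimage.uniform_filter(phase * phase, window_px, mode="reflect")
    var = np.maximum(m2 - m1 * m1, 0.0)
    var_floor = thickness_um / cap_um
    out = np.full(phase.shape, cap_um, dtype=float)
    scattering = var > var_floor
    out[scattering] = thickness_um / var[scattering]
    return out


def ec_median(feature_map: np.ndarray, ec_mask: np.ndarray) -> float:
    """Median of a per-pixel feature map over an EC mask."""
    if not np.any(ec_mask):
        raise ValueError("empty EC mask")
    return float(np.median(feature_map[ec_mask]))


# ---------------------------------------------------------------------------
# texton texture


def filter_bank() -> list[np.ndarray]:
    """Fixed 18-filter multiscale bank in pixel units.

    Gaussians and Laplacian-of-Gaussian at scales sigma = 1, 2, 4 px, and
    first/second directional Gaussian derivatives paired at orientations
    {0, 45, 90, 135} deg at scales sigma = 1.5 and 3 px (elongation 3:1),
    for 3 + 3 + 2*4 + 4 = 18 filters.  All filters are zero-mean except
    the Gaussians (unit-sum), and L1-normalized.
    """
    kernels: list[np.ndarray] = []

    def _grid(sigma: float) -> tuple[np.ndarray, np.ndarray]:
        r = int(np.ceil(3.5 * sigma))
        y, x = np.mgrid[-r : r + 1, -r : r + 1].astype(float)
        return x, y

    for sigma in (1.0, 2.0, 4.0):
        x, y = _grid(sigma)
        g = np.exp(-(x * x + y * y) / (2 * sigma**2))
        kernels.append(g / g.sum())
    for sigma in (1.0, 2.0, 4.0):
        x, y = _grid(sigma)
        r2 = x * x + y * y
        log = (r2 - 2 * sigma**2) * np.exp(-r2 / (2 * sigma**2))
        log -= log.mean()
        kernels.append(log / np.abs(log).sum())
    for order, sigmas in ((1, (1.5, 3.0)), (2, (1.5,))):
        for sigma in sigmas:
            for theta in np.deg2rad((0.0, 45.0, 90.0, 135.0)):
                x, y = _grid(3 * sigma)
                u = x * np.cos(theta) + y * np.sin(theta)
                v = -x * np.sin(theta) + y * np.cos(theta)
                env = np.exp(-(u * u) / (2 * sigma**2) - (v * v) / (2 * (3 * sigma) ** 2))
                if order == 1:
                    k = -u / sigma**2 * env
                else:
                    k = (u * u - sigma**2) / sigma**4 * env
                k -= k.mean()
                kernels.append(k / np.abs(k).sum())
    assert len(kernels) == 18
    return kernels


def filter_responses(
    image: np.ndarray,
    kernels: list[np.ndarray] | None = None,
    rectify: bool = True,
) -> np.ndarray:
    """Stack of filter responses, shape ``(n_filters, ny, nx)``.

    Responses are rectified (absolute value) by default so texton
    clustering is invariant to contrast polarity and to the local phase
    of oscillatory patterns — a texture reads as one cluster, not two.
    """
    image = np.asarray(image, dtype=float)
    kernels = kernels if kernels is not None else filter_bank()
    resp = np.stack([ndimage.convolve(image, k, mode="reflect") for k in kernels])
    return np.abs(resp) if rectify else resp


@dataclass
class TextonDictionary:
    """k texton centroids in (standardized) filter-response space."""

    centroids: np.ndarray
    response_mean: np.ndarray
    response_sd: np.ndarray
    seed: int = 0
    bank: str = "multiscale-18 (gauss/LoG/deriv-pairs)"

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def assign(self, image: np.ndarray) -> np.ndarray:
        """Per-pixel nearest-texton label map."""
        resp = filter_responses(image)
        flat = resp.reshape(resp.shape[0], -1).T
        flat = (flat - self.response_mean) / self.response_sd
        # chunked nearest-centroid search keeps memory bounded
        labels = np.empty(flat.shape[0], dtype=np.int32)
        c2 = np.sum(self.centroids**2, axis=1)
        for start in range(0, flat.shape[0], 65536):
            block = flat[start : start + 65536]
            d2 = c2[None, :] - 2.0 * block @ self.centroids.T
            labels[start : start + 65536] = np.argmin(d2, axis=1)
        return labels.reshape(resp.shape[1:])


def build_texton_dictionary(
    images: list[np.ndarray],
    k: int = 30,
    seed: int = 0,
    samples_per_image: int = 4000,
) -> TextonDictionary:
    """Learn a texton dictionary by k-means on sampled filter responses.

    Responses are standardized (per filter, over the training sample)
    before clustering; the scaling is stored and re-applied at
    assignment time.  k-means uses 10 restarts with a fixed seed, keeping
    the best inertia, so the dictionary is deterministic.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    samples = []
    for img in images:
        resp = filter_responses(img)
        flat = resp.reshape(resp.shape[0], -1).T
        n_take = min(samples_per_image, flat.shape[0])
        idx = rng.choice(flat.shape[0], size=n_take, replace=False)
        samples.append(flat[idx])
    data = np.concatenate(samples, axis=0)
    if data.shape[0] < k:
        raise ValueError(f"fewer samples ({data.shape[0]}) than textons ({k})")
    mean = data.mean(axis=0)
    sd = data.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    data = (data - mean) / sd
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(data)
    return TextonDictionary(
        centroids=km.cluster_centers_, response_mean=mean, response_sd=sd, seed=seed
    )


def texture_vector(
    image: np.ndarray,
    dictionary: TextonDictionary,
    window_px: int = 25,
    ec_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Per-pixel texton-frequency maps and (optionally) the per-EC median.

    ``T(x, y)`` is the normalized histogram of texton labels within a
    ``window_px`` square around each pixel (entries >= 0, summing to 1);
    ``<T>`` is the elementwise median over EC pixels, whose entries sum to
    at most 1 (order-statistic bound) and are kept un-renormalized.
    """
    labels = dictionary.assign(image)
    t_maps = np.empty((dictionary.k,) + labels.shape, dtype=float)
    for j in range(dictionary.k):
        t_maps[j] = ndimage.uniform_filter(
            (labels == j).astype(float), window_px, mode="reflect"
        )
    np.clip(t_maps, 0.0, 1.0, out=t_maps)  # guard float dust from the filter
    if ec_mask is None:
        return t_maps, None
    if not np.any(ec_mask):
        raise ValueError("empty EC mask")
    t_med = np.median(t_maps[:, ec_mask], axis=1)
    return t_maps, t_med


# ---------------------------------------------------------------------------
# feature assembly and classification


def ec_feature_vector(
    curvature: float, scattering_length: float, texture: np.ndarray, k: int | None = None
) -> np.ndarray:
    """Concatenate ``[<C>, <l_s>, <T>_1..k]`` into one EC feature vector."""
    if curvature is None or scattering_length is None:
        raise ValueError("curvature and scattering length are both required")
    texture = np.asarray(texture, dtype=float).ravel()
    if k is not None and texture.size != k:
        raise ValueError(f"texture vector length {texture.size} != dictionary size {k}")
    vec = np.concatenate([[curvature, scattering_length], texture])
    if not np.all(np.isfinite(vec)):
        raise ValueError("feature vector contains non-finite entries")
    return vec


class LDAClassifier:
    """Two-class linear discriminant with ridge-regularized pooled covariance.

    Features are standardized with training-set mean/sd; the pooled
    within-class covariance gets a relative ridge (default 1e-6 of the
    mean variance), which also absorbs exactly collinear (duplicated)
    columns.  ``score`` returns the posterior probability of the positive
    class via the logistic of the linear discriminant.
    """

    def __init__(self, ridge: float = 1e-6):
        self.ridge = ridge

    def fit(self, x: np.ndarray, y: np.ndarray) -> "LDAClassifier":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y).astype(int)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("both classes must be present")
        self.mean_ = x.mean(axis=0)
        sd = x.std(axis=0)
        self.sd_ = np.where(sd > 0, sd, 1.0)
        xs = (x - self.mean_) / self.sd_
        x0, x1 = xs[y == classes[0]], xs[y == classes[1]]
        mu0, mu1 = x0.mean(axis=0), x1.mean(axis=0)
        n, p = xs.shape
        sw = ((x0 - mu0).T @ (x0 - mu0) + (x1 - mu1).T @ (x1 - mu1)) / max(n - 2, 1)
        lam = self.ridge * max(np.trace(sw) / p, 1e-300)
        if np.linalg.matrix_rank(sw) < p:
            warnings.warn("singular pooled covariance; ridge regularization applied",
                          stacklevel=2)
        sw = sw + lam * np.eye(p)
        self.w_ = np.linalg.solve(sw, mu1 - mu0)
        prior = np.log(x1.shape[0] / x0.shape[0])
        self.b_ = -0.5 * float(self.w_ @ (mu0 + mu1)) + prior
        self.classes_ = classes
        return self

    def decision(self, x: np.ndarray) -> np.ndarray:
        xs = (np.asarray(x, dtype=float) - self.mean_) / self.sd_
        return xs @ self.w_ + self.b_

    def score(self, x: np.ndarray) -> np.ndarray:
        """Posterior probability of the positive (second) class, in [0, 1]."""
        d = np.clip(self.decision(x), -500, 500)
        return 1.0 / (1.0 + np.exp(-d))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.where(self.decision(x) > 0, self.classes_[1], self.classes_[0])


def train_lda(vectors: np.ndarray, labels: np.ndarray, ridge: float = 1e-6) -> LDAClassifier:
    """Train the two-class LDA on EC feature vectors (labels: 0/1)."""
    return LDAClassifier(ridge=ridge).fit(vectors, labels)


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray


def crossvalidate_roc(
    vectors: np.ndarray, labels: np.ndarray, folds: int = 3, seed: int = 0
) -> ROCResult:
    """Pooled cross-validated ROC.

    The data are stratified into ``folds`` partitions; each fold is scored
    by an LDA trained on the others (standardization learned on the
    training folds only); the held-out likelihood scores from all folds
    are pooled into a single ROC with trapezoidal AUC.  Every EC is scored
    exactly once.
    """
    x = np.asarray(vectors, dtype=float)
    y = np.asarray(labels).astype(int)
    counts = np.bincount(y)
    if counts.size != 2 or np.any(counts[:2] < folds):
        raise ValueError("each class needs at least one member per fold")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.empty(y.size, dtype=float)
    for train_idx, test_idx in skf.split(x, y):
        if np.unique(y[train_idx]).size < 2:
            raise ValueError("a fold lacks a class after stratification")
        clf = train_lda(x[train_idx], y[train_idx])
        scores[test_idx] = clf.score(x[test_idx])
    fpr, tpr, thr = roc_curve(y, scores)
    return ROCResult(
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        auc=float(_trapezoid_auc(fpr, tpr)),
        pooled_scores=scores,
        pooled_labels=y,
    )
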