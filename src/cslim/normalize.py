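"""Stain-independent Z maps: tissue segmentation and standard-normal phase.

Staining reduces both the phase values and the image contrast of a
quantitative phase map.  Because the stain acts (to first order) as an
affine transform of the phase, the per-tissue standard normal variable

    Z(x, y) = (phi(x, y) - mu) / sigma,

with mu and sigma the spatial mean and standard deviation over the tissue
region only (background pixels removed), is invariant to it: Z(a*phi + b)
= Z(phi) exactly for a > 0.  Agreement between stained and unstained maps
is quantified by the Pearson correlation of their histograms on shared
bin edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from skimage.filters import threshold_otsu
from skimage.morphology import disk


@dataclass
class ZMap:
    """Standard-normal phase map with the tissue mask it was computed on.

    Over the mask, ``mean(z) = 0`` and ``sd(z) = 1`` to 1e-9; background
    pixels carry Z values too but are flagged by the mask and excluded
    from statistics downstream.
    """

    z: np.ndarray
    mu: float
    sigma: float
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.z.shape != self.mask.shape:
            raise ValueError("z and mask shapes differ")

    def masked_values(self) -> np.ndarray:
        return self.z[self.mask]


def segment_background(phase: np.ndarray, opening_radius: int = 2) -> np.ndarray:
    """Segment tissue from background on a phase map.

    Otsu threshold on |phi| (two-sided: tissue is the higher-|phi| mode
    regardless of contrast sign), followed by morphological opening
    (disk radius 2 px) and hole filling.  A unimodal/degenerate image
    yields a full mask with a warning.  Deterministic.
    """
    phase = np.asarray(phase, dtype=float)
    mag = np.abs(phase)
    if np.ptp(mag) <= 1e-12:
        warnings.warn("image appears unimodal; returning full mask", stacklevel=2)
        return np.ones_like(mag, dtype=bool)
    thresh = threshold_otsu(mag)
    mask = mag > thresh
    if not mask.any() or mask.all():
        warnings.warn("threshold failed to split modes; returning full mask", stacklevel=2)
        return np.ones_like(mag, dtype=bool)
    mask = ndimage.binary_opening(mask, structure=disk(opening_radius))
    mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        warnings.warn("opening removed all tissue; returning full mask", stacklevel=2)
        return np.ones_like(mag, dtype=bool)
    return mask


def z_normalize(phase: np.ndarray, mask: np.ndarray) -> ZMap:
    """Standard-normal transform of a phase map over a tissue mask.

    ``mu`` and ``sigma`` (population sd) are computed over masked pixels
    only; the transform is applied to all pixels, with the mask carried
    along.  Raises for masks with fewer than 2 pixels or constant tissue
    (sigma = 0).
    """
    phase = np.asarray(phase, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != phase.shape:
        raise ValueError("mask shape must equal phase shape")
    vals = phase[mask]
    if vals.size < 2:
        raise ValueError("mask must contain at least 2 pixels")
    mu = float(vals.mean())
    sigma = float(vals.std())
    if sigma == 0:
        raise ValueError("degenerate constant tissue: sigma = 0")
    return ZMap(z=(phase - mu) / sigma, mu=mu, sigma=sigma, mask=mask)


def histogram_correlation(
    values_a: np.ndarray, values_b: np.ndarray, n_bins: int = 256
) -> float:
    """Pearson correlation between two histograms on shared bin edges.

    Bin edges span the union of both value ranges; counts are
    density-normalized (cosmetic: Pearson rho is scale-invariant).
    """
    if n_bins < 8:
        raise ValueError("n_bins must be >= 8")
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("empty masked value set")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi == lo:
        hi = lo + 1e-12
    edges = np.linspace(lo, hi, n_bins + 1)
    ha, _ = np.histogram(a, bins=edges, density=True)
    hb, _ = np.histogram(b, bins=edges, density=True)
    rho = stats.pearsonr(ha, hb).statistic
    return float(np.clip(rho, -1.0, 1.0))
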