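"""Equivalent source spectrum, temporal autocorrelation, and coherence.

Interferometry with an RGB camera behaves like interferometry with three
independent sources: the complex fields of the channels do not interfere
with one another but their temporal autocorrelations add.  The equivalent
detected spectrum is

    S_c(omega) = S_i(omega) * [S_R(omega) + S_G(omega) + S_B(omega)],

with S_i the illumination and S_R/G/B the channel spectral responses
(already including the channel weights).  Its Fourier transform is the
temporal autocorrelation Gamma(tau), plotted against distance d = c*tau;
the carrier of Gamma gives the detected central wavelength and the FWHM of
its envelope defines the coherence length.

All Fourier work is done on a uniform angular-frequency grid; inputs
tabulated in wavelength are converted with the |d omega/d lambda|
Jacobian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

#: speed of light in air, in nm/s (n_air ~ 1 at this precision)
C_NM_PER_S = 2.99792458e17
C_UM_PER_S = C_NM_PER_S * 1e-3

#: default Fourier grid: 2**14 samples, support padded 4x
N_GRID = 2**14
PAD_FACTOR = 4.0


@dataclass
class Spectrum:
    """Spectral power density tabulated on a wavelength grid (nm)."""

    wavelength_nm: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.wavelength_nm.ndim != 1 or self.wavelength_nm.shape != self.power.shape:
            raise ValueError("wavelength and power must be equal-length 1-d arrays")
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(self.power < 0) or not np.all(np.isfinite(self.power)):
            raise ValueError("spectral power must be finite and nonnegative")

    def omega(self) -> np.ndarray:
        """Angular frequencies (rad/s), increasing order."""
        return (2 * np.pi * C_NM_PER_S / self.wavelength_nm)[::-1]

    def power_omega(self) -> np.ndarray:
        """Density on the omega grid: S(omega) = S(lambda) * lambda^2 / (2 pi c)."""
        lam = self.wavelength_nm
        return (self.power * lam**2 / (2 * np.pi * C_NM_PER_S))[::-1]

    def sample(self, wavelength_nm: np.ndarray) -> np.ndarray:
        """Interpolate power onto another wavelength grid (0 outside support)."""
        return np.interp(wavelength_nm, self.wavelength_nm, self.power, left=0.0, right=0.0)

    def centroid_nm(self) -> float:
        w = np.trapezoid(self.power, self.wavelength_nm)
        if w <= 0:
            raise ValueError("empty spectrum")
        return float(np.trapezoid(self.wavelength_nm * self.power, self.wavelength_nm) / w)


def gaussian_spectrum(
    center_nm: float, fwhm_nm: float, n: int = 801, span_sigmas: float = 6.0
) -> Spectrum:
    """Gaussian line centered at ``center_nm`` with the given FWHM (nm)."""
    sigma = fwhm_nm / (2 * np.sqrt(2 * np.log(2)))
    lam = np.linspace(center_nm - span_sigmas * sigma, center_nm + span_sigmas * sigma, n)
    lam = lam[lam > 0]
    return Spectrum(lam, np.exp(-0.5 * ((lam - center_nm) / sigma) ** 2))


@dataclass
class CorrelationFunction:
    """Temporal autocorrelation against distance ``d = c*tau`` (um).

    Hermitian by construction for a real spectrum: Gamma(-d) = Gamma(d)*.
    """

    d_um: np.ndarray
    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.d_um = np.asarray(self.d_um, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=complex)
        if self.d_um.shape != self.gamma.shape or self.d_um.ndim != 1:
            raise ValueError("d grid and gamma must be equal-length 1-d arrays")

    @property
    def gamma0(self) -> float:
        """Zero-delay value Gamma(0) (= integral of the spectrum)."""
        i0 = int(np.argmin(np.abs(self.d_um)))
        return float(np.real(self.gamma[i0]))

    def envelope(self) -> np.ndarray:
        """Analytic-signal envelope of Re Gamma (matches the plotted real part)."""
        return np.abs(hilbert(np.real(self.gamma)))


def equivalent_spectrum(
    s_illum: Spectrum,
    s_r: Spectrum,
    s_g: Spectrum,
    s_b: Spectrum,
    weights: tuple[float, float, float] | None = None,
) -> Spectrum:
    """Equivalent detected spectrum S_i * (S_R + S_G + S_B).

    The channel responses are assumed to already include the channel
    weights; pass ``weights`` to apply them here instead.
    """
    lam = s_illum.wavelength_nm
    w = (1.0, 1.0, 1.0) if weights is None else weights
    resp = (
        w[0] * s_r.sample(lam) + w[1] * s_g.sample(lam) + w[2] * s_b.sample(lam)
    )
    power = s_illum.power * resp
    if not np.any(power > 0):
        warnings.warn(
            "illumination and channel responses have disjoint support; "
            "equivalent spectrum is zero",
            stacklevel=2,
        )
    return Spectrum(lam, power)


def autocorrelation(
    spectrum: Spectrum, n: int = N_GRID, pad_factor: float = PAD_FACTOR
) -> CorrelationFunction:
    """Temporal autocorrelation Gamma(tau) = integral S(omega) e^{-i omega tau} d omega.

    The spectrum is resampled onto a uniform omega grid reaching
    ``pad_factor`` times its upper support (zero-padded), so the delay
    sampling resolves the optical carrier; autocorrelations of channel
    spectra add linearly.
    """
    omega = spectrum.omega()
    s_omega = spectrum.power_omega()
    if not np.any(s_omega > 0):
        raise ValueError("empty spectrum")
    # grid extent follows the tabulated grid (not the nonzero support) so
    # spectra sharing a wavelength grid share a delay grid and their
    # autocorrelations add pointwise
    omega_max = omega.max() * pad_factor
    grid = np.linspace(0.0, omega_max, n, endpoint=False)
    s_grid = np.interp(grid, omega, s_omega, left=0.0, right=0.0)
    d_omega = grid[1] - grid[0]

    # DFT: Gamma(tau_m) = d_omega * sum_n S(omega_n) exp(-i omega_n tau_m),
    # tau_m = 2 pi m / (n * d_omega), for m = -n/2 .. n/2 - 1.
    x = np.fft.fft(s_grid) * d_omega
    x = np.fft.fftshift(x)
    m = np.arange(-n // 2, n // 2)
    tau = 2 * np.pi * m / (n * d_omega)
    return CorrelationFunction(d_um=tau * C_UM_PER_S, gamma=x)


def central_wavelength(corr: CorrelationFunction) -> float:
    """Detected central wavelength (nm) from the carrier of Gamma near d = 0.

    Estimated as the envelope-weighted mean phase advance per delay step
    over the half-maximum region of the envelope around zero delay
    (robust to coarse sampling as long as the carrier is not aliased).
    """
    env = np.abs(corr.gamma)
    i0 = int(np.argmin(np.abs(corr.d_um)))
    half = env[i0] / 2.0
    # contiguous half-max region around d = 0
    lo = i0
    while lo > 0 and env[lo - 1] >= half:
        lo -= 1
    hi = i0
    while hi < env.size - 1 and env[hi + 1] >= half:
        hi += 1
    if hi - lo < 3:
        raise ValueError("envelope too narrow to fit a carrier slope")
    g = corr.gamma[lo : hi + 1]
    dd = np.diff(corr.d_um[lo : hi + 1])
    dphase = np.angle(g[1:] * np.conj(g[:-1]))
    wgt = np.abs(g[1:] * g[:-1])
    slope = float(np.sum(wgt * dphase / dd) / np.sum(wgt))  # rad per um
    if slope == 0:
        raise ValueError("no carrier detected")
    lam_um = 2 * np.pi / abs(slope)
    n_osc = (corr.d_um[hi] - corr.d_um[lo]) / lam_um
    if n_osc < 3:
        raise ValueError(
            f"envelope too narrow to fit a carrier slope ({n_osc:.1f} oscillations)"
        )
    return lam_um * 1e3


def coherence_length(corr: CorrelationFunction, use_real_part: bool = True) -> float:
    """Coherence length (um): FWHM of the autocorrelation envelope.

    The envelope is the analytic-signal envelope of Re Gamma (the plotted
    real part) by default, or |Gamma| with ``use_real_part=False``; the
    half-maximum crossings are located by linear interpolation.
    """
    env = corr.envelope() if use_real_part else np.abs(corr.gamma)
    d = corr.d_um
    i_max = int(np.argmax(env))
    half = env[i_max] / 2.0

    def _crossing(idx_range: np.ndarray) -> float:
        for j in idx_range:
            if env[j] < half:
                j0, j1 = (j, j + 1) if j < i_max else (j - 1, j)
                # linear interpolation between the straddling samples
                e0, e1 = env[j0], env[j1]
                if e1 == e0:
                    return d[j]
                t = (half - e0) / (e1 - e0)
                return d[j0] + t * (d[j1] - d[j0])
        raise ValueError("envelope never falls below half maximum within the grid")

    left = _crossing(np.arange(i_max, -1, -1))
    right = _crossing(np.arange(i_max, env.size))
    return float(right - left)
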