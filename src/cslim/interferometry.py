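"""Phase reconstruction from 4-frame RGB phase-shifting acquisitions.

An acquisition holds 12 intensity frames: three camera channels (R, G, B)
at four controlled phase shifts ``phi_k in {0, pi/2, pi, 3*pi/2}`` between
the scattered and incident light.  The channels are combined linearly,

    I(x, y; phi) = r*R + g*G + b*B,        r + g + b = 1,

and the quantitative phase is recovered from the four grayscale frames by
the two-beam interference inversion with a bright-field attenuation factor
``alpha`` (the incident beam is ``alpha`` times weaker than it would be
relative to the scattered beam in an unmodified system; the default 3.4 is
the calibrated bright-field equivalent).

Frame-order contract (enforced at I/O): channel-major R, G, B; shift-minor
0, pi/2, pi, 3*pi/2.  The two-beam model rendered and inverted here is

    I_k = A^2 + B^2 + 2*A*B*cos(dphi + phi_k),

with A the detected incident amplitude, B the scattered amplitude and
``dphi`` their phase difference, so that

    dphi = atan2(I(3pi/2) - I(pi/2), I(0) - I(pi)),
    phi  = arg[1 + (beta/alpha) * exp(i*dphi)],   beta = B/A  (<= 1 branch).

No phase unwrapping is performed: thin sections keep ``|phi| < pi``;
out-of-range pixels are counted, not unwrapped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

SHIFTS = (0.0, np.pi / 2, np.pi, 3 * np.pi / 2)
CHANNELS = ("R", "G", "B")

#: calibrated bright-field attenuation factor
DEFAULT_ALPHA = 3.4


@dataclass
class ChannelWeights:
    """Weights of the equivalent grayscale channel combination."""

    r: float = 0.1
    g: float = 0.6
    b: float = 0.3

    def __post_init__(self) -> None:
        if min(self.r, self.g, self.b) < 0:
            raise ValueError("channel weights must be nonnegative")
        if abs(self.r + self.g + self.b - 1.0) > 1e-12:
            raise ValueError("channel weights must sum to 1 within 1e-12")

    def as_array(self) -> np.ndarray:
        return np.array([self.r, self.g, self.b], dtype=float)


@dataclass
class RawAcquisition:
    """12-frame intensity stack: ``frames[channel, shift, y, x]``.

    Channel order R, G, B; shift order 0, pi/2, pi, 3*pi/2.
    """

    frames: np.ndarray
    pixel_size_um: float = 0.5

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 4 or self.frames.shape[:2] != (3, 4):
            raise ValueError(
                "frames must have shape (3 channels, 4 shifts, ny, nx); "
                f"got {self.frames.shape}"
            )
        if np.any(self.frames < 0):
            raise ValueError("intensities must be >= 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[2:]


@dataclass
class PhaseMap:
    """Reconstructed quantitative phase map (radians)."""

    phi: np.ndarray
    lambda_c_nm: float = 558.0
    pixel_size_um: float = 0.5
    thickness_um: float = 5.0
    alpha: float = DEFAULT_ALPHA
    #: pixels where the beta quadratic had no real root in [0, 1]
    n_beta_clamped: int = 0
    #: pixels with |phi| >= pi (reported, never unwrapped)
    n_out_of_range: int = 0

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi)
        if not np.all(np.isfinite(self.phi)):
            raise ValueError("phase map must be finite everywhere")


def combine_channels(
    acq: RawAcquisition, weights: ChannelWeights | None = None
) -> np.ndarray:
    """Combine R, G, B frames into 4 equivalent grayscale frames.

    Returns an array of shape ``(4, ny, nx)``, one frame per phase shift.
    """
    w = (weights or ChannelWeights()).as_array()
    return np.einsum("c,cs...->s...", w, acq.frames)


def quadrature_phase(frames: np.ndarray) -> np.ndarray:
    """Interferometric phase difference ``dphi = atan2(I3 - I1, I0 - I2)``.

    ``frames`` are the 4 grayscale frames in shift order 0, pi/2, pi,
    3*pi/2.  Exposed separately so the frame-order convention is testable.
    """
    frames = _check_four_frames(frames)
    i0, i1, i2, i3 = (frames[k].astype(float) for k in range(4))
    return np.arctan2(i3 - i1, i0 - i2)


def _check_four_frames(frames: np.ndarray) -> np.ndarray:
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] != 4:
        raise ValueError(f"expected 4 frames of identical shape, got {frames.shape}")
    return frames


def reconstruct_phase(
    frames: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    pixel_size_um: float = 0.5,
    lambda_c_nm: float = 558.0,
    thickness_um: float = 5.0,
) -> PhaseMap:
    """Reconstruct the sample phase from 4 grayscale phase-shifted frames.

    Per pixel, the two-beam amplitudes are solved from

        S = A^2 + B^2 = (I0 + I2) / 2,
        P = A*B      = hypot(I3 - I1, I0 - I2) / 4,

    taking the ``beta = B/A <= 1`` branch (smaller root of the amplitude
    quadratic); the sample phase is ``arg[1 + (beta/alpha)*exp(i*dphi)]``.
    Pixels where the discriminant ``S^2 - 4P^2`` is negative (possible
    under noise) are clamped to the nearest valid root (beta = 1) and
    counted in :attr:`PhaseMap.n_beta_clamped`.

    The result is invariant to a global (or per-pixel, across shifts)
    rescaling of the frames, and ``|phi|`` decreases monotonically with
    increasing ``alpha``.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    frames = _check_four_frames(frames)
    i0, i1, i2, i3 = (frames[k] for k in range(4))

    dphi = np.arctan2(i3 - i1, i0 - i2)
    s = (i0 + i2) / 2.0
    p = np.hypot(i3 - i1, i0 - i2) / 4.0

    disc = s * s - 4.0 * p * p
    n_clamped = int(np.count_nonzero(disc < 0))
    disc = np.maximum(disc, 0.0)
    root = np.sqrt(disc)
    a2 = (s + root) / 2.0
    b2 = (s - root) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.sqrt(np.where(a2 > 0, b2 / np.where(a2 > 0, a2, 1.0), 0.0))
    beta = np.clip(np.nan_to_num(beta, nan=0.0), 0.0, 1.0)

    field_rel = 1.0 + (beta / alpha) * np.exp(1j * dphi)
    phi = np.angle(field_rel)
    n_oor = int(np.count_nonzero(np.abs(phi) >= np.pi))
    return PhaseMap(
        phi=phi.astype(np.float32),
        lambda_c_nm=lambda_c_nm,
        pixel_size_um=pixel_size_um,
        thickness_um=thickness_um,
        alpha=alpha,
        n_beta_clamped=n_clamped,
        n_out_of_range=n_oor,
    )


def extract_brightfield(acq: RawAcquisition) -> np.ndarray:
    """Color bright-field image: the (R, G, B) frames at shift 0.

    Returns a ``(ny, nx, 3)`` float array on the same pixel grid as the
    phase map (co-registered by construction; no resampling).
    """
    return np.moveaxis(acq.frames[:, 0, :, :], 0, -1)


@dataclass
class CalibrationCurve:
    """SLM control-level -> imparted-phase calibration.

    ``phase(level)`` is the unwrapped argument of the analytic signal of
    the mean-removed amplitude-modulation curve, referenced to the first
    calibrated level and oriented so phase increases with level.
    """

    levels: np.ndarray
    phase_rad: np.ndarray
    shift_levels: dict[float, float] = field(default_factory=dict)

    def phase_at(self, level: np.ndarray | float) -> np.ndarray | float:
        return np.interp(level, self.levels, self.phase_rad)


def calibrate_slm(levels: np.ndarray, amplitude: np.ndarray) -> CalibrationCurve:
    """Calibrate SLM phase from an amplitude-modulation curve.

    Parameters
    ----------
    levels : array
        8-bit control levels, covering the full 0-255 range.
    amplitude : array
        Measured intensity modulation at each level.

    Returns the calibration curve together with the four control levels
    realizing phase increments {0, pi/2, pi, 3*pi/2} relative to the first
    level.  Raises if the curve spans less than one full oscillation
    (cannot cover 2*pi) or is degenerate (constant).
    """
    levels = np.asarray(levels, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if levels.shape != amplitude.shape or levels.ndim != 1 or levels.size < 8:
        raise ValueError("levels and amplitude must be equal-length 1-d arrays")
    if levels.min() > 0 or levels.max() < 255:
        raise ValueError("calibration curve must be sampled on the full 0-255 range")
    x = amplitude - amplitude.mean()
    if np.ptp(amplitude) <= 1e-12 * max(1.0, abs(amplitude.mean())):
        raise ValueError("degenerate (constant) amplitude modulation curve")
    analytic = hilbert(x)
    phase = np.unwrap(np.angle(analytic))
    phase = phase - phase[0]
    if phase[-1] < 0:  # orient the calibrated branch to increase with level
        phase = -phase
    # one sample of slack: a full oscillation sampled on N points spans
    # 2*pi*(N-1)/N of unwrapped phase
    if phase[-1] - phase.min() < 2 * np.pi * (1 - 2.0 / levels.size):
        raise ValueError(
            "amplitude curve spans less than one full oscillation; "
            "cannot realize a 2*pi phase range"
        )
    # monotone envelope for inversion (guards small local non-monotonicity)
    mono = np.maximum.accumulate(phase)
    shift_levels = {
        float(s): float(np.interp(s, mono, levels)) for s in SHIFTS
    }
    return CalibrationCurve(levels=levels, phase_rad=phase, shift_levels=shift_levels)


def render_two_beam_frames(
    phi: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    intensity_scale: np.ndarray | float = 1.0,
) -> np.ndarray:
    """Render noiseless 4-frame two-beam interferograms from a phase map.

    Forward model inverted by :func:`reconstruct_phase`: the sample field
    is ``U = exp(i*phi)`` with incident (unscattered) reference ``U_i = 1``
    and scattered part ``U_s = U - 1``; the detected incident amplitude is
    attenuated by ``alpha``.  ``intensity_scale`` multiplies all four
    frames (per pixel or globally), e.g. for channel power and stain
    absorbance.

    Exact inversion holds on the ``beta <= 1`` branch, i.e. for
    ``|phi| <= 2*asin(1/(2*alpha))`` (about 0.295 rad at alpha = 3.4).
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    phi = np.asarray(phi, dtype=float)
    u_s = np.exp(1j * phi) - 1.0
    a = 1.0 / alpha
    b = np.abs(u_s)
    dphi = np.angle(u_s)
    frames = np.empty((4,) + phi.shape, dtype=float)
    for k, shift in enumerate(SHIFTS):
        frames[k] = a * a + b * b + 2 * a * b * np.cos(dphi + shift)
    return frames * np.asarray(intensity_scale, dtype=float)


def clip_negative_intensities(frames: np.ndarray) -> tuple[np.ndarray, int]:
    """Clip negative (noise-driven) intensities at 0; report the count."""
    n_neg = int(np.count_nonzero(frames < 0))
    if n_neg:
        warnings.warn(f"clipped {n_neg} negative intensity values at 0", stacklevel=2)
    return np.maximum(frames, 0.0), n_neg
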