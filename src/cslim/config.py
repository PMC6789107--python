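"""Run configuration shared by all pipeline stages.

Every stage reads its physical and algorithmic parameters from a single
:class:`RunConfig`; defaults are the instrument/analysis settings used
throughout the package (channel weights 0.1/0.6/0.3, attenuation 3.4,
30 textons, 63/100 um fiber eligibility distances, 5 um sections).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class RunConfig:
    """Parameter set for a cSLIM processing run.

    Attributes
    ----------
    pixel_size_um : float
        Lateral sampling of the camera, micrometres per pixel.  The
        instrument calibration is a required input and never inferred
        from image content.
    thickness_um : float
        Histology section thickness ``t`` (um); enters the phase model
        ``phi = 2*pi*(n - n0)*t/lambda`` and the scattering length map.
    channel_weights : tuple of float
        ``(r, g, b)`` weights of the equivalent grayscale combination;
        must sum to 1.
    alpha : float
        Bright-field attenuation factor ``alpha_bf`` applied to the
        incident beam relative to the scattered beam at reconstruction.
    n_textons : int
        Texton dictionary size ``k``; the EC feature vector has length
        ``2 + k``.
    texton_window_px, ls_window_px : int
        Sliding-window sizes (odd, pixels) for the texton-frequency map
        and the local phase variance of the scattering length map.
    curvature_smoothing_px : float
        Gaussian sd (pixels of arc length) for periodic boundary
        smoothing before curvature estimation.
    fiber_max_dist_um : float
        Eligibility distance from the EC/tumor edge for fiber features
        (63 um for near-EC angle analysis, 100 um for TACS-3).
    seed : int
        Master seed; all stage randomness derives from it.
    out_dir : Path
        Output directory for pipeline artifacts.
    """

    pixel_size_um: float = 0.5
    thickness_um: float = 5.0
    channel_weights: tuple[float, float, float] = (0.1, 0.6, 0.3)
    alpha: float = 3.4
    n_textons: int = 30
    texton_window_px: int = 25
    ls_window_px: int = 15
    curvature_smoothing_px: float = 5.0
    fiber_max_dist_um: float = 100.0
    seed: int = 0
    out_dir: Path = field(default_factory=lambda: Path("cslim_out"))

    def __post_init__(self) -> None:
        for name in ("pixel_size_um", "thickness_um", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        w = self.channel_weights
        if len(w) != 3 or any(x < 0 for x in w):
            raise ValueError("channel_weights must be 3 nonnegative numbers")
        if abs(sum(w) - 1.0) > 1e-12:
            raise ValueError("channel weights must sum to 1 (within 1e-12)")
        if self.n_textons < 2:
            raise ValueError("n_textons must be >= 2")
        for name in ("texton_window_px", "ls_window_px"):
            v = getattr(self, name)
            if v < 1 or v % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 1")
        self.out_dir = Path(self.out_dir)

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(d["out_dir"])
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        d["channel_weights"] = tuple(d.get("channel_weights", (0.1, 0.6, 0.3)))
        return cls(**d)
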