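"""Shared containers for the QPI pipeline.

The central raster type is :class:`PhaseImage`, an unwrapped phase map in
radians on a calibrated pixel grid.  Earlier pipeline stages use
:class:`InterferogramFrame` (raw off-axis intensity) and :class:`WrappedPhase`
(phase known modulo 2*pi, confined to (-pi, pi]).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

TWO_PI = 2.0 * np.pi

#: Default acquisition wavelength of the HeNe probe beam (nm).
DEFAULT_WAVELENGTH_NM = 633.0
#: Default lateral sampling on the object plane (um / pixel).
DEFAULT_PIXEL_PITCH_UM = 0.35


def wrap_phase(x: np.ndarray | float) -> np.ndarray | float:
    """Wrap phase values to the half-open interval (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(x, dtype=float), TWO_PI)


@dataclass(frozen=True)
class OpticalConstants:
    """Optical constants used to convert phase into physical quantities.

    Parameters
    ----------
    wavelength_nm:
        Recording light wavelength in nanometres.
    n_cell:
        Assumed (constant) intracellular refractive index.
    n_medium:
        Refractive index of the culture medium.
    alpha_ml_per_g:
        Specific refraction increment used for the dry-mass conversion,
        in mL/g (equivalently um^3/pg).
    """

    wavelength_nm: float = DEFAULT_WAVELENGTH_NM
    n_cell: float = 1.380
    n_medium: float = 1.337
    alpha_ml_per_g: float = 0.19

    def __post_init__(self) -> None:
        if not self.wavelength_nm > 0:
            raise ValueError("wavelength_nm must be positive")
        if not (self.n_cell > self.n_medium > 1.0):
            raise ValueError("require n_cell > n_medium > 1")
        if not self.alpha_ml_per_g > 0:
            raise ValueError("alpha_ml_per_g must be positive")

    @property
    def wavelength_um(self) -> float:
        return self.wavelength_nm * 1e-3

    @property
    def delta_n(self) -> float:
        """Refractive-index contrast n_cell - n_medium."""
        return self.n_cell - self.n_medium


@dataclass
class CarrierSpec:
    """Off-axis carrier: spatial frequency (cycles/pixel), visibility, bias."""

    fx: float
    fy: float
    modulation_depth: float = 0.8
    background_level: float = 1000.0

    def __post_init__(self) -> None:
        f = float(np.hypot(self.fx, self.fy))
        if not (0.0 < f < 0.5):
            raise ValueError(
                f"carrier magnitude {f:.3f} cycles/px must lie in (0, 0.5) (Nyquist)"
            )
        # m = 0 is allowed as a degenerate carrier (no fringes), useful for
        # null tests of carrier detection
        if not (0.0 <= self.modulation_depth <= 1.0):
            raise ValueError("modulation_depth must lie in [0, 1]")

    @property
    def magnitude(self) -> float:
        return float(np.hypot(self.fx, self.fy))


@dataclass
class InterferogramFrame:
    """Raw off-axis intensity image plus acquisition metadata."""

    intensity: np.ndarray
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM
    wavelength_nm: float = DEFAULT_WAVELENGTH_NM
    carrier_hint: Optional[CarrierSpec] = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2 or min(self.intensity.shape) < 32:
            raise ValueError("interferogram must be 2D and at least 32x32")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("interferogram intensity must be finite")
        if np.any(self.intensity < 0):
            raise ValueError("interferogram intensity must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape


@dataclass
class WrappedPhase:
    """Phase map wrapped to (-pi, pi], with an optional fit-quality map."""

    phase: np.ndarray
    quality: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if self.phase.ndim != 2:
            raise ValueError("wrapped phase must be 2D")
        if np.any(self.phase <= -np.pi - 1e-12) or np.any(self.phase > np.pi + 1e-12):
            raise ValueError("wrapped phase values must lie in (-pi, pi]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.phase.shape


@dataclass
class PhaseImage:
    """Unwrapped phase map (radians) on a calibrated pixel grid.

    ``valid_mask`` marks pixels reached by the unwrapping integration; it is
    ``None`` for images that are valid everywhere (e.g. synthetic forward
    projections).
    """

    phase: np.ndarray
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM
    wavelength_nm: float = DEFAULT_WAVELENGTH_NM
    valid_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if self.phase.ndim != 2:
            raise ValueError("phase image must be 2D")
        if not self.pixel_pitch_um > 0:
            raise ValueError("pixel_pitch_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.phase.shape

    def valid(self) -> np.ndarray:
        if self.valid_mask is None:
            return np.ones(self.phase.shape, dtype=bool)
        return self.valid_mask
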