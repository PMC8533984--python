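"""Per-cell optical feature vectors.

The 10-parameter quantitative-phase feature vector for one segmented cell:

1.  ``phi_av``       mean phase shift over the cell (rad)
2.  ``v_phase``      phase volume, sum(phi)*pitch^2 (rad um^2) — proportional
                     to dry mass
3.  ``s_pr``         projected area (um^2)
4.  ``s_top_surf``   top phase-surface area (um^2), attachment area excluded
5.  ``s_membr``      phase membrane area = s_top_surf + s_pr (um^2)
6.  ``psi``          phase sphericity index, pi^(1/3)*(6V)^(2/3)/S (sphere -> 1)
7.  ``var_phi``      variance of in-cell phase (rad^2)
8.  ``kurtosis_phi`` Pearson kurtosis of in-cell phase (normal -> 3)
9.  ``skewness_phi`` skewness of in-cell phase
10. ``eccentricity`` equivalent-ellipse eccentricity of the binary mask

Surface quantities are computed after converting phase to optical path
difference z = phi*lambda/(2*pi) (um), so lateral and axial axes share
units; the sphericity therefore uses the OPD volume (um^3) and the OPD
membrane area (um^2).  The top surface is the graph area of z over the mask
(per-pixel sqrt(1 + |grad z|^2) quadrature with finite differences
restricted to in-mask neighbours); the rim skirt down to z = 0 is excluded.

The 7-parameter bright-field baseline (:func:`amplitude_features`) uses only
the binary mask: projected area, Crofton perimeter, circularity
(4*pi*S/P^2), eccentricity, solidity, and equivalent-ellipse axes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats
from skimage.measure import regionprops

from .datatypes import TWO_PI, OpticalConstants, PhaseImage

FEATURE_NAMES = (
    "phi_av", "v_phase", "s_pr", "s_top_surf", "s_membr",
    "psi", "var_phi", "kurtosis_phi", "skewness_phi", "eccentricity",
)

AMPLITUDE_FEATURE_NAMES = (
    "s_pr", "p_pr", "circularity", "eccentricity", "solidity",
    "minor_axis_um", "major_axis_um",
)

_MIN_MASK_PIXELS = 8


class DegenerateMaskError(ValueError):
    """Mask too small or too thin for stable feature extraction."""


@dataclass
class QPIFeatures:
    phi_av: float
    v_phase: float
    s_pr: float
    s_top_surf: float
    s_membr: float
    psi: float
    var_phi: float
    kurtosis_phi: float
    skewness_phi: float
    eccentricity: float
    opd_volume_um3: float
    degenerate_moments: bool = False

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


@dataclass
class AmplitudeFeatures:
    s_pr: float
    p_pr: float
    circularity: float
    eccentricity: float
    solidity: float
    minor_axis_um: float
    major_axis_um: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in AMPLITUDE_FEATURE_NAMES}


def sphericity(volume: float, surface_area: float) -> float:
    """psi = pi^(1/3) * (6 V)^(2/3) / S; equals 1 for a sphere."""
    if volume <= 0 or surface_area <= 0:
        return 0.0
    return float(np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / surface_area)


def surface_area_graph(z: np.ndarray, mask: np.ndarray, pitch_um: float) -> float:
    """Graph area of the surface z(x, y) over the mask (um^2).

    Per-pixel quadrature sum of sqrt(1 + gx^2 + gy^2) * pitch^2, with
    gradients estimated by central differences restricted to in-mask
    neighbours (one-sided at the support boundary, zero where the pixel has
    no in-mask neighbour along an axis).  The rim skirt down to z = 0 is
    excluded, so a flat pancake of area A has top surface exactly A.
    """
    z = np.where(mask, z, 0.0)

    def _axis_gradient(axis: int) -> np.ndarray:
        zp = np.roll(z, -1, axis=axis)
        zm = np.roll(z, 1, axis=axis)
        mp = np.roll(mask, -1, axis=axis)
        mm = np.roll(mask, 1, axis=axis)
        # roll wraps around; edge rows/cols have no neighbour on that side
        if axis == 0:
            mp = mp.copy(); mp[-1, :] = False
            mm = mm.copy(); mm[0, :] = False
        else:
            mp = mp.copy(); mp[:, -1] = False
            mm = mm.copy(); mm[:, 0] = False
        zp = np.where(mp, zp, z)
        zm = np.where(mm, zm, z)
        span = mp.astype(int) + mm.astype(int)
        return np.where(span > 0, (zp - zm) / (np.maximum(span, 1) * pitch_um), 0.0)

    gy = _axis_gradient(0)
    gx = _axis_gradient(1)
    integrand = np.sqrt(1.0 + gx**2 + gy**2)
    return float(np.sum(integrand[mask])) * pitch_um**2


def _mask_eccentricity(mask: np.ndarray) -> float:
    prop = regionprops(mask.astype(np.uint8))[0]
    return float(prop.eccentricity)


def qpi_features(
    phase: PhaseImage,
    cell_mask: np.ndarray,
    constants: OpticalConstants,
) -> QPIFeatures:
    """Compute the 10-parameter phase feature vector for one cell."""
    mask = np.asarray(cell_mask, dtype=bool)
    if mask.shape != phase.shape:
        raise ValueError("mask shape does not match phase image")
    n_px = int(mask.sum())
    if n_px < _MIN_MASK_PIXELS:
        raise DegenerateMaskError(
            f"mask has {n_px} pixels; need >= {_MIN_MASK_PIXELS} for stable moments"
        )
    vals = phase.phase[mask]
    if not np.all(np.isfinite(vals)):
        raise ValueError("phase is not finite on the cell mask")

    pitch = phase.pixel_pitch_um
    pitch2 = pitch**2
    phi_av = float(vals.mean())
    var_phi = float(vals.var())
    degenerate = var_phi < 1e-12
    if degenerate:
        kurt = skew = 0.0
    else:
        kurt = float(stats.kurtosis(vals, fisher=False))
        skew = float(stats.skew(vals))

    s_pr = n_px * pitch2
    v_phase = float(vals.sum()) * pitch2

    z = phase.phase * (constants.wavelength_um / TWO_PI)  # OPD in um
    s_top = surface_area_graph(z, mask, pitch)
    s_membr = s_top + s_pr
    opd_volume = float(z[mask].sum()) * pitch2
    psi = sphericity(opd_volume, s_membr)

    return QPIFeatures(
        phi_av=phi_av,
        v_phase=v_phase,
        s_pr=s_pr,
        s_top_surf=s_top,
        s_membr=s_membr,
        psi=psi,
        var_phi=var_phi,
        kurtosis_phi=kurt,
        skewness_phi=skew,
        eccentricity=_mask_eccentricity(mask),
        opd_volume_um3=opd_volume,
        degenerate_moments=degenerate,
    )


def amplitude_features(cell_mask: np.ndarray, pitch_um: float) -> AmplitudeFeatures:
    """Bright-field baseline features computed from the binary mask alone."""
    mask = np.asarray(cell_mask, dtype=bool)
    n_px = int(mask.sum())
    if n_px < _MIN_MASK_PIXELS:
        raise DegenerateMaskError(f"mask has {n_px} pixels")
    prop = regionprops(mask.astype(np.uint8))[0]
    if prop.axis_minor_length <= 0:
        raise DegenerateMaskError("mask is degenerate (zero minor axis)")
    s_pr = float(prop.area) * pitch_um**2
    p_pr = float(prop.perimeter_crofton) * pitch_um
    return AmplitudeFeatures(
        s_pr=s_pr,
        p_pr=p_pr,
        circularity=4.0 * np.pi * s_pr / p_pr**2,
        eccentricity=float(prop.eccentricity),
        solidity=float(prop.solidity),
        minor_axis_um=float(prop.axis_minor_length) * pitch_um,
        major_axis_um=float(prop.axis_major_length) * pitch_um,
    )


def dry_mass(
    phase: PhaseImage, cell_mask: np.ndarray, constants: OpticalConstants
) -> float:
    """Cell dry mass in picograms: DM = lambda / (2*pi*alpha) * sum(phi)*pitch^2.

    With lambda in um and alpha in mL/g (= um^3/pg), the OPD integral in um^3
    divided by alpha gives picograms directly.
    """
    mask = np.asarray(cell_mask, dtype=bool)
    vals = phase.phase[mask]
    opd_integral = float(vals.sum()) * phase.pixel_pitch_um**2 * (
        constants.wavelength_um / TWO_PI
    )
    return opd_integral / constants.alpha_ml_per_g


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def feature_table(
    items: Iterable,
    constants: Optional[OpticalConstants] = None,
    use_phantom_mask: bool = True,
) -> pd.DataFrame:
    """QPI feature table for a labeled phantom dataset (one row per cell).

    ``items`` are :class:`~qpicell.phantoms.DatasetItem`.  By default the
    phantom ground-truth mask delimits each cell (segmentation is exercised
    separately); pass ``use_phantom_mask=False`` to run the segmenter and use
    its largest region instead.
    """
    from .segmentation import segment_cells

    if constants is None:
        constants = OpticalConstants()
    rows = []
    for item in items:
        if use_phantom_mask:
            mask = item.phantom.mask
        else:
            seg = segment_cells(item.phase)
            if len(seg) == 0:
                continue
            biggest = max(seg.cells, key=lambda c: c.area_um2)
            mask = seg.mask_for(biggest.label)
        feats = qpi_features(item.phase, mask, constants)
        row = feats.as_dict()
        row["dm_pg"] = dry_mass(item.phase, mask, constants)
        row["line_label"] = item.line
        row["state_label"] = item.state
        row["cell_id"] = item.cell_id
        rows.append(row)
    return pd.DataFrame(rows)


def amplitude_feature_table(items: Iterable) -> pd.DataFrame:
    """Bright-field baseline feature table for a labeled phantom dataset."""
    rows = []
    for item in items:
        feats = amplitude_features(item.phantom.mask, item.phantom.pixel_pitch_um)
        row = feats.as_dict()
        row["line_label"] = item.line
        row["state_label"] = item.state
        row["cell_id"] = item.cell_id
        rows.append(row)
    return pd.DataFrame(rows)
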