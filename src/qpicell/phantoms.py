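"""Synthetic cell phantoms and forward models.

Every downstream stage of the pipeline (demodulation, unwrapping,
segmentation, feature extraction, morphology, classification) is exercised
against phantoms generated here, because the generator knows the ground
truth: the exact height map, volume, mean height and surface area of each
cell, and its (line, state) labels.

Three morphological archetypes are emulated, mirroring how adherent cells
look in quantitative phase images:

* ``live`` — a smooth, spread dome: large projected area, moderate height;
* ``apoptotic`` — a compact rounded cap decorated with small hemispherical
  blebs: small area, large height, reduced sphericity;
* ``necrotic`` — a broad, low, irregular profile: large area, low height,
  high in-cell phase variance.

Cell lines (HeLa, A549, 3T3) modulate overall scale, height and elongation;
3T3 fibroblasts are markedly elongated, A549 are the largest of the three.

Geometry is a rotated superellipse support with a power-law cap profile,
plus Gaussian blebs and a band-limited multiplicative roughness field.  The
height function is analytic, so phantoms can be evaluated at any resolution:
pixel values are area-averaged over a supersampled grid (emulating camera
pixel integration) and ground-truth morphology is integrated on the fine
grid, independently of the feature-extraction module.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .datatypes import (
    TWO_PI,
    CarrierSpec,
    InterferogramFrame,
    OpticalConstants,
    PhaseImage,
    wrap_phase,
)

LINES = ("HeLa", "A549", "3T3")
STATES = ("live", "apoptotic", "necrotic")

#: Archetype shape parameters per cell state.  Lengths in um.
STATE_ARCHETYPES: dict[str, dict] = {
    "live": dict(
        radius_um=14.0, radius_cv=0.12,
        height_um=3.2, height_cv=0.12,
        profile_q=0.45, aspect=1.25,
        n_blebs=0, irregularity=0.04,
    ),
    "apoptotic": dict(
        radius_um=7.5, radius_cv=0.12,
        height_um=6.5, height_cv=0.12,
        profile_q=0.55, aspect=1.05,
        n_blebs=6, bleb_radius_um=1.4, bleb_height_um=1.6,
        irregularity=0.05,
    ),
    "necrotic": dict(
        radius_um=17.0, radius_cv=0.12,
        height_um=2.4, height_cv=0.15,
        profile_q=0.25, aspect=1.30,
        n_blebs=0, irregularity=0.35,
    ),
}

#: Per-line modifiers applied on top of the state archetype.
LINE_MODIFIERS: dict[str, dict] = {
    "HeLa": dict(scale=1.00, height_scale=1.00, aspect_mult=1.0),
    "A549": dict(scale=1.45, height_scale=1.20, aspect_mult=1.0),
    "3T3": dict(scale=0.85, height_scale=0.80, aspect_mult=1.7),
}

#: Default off-axis carrier: well separated from DC, resolvable by a 12x12
#: demodulation window.
DEFAULT_CARRIER = dict(fx=0.2, fy=0.1, modulation_depth=0.8, background_level=1000.0)

_MASK_THRESHOLD_FRACTION = 0.10  # support cut at 10% of peak height
_SUPERSAMPLE = 3


@dataclass
class PhantomCell:
    """A synthetic cell with ground-truth morphology.

    ``height_map`` is physical height in um on the pixel grid, zero outside
    ``mask``; the ``true_*`` fields are integrated from the generating
    geometry on a supersampled grid.
    """

    height_map: np.ndarray
    mask: np.ndarray
    true_volume: float            # um^3
    true_mean_height: float       # um
    true_surface_area: float      # um^2, top surface + base
    class_line: Optional[str]
    class_state: Optional[str]
    pixel_pitch_um: float
    shape_params: dict = field(default_factory=dict, repr=False)

    @property
    def projected_area_um2(self) -> float:
        return float(self.mask.sum()) * self.pixel_pitch_um**2


@dataclass
class SyntheticDatasetSpec:
    """Conditions under which a labeled phantom dataset is generated."""

    n_cells_per_class: int = 50
    lines: Sequence[str] = LINES
    states: Sequence[str] = STATES
    pixel_pitch_um: float = 0.35
    speckle_sigma_rad: float = 0.08
    speckle_corr_px: float = 2.0
    seed: int = 0
    class_parameter_table: Optional[dict] = None  # overrides STATE_ARCHETYPES

    def __post_init__(self) -> None:
        if self.n_cells_per_class < 1:
            raise ValueError("n_cells_per_class must be >= 1")
        if self.pixel_pitch_um <= 0 or self.speckle_sigma_rad < 0:
            raise ValueError("invalid dataset spec")


@dataclass
class DatasetItem:
    """One labeled cell: its phase image, phantom ground truth and labels."""

    phase: PhaseImage
    phantom: PhantomCell
    line: str
    state: str
    cell_id: str


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def draw_shape_params(
    line: str,
    state: str,
    rng: np.random.Generator,
    parameter_table: Optional[dict] = None,
) -> dict:
    """Draw concrete shape parameters for one cell of the given class."""
    _check_labels(line, state)
    table = parameter_table if parameter_table is not None else STATE_ARCHETYPES
    arch = table[state]
    mod = LINE_MODIFIERS[line]

    scale = mod["scale"] * _truncated_normal(rng, 1.0, arch["radius_cv"])
    aspect = arch["aspect"] * mod["aspect_mult"] * _truncated_normal(rng, 1.0, 0.08)
    radius = arch["radius_um"] * scale
    a_um = radius * np.sqrt(aspect)
    b_um = radius / np.sqrt(aspect)
    h0_um = arch["height_um"] * mod["height_scale"] * _truncated_normal(
        rng, 1.0, arch["height_cv"]
    )
    params = dict(
        a_um=float(a_um),
        b_um=float(b_um),
        h0_um=float(h0_um),
        theta=float(rng.uniform(0.0, np.pi)),
        p=float(rng.uniform(2.0, 2.6)),
        q=float(arch["profile_q"] * _truncated_normal(rng, 1.0, 0.08)),
        blebs=[],
        irregularity=float(arch.get("irregularity", 0.0) * _truncated_normal(rng, 1.0, 0.2)),
        irr_components=[],
    )

    n_blebs = int(arch.get("n_blebs", 0))
    if n_blebs > 0:
        n = max(2, int(rng.poisson(n_blebs)))
        for _ in range(n):
            rho = rng.uniform(0.45, 0.85)
            ang = rng.uniform(0.0, TWO_PI)
            # bleb centre inside the support, in the cell's own frame
            bx = rho * a_um * np.cos(ang)
            by = rho * b_um * np.sin(ang)
            sigma = arch["bleb_radius_um"] * _truncated_normal(rng, 1.0, 0.15)
            amp = arch["bleb_height_um"] * _truncated_normal(rng, 1.0, 0.20)
            params["blebs"].append((float(bx), float(by), float(sigma), float(amp)))

    if params["irregularity"] > 0:
        comps = []
        for _ in range(16):
            wavelength = rng.uniform(5.0, 14.0)  # um
            direction = rng.uniform(0.0, np.pi)
            k = TWO_PI / wavelength
            comps.append(
                (
                    float(k * np.cos(direction)),
                    float(k * np.sin(direction)),
                    float(rng.uniform(0.0, TWO_PI)),
                    float(rng.normal()),
                )
            )
        params["irr_components"] = comps

    return params


def _truncated_normal(rng: np.random.Generator, mean: float, cv: float) -> float:
    return float(np.clip(rng.normal(mean, cv * mean), 0.5 * mean, 1.5 * mean))


def _check_labels(line, state) -> None:
    if line is not None and line not in LINES:
        raise ValueError(f"unknown cell line {line!r}; expected one of {LINES}")
    if state is not None and state not in STATES:
        raise ValueError(f"unknown cell state {state!r}; expected one of {STATES}")


def _height_function(params: dict, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Evaluate the analytic height function (um) at physical coords (um)."""
    ct, st = np.cos(params["theta"]), np.sin(params["theta"])
    u = (X * ct + Y * st) / params["a_um"]
    v = (-X * st + Y * ct) / params["b_um"]
    p = params["p"]
    rho_p = np.abs(u) ** p + np.abs(v) ** p
    inside = rho_p < 1.0
    h = np.zeros_like(X)
    h[inside] = params["h0_um"] * (1.0 - rho_p[inside]) ** params["q"]

    if params["irregularity"] > 0 and params["irr_components"]:
        comps = np.asarray(params["irr_components"])
        weights = comps[:, 3]
        norm = np.sqrt(0.5 * np.sum(weights**2))
        g = np.zeros_like(X)
        for kx, ky, ph, w in comps:
            g += w * np.cos(kx * X + ky * Y + ph)
        g /= max(norm, 1e-12)
        # bounded multiplicative roughness: high in-cell variance without
        # thinning the profile to nothing anywhere
        factor = np.clip(1.0 + params["irregularity"] * g, 0.4, 1.6)
        h = h * factor

    for bx, by, sigma, amp in params["blebs"]:
        h = h + amp * np.exp(-(((X - bx) ** 2 + (Y - by) ** 2) / (2.0 * sigma**2)))
    return h


def _fine_axis(n: int, pitch: float, ss: int) -> np.ndarray:
    j = np.arange(n * ss, dtype=float)
    return ((j + 0.5) / ss - 0.5 - (n - 1) / 2.0) * pitch


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    return labels == keep


def _fine_graph_area(h_fine: np.ndarray, mask_fine: np.ndarray, pitch_fine: float) -> float:
    """Top-surface area by triangle tessellation of the fine grid (um^2)."""
    z = np.where(mask_fine, h_fine, 0.0)
    ok = (
        mask_fine[:-1, :-1] & mask_fine[:-1, 1:] & mask_fine[1:, :-1] & mask_fine[1:, 1:]
    )
    z00, z01 = z[:-1, :-1], z[:-1, 1:]
    z10, z11 = z[1:, :-1], z[1:, 1:]
    d = pitch_fine
    # triangles (z00,z01,z10) and (z11,z10,z01)
    a1 = 0.5 * np.sqrt(d**4 + (d * (z01 - z00)) ** 2 + (d * (z10 - z00)) ** 2)
    a2 = 0.5 * np.sqrt(d**4 + (d * (z10 - z11)) ** 2 + (d * (z01 - z11)) ** 2)
    return float(np.sum((a1 + a2)[ok]))


def _realize_phantom(
    params: dict,
    pixel_pitch_um: float,
    line: Optional[str],
    state: Optional[str],
    grid_shape: Optional[tuple[int, int]] = None,
) -> PhantomCell:
    ss = _SUPERSAMPLE
    if grid_shape is None:
        reach = max(params["a_um"], params["b_um"])
        for bx, by, sigma, _amp in params["blebs"]:
            reach = max(reach, float(np.hypot(bx, by)) + 3.0 * sigma)
        half = 1.25 * reach + 2.0
        n = int(np.ceil(2.0 * half / pixel_pitch_um))
        n = max(96, ((n + 15) // 16) * 16)
        grid_shape = (n, n)

    ny, nx = grid_shape
    xf = _fine_axis(nx, pixel_pitch_um, ss)
    yf = _fine_axis(ny, pixel_pitch_um, ss)
    Xf, Yf = np.meshgrid(xf, yf)
    h_fine = _height_function(params, Xf, Yf)

    h_thresh = _MASK_THRESHOLD_FRACTION * params["h0_um"]
    mask_fine = _largest_component(h_fine > h_thresh)
    h_fine = np.where(mask_fine, h_fine, 0.0)

    height_map = h_fine.reshape(ny, ss, nx, ss).mean(axis=(1, 3))
    mask = _largest_component(height_map > h_thresh)
    height_map = np.where(mask, height_map, 0.0)
    if mask.any() and (
        mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any()
    ):
        raise ValueError("phantom support touches the grid border; enlarge the grid")

    pitch_fine = pixel_pitch_um / ss
    base_area = float(mask_fine.sum()) * pitch_fine**2
    true_volume = float(h_fine.sum()) * pitch_fine**2
    true_mean_height = true_volume / base_area if base_area > 0 else 0.0
    true_surface = _fine_graph_area(h_fine, mask_fine, pitch_fine) + base_area

    return PhantomCell(
        height_map=height_map,
        mask=mask,
        true_volume=true_volume,
        true_mean_height=true_mean_height,
        true_surface_area=true_surface,
        class_line=line,
        class_state=state,
        pixel_pitch_um=pixel_pitch_um,
        shape_params=params,
    )


def make_cell_phantom(
    line: str,
    state: str,
    shape_params: Optional[dict] = None,
    pixel_pitch_um: float = 0.35,
    seed: int = 0,
    parameter_table: Optional[dict] = None,
) -> PhantomCell:
    """Generate one cell phantom of the given (line, state) class.

    ``shape_params`` may be supplied directly (as produced by
    :func:`draw_shape_params`); otherwise parameters are drawn from the class
    distribution using ``seed``.
    """
    if pixel_pitch_um <= 0:
        raise ValueError("pixel_pitch_um must be positive")
    _check_labels(line, state)
    if shape_params is None:
        rng = np.random.default_rng(seed)
        shape_params = draw_shape_params(line, state, rng, parameter_table)
    return _realize_phantom(shape_params, pixel_pitch_um, line, state)


def spherical_cap_phantom(
    radius_um: float = 10.0,
    pixel_pitch_um: float = 0.2,
) -> PhantomCell:
    """Hemisphere phantom (full sphere truncated at the equator).

    Closed forms: volume (2/3)*pi*r^3, mean height 2r/3 over the supporting
    disk, top surface 2*pi*r^2.  Used as the analytic oracle for morphology.
    """
    ss = _SUPERSAMPLE
    n = int(np.ceil(2.0 * (1.2 * radius_um + 2.0) / pixel_pitch_um))
    n = max(96, ((n + 15) // 16) * 16)
    xf = _fine_axis(n, pixel_pitch_um, ss)
    Xf, Yf = np.meshgrid(xf, xf)
    r2 = radius_um**2 - Xf**2 - Yf**2
    h_fine = np.sqrt(np.clip(r2, 0.0, None))
    mask_fine = r2 > 0

    height_map = h_fine.reshape(n, ss, n, ss).mean(axis=(1, 3))
    mask = height_map > 0
    pitch_fine = pixel_pitch_um / ss
    base_area = float(mask_fine.sum()) * pitch_fine**2
    true_volume = float(h_fine.sum()) * pitch_fine**2
    return PhantomCell(
        height_map=np.where(mask, height_map, 0.0),
        mask=mask,
        true_volume=true_volume,
        true_mean_height=true_volume / base_area,
        true_surface_area=2.0 * np.pi * radius_um**2 + np.pi * radius_um**2,
        class_line=None,
        class_state=None,
        pixel_pitch_um=pixel_pitch_um,
        shape_params=dict(kind="hemisphere", radius_um=radius_um, h0_um=radius_um),
    )


def smooth_dome_phantom(
    peak_phase_rad: float,
    sigma_px: float,
    shape: tuple[int, int],
    pixel_pitch_um: float = 0.35,
    wavelength_nm: float = 633.0,
) -> PhaseImage:
    """Smooth Gaussian phase dome — a residue-free test object."""
    ny, nx = shape
    y = np.arange(ny) - (ny - 1) / 2.0
    x = np.arange(nx) - (nx - 1) / 2.0
    X, Y = np.meshgrid(x, y)
    phase = peak_phase_rad * np.exp(-(X**2 + Y**2) / (2.0 * sigma_px**2))
    return PhaseImage(phase, pixel_pitch_um=pixel_pitch_um, wavelength_nm=wavelength_nm)


# ---------------------------------------------------------------------------
# Forward models
# ---------------------------------------------------------------------------

def phantom_to_phase(phantom: PhantomCell, constants: OpticalConstants) -> PhaseImage:
    """Forward-project a phantom: phi = 2*pi*(n_cell - n_medium)*h / lambda."""
    phase = TWO_PI * constants.delta_n * phantom.height_map / constants.wavelength_um
    return PhaseImage(
        phase,
        pixel_pitch_um=phantom.pixel_pitch_um,
        wavelength_nm=constants.wavelength_nm,
    )


def add_speckle(
    phase: PhaseImage,
    sigma_rad: float,
    corr_px: float = 2.0,
    mean_rad: float = 0.0,
    seed: int = 0,
) -> PhaseImage:
    """Add a correlated Gaussian speckle field to a phase image.

    Emulates residual coherent noise after background subtraction:
    zero-mean by default, with correlation length ``corr_px`` pixels.
    """
    if sigma_rad < 0:
        raise ValueError("sigma_rad must be >= 0")
    out = phase.phase.copy()
    if sigma_rad > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(size=phase.shape)
        if corr_px > 0:
            noise = ndimage.gaussian_filter(noise, corr_px)
            noise /= max(noise.std(), 1e-12)
        out = out + sigma_rad * noise
    out = out + mean_rad
    return PhaseImage(
        out, pixel_pitch_um=phase.pixel_pitch_um, wavelength_nm=phase.wavelength_nm,
        valid_mask=phase.valid_mask,
    )


def synthesize_hologram(
    phase: PhaseImage,
    carrier: Optional[CarrierSpec] = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> InterferogramFrame:
    """Record an off-axis interferogram of a phase image.

    I(x, y) = B * [1 + m * cos(2*pi*(fx*x + fy*y) + phi(x, y))] + N(0, sigma),
    clipped to nonnegative counts.  The true carrier is stored in
    ``carrier_hint`` for test use.
    """
    if carrier is None:
        carrier = CarrierSpec(**DEFAULT_CARRIER)
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    ny, nx = phase.shape
    X, Y = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float))
    fringe = np.cos(TWO_PI * (carrier.fx * X + carrier.fy * Y) + phase.phase)
    intensity = carrier.background_level * (1.0 + carrier.modulation_depth * fringe)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sigma, size=intensity.shape)
    intensity = np.clip(intensity, 0.0, None)
    return InterferogramFrame(
        intensity,
        pixel_pitch_um=phase.pixel_pitch_um,
        wavelength_nm=phase.wavelength_nm,
        carrier_hint=carrier,
    )


# ---------------------------------------------------------------------------
# Labeled datasets and treatment series
# ---------------------------------------------------------------------------

def make_labeled_dataset(
    spec: SyntheticDatasetSpec,
    constants: Optional[OpticalConstants] = None,
) -> list[DatasetItem]:
    """Generate a balanced labeled dataset of phase images with ground truth."""
    if constants is None:
        constants = OpticalConstants()
    rng = np.random.default_rng(spec.seed)
    items: list[DatasetItem] = []
    for line in spec.lines:
        for state in spec.states:
            for i in range(spec.n_cells_per_class):
                params = draw_shape_params(line, state, rng, spec.class_parameter_table)
                phantom = _realize_phantom(params, spec.pixel_pitch_um, line, state)
                phase = phantom_to_phase(phantom, constants)
                if spec.speckle_sigma_rad > 0:
                    phase = add_speckle(
                        phase,
                        spec.speckle_sigma_rad,
                        corr_px=spec.speckle_corr_px,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    )
                items.append(
                    DatasetItem(
                        phase=phase,
                        phantom=phantom,
                        line=line,
                        state=state,
                        cell_id=f"{line}_{state}_{i:04d}",
                    )
                )
    return items


def _apportion(n: int, fractions: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of n items into len(fractions) bins."""
    quota = n * np.asarray(fractions, dtype=float)
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    for idx in np.argsort(-remainder)[: n - counts.sum()]:
        counts[idx] += 1
    return counts


@dataclass
class TreatmentSeries:
    """Simulated post-treatment monitoring: frames plus ground-truth mixture."""

    frames: list  # list of (time_min, PhaseImage)
    true_fractions: "object"  # pandas.DataFrame: time_min, frac_live, ...
    dose_mw_cm2: Optional[float] = None


def simulate_treatment_series(
    n_timepoints: int = 13,
    step_min: float = 5.0,
    n_cells_per_frame: int = 16,
    start_mix: Sequence[float] = (1.0, 0.0, 0.0),
    end_mix: Sequence[float] = (0.0, 0.2, 0.8),
    line: str = "HeLa",
    constants: Optional[OpticalConstants] = None,
    pixel_pitch_um: float = 0.35,
    speckle_sigma_rad: float = 0.05,
    dose_mw_cm2: Optional[float] = None,
    seed: int = 0,
) -> TreatmentSeries:
    """Simulate monitoring of one cell sample after photodynamic treatment.

    The (live, apoptotic, necrotic) mixture interpolates linearly from
    ``start_mix`` at t=0 to ``end_mix`` at the last timepoint; per-frame
    state counts follow the mixture deterministically (largest-remainder
    apportionment), so the mixture is exact ground truth for the recovered
    fractions.
    """
    import pandas as pd

    if constants is None:
        constants = OpticalConstants()
    start = np.asarray(start_mix, dtype=float)
    end = np.asarray(end_mix, dtype=float)
    if start.shape != (3,) or end.shape != (3,):
        raise ValueError("mixtures must have 3 components (live, apoptotic, necrotic)")
    start, end = start / start.sum(), end / end.sum()

    rng = np.random.default_rng(seed)
    n_side = int(np.ceil(np.sqrt(n_cells_per_frame)))

    frames = []
    truth_rows = []
    for it in range(n_timepoints):
        t = it * step_min
        w = it / max(n_timepoints - 1, 1)
        mix = (1.0 - w) * start + w * end
        counts = _apportion(n_cells_per_frame, mix)
        states = [s for s, c in zip(STATES, counts) for _ in range(c)]
        rng.shuffle(states)

        phantoms = []
        for state in states:
            params = draw_shape_params(line, state, rng)
            phantoms.append(_realize_phantom(params, pixel_pitch_um, line, state))
        slot = max(max(ph.height_map.shape) for ph in phantoms) + 12
        side = n_side * slot
        canvas = np.zeros((side, side))
        for k, ph in enumerate(phantoms):
            r, c = divmod(k, n_side)
            hy, hx = ph.height_map.shape
            jr = int(rng.integers(-4, 5))
            jc = int(rng.integers(-4, 5))
            r0 = r * slot + (slot - hy) // 2 + jr
            c0 = c * slot + (slot - hx) // 2 + jc
            canvas[r0 : r0 + hy, c0 : c0 + hx] += ph.height_map

        phase = PhaseImage(
            TWO_PI * constants.delta_n * canvas / constants.wavelength_um,
            pixel_pitch_um=pixel_pitch_um,
            wavelength_nm=constants.wavelength_nm,
        )
        if speckle_sigma_rad > 0:
            phase = add_speckle(
                phase, speckle_sigma_rad, seed=int(rng.integers(0, 2**31 - 1))
            )
        frames.append((t, phase))
        truth_rows.append(
            dict(
                time_min=t,
                frac_live=counts[0] / n_cells_per_frame,
                frac_apoptotic=counts[1] / n_cells_per_frame,
                frac_necrotic=counts[2] / n_cells_per_frame,
            )
        )

    return TreatmentSeries(
        frames=frames,
        true_fractions=pd.DataFrame(truth_rows),
        dose_mw_cm2=dose_mw_cm2,
    )
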