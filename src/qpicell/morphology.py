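"""Phase-to-morphology conversion and error analysis.

Under the constant intracellular refractive index assumption the phase map
converts directly to a physical height map,

    h(x, y) = phi * lambda / (2 * pi * (n_cell - n_medium)),

from which average height, volume and membrane surface area follow.  The
error-analysis machinery compares per-cell morphology estimates against a
reference cohort (here: phantom ground truth) and separates the systematic
component (cohort mean of the signed relative error) from the random one
(cohort standard deviation), with Figure-style histograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import TWO_PI, OpticalConstants, PhaseImage
from .features import surface_area_graph

MORPHOLOGY_COLUMNS = ("h_av", "volume", "s_surf")


@dataclass
class HeightMap:
    height: np.ndarray           # um, >= 0 on mask, 0 outside
    mask: np.ndarray
    pitch_um: float
    clip_fraction: float = 0.0   # fraction of in-mask pixels clipped at 0


@dataclass
class MorphologySummary:
    h_av: float        # um
    volume: float      # um^3
    s_surf: float      # um^2, top surface + base

    def as_dict(self) -> dict[str, float]:
        return dict(h_av=self.h_av, volume=self.volume, s_surf=self.s_surf)


@dataclass
class MorphologyErrors:
    """Signed per-cell relative errors (%) and their cohort summary."""

    per_cell: pd.DataFrame                  # columns delta_h_av, delta_v, delta_s_surf
    mean: dict[str, float]                  # systematic component
    std: dict[str, float]                   # random component
    histograms: dict[str, tuple[np.ndarray, np.ndarray]]
    n_skipped: int = 0


def height_map(
    phase: PhaseImage, mask: np.ndarray, constants: OpticalConstants
) -> HeightMap:
    """Convert phase to physical height; negative phase clips to zero."""
    if constants.delta_n <= 0:
        raise ValueError("n_cell must exceed n_medium")
    mask = np.asarray(mask, dtype=bool)
    h = phase.phase * (constants.wavelength_um / (TWO_PI * constants.delta_n))
    h = np.where(mask, h, 0.0)
    n_mask = int(mask.sum())
    clipped = int(np.sum(h[mask] < 0)) / n_mask if n_mask else 0.0
    return HeightMap(
        height=np.clip(h, 0.0, None),
        mask=mask,
        pitch_um=phase.pixel_pitch_um,
        clip_fraction=clipped,
    )


def morphology_summary(hm: HeightMap) -> MorphologySummary:
    """Average height, volume and membrane surface area of one cell."""
    if not hm.mask.any():
        raise ValueError("empty mask")
    pitch2 = hm.pitch_um**2
    s_pr = float(hm.mask.sum()) * pitch2
    volume = float(hm.height[hm.mask].sum()) * pitch2
    s_top = surface_area_graph(hm.height, hm.mask, hm.pitch_um)
    return MorphologySummary(
        h_av=volume / s_pr,
        volume=volume,
        s_surf=s_top + s_pr,
    )


def _to_frame(cohort) -> pd.DataFrame:
    if isinstance(cohort, pd.DataFrame):
        return cohort[list(MORPHOLOGY_COLUMNS)].reset_index(drop=True)
    return pd.DataFrame([m.as_dict() for m in cohort])


def relative_errors(
    estimated,
    reference,
    n_bins: int = 10,
    bin_range_pct: float = 40.0,
) -> MorphologyErrors:
    """Signed per-cell relative errors of estimated vs reference morphology.

    ``estimated`` and ``reference`` are matched cohorts (sequences of
    :class:`MorphologySummary` or DataFrames with columns h_av, volume,
    s_surf).  Cells whose reference value is <= 0 are skipped.
    """
    est = _to_frame(estimated)
    ref = _to_frame(reference)
    if len(est) != len(ref):
        raise ValueError("estimated and reference cohorts must be matched per cell")

    ok = (ref > 0).all(axis=1)
    n_skipped = int((~ok).sum())
    est, ref = est[ok], ref[ok]

    errors = pd.DataFrame(
        {
            "delta_h_av": 100.0 * (est["h_av"] - ref["h_av"]) / ref["h_av"],
            "delta_v": 100.0 * (est["volume"] - ref["volume"]) / ref["volume"],
            "delta_s_surf": 100.0 * (est["s_surf"] - ref["s_surf"]) / ref["s_surf"],
        }
    ).reset_index(drop=True)

    bins = np.linspace(-bin_range_pct, bin_range_pct, n_bins + 1)
    histograms = {
        col: np.histogram(errors[col], bins=bins) for col in errors.columns
    }
    return MorphologyErrors(
        per_cell=errors,
        mean={c: float(errors[c].mean()) for c in errors.columns},
        std={c: float(errors[c].std(ddof=0)) for c in errors.columns},
        histograms=histograms,
        n_skipped=n_skipped,
    )


def phantom_reference_summary(phantom) -> MorphologySummary:
    """Ground-truth morphology of a phantom, as a reference cohort entry."""
    return MorphologySummary(
        h_av=phantom.true_mean_height,
        volume=phantom.true_volume,
        s_surf=phantom.true_surface_area,
    )
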