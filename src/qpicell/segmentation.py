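"""Single-cell segmentation on unwrapped phase images.

Cells stand out from a background-subtracted phase image as regions of
elevated phase, so the default pipeline is: Otsu threshold (with a floor, so
an empty field yields no cells) -> 3x3 morphological opening -> hole filling
-> optional watershed split of touching cells -> size / border / validity
filtering.  scikit-image provides all the primitives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .datatypes import PhaseImage

logger = logging.getLogger(__name__)


@dataclass
class SegmentationConfig:
    threshold_method: str = "otsu"        # "otsu" or "fixed"
    fixed_threshold_rad: float = 0.5
    otsu_floor_rad: float = 0.3           # minimum threshold for "otsu"
    min_area_um2: float = 50.0
    split_touching: bool = False
    exclude_border: bool = True
    fill_holes: bool = True

    def __post_init__(self) -> None:
        if self.min_area_um2 <= 0:
            raise ValueError("min_area_um2 must be positive")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")


@dataclass
class CellRecord:
    label: int
    area_um2: float
    centroid: tuple[float, float]
    touches_border: bool
    contains_invalid_phase: bool


@dataclass
class SegmentationResult:
    labels: np.ndarray
    cells: list[CellRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.cells)

    def mask_for(self, label: int) -> np.ndarray:
        return self.labels == label


def _threshold(phase: np.ndarray, config: SegmentationConfig) -> float:
    if config.threshold_method == "fixed":
        return config.fixed_threshold_rad
    # Otsu over the whole image separates the background mode (phase ~ 0)
    # from the cell mode; the floor keeps an empty field empty
    if np.ptp(phase) < 1e-9:
        return config.otsu_floor_rad
    return max(float(threshold_otsu(phase)), config.otsu_floor_rad)


def segment_cells(phase: PhaseImage, config: Optional[SegmentationConfig] = None) -> SegmentationResult:
    """Segment single cells on a background-subtracted phase image."""
    if config is None:
        config = SegmentationConfig()
    img = phase.phase
    if not np.all(np.isfinite(img)):
        raise ValueError("phase image contains non-finite values")
    pitch2 = phase.pixel_pitch_um**2

    high = _threshold(img, config)
    if config.threshold_method == "otsu" and high > config.otsu_floor_rad:
        # hysteresis: Otsu seeds the cells, which then grow down to the floor;
        # recovers the smooth low-phase shoulder that a plain Otsu cut removes
        from skimage.filters import apply_hysteresis_threshold

        binary = apply_hysteresis_threshold(img, config.otsu_floor_rad, high)
    else:
        binary = img > high
    binary = ndimage.binary_opening(binary, structure=np.ones((3, 3), dtype=bool))
    if config.fill_holes:
        binary = ndimage.binary_fill_holes(binary)

    if config.split_touching and binary.any():
        distance = ndimage.distance_transform_edt(binary)
        min_sep = max(3, int(np.sqrt(config.min_area_um2) / phase.pixel_pitch_um))
        from skimage.feature import peak_local_max

        coords = peak_local_max(
            distance, min_distance=min_sep, labels=binary, exclude_border=False
        )
        markers = np.zeros(binary.shape, dtype=int)
        for k, (r, c) in enumerate(coords, start=1):
            markers[r, c] = k
        if markers.max() == 0:
            labels, _ = ndimage.label(binary)
        else:
            labels = watershed(-distance, markers, mask=binary)
    else:
        labels, _ = ndimage.label(binary)

    min_area_px = config.min_area_um2 / pitch2
    valid = phase.valid()
    out = np.zeros_like(labels)
    cells: list[CellRecord] = []
    next_label = 0
    for prop in regionprops(labels):
        if prop.area < min_area_px:
            continue
        minr, minc, maxr, maxc = prop.bbox
        touches = (
            minr == 0 or minc == 0 or maxr == labels.shape[0] or maxc == labels.shape[1]
        )
        if config.exclude_border and touches:
            continue
        region = labels == prop.label
        invalid = bool(np.any(~valid[region]))
        next_label += 1
        out[region] = next_label
        cells.append(
            CellRecord(
                label=next_label,
                area_um2=float(prop.area) * pitch2,
                centroid=tuple(float(v) for v in prop.centroid),
                touches_border=touches,
                contains_invalid_phase=invalid,
            )
        )

    if not cells:
        logger.warning("segmentation produced zero cells")
    return SegmentationResult(labels=out, cells=cells)
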