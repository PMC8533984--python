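"""Goldstein branch-cut phase unwrapping.

The wrapped phase gradient field is path-independent except around residues:
2x2 pixel loops whose wrapped gradient sum is +-2*pi.  The Goldstein method
(1) detects residues, (2) connects opposite charges (or a charge and the
image border) with branch cuts, and (3) integrates wrapped differences by
flood fill from a seed pixel, never crossing a cut.  Pixels isolated by cuts
are flagged in ``valid_mask``.

:func:`itoh_unwrap` is the classical row/column cumulative unwrapper; it is
exact only on residue-free inputs and is used as a test oracle (that
precondition is enforced).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .datatypes import TWO_PI, PhaseImage, WrappedPhase, wrap_phase


class UnwrapError(RuntimeError):
    """Raised when the integration cannot reach any pixel."""


@dataclass
class ResidueMap:
    """Residues on the dual grid of 2x2 pixel loops.

    Site (i, j) refers to the loop whose top-left pixel is (i, j); charge is
    the wrapped-gradient loop sum divided by 2*pi (+1 or -1).
    """

    rows: np.ndarray
    cols: np.ndarray
    charges: np.ndarray
    shape: tuple[int, int]

    def __len__(self) -> int:
        return len(self.charges)

    @property
    def net_charge(self) -> int:
        return int(self.charges.sum())


@dataclass
class BranchCutMask:
    """Rasterized branch cuts and the residue pairing that produced them."""

    cut_pixels: np.ndarray
    pairing: list = field(default_factory=list)


def compute_residues(wrapped: WrappedPhase) -> ResidueMap:
    """Detect phase residues by summing wrapped gradients around 2x2 loops."""
    p = wrapped.phase
    d1 = wrap_phase(p[:-1, 1:] - p[:-1, :-1])   # top edge, left -> right
    d2 = wrap_phase(p[1:, 1:] - p[:-1, 1:])     # right edge, down
    d3 = wrap_phase(p[1:, :-1] - p[1:, 1:])     # bottom edge, right -> left
    d4 = wrap_phase(p[:-1, :-1] - p[1:, :-1])   # left edge, up
    loop = d1 + d2 + d3 + d4
    charge = np.rint(loop / TWO_PI).astype(int)
    rows, cols = np.nonzero(charge)
    return ResidueMap(
        rows=rows, cols=cols, charges=charge[rows, cols], shape=p.shape
    )


def _bresenham(r0: int, c0: int, r1: int, c1: int) -> list[tuple[int, int]]:
    """8-connected raster segment between two pixels, inclusive."""
    points = []
    dr, dc = abs(r1 - r0), abs(c1 - c0)
    sr = 1 if r1 >= r0 else -1
    sc = 1 if c1 >= c0 else -1
    err = dr - dc
    r, c = r0, c0
    while True:
        points.append((r, c))
        if (r, c) == (r1, c1):
            break
        e2 = 2 * err
        if e2 > -dc:
            err -= dc
            r += sr
        if e2 < dr:
            err += dr
            c += sc
    return points


def place_branch_cuts(residues: ResidueMap, shape: Optional[tuple[int, int]] = None) -> BranchCutMask:
    """Connect residues to opposite charges or the border (nearest-neighbour).

    Each unbalanced residue is joined to the nearest unbalanced residue of
    opposite charge, unless the image border is closer, in which case the
    cut runs to the border.  Segments are rasterized 8-connected, which
    blocks the 4-connected integration from crossing them.
    """
    if shape is None:
        shape = residues.shape
    ny, nx = shape
    cuts = np.zeros(shape, dtype=bool)
    pairing: list[dict] = []

    n = len(residues)
    if n == 0:
        return BranchCutMask(cut_pixels=cuts, pairing=pairing)

    rows = residues.rows.astype(int)
    cols = residues.cols.astype(int)
    charges = residues.charges.astype(int)
    balanced = np.zeros(n, dtype=bool)

    def border_target(r: int, c: int) -> tuple[int, tuple[int, int]]:
        # nearest border point (Chebyshev distance) from a residue pixel
        candidates = [
            (r, (0, c)), (ny - 1 - r, (ny - 1, c)),
            (c, (r, 0)), (nx - 1 - c, (r, nx - 1)),
        ]
        return min(candidates, key=lambda t: t[0])

    order = np.lexsort((cols, rows))
    for idx in order:
        if balanced[idx]:
            continue
        r, c = rows[idx], cols[idx]
        d_border, b_point = border_target(r, c)

        opposite = np.nonzero(~balanced & (charges == -charges[idx]))[0]
        if opposite.size:
            d_opp = np.maximum(
                np.abs(rows[opposite] - r), np.abs(cols[opposite] - c)
            )
            k = int(np.argmin(d_opp))
            partner, d_pair = int(opposite[k]), int(d_opp[k])
        else:
            partner, d_pair = -1, np.iinfo(int).max

        if partner >= 0 and d_pair <= d_border:
            seg = _bresenham(r, c, rows[partner], cols[partner])
            balanced[idx] = balanced[partner] = True
            pairing.append(
                dict(kind="pair", a=(int(r), int(c)), b=(int(rows[partner]), int(cols[partner])),
                     charge=int(charges[idx]))
            )
        else:
            seg = _bresenham(r, c, b_point[0], b_point[1])
            balanced[idx] = True
            pairing.append(
                dict(kind="border", a=(int(r), int(c)), b=(int(b_point[0]), int(b_point[1])),
                     charge=int(charges[idx]))
            )
        for rr, cc in seg:
            cuts[rr, cc] = True

    return BranchCutMask(cut_pixels=cuts, pairing=pairing)


_NEIGHBOUR_STEPS = ((-1, 0), (1, 0), (0, -1), (0, 1))


def _flood_integrate(
    phase: np.ndarray, blocked: np.ndarray, seed: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Breadth-first integration of wrapped neighbour differences."""
    ny, nx = phase.shape
    out = np.zeros_like(phase)
    visited = blocked.copy()
    sr, sc = seed
    out[sr, sc] = phase[sr, sc]
    visited[sr, sc] = True
    fr = np.array([sr], dtype=np.intp)
    fc = np.array([sc], dtype=np.intp)
    while fr.size:
        next_r, next_c = [], []
        for dr, dc in _NEIGHBOUR_STEPS:
            nr, nc = fr + dr, fc + dc
            ok = (nr >= 0) & (nr < ny) & (nc >= 0) & (nc < nx)
            nr, nc, pr, pc = nr[ok], nc[ok], fr[ok], fc[ok]
            fresh = ~visited[nr, nc]
            nr, nc, pr, pc = nr[fresh], nc[fresh], pr[fresh], pc[fresh]
            out[nr, nc] = out[pr, pc] + wrap_phase(phase[nr, nc] - phase[pr, pc])
            visited[nr, nc] = True
            next_r.append(nr)
            next_c.append(nc)
        fr = np.concatenate(next_r)
        fc = np.concatenate(next_c)
    return out, visited & ~blocked


def goldstein_unwrap(
    wrapped: WrappedPhase,
    pixel_pitch_um: float = 1.0,
    wavelength_nm: float = 633.0,
) -> PhaseImage:
    """Unwrap a phase map with the Goldstein branch-cut algorithm.

    The seed pixel is the highest-quality non-cut pixel if the input carries
    a quality map, otherwise the image centre (shifted to the nearest
    non-cut pixel if needed).  Integration is a deterministic breadth-first
    flood fill adding wrapped neighbour differences and never crossing a
    branch cut; pixels that cuts isolate from the seed get
    ``valid_mask = False``.
    """
    residues = compute_residues(wrapped)
    cuts = place_branch_cuts(residues, wrapped.shape)
    blocked = cuts.cut_pixels
    ny, nx = wrapped.shape

    open_pixels = ~blocked
    if not open_pixels.any():
        raise UnwrapError(
            f"unwrap failed: all {ny * nx} pixels are crossed by branch cuts "
            f"({len(residues)} residues)"
        )

    if wrapped.quality is not None:
        q = np.where(open_pixels, wrapped.quality, -np.inf)
        seed = np.unravel_index(int(np.argmax(q)), wrapped.shape)
    else:
        seed = (ny // 2, nx // 2)
        if blocked[seed]:
            free = np.argwhere(open_pixels)
            d = np.abs(free[:, 0] - seed[0]) + np.abs(free[:, 1] - seed[1])
            seed = tuple(free[int(np.argmin(d))])

    out, valid = _flood_integrate(wrapped.phase, blocked, seed)
    return PhaseImage(
        out,
        pixel_pitch_um=pixel_pitch_um,
        wavelength_nm=wavelength_nm,
        valid_mask=valid,
    )


def itoh_unwrap(
    wrapped: WrappedPhase,
    pixel_pitch_um: float = 1.0,
    wavelength_nm: float = 633.0,
) -> PhaseImage:
    """Row/column cumulative unwrapping; exact on residue-free inputs only.

    Raises
    ------
    ValueError
        If the input contains residues (this oracle would then be invalid).
    """
    residues = compute_residues(wrapped)
    if len(residues):
        raise ValueError(
            f"itoh_unwrap requires a residue-free input; found {len(residues)} residues"
        )
    p = wrapped.phase.copy()
    p[:, 0] = p[0, 0] + np.concatenate(
        ([0.0], np.cumsum(wrap_phase(np.diff(p[:, 0]))))
    )
    p[:, 1:] = p[:, :1] + np.cumsum(wrap_phase(np.diff(wrapped.phase, axis=1)), axis=1)
    return PhaseImage(
        p,
        pixel_pitch_um=pixel_pitch_um,
        wavelength_nm=wavelength_nm,
        valid_mask=np.ones_like(p, dtype=bool),
    )
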