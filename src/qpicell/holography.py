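"""Off-axis interferogram demodulation.

The primary reconstruction path is :func:`demodulate_lse`: at every pixel a
three-parameter local model

    I(r) ~ a + c*cos(2*pi*f.r) + s*sin(2*pi*f.r)

is fitted by linear least squares over a centred ``window_px`` x ``window_px``
neighbourhood (default 12x12, clipped at image borders), with the carrier
frequency ``f`` supplied externally by :func:`estimate_carrier`.  The wrapped
phase at the window centre is phi = atan2(-s, c), so that increasing optical
thickness increases phi under the forward model
I = B*(1 + m*cos(2*pi*f.r + phi)).

:func:`demodulate_fourier` (standard sideband filtering) serves as an
independent oracle for the least-squares path, and
:func:`subtract_background` removes the empty-field reference, a residual
tilt plane and the background offset.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.fft import fft2, fftfreq, fftshift, ifft2

from .datatypes import (
    TWO_PI,
    CarrierSpec,
    InterferogramFrame,
    PhaseImage,
    WrappedPhase,
    wrap_phase,
)


class NoCarrierError(ValueError):
    """Raised when no off-axis carrier peak is found in the spectrum."""


_DC_EXCLUSION_CYCLES = 0.03   # spectral radius around DC ignored in the search
_PEAK_TO_MEDIAN_MIN = 6.0     # carrier peak must stand this far above the floor
_PEAK_TO_DC_MIN = 1e-4


def estimate_carrier(frame: InterferogramFrame) -> CarrierSpec:
    """Locate the off-axis carrier peak of the 2D spectrum, sub-pixel.

    A Hann window suppresses leakage; the peak is searched outside a DC
    exclusion radius and refined by parabolic interpolation of the log
    magnitude along each frequency axis.  The returned ``fx, fy`` are in
    cycles/pixel, with the convention that the peak in the fx >= 0 half-plane
    is reported.  Modulation depth is estimated from the peak/DC ratio.

    Raises
    ------
    NoCarrierError
        If no peak stands above the spectral noise floor.
    """
    intensity = frame.intensity
    ny, nx = intensity.shape
    # DFT-periodic Hann: exact spectral nulls at integer bins, so a fringe-free
    # image has essentially zero energy outside the DC lobe
    wy = np.hanning(ny + 1)[:-1][:, None]
    wx = np.hanning(nx + 1)[:-1][None, :]
    windowed = intensity * (wy * wx)

    spec = fftshift(fft2(windowed))
    mag = np.abs(spec)
    cy, cx = ny // 2, nx // 2
    dc_mag = mag[cy, cx]

    fy_ax = fftshift(fftfreq(ny))
    fx_ax = fftshift(fftfreq(nx))
    FX, FY = np.meshgrid(fx_ax, fy_ax)
    radius = np.hypot(FX, FY)

    # the Hann main lobe and its first sidelobes span ~6 bins; keep them out
    # of the search on small grids
    dc_excl = max(_DC_EXCLUSION_CYCLES, 6.0 / min(ny, nx))
    search = (radius >= dc_excl) & ((FX > 0) | ((FX == 0) & (FY > 0)))
    if not search.any():
        raise NoCarrierError("image too small for carrier search")
    masked = np.where(search, mag, 0.0)
    iy, ix = np.unravel_index(np.argmax(masked), mag.shape)
    peak_mag = mag[iy, ix]

    floor = np.median(mag[radius >= dc_excl])
    if peak_mag < _PEAK_TO_DC_MIN * dc_mag or peak_mag < _PEAK_TO_MEDIAN_MIN * floor:
        raise NoCarrierError("no carrier detected: no off-axis peak above noise floor")

    def _parabolic_offset(m_minus: float, m0: float, m_plus: float) -> float:
        lm, l0, lp = (np.log(max(v, 1e-300)) for v in (m_minus, m0, m_plus))
        denom = lm - 2.0 * l0 + lp
        if abs(denom) < 1e-12:
            return 0.0
        return float(np.clip(0.5 * (lm - lp) / denom, -0.5, 0.5))

    dy = dx = 0.0
    if 0 < iy < ny - 1:
        dy = _parabolic_offset(mag[iy - 1, ix], mag[iy, ix], mag[iy + 1, ix])
    if 0 < ix < nx - 1:
        dx = _parabolic_offset(mag[iy, ix - 1], mag[iy, ix], mag[iy, ix + 1])

    fy = (iy + dy - cy) / ny
    fx = (ix + dx - cx) / nx
    depth = float(np.clip(2.0 * peak_mag / max(dc_mag, 1e-300), 1e-6, 1.0))
    return CarrierSpec(fx=float(fx), fy=float(fy), modulation_depth=depth)


def demodulate_lse(
    frame: InterferogramFrame,
    carrier: Optional[CarrierSpec] = None,
    window_px: int = 12,
) -> WrappedPhase:
    """Windowed least-squares demodulation at a known carrier.

    Fits I ~ a + c*cos(2*pi*f.r) + s*sin(2*pi*f.r) over the centred
    ``window_px`` square around every pixel (clipped at borders) and returns
    phi = atan2(-s, c) wrapped to (-pi, pi].  ``quality`` is
    1 - normalised fit residual; pixels with singular normal equations get
    phase 0 and quality 0.
    """
    if window_px < 4:
        raise ValueError("window_px must be >= 4")
    if carrier is None:
        carrier = estimate_carrier(frame)

    I = frame.intensity.astype(float)
    ny, nx = I.shape
    X, Y = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float))
    t = TWO_PI * (carrier.fx * X + carrier.fy * Y)
    c1, s1 = np.cos(t), np.sin(t)

    # Even windows cannot be centred on a pixel; a (window+1)-tap kernel with
    # half-weight ends keeps the same support while making the weighting
    # symmetric, avoiding a half-pixel phase attribution bias.
    if window_px % 2 == 0:
        kernel = np.ones(window_px + 1)
        kernel[0] = kernel[-1] = 0.5
    else:
        kernel = np.ones(window_px)

    def wsum(a: np.ndarray) -> np.ndarray:
        # zero padding makes out-of-image samples contribute nothing,
        # i.e. borders are handled by window clipping
        out = ndimage.correlate1d(a, kernel, axis=0, mode="constant")
        return ndimage.correlate1d(out, kernel, axis=1, mode="constant")

    S1 = wsum(np.ones_like(I))
    Sc, Ss = wsum(c1), wsum(s1)
    Scc, Sss, Scs = wsum(c1 * c1), wsum(s1 * s1), wsum(c1 * s1)
    SI, SIc, SIs = wsum(I), wsum(I * c1), wsum(I * s1)
    SII = wsum(I * I)

    # closed-form solve of the symmetric 3x3 normal equations per pixel
    det = (
        S1 * (Scc * Sss - Scs * Scs)
        - Sc * (Sc * Sss - Scs * Ss)
        + Ss * (Sc * Scs - Scc * Ss)
    )
    scale = np.maximum(S1 * Scc * Sss, 1e-30)
    good = np.abs(det) > 1e-9 * scale
    det_safe = np.where(good, det, 1.0)

    a = (
        SI * (Scc * Sss - Scs * Scs)
        - SIc * (Sc * Sss - Scs * Ss)
        + SIs * (Sc * Scs - Scc * Ss)
    ) / det_safe
    c = (
        S1 * (SIc * Sss - SIs * Scs)
        - Sc * (SI * Sss - SIs * Ss)
        + Ss * (SI * Scs - SIc * Ss)
    ) / det_safe
    s = (
        S1 * (Scc * SIs - Scs * SIc)
        - Sc * (Sc * SIs - Scs * SI)
        + Ss * (Sc * SIc - Scc * SI)
    ) / det_safe

    phase = np.where(good, wrap_phase(np.arctan2(-s, c)), 0.0)

    res_ss = np.clip(SII - (a * SI + c * SIc + s * SIs), 0.0, None)
    tot_ss = np.clip(SII - SI**2 / np.maximum(S1, 1.0), 1e-30, None)
    quality = np.where(good, np.clip(1.0 - np.sqrt(res_ss / tot_ss), 0.0, 1.0), 0.0)
    return WrappedPhase(phase=phase, quality=quality)


def demodulate_fourier(
    frame: InterferogramFrame, carrier: Optional[CarrierSpec] = None
) -> WrappedPhase:
    """Fourier sideband demodulation (independent oracle for the LSE path).

    Isolates the +1 spectral order with a soft raised-cosine filter centred
    on the carrier peak, inverse-transforms and removes the carrier ramp.
    If no carrier is supplied it is estimated from the frame; note that a
    linear phase component is then indistinguishable from a carrier shift
    and is absorbed into the estimate.
    """
    if carrier is None:
        carrier = estimate_carrier(frame)
    I = frame.intensity.astype(float)
    ny, nx = I.shape
    F = fft2(I - I.mean())

    fy_ax = fftfreq(ny)
    fx_ax = fftfreq(nx)
    FX, FY = np.meshgrid(fx_ax, fy_ax)
    dist = np.hypot(FX - carrier.fx, FY - carrier.fy)
    r_filt = 0.5 * carrier.magnitude
    soft = np.where(dist < r_filt, 0.5 * (1.0 + np.cos(np.pi * dist / r_filt)), 0.0)

    analytic = ifft2(F * soft)
    X, Y = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float))
    ramp = np.exp(-1j * TWO_PI * (carrier.fx * X + carrier.fy * Y))
    phase = wrap_phase(np.angle(analytic * ramp))
    amp = np.abs(analytic)
    quality = amp / max(amp.max(), 1e-300)
    return WrappedPhase(phase=phase, quality=quality)


def subtract_background(phase: PhaseImage, reference: PhaseImage) -> PhaseImage:
    """Remove the empty-field reference, a residual tilt and the offset.

    The reference phase (absence of the object) is subtracted pixelwise;
    a plane fitted over the non-cell pixels (lowest-phase quartile) is then
    removed, and the result is offset so the background mode is zero.
    """
    if phase.shape != reference.shape:
        raise ValueError(
            f"shape mismatch: phase {phase.shape} vs reference {reference.shape}"
        )
    diff = phase.phase - reference.phase

    bg = diff <= np.quantile(diff, 0.25)
    ny, nx = diff.shape
    X, Y = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float))
    A = np.column_stack([X[bg], Y[bg], np.ones(bg.sum())])
    coef, *_ = np.linalg.lstsq(A, diff[bg], rcond=None)
    diff = diff - (coef[0] * X + coef[1] * Y + coef[2])

    bg_vals = diff[bg]
    if bg_vals.size:
        # histogram mode, refined to the median of the modal bin so that the
        # offset is not quantised to the bin width
        counts, edges = np.histogram(bg_vals, bins=128)
        k = int(np.argmax(counts))
        in_bin = (bg_vals >= edges[k]) & (bg_vals <= edges[k + 1])
        mode = float(np.median(bg_vals[in_bin])) if in_bin.any() else float(np.median(bg_vals))
        diff = diff - mode

    return PhaseImage(
        diff,
        pixel_pitch_um=phase.pixel_pitch_um,
        wavelength_nm=phase.wavelength_nm,
        valid_mask=phase.valid_mask,
    )
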