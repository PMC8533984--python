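"""Demodulation: carrier estimation, LSE vs Fourier, background removal."""

import numpy as np
import pytest

import qpicell as q

CARRIER = dict(fx=0.2, fy=0.1)


def _rmse(a, b, margin=20):
    d = q.wrap_phase(a - b)[margin:-margin, margin:-margin]
    return float(np.sqrt(np.mean(d**2)))


def test_carrier_estimate_noiseless():
    frame = q.synthesize_hologram(
        q.PhaseImage(np.zeros((256, 256))), q.CarrierSpec(**CARRIER)
    )
    est = q.estimate_carrier(frame)
    assert abs(est.fx - 0.2) < 0.005
    assert abs(est.fy - 0.1) < 0.005
    assert 0.3 < est.modulation_depth <= 1.0


def test_carrier_estimate_under_noise():
    """Monte-Carlo over 20 seeds at 5% additive noise."""
    worst = 0.0
    for seed in range(20):
        frame = q.synthesize_hologram(
            q.PhaseImage(np.zeros((128, 128))),
            q.CarrierSpec(**CARRIER),
            noise_sigma=50.0,  # background_level is 1000 counts
            seed=seed,
        )
        est = q.estimate_carrier(frame)
        worst = max(worst, abs(est.fx - 0.2), abs(est.fy - 0.1))
    assert worst < 0.01


def test_no_carrier_detected_on_fringe_free_images():
    with pytest.raises(q.NoCarrierError):
        q.estimate_carrier(q.InterferogramFrame(np.full((64, 64), 100.0)))
    flat = q.synthesize_hologram(
        q.PhaseImage(np.zeros((128, 128))),
        q.CarrierSpec(fx=0.2, fy=0.1, modulation_depth=0.0),
    )
    with pytest.raises(q.NoCarrierError):
        q.estimate_carrier(flat)


def test_lse_recovers_constant_phase():
    carrier = q.CarrierSpec(**CARRIER)
    frame = q.synthesize_hologram(q.PhaseImage(np.full((128, 128), 1.0)), carrier)
    wrapped = q.demodulate_lse(frame, carrier, window_px=12)
    assert np.allclose(wrapped.phase, 1.0, atol=0.01)


def test_lse_recovers_smooth_phase():
    carrier = q.CarrierSpec(**CARRIER)
    dome = q.smooth_dome_phantom(5.0, 60.0, (256, 256))
    frame = q.synthesize_hologram(dome, carrier)
    wrapped = q.demodulate_lse(frame, carrier, window_px=12)
    assert _rmse(wrapped.phase, dome.phase) < 0.02


def test_fourier_recovers_flat_and_ramp_phase():
    carrier = q.CarrierSpec(**CARRIER)
    flat = q.synthesize_hologram(q.PhaseImage(np.zeros((256, 256))), carrier)
    rec = q.demodulate_fourier(flat, carrier)
    assert _rmse(rec.phase, np.zeros((256, 256)), margin=32) < 0.01

    # a linear ramp is degenerate with a carrier shift, so the demodulator
    # must be informed of the true carrier to attribute the ramp to the object
    x = np.arange(256, dtype=float)
    ramp = 0.01 * np.tile(x, (256, 1))
    frame = q.synthesize_hologram(q.PhaseImage(ramp), carrier)
    rec = q.demodulate_fourier(frame, carrier)
    assert _rmse(rec.phase, ramp) < 0.02


def test_lse_and_fourier_agree():
    """Two independent demodulators as mutual oracle on the same frame."""
    carrier = q.CarrierSpec(**CARRIER)
    dome = q.smooth_dome_phantom(4.0, 50.0, (256, 256))
    frame = q.synthesize_hologram(dome, carrier)
    est = q.estimate_carrier(frame)
    lse = q.demodulate_lse(frame, est, window_px=12)
    fourier = q.demodulate_fourier(frame)
    assert _rmse(lse.phase, fourier.phase) < 0.05


def test_carrier_equivariance():
    """Shifting the carrier and informing the demodulator leaves phi unchanged."""
    dome = q.smooth_dome_phantom(4.0, 50.0, (256, 256))
    recovered = []
    for spec in (q.CarrierSpec(0.2, 0.1), q.CarrierSpec(0.23, 0.08)):
        frame = q.synthesize_hologram(dome, spec)
        recovered.append(q.demodulate_lse(frame, spec, window_px=12).phase)
    assert _rmse(recovered[0], recovered[1]) < 0.02


def test_wrapping_contract():
    carrier = q.CarrierSpec(**CARRIER)
    dome = q.smooth_dome_phantom(9.0, 40.0, (128, 128))
    frame = q.synthesize_hologram(dome, carrier, noise_sigma=20.0, seed=0)
    for wrapped in (q.demodulate_lse(frame, carrier), q.demodulate_fourier(frame)):
        assert np.all(wrapped.phase > -np.pi - 1e-12)
        assert np.all(wrapped.phase <= np.pi + 1e-12)


def test_noise_monotonicity():
    """Recovered-phase RMSE is non-decreasing in the noise level."""
    carrier = q.CarrierSpec(**CARRIER)
    dome = q.smooth_dome_phantom(2.0, 40.0, (128, 128))
    rmses = []
    for sigma in (0.0, 30.0, 120.0):
        level = []
        for seed in range(10):
            frame = q.synthesize_hologram(dome, carrier, noise_sigma=sigma, seed=seed)
            wrapped = q.demodulate_lse(frame, carrier)
            level.append(_rmse(wrapped.phase, dome.phase, margin=10))
        rmses.append(np.mean(level))
    assert rmses[0] <= rmses[1] <= rmses[2]


def test_subtract_background_identity_and_plane():
    rng = np.random.default_rng(0)
    field = q.PhaseImage(rng.normal(0, 0.1, (128, 128)))
    out = q.subtract_background(field, q.PhaseImage(field.phase.copy()))
    assert np.allclose(out.phase, 0.0, atol=1e-9)

    # object on a tilted plane, reference carries the same plane
    dome = q.smooth_dome_phantom(3.0, 15.0, (128, 128))
    x = np.arange(128, dtype=float)
    plane = 0.02 * np.tile(x, (128, 1)) + 0.01 * np.tile(x[:, None], (1, 128)) + 0.5
    obj = q.PhaseImage(dome.phase + plane)
    ref = q.PhaseImage(plane)
    rec = q.subtract_background(obj, ref)
    assert np.sqrt(np.mean((rec.phase - dome.phase) ** 2)) < 0.01


def test_subtract_background_shape_mismatch_rejected():
    with pytest.raises(ValueError, match="shape mismatch"):
        q.subtract_background(
            q.PhaseImage(np.zeros((64, 64))), q.PhaseImage(np.zeros((64, 32)))
        )
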