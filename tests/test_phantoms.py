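"""Phantom generator: ground-truth consistency, archetypes, forward models."""

import numpy as np
import pytest
from scipy.fft import fft2, fftshift

import qpicell as q

HEMISPHERE_VOLUME = 2.0 / 3.0 * np.pi * 10.0**3  # r = 10 um


def test_hemisphere_phantom_matches_closed_form_volume():
    ph = q.spherical_cap_phantom(radius_um=10.0, pixel_pitch_um=0.2)
    assert ph.true_volume == pytest.approx(HEMISPHERE_VOLUME, rel=0.005)
    integral = ph.height_map.sum() * ph.pixel_pitch_um**2
    assert integral == pytest.approx(ph.true_volume, rel=0.005)


def test_phantom_generation_is_deterministic():
    a = q.make_cell_phantom("HeLa", "live", seed=3)
    b = q.make_cell_phantom("HeLa", "live", seed=3)
    assert np.array_equal(a.height_map, b.height_map)
    assert np.array_equal(a.mask, b.mask)
    assert a.true_volume == b.true_volume


def test_unknown_class_labels_rejected():
    with pytest.raises(ValueError, match="unknown cell line"):
        q.make_cell_phantom("CHO", "live")
    with pytest.raises(ValueError, match="unknown cell state"):
        q.make_cell_phantom("HeLa", "zombie")


@pytest.mark.parametrize("line", q.LINES)
@pytest.mark.parametrize("state", q.STATES)
def test_ground_truth_volume_consistency(line, state):
    """Discrete integral of the height map matches true_volume within 0.5%."""
    for seed in range(3):
        ph = q.make_cell_phantom(line, state, seed=seed)
        assert np.all(ph.height_map >= 0)
        assert np.all(ph.height_map[~ph.mask] == 0)
        integral = ph.height_map.sum() * ph.pixel_pitch_um**2
        assert integral == pytest.approx(ph.true_volume, rel=0.005)


def test_mask_is_single_connected_component():
    from scipy import ndimage

    for seed in range(5):
        ph = q.make_cell_phantom("3T3", "apoptotic", seed=seed)
        _, n = ndimage.label(ph.mask, structure=np.ones((3, 3), dtype=int))
        assert n == 1


def test_archetype_contrast_live_spread_vs_apoptotic_compact(constants):
    """Live cells project larger areas; apoptotic cells carry higher phase."""
    live_area, apop_area, live_phi, apop_phi = [], [], [], []
    for i in range(50):
        lp = q.make_cell_phantom("HeLa", "live", seed=i)
        ap = q.make_cell_phantom("HeLa", "apoptotic", seed=5000 + i)
        live_area.append(lp.projected_area_um2)
        apop_area.append(ap.projected_area_um2)
        live_phi.append(q.phantom_to_phase(lp, constants).phase[lp.mask].mean())
        apop_phi.append(q.phantom_to_phase(ap, constants).phase[ap.mask].mean())
    assert np.mean(live_area) > np.mean(apop_area)
    assert np.mean(apop_phi) > np.mean(live_phi)


def test_archetype_contrast_sphericity_apoptotic_vs_necrotic(constants):
    psis = {"apoptotic": [], "necrotic": []}
    for state in psis:
        for i in range(50):
            ph = q.make_cell_phantom("HeLa", state, seed=7000 + i)
            phase = q.phantom_to_phase(ph, constants)
            psis[state].append(q.qpi_features(phase, ph.mask, constants).psi)
    assert np.mean(psis["apoptotic"]) > np.mean(psis["necrotic"])


def test_forward_phase_formula(constants):
    """phi = 2*pi*dn*h/lambda; a height of lambda/dn gives exactly 2*pi."""
    ph = q.spherical_cap_phantom(radius_um=8.0, pixel_pitch_um=0.25)
    special_h = constants.wavelength_um / constants.delta_n
    scaled = ph.height_map * (special_h / ph.height_map.max())
    ph.height_map = scaled
    phase = q.phantom_to_phase(ph, constants)
    assert phase.phase.max() == pytest.approx(2.0 * np.pi, rel=1e-12)

    ph.height_map = np.zeros_like(ph.height_map)
    assert np.all(q.phantom_to_phase(ph, constants).phase == 0)


def test_phase_height_round_trip(constants):
    ph = q.make_cell_phantom("A549", "live", seed=1)
    phase = q.phantom_to_phase(ph, constants)
    hm = q.height_map(phase, ph.mask, constants)
    assert np.max(np.abs(hm.height - ph.height_map)) < 1e-9


def test_hologram_of_flat_phase_is_pure_fringe():
    # carrier on integer spectral bins, so the cosine occupies exactly two bins
    carrier = q.CarrierSpec(fx=0.25, fy=0.125)
    frame = q.synthesize_hologram(q.PhaseImage(np.zeros((128, 128))), carrier)
    spec = np.abs(fftshift(fft2(frame.intensity - frame.intensity.mean())))
    # exactly two symmetric off-centre peaks at +-(fx, fy)
    iy, ix = np.unravel_index(np.argmax(spec), spec.shape)
    fy = (iy - 64) / 128.0
    fx = (ix - 64) / 128.0
    assert abs(abs(fx) - 0.25) < 0.005 and abs(abs(fy) - 0.125) < 0.005
    assert spec[64 - int(0.125 * 128), 64 - int(0.25 * 128)] == pytest.approx(
        spec[iy, ix], rel=1e-9
    )
    spec_sorted = np.sort(spec.ravel())[::-1]
    assert spec_sorted[1] > 1e6 * max(spec_sorted[2], 1e-12)


def test_zero_modulation_gives_constant_intensity():
    carrier = q.CarrierSpec(fx=0.2, fy=0.1, modulation_depth=0.0)
    frame = q.synthesize_hologram(q.PhaseImage(np.zeros((64, 64))), carrier)
    assert frame.intensity.std() == 0


def test_carrier_above_nyquist_rejected():
    with pytest.raises(ValueError, match="Nyquist"):
        q.CarrierSpec(fx=0.4, fy=0.4)


def test_labeled_dataset_is_balanced_and_reproducible(constants):
    spec = q.SyntheticDatasetSpec(n_cells_per_class=3, seed=42)
    items = q.make_labeled_dataset(spec, constants)
    assert len(items) == 9 * 3
    from collections import Counter

    counts = Counter((it.line, it.state) for it in items)
    assert all(v == 3 for v in counts.values())

    again = q.make_labeled_dataset(spec, constants)
    t1 = q.feature_table(items, constants)
    t2 = q.feature_table(again, constants)
    assert t1.equals(t2)


def test_treatment_series_mixture_is_ground_truth():
    series = q.simulate_treatment_series(n_timepoints=3, n_cells_per_frame=8, seed=2)
    assert len(series.frames) == 3
    frac = series.true_fractions
    assert np.allclose(
        frac[["frac_live", "frac_apoptotic", "frac_necrotic"]].sum(axis=1), 1.0
    )
    assert frac.frac_live.iloc[0] == 1.0
    assert frac.frac_necrotic.iloc[-1] > frac.frac_necrotic.iloc[0]
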