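"""Phase ramps, chirps, hologram combination and selective-focus display."""

import numpy as np
import pytest
from scipy import ndimage

import holowbc as h


@pytest.fixture(scope="module")
def optics128():
    return h.OpticalConfig(slm_shape=(128, 128))


@pytest.fixture(scope="module")
def spot_hologram(optics128):
    yy, xx = np.mgrid[:128, :128]
    spot = np.exp(-(((yy - 64) / 6.0) ** 2 + ((xx - 64) / 6.0) ** 2))
    res = h.run_ifta(spot, h.IFTAConfig(max_iterations=20, epsilon_rad=0, error_floor=0, seed=7))
    return res.hologram


class TestPhaseRamp:
    def test_zero_tilt_is_identity(self, optics128):
        assert np.allclose(h.phase_ramp(optics128, 0.0, 0.0, (128, 128)), 1.0)

    def test_unit_modulus(self, optics128):
        ramp = h.phase_ramp(optics128, 0.01, -0.02, (64, 64))
        assert np.allclose(np.abs(ramp), 1.0)

    def test_integer_pixel_shift_equals_circular_shift_oracle(self, optics128, spot_hologram):
        """Ramp-then-transform equals circularly shifting the unramped reconstruction."""
        lam, pitch = optics128.wavelength_m, optics128.slm_pitch_m
        base = h.reconstruct_intensity(spot_hologram)
        for p_i, p_j in [(16, 0), (0, -12), (9, 5)]:
            sin_a = p_i * lam / (128 * pitch)
            sin_b = p_j * lam / (128 * pitch)
            ramp = h.phase_ramp(optics128, np.arcsin(sin_a), np.arcsin(sin_b), (128, 128))
            shifted = np.abs(h.fft2c(spot_hologram.field() * ramp)) ** 2
            oracle = np.roll(np.roll(base, p_i, axis=0), p_j, axis=1)
            assert np.allclose(shifted, oracle, atol=1e-8 * base.max())


class TestChirp:
    def test_zero_distance_identity(self, optics128):
        assert np.allclose(h.chirp(optics128, 0.0, (64, 64)), 1.0)

    def test_unit_modulus(self, optics128):
        assert np.allclose(np.abs(h.chirp(optics128, 0.12, (64, 64))), 1.0)

    def test_additivity_in_distance(self, optics128):
        c1 = h.chirp(optics128, 0.03, (96, 96))
        c2 = h.chirp(optics128, 0.07, (96, 96))
        c12 = h.chirp(optics128, 0.10, (96, 96))
        assert np.max(np.abs(c1 * c2 - c12)) < 1e-10


class TestModulationComponent:
    def test_zero_distance_forbids_shift(self, spot_hologram):
        with pytest.raises(ValueError, match="zero lateral shift"):
            h.ModulationComponent(spot_hologram, z_m=0.0, shift_u=(1e-4, 0.0))

    def test_shift_bounded_by_distance(self, spot_hologram):
        with pytest.raises(ValueError, match="sin"):
            h.ModulationComponent(spot_hologram, z_m=0.01, shift_u=(0.02, 0.0))

    def test_tilt_angles_from_geometry(self, spot_hologram):
        comp = h.ModulationComponent(spot_hologram, z_m=0.05, shift_u=(5e-4, -2.5e-4))
        assert comp.sin_alpha == pytest.approx(0.01)
        assert comp.sin_beta == pytest.approx(-0.005)


class TestCombine:
    def test_single_unmodulated_component_identity(self, optics128, spot_hologram):
        combined = h.combine([h.ModulationComponent(spot_hologram)], optics128)
        delta = np.mod(combined.phase_rad - spot_hologram.phase_rad + np.pi, 2 * np.pi) - np.pi
        assert np.max(np.abs(delta)) < 1e-9

    def test_opposite_ramps_symmetric_under_flip(self):
        cfg = h.OpticalConfig(slm_shape=(65, 65))
        base = h.PhaseHologram(np.full((65, 65), 0.7))
        z = 0.05
        sin_a = 8 * cfg.wavelength_m / (65 * cfg.slm_pitch_m)
        plus = h.ModulationComponent(base, z_m=z, shift_u=(sin_a * z, 0.0))
        minus = h.ModulationComponent(base, z_m=z, shift_u=(-sin_a * z, 0.0))
        phase = h.combine([plus, minus], cfg).phase_rad
        # odd coordinate grid: flipping both axes maps nu -> -nu exactly
        flipped = np.flip(phase)
        delta = np.mod(phase - flipped + np.pi, 2 * np.pi) - np.pi
        assert np.max(np.abs(delta)) < 1e-9

    def test_zero_sum_pixels_get_zero_phase(self):
        from holowbc.modulation import phase_of_sum

        total = np.array([[0.0 + 0.0j, 1.0 + 1.0j], [-2.0j, 0.0 + 0.0j]])
        phase = phase_of_sum(total)
        assert phase[0, 0] == 0.0 and phase[1, 1] == 0.0
        assert phase[0, 1] == pytest.approx(np.pi / 4)

    def test_near_cancelling_components_stay_finite(self, optics128):
        a = h.PhaseHologram(np.full((32, 32), 0.3))
        b = h.PhaseHologram(np.full((32, 32), 0.3 + np.pi))
        combined = h.combine(
            [h.ModulationComponent(a), h.ModulationComponent(b)],
            h.OpticalConfig(slm_shape=(32, 32)),
        )
        assert np.all(np.isfinite(combined.phase_rad))
        assert np.all((combined.phase_rad >= 0) & (combined.phase_rad < 2 * np.pi))

    def test_shape_mismatch_rejected(self, optics128, spot_hologram):
        other = h.PhaseHologram(np.zeros((64, 64)))
        with pytest.raises(ValueError, match="shape"):
            h.combine([h.ModulationComponent(spot_hologram), h.ModulationComponent(other)], optics128)

    def test_empty_component_list_rejected(self, optics128):
        with pytest.raises(ValueError, match="at least one"):
            h.combine([], optics128)


class TestReconstructAt:
    def test_z_zero_equals_plain_reconstruction(self, optics128, spot_hologram):
        assert np.allclose(
            h.reconstruct_at(spot_hologram, 0.0, optics128),
            h.reconstruct_intensity(spot_hologram),
        )

    def test_two_component_selective_focus(self, optics128):
        """Each component is sharpest at its own plane and blurred at the other's."""
        yy, xx = np.mgrid[:128, :128]
        ring = (np.abs(np.hypot(yy - 64, xx - 64) - 20) < 2).astype(float)
        disc = (np.hypot(yy - 64, xx - 64) < 11).astype(float)
        cfg_i = h.IFTAConfig(max_iterations=25, epsilon_rad=0, error_floor=0, seed=5)
        h_ring = h.run_ifta(ring, cfg_i).hologram
        h_disc = h.run_ifta(disc, cfg_i).hologram
        z2, shift = 0.30, 46
        sin_a = shift * optics128.wavelength_m / (128 * optics128.slm_pitch_m)
        comps = [
            h.ModulationComponent(h_ring, z_m=0.0),
            h.ModulationComponent(h_disc, z_m=z2, shift_u=(sin_a * z2, 0.0)),
        ]
        combined = h.combine(comps, optics128)
        rois = [
            ndimage.binary_dilation(ring > 0.5, iterations=4),
            ndimage.binary_dilation(np.roll(disc > 0.5, shift, axis=0), iterations=4),
        ]
        stack = h.focal_stack(combined, np.linspace(-0.06, 0.36, 15), optics128, rois=rois)
        best = stack.distances[np.argmax(stack.focus_scores, axis=0)]
        assert best[0] == pytest.approx(0.0, abs=0.016)
        assert best[1] == pytest.approx(z2, abs=0.016)


class TestAnnotateTarget:
    def test_empty_labels_unchanged(self):
        amp = np.random.default_rng(0).uniform(size=(64, 64))
        assert np.array_equal(h.annotate_target(amp, []), amp)

    def test_label_pixels_set_to_max_amplitude(self):
        amp = np.zeros((64, 64))
        amp[30:50, 10:50] = 0.6
        out = h.annotate_target(amp, [("N", (5, 20))])
        changed = out != amp
        assert changed.any()
        assert np.all(out[changed] == 0.6)

    def test_overflowing_label_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            h.annotate_target(np.ones((20, 20)), [("WBC", (18, 18))], scale=3)

    def test_label_legible_in_reconstruction(self):
        """End to end: a burned-in label survives hologram synthesis."""
        target = np.zeros((64, 64))
        target[28:50, 16:48] = 0.6
        labeled = h.annotate_target(target, [("N", (4, 22))], scale=2)
        stencil = labeled > target + 1e-9
        padded = h.render_amplitude_target(labeled, 2, (64, 64))
        res = h.run_ifta(padded, h.IFTAConfig(max_iterations=40, epsilon_rad=0, error_floor=0, seed=3))
        smoothed = ndimage.gaussian_filter(res.reconstruction, 1.0)
        full_stencil = np.zeros((128, 128), bool)
        full_stencil[32:96, 32:96] = stencil
        roi = ndimage.binary_dilation(full_stencil, iterations=3)
        recovered = (smoothed > 0.5 * smoothed[roi].max()) & roi
        assert h.jaccard(recovered, full_stencil) >= 0.5
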