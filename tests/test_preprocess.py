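"""Propagation, autofocus, phase unwrapping and scattering-data filters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import weak_disk
from difftomo import _fft
from difftomo.core import ImagingGeometry, full_turn_angles, validate_sinogram
from difftomo.forward import object_from_ri, rytov_forward
from difftomo.preprocess import (autofocus, propagate, to_born_data,
                                 to_radon_data, to_rytov_data,
                                 unwrap_phase_1d, unwrap_phase_2d)


def bandlimited_field(n: int, geometry: ImagingGeometry, seed: int = 0,
                      cutoff: float = 0.7) -> np.ndarray:
    """Random 1D field with spectrum inside ``cutoff * k_m`` (periodic)."""
    rng = np.random.default_rng(seed)
    spec = rng.normal(size=n) + 1j * rng.normal(size=n)
    spec[np.abs(_fft.kgrid(n)) > cutoff * geometry.km] = 0.0
    return _fft.ift_centered(spec, axes=0)


class TestPropagate:
    def test_zero_distance_is_identity(self, geom4):
        u = bandlimited_field(64, geom4)
        np.testing.assert_allclose(propagate(u, 0.0, geom4, pad_factor=1), u,
                                   atol=1e-12)

    def test_uniform_field_accumulates_plane_wave_phase(self, geom4):
        # only the DC mode: gamma(0) = k_m
        u = np.ones(64, dtype=complex)
        d = 5.5
        out = propagate(u, d, geom4, pad_factor=1)
        np.testing.assert_allclose(out, np.exp(1j * geom4.km * d),
                                   atol=1e-12)

    def test_round_trip_is_identity_on_propagating_modes(self, geom4):
        u = bandlimited_field(64, geom4, seed=3)
        back = propagate(propagate(u, 7.0, geom4, pad_factor=1), -7.0, geom4,
                         pad_factor=1)
        assert np.abs(back - u).max() < 1e-10

    def test_2d_fields_supported(self, geom4):
        rng = np.random.default_rng(0)
        spec = rng.normal(size=(32, 32)) * 1j
        ky = _fft.kgrid(32)
        mask = (ky[:, None] ** 2 + ky[None, :] ** 2) < (0.5 * geom4.km) ** 2
        u = _fft.ift_centered(spec * mask, axes=(0, 1))
        back = propagate(propagate(u, 3.0, geom4, pad_factor=1), -3.0, geom4,
                         pad_factor=1)
        assert np.abs(back - u).max() < 1e-10

    def test_nonfinite_input_rejected(self, geom4):
        u = np.ones(16, dtype=complex)
        u[3] = np.inf
        with pytest.raises(ValueError, match="finite"):
            propagate(u, 1.0, geom4)


class TestAutofocus:
    def focused_field(self, geom, n=128):
        # weak pure-phase specimen: flattest amplitude at focus
        x = np.arange(n) - n // 2
        phase = 0.8 * np.exp(-(x / 12.0) ** 2)
        u = np.exp(1j * phase)
        # band-limit by a forward-backward propagation (removes evanescent)
        return propagate(u, 0.0, geom)

    def test_focused_input_yields_near_zero_distance(self, geom4):
        res = autofocus(self.focused_field(geom4), geom4,
                        (-2 * geom4.wavelength, 2 * geom4.wavelength))
        assert abs(res.distance) < geom4.wavelength / 50

    @pytest.mark.parametrize("shift_wl", [1.0, -2.0, 3.0])
    def test_recovers_known_defocus(self, geom4, shift_wl):
        d = shift_wl * geom4.wavelength
        defocused = propagate(self.focused_field(geom4), d, geom4)
        res = autofocus(defocused, geom4,
                        (-3.5 * geom4.wavelength, 3.5 * geom4.wavelength))
        assert res.distance == pytest.approx(-d, abs=geom4.wavelength / 50)

    def test_minimum_beats_interval_endpoints(self, geom4):
        from difftomo.preprocess import _amplitude_gradient
        field = propagate(self.focused_field(geom4), 4.0, geom4)
        lo, hi = -3 * geom4.wavelength, 3 * geom4.wavelength
        res = autofocus(field, geom4, (lo, hi))
        m_best = _amplitude_gradient(res.field)
        for d in (lo, hi):
            assert m_best <= _amplitude_gradient(propagate(field, d, geom4))


class TestUnwrap:
    def test_constant_phase_unchanged(self):
        res = unwrap_phase_2d(np.full((16, 16), 0.3))
        np.testing.assert_allclose(res.phase, 0.3, atol=1e-12)
        assert res.residue_count == 0

    def test_linear_ramp_recovered_up_to_global_offset(self):
        n = 64
        ramp = np.linspace(0.0, 6 * np.pi, n)[None, :] * np.ones((n, 1))
        wrapped = np.angle(np.exp(1j * ramp))
        res = unwrap_phase_2d(wrapped)
        offset = res.phase - ramp
        k = np.round(offset.mean() / (2 * np.pi))
        np.testing.assert_allclose(res.phase - 2 * np.pi * k, ramp,
                                   atol=1e-9)

    def test_smooth_gaussian_bump_of_4pi(self):
        n = 48
        y, x = np.meshgrid(*[np.arange(n) - n // 2] * 2, indexing="ij")
        truth = 4 * np.pi * np.exp(-(x ** 2 + y ** 2) / (2 * 8.0 ** 2))
        res = unwrap_phase_2d(np.angle(np.exp(1j * truth)))
        offset = 2 * np.pi * np.round((res.phase - truth).mean() / (2 * np.pi))
        assert np.abs(res.phase - offset - truth).max() < 1e-6

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_rewrap_identity(self, seed):
        # unwrapped - wrapped must be a multiple of 2*pi at every pixel
        rng = np.random.default_rng(seed)
        smooth = rng.normal(size=(12, 12))
        from scipy.ndimage import gaussian_filter
        wrapped = np.angle(np.exp(1j * 8.0 * gaussian_filter(smooth, 2.0)))
        res = unwrap_phase_2d(wrapped)
        cycles = (res.phase - wrapped) / (2 * np.pi)
        np.testing.assert_allclose(cycles, np.round(cycles), atol=1e-9)

    def test_1d_unwrap_matches_known_ramp(self):
        ramp = np.linspace(0.0, 5 * np.pi, 128)[None, :]
        wrapped = np.angle(np.exp(1j * ramp))
        un = unwrap_phase_1d(wrapped)
        k = np.round((un - ramp).mean() / (2 * np.pi))
        np.testing.assert_allclose(un - 2 * np.pi * k, ramp, atol=1e-9)


class TestScatteringDataFilters:
    def unit_sinogram(self, geom, value):
        fields = np.full((4, 32), value, dtype=complex)
        return validate_sinogram(fields, full_turn_angles(4), geom)

    def test_unit_field_maps_to_zero_everywhere(self, geom4):
        sino = self.unit_sinogram(geom4, 1.0)
        np.testing.assert_allclose(to_born_data(sino).data, 0.0, atol=1e-15)
        np.testing.assert_allclose(to_rytov_data(sino).data, 0.0, atol=1e-15)
        np.testing.assert_allclose(to_radon_data(sino), 0.0, atol=1e-15)

    def test_born_is_exact_field_difference(self, geom4):
        sino = self.unit_sinogram(geom4, 1.0 + 1e-4)
        np.testing.assert_array_equal(to_born_data(sino).data,
                                      sino.fields - 1.0)

    def test_rytov_log_identity_without_wrapping(self, geom4):
        sino = self.unit_sinogram(geom4, np.exp(0.2 + 0.3j))
        np.testing.assert_allclose(to_rytov_data(sino).data, 0.2 + 0.3j,
                                   atol=1e-12)

    def test_rytov_unwraps_multi_pi_phase_excursion(self, geom4):
        # smooth 3*pi phase bump across the detector: the wrapped argument
        # alone is wrong, the unwrapped Rytov phase matches the truth
        x = np.linspace(-1, 1, 64)
        truth = 3 * np.pi * np.exp(-(x / 0.4) ** 2)[None, :] * np.ones((4, 1))
        sino = validate_sinogram(np.exp(1j * truth), full_turn_angles(4),
                                 geom4)
        data = to_rytov_data(sino).data
        assert np.abs(data.imag - truth).max() < 1e-9
        assert np.abs(np.angle(sino.fields) - truth).max() > np.pi

    def test_radon_equals_rytov_imaginary_part_for_pure_phase(self, geom4):
        x = np.linspace(-1, 1, 48)
        phase = 2.5 * np.exp(-(x / 0.5) ** 2)[None, :] * np.ones((4, 1))
        sino = validate_sinogram(np.exp(1j * phase), full_turn_angles(4),
                                 geom4)
        np.testing.assert_allclose(to_radon_data(sino),
                                   to_rytov_data(sino).data.imag, atol=1e-12)

    def test_zero_modulus_rejected(self, geom4):
        fields = np.ones((4, 16), dtype=complex)
        fields[2, 5] = 0.0
        sino = validate_sinogram(fields, full_turn_angles(4), geom4)
        with pytest.raises(ValueError, match="zero-modulus"):
            to_rytov_data(sino)
        with pytest.raises(ValueError, match="zero-modulus"):
            to_radon_data(sino)

    def test_born_and_rytov_agree_to_second_order(self, geom4):
        obj = object_from_ri(weak_disk(48, 12.0, delta_n=2e-5,
                                       geometry=geom4))
        sino = rytov_forward(obj, full_turn_angles(8), geom4)
        born = to_born_data(sino).data
        rytov = to_rytov_data(sino).data
        assert np.abs(born).max() <= 1e-3
        assert np.abs(born - rytov).max() <= 1e-6
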