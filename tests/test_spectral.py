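"""Spectral engine: resampling, absorbance, forward model, retrieval."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

import cholspec as cs
from cholspec.errors import (
    AlignmentError,
    DegenerateDesignError,
    SpanError,
    ValidationError,
)


def make_spectrum(wavelengths, intensities):
    return cs.Spectrum(np.asarray(wavelengths, float), np.asarray(intensities, float))


class TestSpectrumValidation:
    def test_rejects_non_monotone_wavelengths(self):
        with pytest.raises(ValidationError):
            make_spectrum([400, 399, 401], [1, 1, 1])

    def test_rejects_negative_intensity(self):
        with pytest.raises(ValidationError):
            make_spectrum([400, 401], [1, -0.1])

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValidationError):
            make_spectrum([400, 401, 402], [1, 1])


class TestWavelengthGrid:
    def test_default_half_open_grid_has_400_points(self, grid):
        w = grid.wavelengths()
        assert w.size == 400
        assert w[0] == 380.0 and w[-1] == 779.0
        assert np.all(np.diff(w) == 1.0)

    def test_inclusive_convention_has_401_points(self):
        w = cs.WavelengthGrid(include_endpoint=True).wavelengths()
        assert w.size == 401 and w[-1] == 780.0


class TestResampling:
    def test_simulated_2048_point_raw_yields_400_points(self, led, grid):
        raw = led.nominal_spectrum()
        assert len(raw) == 2048
        out = cs.resample_to_integer_grid(raw, grid)
        assert len(out) == 400
        assert np.array_equal(out.wavelengths, grid.wavelengths())

    def test_identity_on_grid_knots(self, grid, rng):
        w = grid.wavelengths()
        values = rng.uniform(0.1, 2.0, w.size)
        out = cs.resample_to_integer_grid(make_spectrum(w, values), grid)
        np.testing.assert_array_equal(out.intensities, values)

    def test_linear_ramp_reproduced_exactly(self, grid):
        raw_w = np.linspace(330.0, 850.0, 2048)
        out = cs.resample_to_integer_grid(make_spectrum(raw_w, 2.0 * raw_w), grid)
        np.testing.assert_allclose(out.intensities, 2.0 * out.wavelengths, rtol=1e-13)

    def test_grid_beyond_raw_span_raises(self, grid):
        raw = make_spectrum([400.0, 700.0], [1.0, 1.0])
        with pytest.raises(SpanError):
            cs.resample_to_integer_grid(raw, grid)

    def test_single_point_raw_raises(self, grid):
        with pytest.raises(ValidationError):
            cs.resample_to_integer_grid(make_spectrum([500.0], [1.0]), grid)


class TestAbsorbance:
    def test_equal_spectra_give_zero(self, incident):
        a = cs.compute_absorbance(incident, incident)
        np.testing.assert_array_equal(a.absorbance, 0.0)

    def test_transmitted_over_e_gives_unit_absorbance(self, incident):
        trans = make_spectrum(incident.wavelengths, incident.intensities / np.e)
        a = cs.compute_absorbance(incident, trans)
        np.testing.assert_allclose(a.absorbance, 1.0, rtol=1e-12)

    def test_matches_elementwise_log_ratio_oracle(self, grid, rng):
        w = grid.wavelengths()
        i0 = rng.uniform(0.5, 3.0, w.size)
        i1 = rng.uniform(0.1, 3.0, w.size)
        a = cs.compute_absorbance(make_spectrum(w, i0), make_spectrum(w, i1))
        oracle = np.array([np.log(x / y) for x, y in zip(i0, i1)])
        np.testing.assert_allclose(a.absorbance, oracle, atol=1e-12)

    def test_mismatched_grids_raise(self, incident):
        other = make_spectrum(incident.wavelengths + 0.5, incident.intensities)
        with pytest.raises(AlignmentError):
            cs.compute_absorbance(incident, other)

    def test_nonpositive_incident_raises(self, grid):
        w = grid.wavelengths()
        i0 = np.ones(w.size)
        i0[5] = 0.0
        with pytest.raises(ValidationError):
            cs.compute_absorbance(make_spectrum(w, i0), make_spectrum(w, np.ones(w.size)))


class TestForwardModel:
    def test_zero_concentration_is_identity(self, incident, profile):
        out = cs.forward_transmission(incident, profile, 0.0)
        np.testing.assert_array_equal(out.intensities, incident.intensities)

    def test_single_wavelength_beer_lambert(self):
        inc = make_spectrum([650.0], [3.0])
        prof = cs.ExtinctionProfile(np.array([650.0]), np.array([1.0]))
        out = cs.forward_transmission(inc, prof, 2.0, cs.RetrievalSettings(path_length_mm=1.0))
        np.testing.assert_allclose(out.intensities, [3.0 * np.exp(-2.0)], rtol=1e-15)

    def test_negative_concentration_raises(self, incident, profile):
        with pytest.raises(ValidationError):
            cs.forward_transmission(incident, profile, -0.5)

    def test_never_exceeds_incident_where_absorbing(self, incident, profile):
        out = cs.forward_transmission(incident, profile, 1.3)
        absorbing = profile.alpha > 0
        assert np.all(out.intensities[absorbing] <= incident.intensities[absorbing])


class TestRetrieval:
    def test_zero_absorbance_gives_zero_concentration(self, incident, profile):
        res = cs.retrieve_relative_concentration(incident, incident, profile)
        assert res.concentration == 0.0
        assert res.residual_norm == 0.0
        assert res.n_wavelengths_used == 305  # integers in [475, 779]

    @pytest.mark.parametrize("c", [0.0, 0.3, 0.7, 2.5, 8.0])
    def test_noiseless_round_trip(self, incident, profile, c):
        trans = cs.forward_transmission(incident, profile, c)
        res = cs.retrieve_relative_concentration(incident, trans, profile)
        assert abs(res.concentration - c) < 1e-10
        assert res.residual_norm < 1e-10

    def test_closed_form_matches_grid_search_on_small_instance(self):
        w = np.array([500.0, 550.0, 600.0, 650.0, 700.0])
        alpha = np.array([0.2, 0.9, 1.4, 0.7, 0.1])
        a_noisy = np.array([0.35, 1.21, 1.95, 1.02, 0.07])
        inc = make_spectrum(w, np.ones(5))
        trans = make_spectrum(w, np.exp(-a_noisy))
        prof = cs.ExtinctionProfile(w, alpha)
        res = cs.retrieve_relative_concentration(inc, trans, prof)
        c_grid = np.arange(-10.0, 10.0, 1e-4)
        sse = ((a_noisy[None, :] - alpha[None, :] * c_grid[:, None]) ** 2).sum(axis=1)
        c_star = c_grid[np.argmin(sse)]
        assert abs(res.concentration - c_star) < 1e-3

    def test_degenerate_profile_raises(self, incident):
        prof = cs.ExtinctionProfile(incident.wavelengths, np.zeros(len(incident)))
        with pytest.raises(DegenerateDesignError):
            cs.retrieve_relative_concentration(incident, incident, prof)

    def test_negative_concentration_reported_unclamped(self, incident, profile):
        # transmitted brighter than incident -> negative absorbance -> c < 0
        trans = make_spectrum(incident.wavelengths, incident.intensities * 1.05)
        res = cs.retrieve_relative_concentration(incident, trans, profile)
        assert res.concentration < 0


class TestRetrievalProperties:
    @given(scale=st.floats(0.01, 100.0), c=st.floats(0.0, 5.0))
    def test_scale_invariance(self, incident, profile, scale, c):
        trans = cs.forward_transmission(incident, profile, c)
        res1 = cs.retrieve_relative_concentration(incident, trans, profile)
        inc2 = make_spectrum(incident.wavelengths, incident.intensities * scale)
        trans2 = make_spectrum(trans.wavelengths, trans.intensities * scale)
        res2 = cs.retrieve_relative_concentration(inc2, trans2, profile)
        assert res2.concentration == pytest.approx(res1.concentration, abs=1e-9)

    def test_linearity_doubling_absorbance_doubles_estimate(self, incident, profile, rng):
        ratio = np.exp(-rng.uniform(0.0, 1.0, len(incident)))
        trans = make_spectrum(incident.wavelengths, incident.intensities * ratio)
        trans2 = make_spectrum(incident.wavelengths, incident.intensities * ratio**2)
        c1 = cs.retrieve_relative_concentration(incident, trans, profile).concentration
        c2 = cs.retrieve_relative_concentration(incident, trans2, profile).concentration
        assert c2 == pytest.approx(2.0 * c1, rel=1e-10)

    def test_band_restriction_ignores_out_of_band_perturbation(self, incident, profile, rng):
        trans = cs.forward_transmission(incident, profile, 1.1)
        c_ref = cs.retrieve_relative_concentration(incident, trans, profile).concentration
        perturbed = trans.intensities.copy()
        outside = incident.wavelengths < 475.0
        perturbed[outside] *= rng.uniform(0.5, 1.5, outside.sum())
        trans_p = make_spectrum(trans.wavelengths, perturbed)
        c_p = cs.retrieve_relative_concentration(incident, trans_p, profile).concentration
        assert c_p == pytest.approx(c_ref, abs=1e-12)

    def test_closed_form_equals_numeric_minimizer(self, rng):
        for _ in range(20):
            n = rng.integers(3, 12)
            w = np.sort(rng.uniform(480.0, 770.0, n))
            w += np.arange(n) * 1e-6  # ensure strictly increasing
            alpha = rng.uniform(0.0, 2.0, n)
            alpha[rng.integers(0, n)] = rng.uniform(0.5, 2.0)  # non-degenerate
            a = rng.normal(0.0, 1.0, n)
            inc = make_spectrum(w, np.ones(n))
            trans = make_spectrum(w, np.exp(-np.clip(a, -30, 30)))
            prof = cs.ExtinctionProfile(w, alpha)
            res = cs.retrieve_relative_concentration(inc, trans, prof)
            a_eff = cs.compute_absorbance(inc, trans).absorbance
            num = minimize_scalar(
                lambda c: float(((a_eff - alpha * c) ** 2).sum()),
                bounds=(-50, 50),
                method="bounded",
                options={"xatol": 1e-12},
            )
            assert res.concentration == pytest.approx(num.x, abs=1e-6)
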