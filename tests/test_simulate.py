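"""Synthetic instrument and study generators: contracts and physics."""

import numpy as np
import pytest

import cholspec as cs
from cholspec.errors import ValidationError

# measured floor of the piecewise-linear resampling chain (raw 2048-sample
# grid is not aligned with the integer-wavelength grid); see docs/methods.md
RESAMPLE_RTOL = 5e-5


class TestSourceSpectrum:
    def test_noiseless_draws_identical_across_seeds(self, led):
        a = cs.simulate_source_spectrum(led, cs.NoiseModel(jitter=0.0, seed=1), 0)
        b = cs.simulate_source_spectrum(led, cs.NoiseModel(jitter=0.0, seed=2), 7)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_output_has_2048_samples(self, led):
        out = cs.simulate_source_spectrum(led, cs.NoiseModel(seed=0), 0)
        assert len(out) == 2048
        assert out.span_nm == (330.0, 850.0)

    def test_jitter_is_bounded_and_sd_below_one_percent(self, led):
        noise = cs.NoiseModel(jitter=0.01, seed=5)
        nominal = led.nominal_spectrum().intensities.sum()
        totals = np.array(
            [
                cs.simulate_source_spectrum(led, noise, k).intensities.sum()
                for k in range(1000)
            ]
        )
        rel = totals / nominal - 1.0
        assert np.max(np.abs(rel)) <= 0.01 + 1e-12
        assert totals.std() / totals.mean() <= 0.01

    def test_seeded_reproducibility(self, led):
        noise = cs.NoiseModel(jitter=0.01, seed=9)
        a = cs.simulate_source_spectrum(led, noise, 3)
        b = cs.simulate_source_spectrum(led, noise, 3)
        np.testing.assert_array_equal(a.intensities, b.intensities)


class TestMeasurement:
    def measure(self, c, noise, seed=0, chromogen=None):
        chromogen = chromogen or cs.ChromogenModel()
        incident, transmitted = cs.simulate_measurement(c, noise=noise, seed=seed,
                                                        chromogen=chromogen)
        profile = chromogen.profile(cs.WavelengthGrid().wavelengths())
        return cs.measure_sample(incident, transmitted, profile)

    def test_zero_concentration_noiseless_measures_zero(self, noiseless):
        res = self.measure(0.0, noiseless)
        assert abs(res.raw_concentration) < 1e-10

    def test_unit_concentration_noiseless_round_trip(self, noiseless):
        res = self.measure(1.0, noiseless)
        assert res.raw_concentration == pytest.approx(1.0, rel=RESAMPLE_RTOL)

    def test_fixed_seed_gives_bit_identical_spectra(self):
        noise = cs.NoiseModel(jitter=0.01, seed=4)
        a = cs.simulate_measurement(1.0, noise=noise, seed=11)
        b = cs.simulate_measurement(1.0, noise=noise, seed=11)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.intensities, sb.intensities)

    def test_negative_concentration_rejected(self, noiseless):
        with pytest.raises(ValidationError):
            cs.simulate_measurement(-1.0, noise=noiseless)


class TestDilutionSeries:
    def test_signals_strictly_increase_with_concentration(self, noiseless):
        points = cs.simulate_dilution_series(noise=noiseless)
        by_conc = sorted(points, key=lambda p: p.concentration)
        signals = [p.signal for p in by_conc]
        assert np.all(np.diff(signals) > 0)

    def test_repeated_concentration_identical_without_jitter(self, noiseless):
        points = cs.simulate_dilution_series([1.0, 1.0, 1.0], noise=noiseless)
        assert points[0].signal == points[1].signal == points[2].signal

    def test_fitted_4pl_recovers_generating_response(self, noiseless):
        response = cs.SaturatingResponse()
        points = cs.simulate_dilution_series(noise=noiseless, response=response)
        curve = cs.fit_calibration_curve(points)
        # generating Hill response == 4PL(lower=0, upper=smax, mid=log10 k, slope=hill)
        assert curve.lower == pytest.approx(0.0, abs=1e-4 * response.smax)
        assert curve.upper == pytest.approx(response.smax, rel=1e-4)
        assert curve.midpoint_concentration == pytest.approx(response.k_ug_ml, rel=1e-4)
        assert curve.slope == pytest.approx(response.hill, rel=1e-4)


class TestExtractionTimecourse:
    def test_strictly_decreasing_without_jitter(self, noiseless):
        rows = cs.simulate_extraction_timecourse(noise=noiseless)
        values = [v for _, v in rows]
        assert [t for t, _ in rows] == [0.0, 1.0, 2.0, 3.0, 4.0]
        assert np.all(np.diff(values) < 0)

    def test_vanishing_decay_rate_limit_is_constant(self, noiseless):
        rows = cs.simulate_extraction_timecourse(
            decay_rate_per_min=1e-12, noise=noiseless
        )
        values = np.array([v for _, v in rows])
        np.testing.assert_allclose(values, values[0], rtol=1e-9)

    def test_matches_exponential_decay_oracle(self, noiseless):
        baseline, rate = 2.0, 0.5
        rows = cs.simulate_extraction_timecourse(
            decay_rate_per_min=rate, baseline_concentration=baseline, noise=noiseless
        )
        for t, v in rows:
            assert v == pytest.approx(baseline * np.exp(-rate * t), rel=RESAMPLE_RTOL,
                                      abs=1e-8)


class TestControlLoop:
    def test_starting_at_target_settles_immediately(self):
        traj = cs.simulate_control_loop(cs.ControlLoopConfig(initial_fraction=1.0))
        assert traj.settled and traj.settling_time_s == 0.0

    @pytest.mark.parametrize("fraction", [0.5, 0.75, 1.0, 1.25, 1.5])
    def test_all_initial_fractions_settle_within_4s(self, fraction):
        traj = cs.simulate_control_loop(cs.ControlLoopConfig(initial_fraction=fraction))
        assert traj.settled
        assert traj.settling_time_s <= 4.0

    def test_post_settling_excursions_within_one_percent(self):
        config = cs.ControlLoopConfig(initial_fraction=0.5)
        traj = cs.simulate_control_loop(config)
        settled = traj.time_s >= traj.settling_time_s
        excursions = np.abs(traj.intensity[settled] - config.target_intensity)
        assert np.all(excursions <= 0.01 * config.target_intensity)

    def test_unstable_gains_reported_as_non_settling(self):
        traj = cs.simulate_control_loop(
            cs.ControlLoopConfig(initial_fraction=0.5, kp=25.0, ki=0.0)
        )
        assert not traj.settled and traj.settling_time_s is None


class TestRepeatability:
    def test_zero_jitter_gives_zero_cv(self, noiseless):
        study = cs.simulate_repeatability_study(replicates=3, noise=noiseless, seed=1)
        for values in study.values():
            assert cs.coefficient_of_variation(values) == pytest.approx(0.0, abs=1e-9)

    def test_one_percent_jitter_keeps_cv_within_five_percent(self):
        study = cs.simulate_repeatability_study(
            noise=cs.NoiseModel(jitter=0.01, seed=1), seed=1
        )
        cvs = [cs.coefficient_of_variation(v) for v in study.values()]
        assert max(cvs) <= 5.0

    def test_fixed_seed_reproduces_cvs(self):
        noise = cs.NoiseModel(jitter=0.01, seed=2)
        a = cs.simulate_repeatability_study(noise=noise, seed=3)
        b = cs.simulate_repeatability_study(noise=noise, seed=3)
        for level in a:
            np.testing.assert_array_equal(a[level], b[level])


class TestCohort:
    def test_group_sizes_match_design(self):
        records = cs.simulate_cohort(cs.CohortConfig(seed=0))
        counts = {g: sum(r.group == g for r in records) for g in ("normal", "risk", "disease")}
        assert counts == {"normal": 115, "risk": 117, "disease": 110}

    def test_auc_monotone_in_effect_size(self):
        aucs = []
        for ratio in (1.0, 1.25, 1.5, 2.0):
            vals = []
            for seed in range(20):
                records = cs.simulate_cohort(cs.CohortConfig(seed=seed, disease_ratio=ratio))
                normal = [r.device_value for r in records if r.group == "normal"]
                disease = [r.device_value for r in records if r.group == "disease"]
                rep = cs.roc_auc_with_ci(
                    normal + disease, [0] * len(normal) + [1] * len(disease)
                )
                vals.append(rep.auc)
            aucs.append(np.mean(vals))
        assert np.all(np.diff(aucs) > 0)

    def test_reference_exact_offset_without_noise(self):
        config = cs.CohortConfig(seed=0, ref_diff_sd=0.0)
        records = cs.simulate_reference_method(cs.simulate_cohort(config), config)
        for r in records:
            assert r.reference_value - r.device_value == pytest.approx(72.78)

    def test_noiseless_reference_perfectly_correlated(self):
        config = cs.CohortConfig(seed=0, ref_offset=0.0, ref_diff_sd=0.0)
        records = cs.simulate_reference_method(cs.simulate_cohort(config), config)
        device = np.array([r.device_value for r in records])
        ref = np.array([r.reference_value for r in records])
        assert cs.pearson_correlation(cs.PairedSample(device, ref)) == pytest.approx(1.0)

    def test_bland_altman_bias_within_sampling_error(self):
        config = cs.CohortConfig(seed=11)
        records = cs.simulate_accuracy_pairs(config)
        assert len(records) == 73
        report = cs.run_accuracy_study(records)
        se = config.ref_diff_sd / np.sqrt(config.n_accuracy)
        assert abs(report.agreement.bias - (-72.78)) <= 3.0 * se
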