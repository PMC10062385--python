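"""Preprocessing oracles: closed forms, conservation laws, planted-transform recovery."""
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ramanmargin.spectra import RawAcquisition, Spectrum, default_axis
from ramanmargin.preprocess import (
    apply_calibration,
    average_accumulations,
    bubblefill,
    correct_instrument_response,
    fit_calibration,
    run_pipeline,
    snv,
    subtract_dark,
)
from ramanmargin.synthetic import (
    CohortSpec,
    generate_acquisition,
    generate_polycarbonate,
    render_signature,
)


def _acq(repeats, darks=None, axis=None):
    repeats = np.atleast_2d(np.asarray(repeats, dtype=float))
    if axis is None:
        axis = np.arange(repeats.shape[1], dtype=float) + 600.0
    if darks is None:
        darks = np.zeros((1, repeats.shape[1]))
    return RawAcquisition(axis, repeats, darks, exposure_s=1.0)


class TestAveraging:
    def test_identical_repeats_pass_through(self):
        v = np.array([1.0, 5.0, 2.0])
        s = average_accumulations(_acq(np.tile(v, (10, 1))))
        np.testing.assert_array_equal(s.intensities, v)
        assert s.stage == "averaged"

    def test_closed_form_mean(self):
        s = average_accumulations(_acq([[1.0, 3.0], [3.0, 1.0]]))
        np.testing.assert_array_equal(s.intensities, [2.0, 2.0])

    def test_noise_reduction_scales_as_sqrt_n(self):
        rng = np.random.default_rng(0)
        sigma, n_rep, trials = 1.0, 10, 100
        sds = []
        for _ in range(trials):
            noise = rng.normal(0, sigma, size=(n_rep, 64))
            sds.append(average_accumulations(_acq(noise)).intensities.std())
        observed = np.mean(sds)
        assert abs(observed - sigma / np.sqrt(n_rep)) / (sigma / np.sqrt(n_rep)) < 0.15


class TestDarkSubtraction:
    def test_zero_darks_leave_spectrum_unchanged(self):
        s = average_accumulations(_acq([[4.0, 4.0]]))
        out = subtract_dark(s, np.zeros((2, 2)))
        np.testing.assert_array_equal(out.intensities, s.intensities)

    def test_mean_of_darks_subtracted(self):
        s = average_accumulations(_acq([[5.0, 5.0]]))
        out = subtract_dark(s, [[1.0, 1.0], [3.0, 3.0]])
        np.testing.assert_array_equal(out.intensities, [3.0, 3.0])

    def test_generator_dark_offset_removed(self, profiles):
        spec = CohortSpec(noise_sd=2.0, baseline_scale=0.0, raman_counts=0.0,
                          dark_counts=100.0, n_accumulations=50, n_darks=20,
                          measurement_effect_sd=0.0)
        acq = generate_acquisition(profiles, "normal", None, spec, seed=1)
        out = subtract_dark(average_accumulations(acq), acq.darks)
        assert abs(out.intensities.mean()) < 1.0  # residual offset within noise

    def test_shape_mismatch_rejected(self):
        s = average_accumulations(_acq([[1.0, 2.0]]))
        with pytest.raises(ValueError):
            subtract_dark(s, [[1.0, 2.0, 3.0]])


class TestResponseCorrection:
    def test_flat_response_identity(self):
        s = average_accumulations(_acq([[2.0, 4.0, 6.0]]))
        certified = np.array([1.0, 2.0, 3.0])
        out = correct_instrument_response(s, certified.copy(), certified)
        np.testing.assert_allclose(out.intensities, s.intensities)

    def test_exact_cancellation_of_known_response(self):
        true_signal = np.array([1.0, 2.0, 3.0, 4.0])
        r = np.array([0.5, 1.0, 2.0, 1.5])
        certified = np.full(4, 2.0)
        s = average_accumulations(_acq([true_signal * r]))
        out = correct_instrument_response(s, certified * r, certified)
        np.testing.assert_allclose(out.intensities, true_signal, rtol=1e-12)

    def test_nonpositive_certified_rejected(self):
        s = average_accumulations(_acq([[1.0, 1.0]]))
        with pytest.raises(ValueError, match="positive"):
            correct_instrument_response(s, np.ones(2), np.array([1.0, 0.0]))

    def test_hidden_generator_response_recovered(self, axis, standard, profiles):
        spec = CohortSpec(noise_sd=0.0, dark_counts=0.0, measurement_effect_sd=0.0)
        acq = generate_acquisition(profiles, "cancer", None, spec, seed=3, exposure_s=1.0)
        # imprint the hidden response on the clean signal
        distorted = RawAcquisition(axis, acq.repeats * standard.response, acq.darks, exposure_s=1.0)
        s = average_accumulations(distorted)
        out = correct_instrument_response(s, standard.measured, standard.certified)
        truth = acq.repeats[0]
        rel_err = np.max(np.abs(out.intensities - truth) / np.abs(truth))
        assert rel_err < 0.02


class TestCalibration:
    def test_zero_shift_gives_identity_map(self, axis):
        model = fit_calibration(generate_polycarbonate(axis, true_shift=0.0, seed=0))
        assert model.max_abs_residual < 0.5
        mapped = model(axis)
        assert np.max(np.abs(mapped - axis)) < 0.5

    def test_planted_shift_recovered(self, axis):
        poly = generate_polycarbonate(axis, true_shift=2.0, seed=1)
        model = fit_calibration(poly)
        recovered = float(np.mean(model.matched_observed - model.matched_reference))
        assert abs(recovered - 2.0) < 0.2

    def test_planted_affine_recovered(self, axis):
        poly = generate_polycarbonate(axis, true_shift=1.0, scale=1.001, seed=2)
        model = fit_calibration(poly)
        a, b = model.coefficients[1], model.coefficients[0]  # ref = a*obs + b
        scale_hat, shift_hat = 1.0 / a, -b / a
        assert abs(scale_hat - 1.001) < 0.001 * 0.05 + 5e-4
        assert abs(shift_hat - 1.0) < 0.3

    def test_too_few_peaks_rejected(self, axis):
        flat = Spectrum(axis, np.ones_like(axis))
        with pytest.raises(ValueError):
            fit_calibration(flat)

    def test_applying_model_keeps_reference_peaks_within_half_wavenumber(self, axis):
        poly = generate_polycarbonate(axis, true_shift=1.5, seed=3)
        model = fit_calibration(poly)
        resampled = apply_calibration(
            average_accumulations(_acq([poly.intensities], axis=axis)), model
        )
        from ramanmargin.synthetic import POLYCARBONATE_PEAKS

        for p in POLYCARBONATE_PEAKS:
            window = (resampled.wavenumbers > p - 15) & (resampled.wavenumbers < p + 15)
            peak_pos = resampled.wavenumbers[window][np.argmax(resampled.intensities[window])]
            assert abs(peak_pos - p) <= resampled.spacing / 2 + 0.5


class TestBubbleFill:
    def test_pure_line_leaves_no_raman(self, axis):
        line = 3000.0 - 1.2 * axis
        fit = bubblefill(Spectrum(axis, line))
        assert np.max(np.abs(fit.raman)) < 0.01 * np.ptp(line)

    def test_narrow_peak_survives_baseline_removal(self, axis):
        peak = np.exp(-4 * np.log(2) * ((axis - 1004.0) / 12.0) ** 2)
        fit = bubblefill(Spectrum(axis, peak))
        assert np.corrcoef(fit.raman, peak)[0, 1] > 0.99

    def test_generator_oracle_baseline_plus_bands(self, axis, profiles):
        spec = CohortSpec(noise_sd=0.0, dark_counts=0.0, measurement_effect_sd=0.0)
        acq = generate_acquisition(profiles, "cancer", None, spec, seed=11, exposure_s=1.0)
        truth = spec.raman_counts * render_signature(axis, profiles, "cancer")
        fit = bubblefill(Spectrum(axis, acq.repeats[0]))
        assert np.corrcoef(fit.raman, truth)[0, 1] > 0.99

    def test_decomposition_reconstructs_input_exactly(self, axis, profiles):
        spec = CohortSpec(noise_sd=40.0)
        acq = generate_acquisition(profiles, "fat", None, spec, seed=12)
        y = acq.repeats[0]
        fit = bubblefill(Spectrum(axis, y))
        np.testing.assert_allclose(fit.baseline + fit.raman, y, rtol=0, atol=1e-9)

    def test_too_short_spectrum_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            bubblefill(Spectrum(np.arange(10.0), np.ones(10)), min_bubble_width=50.0)


class TestSNV:
    def test_closed_form(self):
        s = Spectrum(np.arange(3.0), [1.0, 2.0, 3.0], stage="baseline_removed")
        np.testing.assert_allclose(snv(s).intensities, [-1.0, 0.0, 1.0])

    @given(st.lists(st.floats(-1e4, 1e4), min_size=8, max_size=64))
    def test_output_statistics_exact(self, values):
        arr = np.asarray(values)
        if np.std(arr, ddof=1) < 1e-6:
            return
        out = snv(Spectrum(np.arange(len(arr), dtype=float), arr, stage="baseline_removed"))
        assert abs(out.intensities.mean()) < 1e-10
        assert abs(out.intensities.std(ddof=1) - 1.0) < 1e-10

    @given(
        st.floats(0.1, 50.0),
        st.floats(-100.0, 100.0),
    )
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(0)
        x = rng.normal(size=32)
        s1 = snv(Spectrum(np.arange(32.0), x, stage="baseline_removed"))
        s2 = snv(Spectrum(np.arange(32.0), a * x + b, stage="baseline_removed"))
        np.testing.assert_allclose(s1.intensities, s2.intensities, atol=1e-8)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            snv(Spectrum(np.arange(4.0), np.ones(4), stage="baseline_removed"))


class TestPipeline:
    def test_noise_free_end_to_end_matches_snv_of_band_sum(self, standard, calibration, profiles):
        spec = CohortSpec(noise_sd=0.0, measurement_effect_sd=0.0)
        acq = generate_acquisition(profiles, "cancer", None, spec, seed=5, exposure_s=1.0)
        out = run_pipeline(acq, standard, calibration)
        truth = render_signature(out.wavenumbers, profiles, "cancer")
        truth_snv = (truth - truth.mean()) / truth.std(ddof=1)
        assert out.stage == "snv"
        assert np.corrcoef(out.intensities, truth_snv)[0, 1] > 0.99

    def test_pipeline_deterministic(self, standard, calibration, profiles, cohort_spec):
        acq = generate_acquisition(profiles, "normal", None, cohort_spec, seed=6)
        a = run_pipeline(acq, standard, calibration)
        b = run_pipeline(acq, standard, calibration)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_scale_equivariance_through_terminal_snv(self, standard, calibration, profiles):
        spec = CohortSpec(noise_sd=0.0, measurement_effect_sd=0.0)
        acq = generate_acquisition(profiles, "fat", None, spec, seed=8, exposure_s=1.0)
        scaled = RawAcquisition(
            acq.wavenumbers, acq.repeats * 3.7, acq.darks * 3.7, exposure_s=acq.exposure_s
        )
        a = run_pipeline(acq, standard, calibration)
        b = run_pipeline(scaled, standard, calibration)
        np.testing.assert_allclose(a.intensities, b.intensities, atol=1e-8)

    def test_baseline_ablation_leaves_baseline_shape(self, standard, calibration, profiles):
        from ramanmargin.preprocess import PreprocessConfig

        spec = CohortSpec(noise_sd=0.0, raman_counts=0.0, measurement_effect_sd=0.0)
        acq = generate_acquisition(profiles, "normal", None, spec, seed=9, exposure_s=1.0)
        out = run_pipeline(acq, standard, calibration, PreprocessConfig(baseline_removal=False))
        # pure-baseline input with step (5) disabled: the output keeps the
        # (dark-subtracted, response-corrected) baseline shape
        corrected = (acq.repeats[0] - spec.dark_counts) / standard.response
        baseline_truth = np.interp(out.wavenumbers, acq.wavenumbers, corrected)
        assert np.corrcoef(out.intensities, baseline_truth)[0, 1] > 0.9

    def test_step_errors_name_the_stage(self, standard, calibration):
        bad = RawAcquisition(np.arange(20.0) + 600, np.ones((2, 20)), np.zeros((1, 20)), 1.0)
        with pytest.raises(ValueError, match="pipeline failed at"):
            run_pipeline(bad, standard, calibration)
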