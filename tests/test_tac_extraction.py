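"""Input-ROI detection, TAC extraction, peak splitting and gamma fitting."""

import math

import numpy as np
import pytest

from ecdquant.core_model import DynamicPlanarSeries, TimeActivityCurve, roi_mask
from ecdquant.synthetic_acquisition import (
    GammaParams,
    gamma_integral,
    gamma_peak_time,
    gamma_values,
)
from ecdquant.tac_extraction import (
    GammaFit,
    detect_aorta_roi,
    extract_tac,
    fit_gamma,
    input_counts,
    split_peaks,
)


def _series(frames):
    return DynamicPlanarSeries(frames=np.asarray(frames, float), frame_duration_s=1.0)


class TestDetectAortaRoi:
    def test_finds_simulated_aorta_pixel(self, bundle):
        roi = detect_aorta_roi(bundle.series)
        assert roi.center == bundle.truth.aorta_center

    def test_survives_poisson_noise_nearby(self, noisy_bundle):
        roi = detect_aorta_roi(noisy_bundle.series)
        dr = roi.center[0] - noisy_bundle.truth.aorta_center[0]
        dc = roi.center[1] - noisy_bundle.truth.aorta_center[1]
        assert dr * dr + dc * dc <= 2

    def test_tie_breaks_earlier_frame_then_row_major(self):
        frames = np.zeros((3, 8, 8))
        frames[2, 1, 1] = 5.0  # late maximum
        frames[0, 4, 4] = 5.0  # same value, earlier frame -> wins
        roi = detect_aorta_roi(_series(frames), diameter_px=1)
        assert roi.center == (4, 4)
        frames2 = np.zeros((2, 8, 8))
        frames2[0, 3, 6] = 5.0
        frames2[0, 3, 2] = 5.0  # simultaneous: smaller (row, col) wins
        roi2 = detect_aorta_roi(_series(frames2), diameter_px=1)
        assert roi2.center == (3, 2)

    def test_zero_series_rejected(self):
        with pytest.raises(ValueError, match="no signal"):
            detect_aorta_roi(_series(np.zeros((4, 8, 8))))

    def test_background_invariance_and_translation_equivariance(self, bundle):
        """Adding a constant offset leaves the argmax unchanged; rolling the
        scene rolls the detected center."""
        frames = bundle.series.frames
        offset = DynamicPlanarSeries(frames=frames + 7.0, frame_duration_s=1.0)
        assert detect_aorta_roi(offset).center == bundle.truth.aorta_center
        rolled = DynamicPlanarSeries(
            frames=np.roll(frames, (3, -2), axis=(1, 2)), frame_duration_s=1.0
        )
        r0, c0 = bundle.truth.aorta_center
        assert detect_aorta_roi(rolled).center == (r0 + 3, c0 - 2)


class TestExtractTac:
    def test_single_pixel_identity(self):
        frames = np.zeros((5, 8, 8))
        frames[:, 1, 2] = np.arange(1, 6)
        roi = roi_mask((1, 2), 1, (8, 8))
        tac = extract_tac(_series(frames), roi)
        assert np.array_equal(tac.counts, [1, 2, 3, 4, 5])
        assert np.array_equal(tac.times_s, np.arange(5) + 0.5)

    def test_constant_frames_linearity(self):
        frames = np.full((4, 16, 16), 3.0)
        roi = roi_mask((8, 8), 4, (16, 16))
        tac = extract_tac(_series(frames), roi)
        assert np.allclose(tac.counts, roi.n_pixels * 3.0)

    def test_simulated_aorta_tac_matches_forward_model(self, bundle):
        """Noiseless: the input-ROI TAC equals the aortic gamma curve plus
        the pulmonary contamination, sampled at frame midpoints."""
        roi = detect_aorta_roi(bundle.series)
        tac = extract_tac(bundle.series, roi)
        aorta = gamma_values(bundle.truth.input_params, tac.times_s)
        # shortly after the pulmonary transit its tail still adds a few
        # counts; by t > 25 s the aortic term dominates to high precision
        mid = (tac.times_s > 12.0) & (tac.times_s <= 25.0)
        assert np.allclose(tac.counts[mid], aorta[mid], rtol=5e-3)
        late = tac.times_s > 25.0
        assert np.allclose(tac.counts[late], aorta[late], rtol=1e-5, atol=1e-3)

    def test_mismatched_grid_rejected(self, bundle):
        roi = roi_mask((2, 2), 4, (16, 16))
        with pytest.raises(ValueError, match="does not match"):
            extract_tac(bundle.series, roi)


class TestSplitPeaks:
    def test_windows_bracket_the_true_peaks(self, bundle):
        roi = detect_aorta_roi(bundle.series)
        tac = extract_tac(bundle.series, roi)
        split = split_peaks(tac)
        t = tac.times_s
        pulm_peak = gamma_peak_time(bundle.truth.pulmonary_params)
        aorta_peak = gamma_peak_time(bundle.truth.input_params)
        f0, f1 = split.first_peak_window
        s0, s1 = split.second_peak_window
        assert t[f0] <= pulm_peak <= t[f1]
        assert t[s0] <= aorta_peak <= t[s1 - 1]
        assert f1 <= s0  # disjoint, ordered

    def test_monotone_curve_rejected(self):
        tac = TimeActivityCurve(
            times_s=np.arange(20) + 0.5, counts=np.linspace(0, 10, 20)
        )
        with pytest.raises(ValueError, match="fewer than two peaks"):
            split_peaks(tac)

    def test_heavily_overlapped_peaks_warn_but_return(self):
        t = np.arange(40) + 0.5
        # two maxima of height 1.0 separated by a shallow valley at 0.92:
        # above 90% of the first peak, i.e. heavily overlapped boluses
        y = np.concatenate(
            [
                np.linspace(0.0, 1.0, 11),
                np.linspace(1.0, 0.92, 6)[1:],
                np.linspace(0.92, 1.0, 6)[1:],
                np.linspace(1.0, 0.0, 20)[1:],
            ]
        )
        tac = TimeActivityCurve(times_s=t, counts=y)
        with pytest.warns(UserWarning, match="heavily overlapped"):
            split = split_peaks(tac, smooth_window=1)
        assert split.second_peak_window[1] > split.second_peak_window[0]


class TestFitGamma:
    def test_noiseless_recovery_to_four_significant_figures(self):
        true = GammaParams(5.0, 2.0, 3.0, 4.0)
        t = np.arange(120) + 0.5
        tac = TimeActivityCurve(times_s=t, counts=gamma_values(true, t))
        fit = fit_gamma(tac, window=(4, 60))
        assert fit.converged
        assert fit.params.k_scale == pytest.approx(5.0, rel=1e-4)
        assert fit.params.alpha_shape == pytest.approx(2.0, rel=1e-4)
        assert fit.params.beta_scale_s == pytest.approx(3.0, rel=1e-4)
        assert fit.params.t0_s == pytest.approx(4.0, abs=1e-3)
        assert fit.integral_counts == pytest.approx(gamma_integral(true), rel=1e-4)

    def test_integral_is_closed_form_of_fitted_params(self):
        true = GammaParams(1.0, 1.0, 2.0, 0.0)
        t = np.linspace(0.25, 30, 120)
        tac = TimeActivityCurve(times_s=t, counts=gamma_values(true, t))
        fit = fit_gamma(tac)
        assert fit.integral_counts == pytest.approx(4.0, rel=1e-5)

    def test_poisson_noise_monte_carlo_integral_recovery(self):
        """Median relative error of the input counts stays below 5% at a
        realistic ~1e3 counts/frame peak over 100 noise realizations."""
        true = GammaParams(127.0, 3.0, 1.8, 9.0)  # peak ~1e3 counts/frame
        t = np.arange(120) + 0.5
        clean = gamma_values(true, t)
        truth_integral = gamma_integral(true)
        errors = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = rng.poisson(clean).astype(float)
            tac = TimeActivityCurve(times_s=t, counts=noisy)
            fit = fit_gamma(tac, window=(8, 40))
            errors.append(abs(fit.integral_counts - truth_integral) / truth_integral)
        assert np.median(errors) < 0.05

    def test_window_too_small_rejected(self):
        t = np.arange(10) + 0.5
        tac = TimeActivityCurve(times_s=t, counts=np.ones(10))
        with pytest.raises(ValueError, match="at least 5 samples"):
            fit_gamma(tac, window=(0, 4))

    def test_scale_equivariance(self):
        """Scaling all counts by c scales the fitted integral by c."""
        true = GammaParams(2.0, 2.5, 1.5, 6.0)
        t = np.arange(60) + 0.5
        y = gamma_values(true, t)
        f1 = fit_gamma(TimeActivityCurve(times_s=t, counts=y), window=(5, 40))
        f2 = fit_gamma(TimeActivityCurve(times_s=t, counts=3.0 * y), window=(5, 40))
        assert f2.integral_counts == pytest.approx(3.0 * f1.integral_counts, rel=1e-6)

    def test_analytic_integral_dominates_windowed_trapezoid(self, bundle):
        roi = detect_aorta_roi(bundle.series)
        tac = extract_tac(bundle.series, roi)
        split = split_peaks(tac)
        fit = fit_gamma(tac, window=split.second_peak_window)
        w0, w1 = split.second_peak_window
        t = tac.times_s[w0:w1]
        quad = np.trapezoid(gamma_values(fit.params, t), t)
        assert fit.integral_counts >= quad


class TestInputCounts:
    @pytest.mark.parametrize(
        "params, expected",
        [
            (GammaParams(1.0, 1.0, 1.0, 0.0), 1.0),  # Gamma(2) = 1
            (GammaParams(1.0, 1.0, 1.0, 7.0), 1.0),  # t0 does not matter
            (GammaParams(1.0, 0.5, 1.0, 0.0), math.gamma(1.5)),
            (GammaParams(2.0, 1.0, 1.0, 0.0), 2.0),  # linear in K
        ],
    )
    def test_closed_forms(self, params, expected):
        fit = GammaFit.from_params(params)
        assert input_counts(fit) == pytest.approx(expected, rel=1e-9)

    def test_unconverged_fit_rejected(self):
        fit = GammaFit(
            params=GammaParams(1.0, 1.0, 1.0, 0.0),
            rss=np.inf,
            converged=False,
            integral_counts=1.0,
        )
        with pytest.raises(ValueError, match="unconverged"):
            input_counts(fit)
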