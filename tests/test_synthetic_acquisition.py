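"""Forward-model correctness of the synthetic acquisition simulator."""

import math

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

from ecdquant.core_model import roi_mask
from ecdquant.ibur_quant import LassenParams, lassen_correct, segment_mean_counts
from ecdquant.synthetic_acquisition import (
    GammaParams,
    GridSpec,
    gamma_curve,
    gamma_integral,
    gamma_peak_time,
    make_ground_truth,
    simulate_cohort,
    simulate_subject,
)
from ecdquant.tac_extraction import extract_tac


class TestGammaCurve:
    def test_peak_location_and_value_closed_form(self):
        """dC/dt = 0 at t0 + alpha*beta; unit parameters peak at e^-1."""
        params = GammaParams(1.0, 1.0, 1.0, 0.0)
        t = np.linspace(0.01, 10, 5000)
        tac = gamma_curve(params, t)
        assert gamma_peak_time(params) == 1.0
        i = np.argmax(tac.counts)
        assert t[i] == pytest.approx(1.0, abs=0.01)
        assert tac.counts[i] == pytest.approx(math.exp(-1), abs=1e-4)

    def test_zero_before_appearance_time(self):
        params = GammaParams(3.0, 2.0, 1.5, 5.0)
        tac = gamma_curve(params, np.linspace(0.5, 12, 30))
        assert np.all(tac.counts[tac.times_s <= 5.0] == 0)

    @pytest.mark.parametrize(
        "params, expected",
        [
            (GammaParams(1.0, 1.0, 2.0, 0.0), 4.0),  # K*b^(a+1)*Gamma(a+1)
            (GammaParams(1.0, 0.5, 1.0, 3.0), math.gamma(1.5)),
            (GammaParams(2.0, 3.0, 1.5, 0.0), 2.0 * 1.5**4 * 6.0),
        ],
    )
    def test_analytic_integral(self, params, expected):
        assert gamma_integral(params) == pytest.approx(expected, rel=1e-12)
        # and the closed form dominates any finite-window quadrature
        t = np.linspace(params.t0_s, params.t0_s + 120, 4000)
        quad = np.trapezoid(gamma_curve(params, t[1:]).counts, t[1:])
        assert gamma_integral(params) >= quad

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GammaParams(-1.0, 1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            GammaParams(1.0, 1.0, 0.0, 0.0)


class TestSimulateSubject:
    def test_noiseless_runs_are_identical(self):
        truth = make_ground_truth(35.0, seed=2)
        a = simulate_subject(truth, noise="none", seed=11)
        b = simulate_subject(truth, noise="none", seed=99)
        assert np.array_equal(a.series.frames, b.series.frames)
        assert np.array_equal(a.spect.voxels, b.spect.voxels)

    def test_poisson_is_reproducible_from_seed(self):
        truth = make_ground_truth(35.0, seed=2)
        a = simulate_subject(truth, noise="poisson", seed=5)
        b = simulate_subject(truth, noise="poisson", seed=5)
        assert np.array_equal(a.series.frames, b.series.frames)
        assert np.array_equal(a.spect.voxels, b.spect.voxels)

    def test_uniform_flow_gives_uniform_spect(self):
        """Equal flows are a fixed point of the inverse Lassen transform."""
        truth = make_ground_truth(35.0, seed=0, flow_cv=0.0)
        truth.segment_flow = {s: 35.0 for s in truth.segment_flow}
        b = simulate_subject(truth, noise="none", seed=0)
        vals = list(b.truth.segment_counts.values())
        assert np.ptp(vals) < 1e-9 * vals[0]
        nz = b.spect.voxels[b.template.labels > 0]
        assert np.ptp(nz) < 1e-9 * nz.mean()

    def test_poisson_mean_matches_noiseless_frames(self):
        """Monte-Carlo check of the Poisson law on the planar frames."""
        truth = make_ground_truth(35.0, seed=4)
        grid = GridSpec(n_frames=40)
        clean = simulate_subject(truth, grid=grid, noise="none", seed=0)
        n_rep = 200
        acc = np.zeros_like(clean.series.frames)
        for rep in range(n_rep):
            noisy = simulate_subject(truth, grid=grid, noise="poisson", seed=1000 + rep)
            acc += noisy.series.frames
        mean = acc / n_rep
        se = np.sqrt(np.maximum(clean.series.frames, 1e-12) / n_rep)
        signal = clean.series.frames > 5.0
        z = (mean[signal] - clean.series.frames[signal]) / se[signal]
        # averaged over all signal pixels the z-scores must be centred
        assert abs(z.mean()) < 3.0 / np.sqrt(z.size) * 3
        assert np.mean(np.abs(z) < 3) > 0.99

    def test_flow_below_calibration_floor_rejected(self):
        truth = make_ground_truth(20.0, seed=0)
        truth.segment_flow["anterior_left"] = 1.0
        with pytest.raises(ValueError, match="below the calibration floor"):
            simulate_subject(truth, noise="none", seed=0)


class TestForwardModelOracles:
    def test_brain_counts_conserve_input_integral(self, bundle):
        """Microsphere kinetics: late hemispheric counts equal Ku times the
        cumulative arterial integral (noiseless)."""
        cfg = bundle.config
        arch = roi_mask(
            cfg.arch_roi_center, cfg.arch_roi_diameter_px, bundle.series.grid_shape
        )
        hemi = roi_mask(
            cfg.hemisphere_roi_center,
            cfg.hemisphere_roi_diameter_px,
            bundle.series.grid_shape,
        )
        ca = extract_tac(bundle.series, arch)
        cb = extract_tac(bundle.series, hemi)
        integral = cumulative_trapezoid(ca.counts, ca.times_s, initial=0.0)
        expected = bundle.truth.ku_true * integral[-1]
        assert cb.counts[-1] == pytest.approx(expected, rel=1e-6)

    def test_lassen_round_trip_linearizes_segment_counts(self, bundle):
        """Correcting the noiseless SPECT means with the true alpha must
        reproduce counts linear in the uptake ratio (flow minus the
        calibration floor) to 0.1%."""
        means = segment_mean_counts(bundle.spect, bundle.template)
        corrected = lassen_correct(
            means,
            LassenParams(
                alpha=bundle.truth.lassen_alpha_true,
                reference_segments=("lenticular_nucleus_left", "thalamus_left"),
            ),
        )
        flows = bundle.truth.segment_flow
        ratios = np.array(
            [corrected[s] / (flows[s] - 4.66) for s in corrected]
        )
        assert np.ptp(ratios) / ratios.mean() < 1e-3

    def test_spect_segment_means_match_generated_counts(self, bundle):
        means = segment_mean_counts(bundle.spect, bundle.template)
        for s, c in bundle.truth.segment_counts.items():
            assert means[s] == pytest.approx(c, rel=1e-3)


class TestSimulateCohort:
    def test_cohort_flows_within_range_and_sized(self, cohort):
        assert len(cohort) == 15
        for b in cohort:
            assert 19.0 <= b.truth.true_mcbf <= 45.0

    def test_point_range_pins_the_flow(self):
        (b,) = simulate_cohort(n_subjects=1, flow_range=(40.0, 40.0), seed=3)
        assert b.truth.true_mcbf == pytest.approx(40.0)

    def test_same_seed_reproduces_cohort(self):
        a = simulate_cohort(n_subjects=2, seed=21)
        b = simulate_cohort(n_subjects=2, seed=21)
        for x, y in zip(a, b):
            assert np.array_equal(x.series.frames, y.series.frames)
            assert x.truth.segment_flow == y.truth.segment_flow

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(n_subjects=0)
        with pytest.raises(ValueError):
            simulate_cohort(flow_range=(5.0, 45.0))
        with pytest.raises(ValueError):
            simulate_cohort(flow_range=(45.0, 19.0))
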