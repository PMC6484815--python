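"""Synthetic-data generator: analytic landmarks, determinism, calibration."""

import json
import math

import numpy as np
import pytest
from scipy.stats import truncnorm

from icgquant import (
    CohortSpec,
    FrameStackSpec,
    InvalidSpecificationError,
    KineticTruth,
    PerfusionCurve,
    gamma_for_tr,
    generate_cohort,
    generate_curve,
    generate_frame_stack,
)
from icgquant import reference

from conftest import GAMMA_GRID


class TestKineticTruth:
    @pytest.mark.parametrize("gamma", GAMMA_GRID)
    def test_analytic_tr_matches_brute_force_half_crossing(self, gamma):
        """TR = 0.5 ** (1/gamma) agrees with a 1 ms grid scan of the rise."""
        truth = KineticTruth(shape_gamma=gamma, rise_duration=30.0,
                             onset_t0=0.0, amplitude_a=60.0)
        tt = np.arange(0.0, 30.0, 1e-3)
        vals = truth.value(tt)
        half = truth.baseline_f0 + 0.5 * truth.amplitude_a
        t_half_scan = tt[np.nonzero(vals >= half)[0][0]]
        assert truth.tr == pytest.approx(0.5 ** (1.0 / gamma), abs=1e-12)
        assert truth.t_half_max == pytest.approx(t_half_scan, abs=2e-3)
        assert 0.0 < truth.tr < 1.0

    def test_analytic_identities(self):
        truth = KineticTruth(amplitude_a=45.0, rise_duration=20.0)
        assert truth.t_max == 20.0  # rise duration, washout 0
        assert truth.slope == pytest.approx(45.0 / 20.0)
        assert truth.t_half_max == pytest.approx(truth.t_max * truth.tr)

    def test_gamma_for_tr_inverts_tr(self):
        for tr in (0.1, 0.4, 0.5, 0.6, 0.9):
            assert KineticTruth(shape_gamma=gamma_for_tr(tr)).tr == pytest.approx(tr)
        with pytest.raises(InvalidSpecificationError):
            gamma_for_tr(1.0)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(amplitude_a=-1.0), dict(rise_duration=0.0),
         dict(shape_gamma=0.0), dict(onset_t0=-1.0), dict(noise_sd=-0.1)],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(InvalidSpecificationError):
            KineticTruth(**kwargs)


class TestGenerateCurve:
    def test_linear_rise_has_midpoint_half_max(self, linear_curve, linear_truth):
        """gamma=1, 30 s rise: half-max at 15 s, TR 0.5 analytically."""
        assert linear_truth.t_half_max == pytest.approx(15.0)
        assert linear_truth.tr == pytest.approx(0.5)
        # sampled values follow the piecewise trajectory exactly
        t = linear_curve.times
        expected = linear_truth.value(t)
        np.testing.assert_allclose(linear_curve.intensities, expected)

    def test_complication_group_calibration_curve(self):
        """gamma = ln 0.5 / ln 0.6 and a 64 s rise give TR 0.6, T_MAX 64."""
        truth = KineticTruth(shape_gamma=gamma_for_tr(0.6), rise_duration=64.0)
        assert truth.tr == pytest.approx(0.6, abs=1e-12)
        assert truth.t_max == 64.0
        assert truth.shape_gamma == pytest.approx(
            math.log(0.5) / math.log(0.6), abs=1e-12
        )

    def test_zero_amplitude_gives_flat_baseline(self):
        truth = KineticTruth(amplitude_a=0.0, noise_sd=0.0, baseline_f0=7.5)
        curve = generate_curve(truth, 10.0, 60.0)
        assert np.all(curve.intensities == 7.5)

    def test_sample_times_are_frame_index_over_rate(self):
        curve = generate_curve(KineticTruth(), 4.0, 60.0)
        np.testing.assert_allclose(curve.times, np.arange(len(curve)) / 4.0)
        assert curve.frame_rate == 4.0

    def test_same_seed_same_curve(self):
        truth = KineticTruth(noise_sd=2.0)
        a = generate_curve(truth, 10.0, 60.0, seed=11)
        b = generate_curve(truth, 10.0, 60.0, seed=11)
        np.testing.assert_array_equal(a.intensities, b.intensities)
        c = generate_curve(truth, 10.0, 60.0, seed=12)
        assert not np.array_equal(a.intensities, c.intensities)

    def test_washout_decays_after_peak(self):
        truth = KineticTruth(washout_rate=0.05, rise_duration=10.0,
                             onset_t0=5.0)
        curve = generate_curve(truth, 10.0, 60.0)
        peak_idx = int(np.argmax(curve.intensities))
        assert curve.times[peak_idx] == pytest.approx(15.0, abs=0.11)
        assert curve.intensities[-1] < curve.intensities[peak_idx]

    def test_invalid_specification_errors(self):
        with pytest.raises(InvalidSpecificationError):
            generate_curve(KineticTruth(), -1.0, 60.0)
        with pytest.raises(InvalidSpecificationError):
            generate_curve(KineticTruth(onset_t0=10, rise_duration=30), 10.0, 35.0)

    def test_tr_invariant_to_intensity_scaling(self):
        """Scaling amplitude and shifting baseline leave TR untouched."""
        base = KineticTruth(shape_gamma=1.7)
        scaled = KineticTruth(shape_gamma=1.7, amplitude_a=base.amplitude_a * 9,
                              baseline_f0=base.baseline_f0 + 123.0)
        assert scaled.tr == base.tr
        assert scaled.t_half_max == base.t_half_max


class TestFrameStack:
    def test_single_pixel_roi_reproduces_curve(self, tmp_path):
        """Noise-free one-pixel ROI: extracted series equals the curve."""
        from icgquant import RoiMask, extract_curve, read_frames

        truth = KineticTruth(onset_t0=3.0, rise_duration=8.0)
        mask = np.zeros((8, 8), dtype=bool)
        mask[4, 4] = True
        spec = FrameStackSpec(height=8, width=8, duration=15.0,
                              roi_mask=mask, pixel_noise_sd=0.0)
        path = generate_frame_stack(truth, spec, tmp_path / "s.tif", seed=0)
        frames, rate = read_frames(path)
        got = extract_curve(frames, RoiMask(mask), rate)
        want = generate_curve(truth, spec.frame_rate, spec.duration)
        # float32 TIFF storage rounds at ~1e-7 relative
        np.testing.assert_allclose(got.intensities, want.intensities, rtol=1e-5)

    def test_noisy_stack_recovers_tr(self, tmp_path):
        """64x64 at 10 fps with 2 AU pixel noise: ROI-mean TR within 0.02."""
        from icgquant import RoiMask, compute_params, extract_curve, read_frames

        truth = KineticTruth(shape_gamma=1.357, onset_t0=10.0,
                             rise_duration=30.0)
        spec = FrameStackSpec(height=64, width=64, duration=60.0,
                              pixel_noise_sd=2.0)
        path = generate_frame_stack(truth, spec, tmp_path / "s.tif", seed=4)
        frames, rate = read_frames(path)
        curve = extract_curve(frames, RoiMask(spec.roi_mask), rate)
        params = compute_params(curve)
        assert abs(params.tr - truth.tr) <= 0.02

    def test_flat_stack_raises_no_perfusion_downstream(self, tmp_path):
        from icgquant import (NoPerfusionError, RoiMask, compute_params,
                              extract_curve, read_frames)

        truth = KineticTruth(amplitude_a=0.0, onset_t0=1.0, rise_duration=1.0)
        spec = FrameStackSpec(height=8, width=8, duration=20.0,
                              background_level=10.0, pixel_noise_sd=1.0)
        path = generate_frame_stack(truth, spec, tmp_path / "s.tif", seed=0)
        frames, rate = read_frames(path)
        curve = extract_curve(frames, RoiMask(spec.roi_mask), rate)
        assert np.ptp(curve.intensities) < 3.0  # flat up to averaged noise
        with pytest.raises(NoPerfusionError):
            compute_params(curve)

    def test_sidecar_metadata_written(self, tmp_path):
        truth = KineticTruth(onset_t0=2.0, rise_duration=4.0)
        spec = FrameStackSpec(height=8, width=8, duration=10.0, frame_rate=5.0)
        path = generate_frame_stack(truth, spec, tmp_path / "s.tif", seed=0)
        meta = json.loads((tmp_path / "s.json").read_text())
        assert meta["frame_rate_fps"] == 5.0
        assert meta["truth"]["rise_duration"] == 4.0

    def test_png_directory_flavor(self, tmp_path):
        truth = KineticTruth(onset_t0=2.0, rise_duration=4.0, amplitude_a=60.0)
        spec = FrameStackSpec(height=8, width=8, duration=10.0)
        path = generate_frame_stack(truth, spec, tmp_path / "frames", seed=0)
        assert (path / "metadata.json").is_file()
        assert len(list(path.glob("frame_*.png"))) == len(
            generate_curve(truth, spec.frame_rate, spec.duration)
        )

    def test_roi_mask_validation(self):
        with pytest.raises(InvalidSpecificationError):
            FrameStackSpec(height=8, width=8,
                           roi_mask=np.zeros((8, 8), dtype=bool))
        with pytest.raises(InvalidSpecificationError):
            FrameStackSpec(height=8, width=8,
                           roi_mask=np.ones((4, 4), dtype=bool))

    def test_unwritable_path_raises(self, tmp_path):
        truth = KineticTruth(onset_t0=2.0, rise_duration=4.0)
        spec = FrameStackSpec(height=8, width=8, duration=10.0)
        blocker = tmp_path / "not_a_dir"
        blocker.write_text("occupied")  # a file where a directory is needed
        with pytest.raises(OSError):
            generate_frame_stack(truth, spec, blocker / "x" / "s.tif", seed=0)


class TestCohort:
    def test_same_seed_byte_identical(self):
        a = generate_cohort(CohortSpec(random_seed=3))
        b = generate_cohort(CohortSpec(random_seed=3))
        assert len(a) == len(b) == 86
        for ma, mb in zip(a, b):
            assert ma.truth == mb.truth
            assert ma.outcome == mb.outcome
            np.testing.assert_array_equal(ma.curve.intensities,
                                          mb.curve.intensities)

    def test_truncation_bounds_respected(self):
        cohort = generate_cohort(CohortSpec(random_seed=5, generate_curves=False))
        for m in cohort:
            assert 0.05 < m.truth.tr < 0.95
            assert m.truth.t_max > 1.0
            assert m.truth.amplitude_a > 0.0

    def test_outcome_labels_and_group_sizes(self):
        cohort = generate_cohort(
            CohortSpec(n_complication=4, n_no_complication=10,
                       random_seed=0, generate_curves=False)
        )
        assert int(cohort.outcomes.sum()) == 4
        assert len(cohort) == 14
        assert all(m.outcome == 1 for m in cohort if m.group == "complication")

    def test_all_negative_cohort_flags_sensitivity_undefined(self):
        """n_complication = 0: downstream sensitivity must be undefined."""
        from icgquant import ContingencyTable2x2, diagnostic_values

        cohort = generate_cohort(
            CohortSpec(n_complication=0, n_no_complication=12,
                       random_seed=1, generate_curves=False)
        )
        assert cohort.outcomes.sum() == 0
        table = ContingencyTable2x2.from_predictions(
            [m.truth.tr > 0.6 for m in cohort], cohort.outcomes
        )
        diag = diagnostic_values(table)
        assert not diag.sensitivity.defined
        assert "no positive outcomes" in str(diag.sensitivity)

    def test_infeasible_truncation_bounds_rejected(self):
        with pytest.raises(InvalidSpecificationError):
            CohortSpec(tr_bounds=(0.9, 0.1))

    def test_complication_t_max_calibration(self):
        """Complication-group T_MAX sampling matches its configured law.

        Pooled over 200 seeded six-patient replicates, the grand mean must
        sit within 2 pooled SEs of the analytic truncated-normal mean, and
        that analytic mean within 2 published SEs of the published 64.0 s
        (truncating at 1 s shifts the mean up by ~1 s).
        """
        means = [
            np.mean([
                m.truth.t_max
                for m in generate_cohort(
                    CohortSpec(n_no_complication=0, n_complication=6,
                               random_seed=seed, generate_curves=False)
                )
            ])
            for seed in range(200)
        ]
        sd = 11.7 * math.sqrt(6)  # published SE -> SD
        a, b = (1.0 - 64.0) / sd, (240.0 - 64.0) / sd
        analytic = truncnorm.mean(a, b, loc=64.0, scale=sd)
        pooled_se = sd / math.sqrt(200 * 6)
        assert abs(np.mean(means) - analytic) <= 2 * pooled_se
        assert abs(analytic - 64.0) <= 2 * 11.7

    def test_group_tr_means_match_reference(self):
        """Sampled TR group means land near the published 0.4 / 0.6."""
        spec = CohortSpec(n_complication=60, n_no_complication=60,
                          random_seed=9, generate_curves=False)
        frame = generate_cohort(spec).to_frame()
        means = frame.groupby("group")["true_tr"].mean()
        assert means["complication"] == pytest.approx(
            reference.GROUP_SUMMARIES["complication"]["tr"][0], abs=0.03
        )
        assert means["no_complication"] == pytest.approx(
            reference.GROUP_SUMMARIES["no_complication"]["tr"][0], abs=0.03
        )
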