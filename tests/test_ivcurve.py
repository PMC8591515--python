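import dataclasses

import numpy as np
import pytest

import patchleak as pl
from patchleak.ivcurve import curve_from_frame, normalized_leak_value


def fits_for(staircase, scenario="linear", seed=0, sigma=None, **overrides):
    kw = {} if sigma is None else {"sigma": sigma}
    params = pl.scenario_params(scenario, seed=seed, **kw, **overrides)
    trace, truth = pl.generate_trace(staircase, params)
    return pl.fit_all_steps(trace, staircase), truth


class TestBuildIV:
    def test_range_and_repeats(self, staircase, scenario1_trace):
        trace, _ = scenario1_trace
        fits = pl.fit_all_steps(trace, staircase)
        curve = pl.build_iv(fits, recording_id="r0")
        volts = curve.voltages
        assert volts.min() >= -120.0 - 0.5 and volts.max() <= 40.0 + 0.5
        # the +60 mV step is excluded; both +40 mV steps are present
        assert not np.any(np.isclose(volts, 60.0, atol=0.5))
        assert np.sum(np.isclose(volts, 40.0, atol=0.5)) == 2

    def test_all_unconverged_is_empty(self, staircase, scenario1_trace):
        trace, _ = scenario1_trace
        fits = [
            dataclasses.replace(f, converged=False)
            for f in pl.fit_all_steps(trace, staircase)
        ]
        with pytest.raises(pl.EmptyCurveError):
            pl.build_iv(fits)

    def test_unconverged_counted(self, staircase, scenario1_trace):
        trace, _ = scenario1_trace
        fits = pl.fit_all_steps(trace, staircase)
        fits[0] = dataclasses.replace(fits[0], converged=False)
        curve = pl.build_iv(fits)
        assert curve.n_excluded == 1


class TestNormalize:
    def test_leak_line_endpoints_map_to_0_and_1(self, staircase):
        fits, _ = fits_for(staircase, "linear", seed=2)
        curve = pl.build_iv(fits)
        leak = pl.LinearLeak(g_leak=0.5, e_leak=0.0)
        normalized = pl.normalize_iv(curve, leak)
        lo, hi = normalized.v_range
        assert normalized_leak_value(leak, lo, normalized.v_range) == 0.0
        assert normalized_leak_value(leak, hi, normalized.v_range) == 1.0

    def test_midpoint_maps_to_half(self):
        leak = pl.LinearLeak(g_leak=2.0, e_leak=0.0)
        point = pl.IVPoint(voltage=0.0, steady_state=-80.0, step_index=0, occurrence=1)
        curve = pl.IVCurve(recording_id="r", points=(point,), v_range=(-120.0, 40.0))
        # leak spans [-240, 80] pA; midpoint (L_min+L_max)/2 = -80 pA
        out = pl.normalize_iv(curve, leak)
        assert out.points[0].normalized == pytest.approx(0.5)

    def test_zero_conductance_degenerate(self, staircase):
        fits, _ = fits_for(staircase, "linear", seed=2)
        curve = pl.build_iv(fits)
        with pytest.raises(pl.DegenerateNormalizationError):
            pl.normalize_iv(curve, pl.LinearLeak(g_leak=0.0, e_leak=0.0))


class TestAggregate:
    def test_quartiles_of_arithmetic_sequence(self):
        points = tuple(
            pl.IVPoint(voltage=-40.0, steady_state=v, step_index=i, occurrence=1,
                       normalized=float(v))
            for i, v in enumerate(range(5))
        )
        curves = [
            pl.IVCurve(recording_id=f"r{j}", points=(points[j],)) for j in range(5)
        ]
        # 5 curves each contributing one point {0,1,2,3,4} at -40 mV
        summary = pl.aggregate_cohort(curves)
        row = summary.table.iloc[0]
        assert (row["min"], row["q1"], row["median"], row["q3"], row["max"]) == (
            0.0, 1.0, 2.0, 3.0, 4.0,
        )
        assert row["n_points"] == 5
        assert summary.n_recordings == 5

    def test_single_recording_identity(self, staircase):
        fits, truth = fits_for(staircase, "linear", seed=3)
        leak = pl.LinearLeak(truth.params.g_leak, truth.params.e_leak)
        curve = pl.normalize_iv(pl.build_iv(fits), leak)
        summary = pl.aggregate_cohort([curve])
        assert summary.n_recordings == 1
        for row in summary.table.itertuples():
            assert row.min <= row.q1 <= row.median <= row.q3 <= row.max

    def test_linear_cohort_median_on_leak_line(self, staircase):
        params = pl.scenario_params("linear")
        cohort = pl.generate_cohort(staircase, 20, params, seed=8)
        curves = []
        for trace, _ in cohort:
            leak = pl.estimate_linear_leak(trace, staircase)
            fits = pl.fit_all_steps(trace, staircase)
            curves.append(pl.normalize_iv(pl.build_iv(fits, recording_id=trace.meta.id), leak))
        summary = pl.aggregate_cohort(curves)
        for row in summary.table.itertuples():
            # leak lines differ per recording, but each recording's own leak
            # was used; use the pooled mean leak position as reference
            ref = np.mean(
                [normalized_leak_value(c.leak, row.voltage_mV, c.v_range) for c in curves]
            )
            assert row.median == pytest.approx(ref, abs=0.02)

    def test_point_count_conservation(self, staircase):
        params = pl.scenario_params("linear")
        cohort = pl.generate_cohort(staircase, 5, params, seed=9)
        curves = []
        total = 0
        for trace, _ in cohort:
            leak = pl.estimate_linear_leak(trace, staircase)
            fits = pl.fit_all_steps(trace, staircase)
            c = pl.normalize_iv(pl.build_iv(fits, recording_id=trace.meta.id), leak)
            total += len(c.points)
            curves.append(c)
        summary = pl.aggregate_cohort(curves)
        assert summary.table["n_points"].sum() == total

    def test_mismatched_voltage_sets_rejected(self, staircase):
        fits, truth = fits_for(staircase, "linear", seed=3)
        leak = pl.LinearLeak(truth.params.g_leak, truth.params.e_leak)
        full = pl.normalize_iv(pl.build_iv(fits), leak)
        kept = tuple(p for p in full.points if not np.isclose(p.voltage, -120.0, atol=0.5))
        clipped = dataclasses.replace(full, points=kept, recording_id="r2")
        with pytest.raises(pl.AggregationError, match="mismatch"):
            pl.aggregate_cohort([full, clipped])


class TestNonlinearityProfile:
    def test_linear_trace_deviations_within_noise(self, staircase):
        fits, truth = fits_for(staircase, "linear", seed=4)
        leak = pl.LinearLeak(truth.params.g_leak, truth.params.e_leak)
        curve = pl.normalize_iv(pl.build_iv(fits), leak)
        dev = pl.nonlinearity_profile(curve)
        # noise tolerance includes the asymptote-extrapolation spread of
        # transient-free exponential fits (a few pA on an ~80 pA span)
        assert np.abs(dev["deviation"]).max() < 0.1

    def test_scenario1_superlinear_at_plus40(self, staircase, scenario1_trace):
        trace, _ = scenario1_trace
        leak = pl.estimate_linear_leak(trace, staircase)
        fits = pl.fit_all_steps(trace, staircase)
        dev = pl.nonlinearity_profile(pl.normalize_iv(pl.build_iv(fits), leak))
        at40 = dev.loc[np.isclose(dev.voltage_mV, 40.0, atol=0.5), "deviation"]
        assert (at40 > 0).all()

    def test_scenario2_sublinear_at_minus120(self, staircase):
        params = pl.scenario_params("II", seed=6)
        trace, _ = pl.generate_trace(staircase, params)
        # nonlinearity sits at negative voltages: fit leak at (+40, +60) mV
        leak = pl.estimate_linear_leak(trace, staircase, step_pair=(40.0, 60.0))
        fits = pl.fit_all_steps(trace, staircase)
        dev = pl.nonlinearity_profile(pl.normalize_iv(pl.build_iv(fits), leak))
        at_neg = dev.loc[np.isclose(dev.voltage_mV, -120.0, atol=0.5), "deviation"]
        assert (at_neg < 0).all()

    def test_washout_deviation_vanishes_without_noise(self, staircase):
        fits, truth = fits_for(staircase, "III", seed=7, sigma=0.0)
        leak = pl.LinearLeak(truth.params.g_leak, truth.params.e_leak)
        dev = pl.nonlinearity_profile(pl.normalize_iv(pl.build_iv(fits), leak))
        # limited only by step/ramp boundary bleed (< delta_v over a few ms),
        # three orders of magnitude below the noisy-case deviations
        assert np.abs(dev["deviation"]).max() < 1e-3

    def test_affine_invariance(self, staircase):
        fits, _ = fits_for(staircase, "I", seed=8)
        leak = pl.LinearLeak(g_leak=0.5, e_leak=0.0)
        curve = pl.build_iv(fits)
        dev0 = pl.nonlinearity_profile(pl.normalize_iv(curve, leak))
        # add a constant offset to every steady state and shift E_leak to match
        offset = 37.0
        shifted_points = tuple(
            dataclasses.replace(p, steady_state=p.steady_state + offset)
            for p in curve.points
        )
        shifted_curve = dataclasses.replace(curve, points=shifted_points)
        shifted_leak = pl.LinearLeak(g_leak=0.5, e_leak=-offset / 0.5)
        dev1 = pl.nonlinearity_profile(pl.normalize_iv(shifted_curve, shifted_leak))
        np.testing.assert_allclose(
            dev1["deviation"].to_numpy(), dev0["deviation"].to_numpy(), atol=1e-12
        )


def test_curve_frame_roundtrip(staircase, scenario1_trace):
    trace, _ = scenario1_trace
    leak = pl.estimate_linear_leak(trace, staircase)
    fits = pl.fit_all_steps(trace, staircase)
    curve = pl.normalize_iv(pl.build_iv(fits, recording_id="rt"), leak)
    back = curve_from_frame(curve.to_frame())
    assert back.recording_id == "rt"
    assert back.is_normalized
    np.testing.assert_allclose(
        [p.normalized for p in back.points], [p.normalized for p in curve.points]
    )
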