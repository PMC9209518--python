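"""FRAP trace generation, correction, fitting and condition summaries."""
import math

import numpy as np
import pytest

from chromodyn import frap, presets, synthgen
from chromodyn.frap import FrapTrace


@pytest.fixture(scope="module")
def tale_ctrl():
    return presets.frap_preset("tale_ctrl")


class TestMakeFrapTrace:
    def test_noiseless_first_post_bleach_equals_bleach_depth(self, tale_ctrl):
        trace, truth = synthgen.make_frap_trace(tale_ctrl, seed=0, noise_sd=0.0)
        curve = frap.correct_trace(trace)
        assert curve[:trace.bleach_frame].mean() == pytest.approx(1.0)
        assert curve[trace.bleach_frame] == pytest.approx(
            tale_ctrl.bleach_depth, abs=1e-12)

    def test_no_recovery_when_immobile(self, tale_ctrl):
        from dataclasses import replace
        p = replace(tale_ctrl, mobile_fraction=0.0)
        trace, _ = synthgen.make_frap_trace(p, seed=0, noise_sd=0.0)
        curve = frap.correct_trace(trace)
        post = curve[trace.bleach_frame:]
        assert np.allclose(post, p.bleach_depth, atol=1e-10)

    def test_determinism(self, tale_ctrl):
        a, _ = synthgen.make_frap_trace(tale_ctrl, seed=42)
        b, _ = synthgen.make_frap_trace(tale_ctrl, seed=42)
        assert np.array_equal(a.i_bleached, b.i_bleached)
        assert np.array_equal(a.i_control, b.i_control)

    def test_nonuniform_hp1a_timestamps(self):
        p = presets.frap_preset("hp1a_ctrl")
        t = synthgen.frap_times(p)
        assert t[0] == 0.0 and t[1] == 1.0 and t[2] == 2.0
        assert np.allclose(np.diff(t[2:]), 5.0)

    def test_csv_roundtrip(self, tale_ctrl, tmp_path):
        trace, _ = synthgen.make_frap_trace(tale_ctrl, seed=1)
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        back = FrapTrace.from_csv(path)
        assert back.bleach_frame == trace.bleach_frame
        assert np.allclose(back.i_bleached, trace.i_bleached)


class TestCorrectTrace:
    def test_self_normalization_bleached_equals_control(self):
        t = np.arange(20.0)
        shared = 500.0 * np.exp(-0.01 * t)
        trace = FrapTrace(t, shared + 50, shared + 50, np.full(20, 50.0), 5)
        curve = frap.correct_trace(trace)
        assert np.allclose(curve, 1.0)

    def test_control_removes_acquisition_bleaching(self):
        p = presets.frap_preset("hp1a_ctrl")
        trace, truth = synthgen.make_frap_trace(p, seed=0, noise_sd=0.0)
        curve = frap.correct_trace(trace, use_control=True)
        fit = frap.fit_recovery(curve, trace.time_s, trace.bleach_frame)
        assert fit.plateau == pytest.approx(truth["plateau"], abs=1e-3)

    def test_nonpositive_control_names_frame(self):
        t = np.arange(12.0)
        bleached = np.full(12, 100.0)
        control = np.full(12, 100.0)
        control[7] = 5.0
        trace = FrapTrace(t, bleached, control, np.full(12, 10.0), 3)
        with pytest.raises(ValueError, match="frame 7"):
            frap.correct_trace(trace)


class TestFitRecovery:
    def test_exact_recovery_on_noiseless_model(self):
        t = np.arange(120.0)
        y0, plateau, k = 0.3, 0.85, 0.0866
        curve = np.ones(120)
        x = t[10:] - t[10]
        curve[10:] = y0 + (plateau - y0) * (1 - np.exp(-k * x))
        fit = frap.fit_recovery(curve, t, 10)
        assert fit.converged
        assert fit.y0 == pytest.approx(y0, abs=1e-6)
        assert fit.plateau == pytest.approx(plateau, abs=1e-6)
        assert fit.k_per_s == pytest.approx(k, abs=1e-6)

    @pytest.mark.parametrize("name", ["tale_ctrl", "tale_msr",
                                      "hp1a_ctrl", "hp1a_msr"])
    def test_generative_self_consistency_all_presets(self, name):
        p = presets.frap_preset(name)
        trace, truth = synthgen.make_frap_trace(p, seed=0, noise_sd=0.0)
        curve = frap.correct_trace(trace)
        fit = frap.fit_recovery(curve, trace.time_s, trace.bleach_frame)
        assert fit.k_per_s == pytest.approx(truth["k_per_s"], abs=1e-6)
        assert fit.plateau == pytest.approx(truth["plateau"], abs=1e-6)
        assert fit.y0 == pytest.approx(truth["y0"], abs=1e-6)

    def test_flat_curve_gives_zero_mobile_fraction(self):
        t = np.arange(60.0)
        curve = np.ones(60)
        curve[10:] = 0.3
        fit = frap.fit_recovery(curve, t, 10)
        assert fit.plateau == pytest.approx(fit.y0, abs=1e-6)
        assert fit.mobile_fraction == pytest.approx(0.0, abs=1e-6)

    def test_too_few_post_bleach_frames_rejected(self):
        t = np.arange(10.0)
        with pytest.raises(ValueError):
            frap.fit_recovery(np.ones(10), t, 5)

    def test_half_time_monotone_in_k(self):
        ks = np.linspace(0.01, 1.0, 25)
        ths = [frap.half_time(k) for k in ks]
        assert all(a > b for a, b in zip(ths, ths[1:]))


class TestHalfTimeAndFractions:
    def test_half_time_values(self):
        assert frap.half_time(math.log(2)) == pytest.approx(1.0)
        assert frap.half_time(0.0866) == pytest.approx(8.004, abs=0.01)
        assert frap.half_time(0.0533) == pytest.approx(13.006, abs=0.01)
        with pytest.raises(ValueError):
            frap.half_time(0.0)

    def test_fraction_limits_and_direct_substitution(self):
        assert frap.fractions(1.0, 1.0, 0.3) == (1.0, 0.0)
        assert frap.fractions(0.3, 1.0, 0.3) == (0.0, 1.0)
        mob, imm = frap.fractions(0.825, 1.0, 0.3)
        assert mob == pytest.approx(0.75)
        assert imm == pytest.approx(0.25)

    def test_failed_bleach_rejected(self):
        with pytest.raises(ValueError):
            frap.fractions(0.9, 0.5, 0.8)

    def test_fractions_sum_to_one_and_clamped(self):
        with pytest.warns(UserWarning):
            mob, imm = frap.fractions(1.2, 1.0, 0.3)
        assert mob + imm == pytest.approx(1.0)
        assert 0.0 <= mob <= 1.0

    def test_fm_invariant_under_affine_intensity_rescaling(self):
        p = presets.frap_preset("tale_ctrl")
        trace, _ = synthgen.make_frap_trace(p, seed=9)
        fit_a = frap.analyze_trace(trace)
        scaled = FrapTrace(trace.time_s, 3.0 * trace.i_bleached,
                           3.0 * trace.i_control, 3.0 * trace.i_background,
                           trace.bleach_frame)
        fit_b = frap.analyze_trace(scaled)
        assert fit_b.mobile_fraction == pytest.approx(fit_a.mobile_fraction,
                                                      abs=1e-9)


class TestSummaries:
    def test_parameter_recovery_bias_under_noise(self):
        p = presets.frap_preset("hp1a_ctrl")
        th, fm = [], []
        for s in range(100):
            trace, _ = synthgen.make_frap_trace(p, seed=s, noise_sd=p.noise_sd)
            fit = frap.analyze_trace(trace)
            th.append(fit.t_half_s)
            fm.append(fit.mobile_fraction)
        t_true = math.log(2) / p.k_per_s
        assert abs(np.mean(th) - t_true) / t_true < 0.05
        assert abs(np.mean(fm) - p.mobile_fraction) / p.mobile_fraction < 0.05

    def test_summarize_two_conditions_reports_p(self):
        fits, labels = [], []
        for name in ("hp1a_ctrl", "hp1a_msr"):
            p = presets.frap_preset(name)
            for s in range(12):
                trace, _ = synthgen.make_frap_trace(p, seed=s)
                fits.append(frap.analyze_trace(trace))
                labels.append(name)
        df = frap.summarize_condition(fits, labels)
        row = df[(df.quantity == "t_half_s")].iloc[0]
        assert "p_mannwhitney" in df.columns
        assert df["p_mannwhitney"].notna().any()
        assert row["n"] == 12

    def test_single_condition_descriptives_only(self):
        p = presets.frap_preset("tale_ctrl")
        fits = []
        for s in range(5):
            trace, _ = synthgen.make_frap_trace(p, seed=s)
            fits.append(frap.analyze_trace(trace))
        df = frap.summarize_condition(fits, ["only"] * 5)
        assert "p_mannwhitney" not in df.columns
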