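"""Tests for optical-trap calibration and force-trace analysis."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtcoupler.force import (
    CalibrationError,
    QPDTrace,
    StallEvent,
    TrapCalibration,
    analyze_force_trace,
    classify_outcome,
    detect_stall,
    faxen_drag_factor,
    kbt,
    link_stiffness,
    preprocess_pull_segment,
    qpd_conversion,
    rescue_fraction,
    rotate_to_mt_axes,
    stall_force,
    trap_stiffness_psd,
)
from mtcoupler.synthetic import StallSegment, TrapGroundTruth, gen_qpd_trace

KAPPA = 0.03
CALIB = TrapCalibration(kappa_pn_nm=KAPPA, corner_frequency_hz=600.0)


def stall_trace(plateau_nm, outcome="detachment", seed=0, duration=10.0,
                stall_s=1.5, kappa=KAPPA, rate=10_000.0, link=0.2):
    truth = TrapGroundTruth(
        kappa_pn_nm=kappa,
        stalls=(StallSegment(3.0, plateau_nm, stall_s, outcome, link_stiffness_pn_nm=link),),
    )
    return gen_qpd_trace(truth, duration, rate, seed=seed)


class TestConversion:
    def test_linear_sweep(self):
        d = np.linspace(-400, 400, 801)
        assert qpd_conversion(d, 0.005 * d) == pytest.approx(200.0)

    def test_saturating_sweep_core_slope(self):
        d = np.linspace(-400, 400, 801)
        v = 0.005 * d - 1e-9 * d**3  # cubic saturation outside the core
        assert qpd_conversion(d, v) == pytest.approx(200.0, rel=0.01)

    def test_flat_sweep_rejected(self):
        d = np.linspace(-300, 300, 601)
        with pytest.raises(ValueError, match="flat"):
            qpd_conversion(d, np.zeros_like(d))

    def test_narrow_sweep_rejected(self):
        d = np.linspace(-150, 150, 301)
        with pytest.raises(ValueError, match="span"):
            qpd_conversion(d, 0.005 * d)


class TestTrapStiffness:
    def test_psd_kappa_within_10_percent(self):
        truth = TrapGroundTruth(kappa_pn_nm=0.02)  # bulk drag
        trace = gen_qpd_trace(truth, 30.0, 10_000.0, seed=4)
        cal = trap_stiffness_psd(trace, height_nm=np.inf)  # bulk: Faxen factor 1
        assert cal.kappa_pn_nm == pytest.approx(0.02, rel=0.10)

    def test_equipartition_cross_check(self):
        truth = TrapGroundTruth(kappa_pn_nm=0.02)
        trace = gen_qpd_trace(truth, 30.0, 10_000.0, seed=4)
        cal = trap_stiffness_psd(trace, height_nm=np.inf)
        kappa_eq = kbt(303.0) / trace.x.var()
        assert cal.kappa_pn_nm == pytest.approx(kappa_eq, rel=0.10)

    def test_faxen_factor_limits(self):
        assert faxen_drag_factor(1000.0, np.inf) == pytest.approx(1.0)
        assert faxen_drag_factor(1000.0, 100.0) > 1.5  # strong wall enhancement

    def test_near_wall_drag_consistency(self):
        # generate with the wall-enhanced drag, calibrate with matching height
        from mtcoupler.force import stokes_drag

        gamma = stokes_drag(1000.0) * faxen_drag_factor(1000.0, 150.0)
        truth = TrapGroundTruth(kappa_pn_nm=0.025, gamma_pn_s_nm=gamma)
        trace = gen_qpd_trace(truth, 30.0, 10_000.0, seed=9)
        cal = trap_stiffness_psd(trace, height_nm=150.0)
        assert cal.kappa_pn_nm == pytest.approx(0.025, rel=0.10)

    def test_short_trace_rejected(self):
        trace = gen_qpd_trace(TrapGroundTruth(kappa_pn_nm=0.02), 2.0, 10_000.0, seed=1)
        with pytest.raises(ValueError, match="10 s"):
            trap_stiffness_psd(trace)


class TestRotation:
    def test_identity_at_zero(self):
        tr = gen_qpd_trace(TrapGroundTruth(kappa_pn_nm=KAPPA), 1.0, 1000.0, seed=2)
        rot = rotate_to_mt_axes(dataclasses.replace(tr, axis_angle_rad=0.0))
        assert np.allclose(rot.x, tr.x) and np.allclose(rot.y, tr.y)

    def test_quarter_turn_swaps_axes(self):
        tr = gen_qpd_trace(TrapGroundTruth(kappa_pn_nm=KAPPA), 1.0, 1000.0, seed=2)
        rot = rotate_to_mt_axes(dataclasses.replace(tr, axis_angle_rad=np.pi / 2))
        assert np.allclose(rot.x, tr.y) and np.allclose(rot.y, -tr.x)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(angle=st.floats(-np.pi, np.pi), seed=st.integers(0, 50))
    def test_rotation_is_isometry(self, angle, seed):
        tr = gen_qpd_trace(TrapGroundTruth(kappa_pn_nm=KAPPA), 0.2, 1000.0, seed=seed)
        rot = rotate_to_mt_axes(dataclasses.replace(tr, axis_angle_rad=angle))
        assert np.allclose(np.hypot(rot.x, rot.y), np.hypot(tr.x, tr.y))

    def test_missing_angle_rejected(self):
        tr = gen_qpd_trace(TrapGroundTruth(kappa_pn_nm=KAPPA), 0.2, 1000.0, seed=1)
        with pytest.raises(ValueError, match="axis_angle"):
            rotate_to_mt_axes(dataclasses.replace(tr, axis_angle_rad=None))


class TestPreprocess:
    def test_decimation_counts_and_mean(self):
        tr = gen_qpd_trace(TrapGroundTruth(kappa_pn_nm=KAPPA), 2.0, 10_000.0, seed=3)
        out = preprocess_pull_segment(tr, 1000.0)
        assert out.x.size == tr.x.size // 10
        assert out.y.mean() == pytest.approx(tr.y.mean(), abs=1e-9)  # y only decimated

    def test_constant_signal_identity(self):
        t = np.arange(2000) / 1000.0
        tr = QPDTrace(t, np.full(2000, 3.0), np.full(2000, -1.0), 1000.0)
        out = preprocess_pull_segment(tr, 1000.0)
        assert np.allclose(out.x, 3.0) and np.allclose(out.y, -1.0)

    def test_decimated_ou_variance_matches_theory(self):
        # block averaging an OU process with correlation time tau over
        # windows T shrinks the variance by ~ 2 tau / T for T >> tau
        truth = TrapGroundTruth(kappa_pn_nm=KAPPA, temperature_k=300.0)
        tr = gen_qpd_trace(truth, 60.0, 10_000.0, seed=12)
        factor = 10
        n = (tr.x.size // factor) * factor
        dec = tr.x[:n].reshape(-1, factor).mean(axis=1)
        tau = truth.gamma_pn_s_nm / KAPPA
        T = factor / tr.rate_hz
        var_inf = 0.0138065 * 300.0 / KAPPA
        r = tau / T
        expected = var_inf * 2 * r * (1 - r * (1 - np.exp(-1 / r)))
        assert dec.var() == pytest.approx(expected, rel=0.05)

    def test_upsampling_rejected(self):
        tr = gen_qpd_trace(TrapGroundTruth(kappa_pn_nm=KAPPA), 0.2, 1000.0, seed=1)
        with pytest.raises(ValueError, match="target rate"):
            preprocess_pull_segment(tr, 2000.0)


class TestStallDetection:
    def test_programmed_stall_recovered(self):
        tr = stall_trace(100.0, seed=5)
        sm = preprocess_pull_segment(tr)
        ev = detect_stall(sm, baseline_window_s=(0.0, 2.0))
        assert ev is not None
        assert ev.duration_s == pytest.approx(1.5, abs=0.1)
        assert ev.stall_level_nm == pytest.approx(100.0, abs=2.0)

    def test_stall_free_trace_gives_none(self):
        tr = gen_qpd_trace(TrapGroundTruth(kappa_pn_nm=KAPPA), 6.0, 10_000.0, seed=6)
        sm = preprocess_pull_segment(tr)
        assert detect_stall(sm, baseline_window_s=(0.0, 1.0)) is None

    def test_noiseless_ramp_plateau_exact_bounds(self):
        rate = 1000.0
        t = np.arange(int(8 * rate)) / rate
        x = np.interp(t, [3.0, 4.0, 5.5, 5.501], [0.0, 100.0, 100.0, 0.0])
        x[t < 3.0] = 0.0
        # add a hair of baseline noise so the 5-sigma threshold is defined
        rng = np.random.default_rng(0)
        x += rng.normal(0, 0.01, x.size)
        tr = QPDTrace(t, x, np.zeros_like(x), rate)
        ev = detect_stall(tr, baseline_window_s=(0.0, 2.0))
        assert ev.t_start_s == pytest.approx(4.0, abs=0.06)
        assert ev.t_end_s == pytest.approx(5.5, abs=0.06)


class TestStallForce:
    def test_arithmetic_with_and_without_correction(self):
        ev = StallEvent(1.0, 2.0, stall_level_nm=100.0, free_level_nm=0.0)
        assert stall_force(ev, CALIB) == pytest.approx(3.0)
        assert stall_force(ev, CALIB, correction=lambda x: 1.1) == pytest.approx(3.3)

    def test_correction_table_domain(self):
        ev = StallEvent(1.0, 2.0, stall_level_nm=250.0, free_level_nm=0.0)
        table = (np.array([0.0, 200.0]), np.array([1.0, 1.2]))
        with pytest.raises(ValueError, match="domain"):
            stall_force(ev, CALIB, correction=table)

    def test_pipeline_force_recovery_within_5_percent(self):
        for plateau, seed in ((50.0, 1), (120.0, 2), (200.0, 3)):
            tr = stall_trace(plateau, seed=seed)
            ev = analyze_force_trace(tr, CALIB, baseline_window_s=(0.0, 2.0))
            assert ev.force_pn == pytest.approx(KAPPA * plateau, rel=0.05)


class TestOutcome:
    def test_snap_back_is_detachment(self):
        tr = stall_trace(100.0, "detachment", seed=7)
        ev = analyze_force_trace(tr, CALIB, baseline_window_s=(0.0, 2.0))
        assert ev.outcome == "detachment"

    def test_gradual_return_is_rescue(self):
        tr = stall_trace(100.0, "rescue", seed=8, duration=13.0)
        ev = analyze_force_trace(tr, CALIB, baseline_window_s=(0.0, 2.0))
        assert ev.outcome == "rescue"

    def test_truncated_trace_indeterminate(self):
        tr = stall_trace(100.0, "rescue", seed=9, duration=5.6)  # ends mid-return
        ev = analyze_force_trace(tr, CALIB, baseline_window_s=(0.0, 2.0))
        assert ev.outcome == "indeterminate"


class TestLinkStiffness:
    def test_equipartition_inversion(self):
        rng = np.random.default_rng(4)
        seg = rng.normal(0.0, np.sqrt(kbt(303.0) / 0.03), 20_000)
        assert link_stiffness(seg, 303.0) == pytest.approx(0.03, rel=0.05)

    def test_halved_variance_doubles_stiffness(self):
        rng = np.random.default_rng(4)
        seg = rng.normal(0.0, 1.0, 50_000)
        k1 = link_stiffness(seg)
        k2 = link_stiffness(seg / np.sqrt(2))
        assert k2 == pytest.approx(2 * k1, rel=0.01)

    def test_stiffened_stall_recovered(self):
        # during the stall the bead feels trap + link in parallel
        tr = stall_trace(100.0, seed=10, link=0.2)
        ev = analyze_force_trace(tr, CALIB, baseline_window_s=(0.0, 2.0))
        assert ev.link_stiffness_pn_nm == pytest.approx(KAPPA + 0.2, rel=0.10)

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError, match=">= 100"):
            link_stiffness(np.ones(50))


class TestRescueFraction:
    def test_paper_style_counts(self):
        events = [
            StallEvent(0, 1, 100, 0, outcome="detachment") for _ in range(51)
        ] + [StallEvent(0, 1, 100, 0, outcome="rescue") for _ in range(21)]
        res = rescue_fraction(events)
        assert res["n_detachment"] == 51 and res["n_rescue"] == 21
        assert round(res["percent_rescue"]) == 29

    def test_all_rescue(self):
        events = [StallEvent(0, 1, 50, 0, outcome="rescue")] * 4
        assert rescue_fraction(events)["percent_rescue"] == 100.0

    def test_force_binned_fractions(self):
        events = [
            StallEvent(0, 1, 50, 0, force_pn=1.0, outcome="detachment"),
            StallEvent(0, 1, 50, 0, force_pn=1.2, outcome="detachment"),
            StallEvent(0, 1, 150, 0, force_pn=5.0, outcome="rescue"),
            StallEvent(0, 1, 150, 0, force_pn=5.5, outcome="rescue"),
        ]
        res = rescue_fraction(events, force_bin_edges_pn=np.array([0.0, 3.0, 6.0]))
        by = res["by_force"]
        assert by.loc[0, "percent_rescue"] == 0.0
        assert by.loc[1, "percent_rescue"] == 100.0

    def test_empty_and_unlabelled_rejected(self):
        with pytest.raises(ValueError):
            rescue_fraction([])
        with pytest.raises(ValueError, match="labelled"):
            rescue_fraction([StallEvent(0, 1, 50, 0)])
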