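"""Tests for kymograph construction and spot tracing."""

import numpy as np
import pytest

from mtcoupler.kymograph import (
    EmptyTrackError,
    Kymograph,
    SpotTrack,
    TipTrack,
    build_kymograph,
    classify_tip_tracking,
    fit_line_gaussian,
    residence_time,
    tip_velocity,
    trace_spot,
    trace_tip,
)
from mtcoupler.synthetic import CameraNoise, SpotModel, gen_kymograph


class TestBuildKymograph:
    def test_constant_stack_gives_constant_kymograph(self):
        stack = np.full((5, 20, 30), 7.0)
        line = np.array([[2.0, 10.0], [27.0, 10.0]])
        kymo = build_kymograph(stack, line, width=3)
        assert np.allclose(kymo.matrix, 7.0)

    def test_width_one_axis_aligned_line_is_raw_row(self):
        rng = np.random.default_rng(0)
        stack = rng.normal(10, 2, (4, 15, 25))
        y = 6
        line = np.array([[0.0, float(y)], [24.0, float(y)]])
        kymo = build_kymograph(stack, line, width=1)
        assert np.allclose(kymo.matrix, stack[:, y, :])

    def test_moving_spot_maximum_follows_truth(self):
        # build a stack with a bright spot moving along y=8
        frames, h, w = 12, 17, 40
        stack = np.zeros((frames, h, w))
        xs = np.linspace(5, 30, frames)
        yy, xx = np.mgrid[0:h, 0:w]
        for t, cx in enumerate(xs):
            stack[t] = 50 * np.exp(-((xx - cx) ** 2 + (yy - 8) ** 2) / (2 * 1.3**2))
        kymo = build_kymograph(stack, np.array([[0.0, 8.0], [39.0, 8.0]]), width=5)
        argmax = np.argmax(kymo.matrix, axis=1)
        assert np.all(np.abs(argmax - xs) <= 1.0)

    def test_line_outside_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            build_kymograph(np.zeros((3, 10, 10)), np.array([[0.0, 0.0], [20.0, 0.0]]))

    def test_even_width_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            build_kymograph(np.zeros((3, 10, 10)), np.array([[0.0, 5.0], [9.0, 5.0]]), width=4)


class TestGaussianFit:
    def test_noiseless_center_and_analytic_area(self):
        x = np.arange(41.0)
        profile = 100.0 * np.exp(-((x - 20.3) ** 2) / (2 * 1.5**2)) + 10.0
        fit = fit_line_gaussian(profile)
        assert fit.success
        assert fit.center_px == pytest.approx(20.3, abs=0.01)
        assert fit.area_au == pytest.approx(100 * 1.5 * np.sqrt(2 * np.pi), rel=1e-3)

    def test_flat_profile_flags_failure(self):
        fit = fit_line_gaussian(np.full(20, 5.0))
        assert not fit.success

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError, match=">= 7"):
            fit_line_gaussian(np.ones(5))

    def test_localization_rmse_under_shot_noise(self):
        # moderate-SNR Monte Carlo against the generating position
        rng = np.random.default_rng(3)
        x = np.arange(15.0)
        model = 25.0 * np.exp(-((x - 7.25) ** 2) / (2 * 1.3**2))
        errs = []
        for _ in range(300):
            y = rng.poisson(model).astype(float)
            fit = fit_line_gaussian(y, weight_poisson=True, fix_sigma=True)
            if fit.success:
                errs.append(fit.center_px - 7.25)
        errs = np.asarray(errs)
        assert errs.size > 250
        assert np.sqrt((errs**2).mean()) < 0.20


class TestTraceSpot:
    def test_noiseless_static_spot_full_span(self):
        spot = SpotModel(position_px=20.3, peak_photons=100)
        kymo, _, _ = gen_kymograph(50, spot=spot, noise=CameraNoise(poisson=False), seed=0)
        track = trace_spot(kymo, (0, 20.0))
        assert track.frames.size == 50
        assert np.allclose(track.positions_px, 20.3, atol=0.01)
        assert track.left_censored  # present in frame 0

    def test_landing_and_detachment_recovered(self):
        spot = SpotModel(position_px=30.0, peak_photons=100, landing_frame=8, detach_frame=33)
        kymo, _, truth = gen_kymograph(50, spot=spot, noise=CameraNoise(background=2.0), seed=7)
        track = trace_spot(kymo, (15, 30.0))
        assert abs(track.landing_frame - truth.landing_frame) <= 1
        assert abs(track.detach_frame - truth.detach_frame) <= 1
        assert not track.left_censored

    def test_seed_on_background_raises(self):
        spot = SpotModel(position_px=10.0, peak_photons=100, landing_frame=20)
        kymo, _, _ = gen_kymograph(40, spot=spot, noise=CameraNoise(background=2.0), seed=1)
        with pytest.raises(EmptyTrackError):
            trace_spot(kymo, (5, 50.0))

    def test_translation_equivariance(self):
        spot = SpotModel(position_px=25.3, peak_photons=100)
        kymo, _, _ = gen_kymograph(20, spot=spot, noise=CameraNoise(background=2.0), seed=5)
        shifted = Kymograph(
            np.roll(kymo.matrix, 7, axis=1), kymo.px_size_nm, kymo.frame_dt_s
        )
        a = trace_spot(kymo, (0, 25.0))
        b = trace_spot(shifted, (0, 32.0))
        common = np.intersect1d(a.frames, b.frames)
        ia = np.isin(a.frames, common)
        ib = np.isin(b.frames, common)
        assert np.allclose(b.positions_px[ib] - a.positions_px[ia], 7.0, atol=1e-6)


class TestResidenceTime:
    def test_arithmetic(self):
        track = SpotTrack(
            frames=np.arange(10, 111),
            positions_px=np.full(101, 5.0),
            intensities_au=np.ones(101),
            landing_frame=10,
            detach_frame=110,
        )
        tau, censored = residence_time(track, 1.1)
        assert tau == pytest.approx(110.0)
        assert not censored

    def test_zero_duration(self):
        track = SpotTrack(
            frames=np.array([4]), positions_px=np.array([1.0]),
            intensities_au=np.array([1.0]), landing_frame=4, detach_frame=4,
        )
        assert residence_time(track, 1.1)[0] == 0.0

    def test_traced_monovalent_ensemble_matches_kinetics(self):
        """Close the loop kinetics -> images -> tracing -> residence times."""
        from mtcoupler.kinetics import KineticParams, simulate_residence

        k_off, dt = 0.62, 0.2
        n = 120
        sim = simulate_residence(KineticParams(1, k_off), n, seed=31)
        taus = []
        for i, true_tau in enumerate(sim.times):
            detach = 3 + max(int(round(true_tau / dt)), 0)
            spot = SpotModel(
                position_px=30.0, peak_photons=120, landing_frame=3,
                detach_frame=min(detach, 59),
            )
            kymo, _, _ = gen_kymograph(
                60, frame_dt_s=dt, spot=spot, noise=CameraNoise(background=2.0), seed=400 + i
            )
            try:
                track = trace_spot(kymo, (3, 30.0))
            except EmptyTrackError:
                continue
            tau, censored = residence_time(track, dt)
            if not censored:
                taus.append(tau)
        taus = np.asarray(taus)
        sem = taus.std() / np.sqrt(taus.size)
        assert taus.size > 100
        assert abs(taus.mean() - 1 / k_off) < 4 * sem + dt


class TestTipTracking:
    def test_comoving_spot_classified_true(self):
        spot = SpotModel(position_px=50.0, tip_tracking=True, peak_photons=100)
        kymo, mt, truth = gen_kymograph(
            40, tip_velocity_nm_s=150.0, spot=spot, noise=CameraNoise(background=2.0), seed=3
        )
        spot_track = trace_spot(kymo, (5, truth.spot_position_px[5]))
        tip = TipTrack(frames=np.arange(40), positions_px=truth.tip_position_px)
        assert classify_tip_tracking(spot_track, tip)

    def test_static_spot_moving_tip_false(self):
        tip = TipTrack(frames=np.arange(40), positions_px=60.0 - 0.5 * np.arange(40))
        spot = SpotTrack(
            frames=np.arange(40), positions_px=np.full(40, 30.0),
            intensities_au=np.ones(40), landing_frame=0, detach_frame=39,
        )
        assert not classify_tip_tracking(spot, tip)

    def test_static_tip_never_tip_tracking(self):
        tip = TipTrack(frames=np.arange(40), positions_px=np.full(40, 30.0))
        spot = SpotTrack(
            frames=np.arange(40), positions_px=np.full(40, 30.0),
            intensities_au=np.ones(40), landing_frame=0, detach_frame=39,
        )
        assert not classify_tip_tracking(spot, tip)  # tip never moves 3 px

    def test_no_overlap_raises(self):
        tip = TipTrack(frames=np.arange(10), positions_px=np.full(10, 3.0))
        spot = SpotTrack(
            frames=np.arange(20, 30), positions_px=np.full(10, 3.0),
            intensities_au=np.ones(10), landing_frame=20, detach_frame=29,
        )
        with pytest.raises(ValueError, match="share no frames"):
            classify_tip_tracking(spot, tip)

    def test_classification_accuracy_on_mixed_ensemble(self):
        correct = 0
        n_each = 30
        for i in range(2 * n_each):
            tracking = i < n_each
            spot = SpotModel(
                position_px=40.0, tip_tracking=tracking, peak_photons=100,
            )
            kymo, _, truth = gen_kymograph(
                40, tip_velocity_nm_s=180.0, tip_start_px=58.0, spot=spot,
                noise=CameraNoise(background=2.0), seed=800 + i,
                detach_on_tip_pass=False,
            )
            tip = TipTrack(frames=np.arange(40), positions_px=truth.tip_position_px)
            try:
                track = trace_spot(kymo, (2, truth.spot_position_px[2]))
            except EmptyTrackError:
                continue
            if classify_tip_tracking(track, tip) == tracking:
                correct += 1
        assert correct / (2 * n_each) >= 0.95


class TestTipVelocity:
    def test_exact_slope(self):
        tip = TipTrack(frames=np.arange(20), positions_px=50.0 - 1.375 * np.arange(20))
        assert tip_velocity(tip, 160.0, 1.1) == pytest.approx(200.0)

    def test_static_tip_zero(self):
        tip = TipTrack(frames=np.arange(10), positions_px=np.full(10, 12.0))
        assert tip_velocity(tip, 160.0, 1.1) == pytest.approx(0.0)

    def test_noisy_tip_within_5_percent(self):
        rng = np.random.default_rng(6)
        pos = 55.0 - 1.0 * np.arange(60) + rng.normal(0, 0.3, 60)
        tip = TipTrack(frames=np.arange(60), positions_px=pos)
        assert tip_velocity(tip, 160.0, 1.1) == pytest.approx(160.0 / 1.1, rel=0.05)

    def test_too_few_frames(self):
        tip = TipTrack(frames=np.arange(4), positions_px=np.zeros(4))
        with pytest.raises(ValueError, match=">= 5"):
            tip_velocity(tip, 160.0, 1.0)

    def test_trace_tip_recovers_erf_edge(self):
        _, mt, truth = gen_kymograph(
            30, tip_velocity_nm_s=200.0, noise=CameraNoise(background=2.0), seed=9
        )
        tip = trace_tip(mt)
        err = tip.positions_px - truth.tip_position_px[tip.frames]
        assert tip.frames.size >= 28
        assert np.sqrt((err**2).mean()) < 0.4
        assert np.abs(err).max() < 1.0
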