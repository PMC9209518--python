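"""Linking, event calling, engagement and MSD analysis."""
import numpy as np
import pytest

from chromodyn import presets, synthgen, tracking
from chromodyn.tracking import Detection, msd, msd_bruteforce


def _det(frame, y, x, inten=100.0):
    return Detection(frame=frame, y_um=y, x_um=x, total_intensity=inten)


class TestLinking:
    def test_two_stationary_foci_two_tracks_no_events(self):
        dets = [[_det(f, 0.0, 0.0), _det(f, 5.0, 5.0)] for f in range(10)]
        tracks, events = tracking.link_tracks(dets, max_disp_um=1.0)
        assert len(tracks) == 2
        assert events == []
        assert all(len(t.frames) == 10 for t in tracks)

    def test_scripted_merge_called_at_exact_frame(self):
        dets = []
        for f in range(40):
            if f < 20:
                dets.append([_det(f, 0.0, 0.0), _det(f, 0.0, 0.8)])
            else:
                dets.append([_det(f, 0.0, 0.1)])
        tracks, events = tracking.link_tracks(dets, max_disp_um=1.0)
        coal = [e for e in events if e.kind == "coalescence"]
        assert len(coal) == 1
        assert coal[0].frame == 20

    def test_scripted_split_called_at_exact_frame(self):
        dets = []
        for f in range(40):
            if f < 20:
                dets.append([_det(f, 0.0, 0.0)])
            else:
                dets.append([_det(f, 0.0, 0.0), _det(f, 0.0, 0.8)])
        tracks, events = tracking.link_tracks(dets, max_disp_um=1.0)
        cleav = [e for e in events if e.kind == "cleavage"]
        assert len(cleav) == 1
        assert cleav[0].frame == 20

    def test_permutation_invariance_within_frame(self):
        rng = np.random.default_rng(0)
        base = [[_det(f, y, x) for y, x in rng.uniform(0, 10, (5, 2))]
                for f in range(1)]
        frames = [base[0]]
        for f in range(1, 8):
            frames.append([_det(f, d.y_um + 0.05, d.x_um) for d in frames[-1]])
        shuffled = [list(fr) for fr in frames]
        for fr in shuffled:
            rng.shuffle(fr)
        a, _ = tracking.link_tracks(frames, max_disp_um=1.0)
        b, _ = tracking.link_tracks(shuffled, max_disp_um=1.0)
        key = lambda tracks: sorted(tuple(map(tuple, t.xy())) for t in tracks)
        assert key(a) == key(b)

    def test_no_detections_gives_empty_result(self):
        tracks, events = tracking.link_tracks([[], [], []])
        assert tracks == [] and events == []


class TestEngagement:
    def test_zero_events_is_zero(self):
        dets = [[_det(f, 0.0, 0.0)] for f in range(41)]
        tracks, events = tracking.link_tracks(dets, max_disp_um=1.0)
        assert tracking.event_engagement(tracks, events, 30.0) == 0.0

    def test_short_tracks_excluded(self):
        dets = [[_det(f, 0.0, 0.0)] for f in range(41)]
        for f in range(5):  # a 5-frame track, far away
            dets[f].append(_det(f, 20.0, 20.0))
        tracks, events = tracking.link_tracks(dets, max_disp_um=1.0)
        frac = tracking.event_engagement(tracks, events, 30.0,
                                         min_duration_s=600.0)
        assert frac == 0.0
        with pytest.warns(UserWarning):
            out = tracking.event_engagement(tracks, events, 30.0,
                                            min_duration_s=1e9)
        assert np.isnan(out)


class TestMsd:
    def test_stationary_track_zero(self):
        pos = np.zeros((50, 2))
        _, m = msd(pos, 1.0)
        assert np.allclose(m, 0.0)

    def test_pure_drift_closed_form(self):
        v = 0.02
        t = np.arange(100.0)
        pos = np.stack([v * t, np.zeros(100)], axis=1)
        lags, m = msd(pos, 1.0)
        assert np.allclose(m, (v * lags) ** 2, rtol=1e-12)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(20, 100))
            pos = rng.normal(size=(n, 2)).cumsum(axis=0)
            l1, m1 = msd(pos, 2.0)
            l2, m2 = msd_bruteforce(pos, 2.0)
            assert np.allclose(l1, l2)
            assert np.allclose(m1, m2, atol=1e-12)


class TestFitMsd:
    def test_brownian_line_exact(self):
        lags = np.arange(1.0, 30.0)
        c = 0.4
        fit = tracking.fit_msd(lags, c * lags)
        assert fit.alpha == pytest.approx(1.0, abs=1e-9)
        assert fit.d_app == pytest.approx(c / 4, rel=1e-9)

    def test_pure_drift_velocity_recovered(self):
        v = 0.02
        lags = np.arange(1.0, 40.0)
        fit = tracking.fit_msd(lags, (v * lags) ** 2)
        assert fit.velocity == pytest.approx(v, rel=0.05)
        assert fit.d_lin == pytest.approx(0.0, abs=1e-9)

    def test_refuses_underdetermined_curve(self):
        with pytest.raises(ValueError):
            tracking.fit_msd(np.arange(1.0, 5.0), np.zeros(4))

    def test_net_displacement_velocity(self):
        pos = np.array([[0.0, 0.0], [3.0, 4.0]])
        assert tracking.net_displacement_velocity(pos, 10.0) == pytest.approx(0.5)


class TestTrajectoryGeneration:
    def test_pure_drift_trajectory(self):
        from dataclasses import replace
        dp = replace(presets.dynamics_preset("displacement_ctrl"),
                     d_app=0.0, velocity=0.02)
        pos = synthgen.make_trajectory(dp, seed=0)
        lags, m = msd(pos, dp.frame_interval_s)
        assert np.allclose(m, (0.02 * lags) ** 2, rtol=1e-9)

    def test_alpha_recovery_short_battery(self):
        """Log-log MSD slope recovers the anomalous exponent on fBm tracks."""
        dp = presets.dynamics_preset("displacement_ctrl")
        alphas = [tracking.fit_msd(*msd(synthgen.make_trajectory(dp, seed=s),
                                        dp.frame_interval_s)).alpha
                  for s in range(40)]
        assert abs(np.mean(alphas) - dp.alpha) < 0.1

    def test_timelapse_truth_consistency(self):
        dp = presets.dynamics_preset("ctrl_dynamics")
        npre = presets.nucleus_preset("gfp_gapmer")
        stack, truth = synthgen.make_timelapse(dp, npre, seed=5)
        assert stack.shape[0] == dp.n_frames
        spans = {f["uid"]: (f["birth"], f["death"]) for f in truth.foci}
        for e in truth.events:
            for uid in e["participants"]:
                b, d = spans[uid]
                assert b <= e["frame"] <= d + 1

    def test_no_events_when_rates_zero(self):
        from dataclasses import replace
        dp = replace(presets.dynamics_preset("ctrl_dynamics"),
                     fusion_rate=0.0, fission_rate=0.0)
        npre = presets.nucleus_preset("gfp_gapmer")
        _, truth = synthgen.make_timelapse(dp, npre, seed=0)
        assert truth.events == []
        assert all(f["birth"] == 0 and f["death"] == dp.n_frames - 1
                   for f in truth.foci)

    def test_timelapse_determinism(self):
        dp = presets.dynamics_preset("msr_dynamics")
        npre = presets.nucleus_preset("gfp_gapmer")
        a, ta = synthgen.make_timelapse(dp, npre, seed=3)
        b, tb = synthgen.make_timelapse(dp, npre, seed=3)
        assert np.array_equal(a, b)
        assert ta.events == tb.events

    def test_track_recovery_exact_on_separated_noiseless_movie(self):
        """Every truth track is recovered one-to-one when foci stay apart."""
        from dataclasses import replace
        dp = replace(presets.dynamics_preset("ctrl_dynamics"),
                     fusion_rate=0.0, fission_rate=0.0, n_foci=8)
        npre = presets.nucleus_preset("gfp_gapmer")
        stack, truth = synthgen.make_timelapse(dp, npre, seed=2)
        dets = tracking.detect_foci(stack, pixel_size_um=npre.voxel_size_um)
        tracks, _ = tracking.link_tracks(dets, max_disp_um=1.5)
        full = [t for t in tracks if len(t.frames) == dp.n_frames]
        assert len(full) == 8
        center = np.array(stack.shape[1:]) / 2 * npre.voxel_size_um
        ends = np.array([t.positions[-1] for t in full])
        for f in truth.foci:
            true_end = np.asarray(f["positions"][-1]) + center
            d = np.linalg.norm(ends - true_end, axis=1).min()
            assert d < 0.3
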