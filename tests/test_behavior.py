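import numpy as np
import pytest

from circadia import (
    CircadianSeries,
    LightingSchedule,
    activity_amplitude,
    chi_square_periodogram,
    compare_g_distributions,
    day_night_summary,
    g_factor,
    masking_percentages,
    movement_seconds,
    place_preference,
    sleep_time,
)
from circadia.behavior import LarvaTrack, zone_of
from circadia.synth import (
    GenotypeProfile,
    RhythmSpec,
    control_activity_profile,
    dclk_activity_profile,
    make_locomotor_track,
)

DARK = LightingSchedule.constant("dark")


def velocity_track(velocities, rate_hz=1.0):
    v = np.asarray(velocities, dtype=float)
    return LarvaTrack(
        larva_id="t", schedule=DARK,
        frame_times_s=np.arange(v.size) / rate_hz,
        frame_velocity_cm_s=v,
    )


class TestMovementSeconds:
    def test_still_larva_scores_zero(self):
        sec = movement_seconds(velocity_track(np.zeros(180)))
        assert sec.tolist() == [0.0, 0.0, 0.0]

    def test_constantly_moving_larva_scores_full_minutes(self):
        sec = movement_seconds(velocity_track(np.ones(120)))
        assert sec.tolist() == [60.0, 60.0]

    def test_hysteresis_state_persists_between_thresholds(self):
        # stopped larva at 0.595 cm/s (between stop 0.59 and start 0.6) stays stopped
        v = np.concatenate([np.zeros(60), np.full(60, 0.595)])
        sec = movement_seconds(velocity_track(v))
        assert sec.tolist() == [0.0, 0.0]
        # but a moving larva at 0.595 stays moving
        v = np.concatenate([np.ones(60), np.full(60, 0.595)])
        sec = movement_seconds(velocity_track(v))
        assert sec.tolist() == [60.0, 60.0]

    def test_matches_stateful_loop_oracle(self, rng):
        v = rng.uniform(0, 1.2, size=600)
        sec = movement_seconds(velocity_track(v))
        state, acc = 0, np.zeros(10)
        for i, vi in enumerate(v):
            if vi >= 0.6:
                state = 1
            elif vi <= 0.59:
                state = 0
            acc[i // 60] += state
        np.testing.assert_allclose(sec, acc)

    def test_missing_frame_metadata_is_an_error(self):
        track = LarvaTrack(larva_id="x", schedule=DARK)
        with pytest.raises(ValueError):
            movement_seconds(track)


class TestSleepTime:
    def test_fully_still_hour_sleeps_sixty_minutes(self):
        rec = sleep_time(np.zeros(60))
        assert rec.sleep_minutes.tolist() == [60.0]
        assert np.isnan(rec.waking_activity[0])

    def test_alternating_minutes_sleep_thirty(self):
        sec = np.tile([0.0, 5.0], 30)
        rec = sleep_time(sec)
        assert rec.sleep_minutes.tolist() == [30.0]
        assert rec.waking_activity[0] == pytest.approx(5.0)

    def test_matches_direct_count_oracle(self, rng):
        moving = rng.integers(0, 2, size=240).astype(float) * rng.uniform(1, 30, 240)
        rec = sleep_time(moving)
        for h in range(4):
            chunk = moving[h * 60 : (h + 1) * 60]
            assert rec.sleep_minutes[h] == (chunk == 0).sum()

    def test_sleep_plus_waking_minutes_conserve_the_hour(self, rng):
        moving = (rng.uniform(size=120) < 0.5) * 10.0
        rec = sleep_time(moving)
        waking_minutes = 60.0 - rec.sleep_minutes
        assert np.all(rec.sleep_minutes + waking_minutes == 60.0)

    def test_partial_trailing_hour_dropped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="partial"):
            rec = sleep_time(np.zeros(90))
        assert rec.sleep_minutes.size == 1

    def test_waking_activity_values(self):
        sec = np.concatenate([np.full(30, 10.0), np.zeros(30)])
        rec = sleep_time(sec)
        assert rec.waking_activity[0] == pytest.approx(300.0 / 30.0)


class TestChiSquarePeriodogram:
    @staticmethod
    def fold_oracle(x, dt, period):
        """Direct fold-and-variance computation."""
        k = int(round(period / dt))
        r = x.size // k
        folded = x[: r * k].reshape(r, k)
        n = r * k
        return n * folded.mean(axis=0).var() / folded.var()

    def test_square_wave_peaks_at_24(self):
        dt = 1 / 6  # 10-min bins
        t = np.arange(0, 96, dt)
        x = (t % 24 < 12).astype(float)
        s = CircadianSeries(0.0, dt, x)
        res = chi_square_periodogram(s)
        assert res.best_period_hr == pytest.approx(24.0, abs=dt)

    def test_matches_fold_oracle(self, rng):
        dt = 0.5
        x = rng.normal(size=300) + np.cos(2 * np.pi * np.arange(300) * dt / 24)
        s = CircadianSeries(0.0, dt, x)
        res = chi_square_periodogram(s)
        for p, qp in zip(res.periods_hr, res.qp):
            assert qp == pytest.approx(self.fold_oracle(x, dt, p), abs=1e-10)

    def test_constant_series_is_never_significant(self):
        s = CircadianSeries(0.0, 0.5, np.full(200, 4.0))
        res = chi_square_periodogram(s)
        assert res.best_period_hr is None

    def test_white_noise_false_positive_rate_bonferroni(self, rng):
        alpha = 0.01
        hits = 0
        n_seeds = 100
        for _ in range(n_seeds):
            x = rng.normal(size=600)
            s = CircadianSeries(0.0, 0.5, x)
            grid = np.arange(40, 57) * 0.5  # 20-28 hr
            res = chi_square_periodogram(s, period_grid_hr=grid, alpha=alpha / grid.size)
            hits += res.best_period_hr is not None
        assert hits / n_seeds <= alpha * grid.size + 0.05

    def test_grid_beyond_data_span_rejected(self):
        s = CircadianSeries(0.0, 1.0, np.random.default_rng(0).normal(size=30))
        with pytest.raises(ValueError):
            chi_square_periodogram(s, period_grid_hr=np.array([20.0]))

    @pytest.mark.parametrize("true_period", [23.6, 24.0, 24.9, 25.8])
    def test_recovers_generating_period_within_one_grid_step(self, true_period):
        # ten simulated days give the fold enough rows to resolve one bin
        dt = 1 / 6
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            profile = GenotypeProfile(
                "c", RhythmSpec(period_hr=true_period, amplitude=10.0,
                                baseline=20.0, noise_sd=2.0),  # snr 5
            )
            track = make_locomotor_track(profile, DARK, days=10, seed=seed,
                                         emit_frames=False)
            res = chi_square_periodogram(track.activity)
            if res.best_period_hr is not None and abs(res.best_period_hr - true_period) <= dt + 1e-9:
                hits += 1
        assert hits >= int(0.9 * n_seeds)


class TestActivityAmplitude:
    def test_peak_minus_trough_over_two(self):
        dt = 1.0
        vals = np.full(72, 20.0)
        vals[30] = 45.0   # day-7 window is hours 24..48 when recording starts day 6
        vals[27] = 15.0   # preceding trough between prior peak and the day-7 peak
        vals[20] = 30.0   # prior day's peak
        s = CircadianSeries(0.0, dt, vals)
        assert activity_amplitude(s, target_day=7, recording_start_day=6.0) == 15.0

    def test_flat_series_has_zero_amplitude(self):
        s = CircadianSeries(0.0, 1.0, np.full(72, 7.0))
        assert activity_amplitude(s) == 0.0

    def test_missing_day_window_is_an_error(self):
        s = CircadianSeries(0.0, 1.0, np.ones(24))
        with pytest.raises(ValueError):
            activity_amplitude(s, target_day=7)

    def test_recovers_generating_amplitude_within_ten_percent(self):
        from circadia import moving_average

        amp = 13.4
        rel_errors = []
        for seed in range(50):
            profile = GenotypeProfile(
                "c", RhythmSpec(amplitude=amp, baseline=30.0, noise_sd=amp / 5),  # snr 5
            )
            track = make_locomotor_track(profile, DARK, days=3, seed=seed,
                                         emit_frames=False)
            smoothed = moving_average(track.activity, 20)
            est = activity_amplitude(smoothed, target_day=7, recording_start_day=6.0)
            rel_errors.append(abs(est - amp) / amp)
        assert np.mean(rel_errors) <= 0.10


class TestMaskingPercentages:
    def test_activity_only_in_light(self):
        sched = LightingSchedule.cycles("light", "dark", 3.5, 4)
        t_exp = np.arange(0, 28, 0.5)
        conds = sched.conditions_at(t_exp)
        vals = (conds == "light").astype(float)
        s = CircadianSeries(0.0, 0.5, vals, schedule=sched)
        light, dark = masking_percentages(s)
        assert (light, dark) == (100.0, 0.0)

    def test_uniform_activity_splits_by_bout_length(self):
        sched = LightingSchedule.cycles("light", "dark", 3.5, 4)
        s = CircadianSeries(0.0, 0.5, np.ones(56), schedule=sched)
        light, dark = masking_percentages(s)
        assert light == pytest.approx(50.0)
        assert dark == pytest.approx(50.0)

    def test_matches_per_epoch_summation_oracle(self, rng):
        sched = LightingSchedule.cycles("light", "dark", 3.5, 4)
        vals = rng.uniform(0, 5, size=56)
        s = CircadianSeries(0.0, 0.5, vals, schedule=sched)
        light, dark = masking_percentages(s)
        conds = sched.conditions_at(s.t_exp)
        exp_light = 100 * vals[conds == "light"].sum() / vals.sum()
        assert light == pytest.approx(exp_light)
        assert light + dark == pytest.approx(100.0)

    def test_zero_activity_is_an_error(self):
        s = CircadianSeries(0.0, 1.0, np.zeros(24), schedule=DARK)
        with pytest.raises(ValueError):
            masking_percentages(s)


class TestPlacePreference:
    def test_zone_boundaries_go_to_upper_zone(self):
        h = 30.0
        assert zone_of(np.array([30.0]), h)[0] == 0   # surface
        assert zone_of(np.array([20.0]), h)[0] == 0   # top/middle line -> top
        assert zone_of(np.array([10.0]), h)[0] == 1   # middle/bottom line -> middle
        assert zone_of(np.array([0.0]), h)[0] == 2    # floor

    def test_even_spread_gives_third_in_top(self):
        y = np.concatenate([np.full(5, 25.0), np.full(5, 15.0), np.full(5, 5.0)])
        series = place_preference(np.array([0.0]), y[None, :], 30.0)
        assert series.top[0] == pytest.approx(1 / 3)

    def test_all_at_surface(self):
        series = place_preference(np.array([0.0]), np.full((1, 15), 30.0), 30.0)
        assert series.top[0] == 1.0

    def test_fractions_sum_to_one_and_match_count_oracle(self, rng):
        times = np.arange(40) * 15.0
        y = rng.uniform(0, 30, size=(40, 15))
        series = place_preference(times, y, 30.0, bin_minutes=5.0)
        np.testing.assert_allclose(series.top + series.middle + series.bottom, 1.0)
        zones = zone_of(y.ravel(), 30.0).reshape(40, 15)
        # first 5-min bin holds the first 20 snapshots
        assert series.top[0] == pytest.approx((zones[:20] == 0).mean())

    def test_out_of_chamber_position_is_an_error(self):
        with pytest.raises(ValueError, match="snapshot"):
            place_preference(np.array([0.0]), np.array([[31.0]]), 30.0)


class TestDayNightSummary:
    def test_day_indicator_metric(self):
        s = CircadianSeries(0.0, 1.0, (np.arange(48) % 24 < 12).astype(float))
        day, night = day_night_summary(s)
        assert (day, night) == (1.0, 0.0)

    def test_constant_metric_equal_means(self):
        s = CircadianSeries(0.0, 1.0, np.full(48, 3.0))
        day, night = day_night_summary(s)
        assert day == night == 3.0

    def test_day_active_cosine_signs(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            ct = np.arange(48) % 24
            vals = 10 + 5 * np.cos(2 * np.pi * (ct - 6) / 24) + rng.normal(0, 1, 48)
            s = CircadianSeries(0.0, 1.0, vals)
            day, night = day_night_summary(s)
            assert day > night

    def test_narrow_ct_windows(self):
        s = CircadianSeries(0.0, 1.0, np.arange(24.0))
        day, night = day_night_summary(s, (5.0, 6.0), (17.0, 18.0))
        assert (day, night) == (5.0, 17.0)

    def test_empty_window_is_an_error(self):
        s = CircadianSeries(0.0, 4.0, np.ones(12))
        with pytest.raises(ValueError):
            day_night_summary(s, (1.0, 2.0), (12.0, 24.0))


class TestGroupSeparation:
    def test_control_vs_dclk_g_distributions_separate_under_dd(self):
        # synthetic analogue of the DD locomotor comparison: 24 larvae per
        # group, two cycles, KS on per-larva G-factors
        n_sig = 0
        n_runs = 20
        for seed in range(n_runs):
            g = {}
            for profile in (control_activity_profile(), dclk_activity_profile()):
                gs = []
                for i in range(24):
                    track = make_locomotor_track(
                        profile, DARK, days=2, seed=seed * 1000 + i
                        + (0 if profile.name == "control" else 500),
                        emit_frames=False,
                    )
                    gs.append(g_factor(track.activity))
                g[profile.name] = gs
            res = compare_g_distributions(g["control"], g["dclk"])
            n_sig += res.pvalue < 0.05
        assert n_sig >= int(0.8 * n_runs)
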