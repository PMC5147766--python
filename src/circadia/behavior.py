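"""Larval locomotor, sleep, masking, and place-preference analytics.

Conventions follow the standard larval-zebrafish assays: activity is total
distance moved per 10-min bin; movement detection uses a velocity hysteresis
(start at 0.6 cm/s, stop at 0.59 cm/s); sleep is a minute without movement,
aggregated per hour; waking activity is seconds of movement per awake
minute; periods come from the Enright / Sokolove-Bushell chi-square
periodogram; amplitude is (day-7 peak - preceding trough) / 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .timeseries import CircadianSeries, LightingSchedule

START_VELOCITY_CM_S = 0.6
STOP_VELOCITY_CM_S = 0.59


@dataclass
class LarvaTrack:
    """Per-larva movement record under a lighting schedule.

    Holds per-frame velocities (for sleep scoring) and/or a pre-binned
    activity series (distance per bin). ``t0_ct_hr`` is the circadian time
    at recording start; ``start_day`` the developmental day (dpf) on which
    the recording starts.
    """

    larva_id: str
    schedule: LightingSchedule
    genotype: str = ""
    frame_times_s: np.ndarray | None = None
    frame_velocity_cm_s: np.ndarray | None = None
    activity: CircadianSeries | None = None
    t0_ct_hr: float = 0.0
    start_day: float = 6.0

    def __post_init__(self) -> None:
        if self.frame_times_s is not None:
            self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
            if np.any(np.diff(self.frame_times_s) <= 0):
                raise ValueError("frame times must be strictly increasing")
        if self.frame_velocity_cm_s is not None:
            self.frame_velocity_cm_s = np.asarray(self.frame_velocity_cm_s, dtype=float)
            if np.any(self.frame_velocity_cm_s < 0):
                raise ValueError("velocities must be nonnegative")

    @property
    def frame_rate_hz(self) -> float:
        if self.frame_times_s is None or self.frame_times_s.size < 2:
            raise ValueError("frame-rate metadata unavailable: no frame times")
        dts = np.diff(self.frame_times_s)
        if not np.allclose(dts, dts[0]):
            raise ValueError("frame times are not uniform; frame rate undefined")
        return 1.0 / float(dts[0])


def movement_seconds(track: LarvaTrack, bin_minutes: float = 1.0) -> np.ndarray:
    """Seconds spent moving per time bin, by velocity hysteresis.

    The larva enters the moving state when velocity >= 0.6 cm/s and leaves
    it when velocity <= 0.59 cm/s; between the thresholds the state
    persists (initial state: stopped). Seconds in the moving state are
    accumulated per ``bin_minutes`` bin; the trailing partial bin is dropped.
    """
    if track.frame_velocity_cm_s is None:
        raise ValueError("track has no per-frame velocities")
    rate = track.frame_rate_hz
    v = track.frame_velocity_cm_s
    decided = np.where(
        v >= START_VELOCITY_CM_S, 1.0, np.where(v <= STOP_VELOCITY_CM_S, 0.0, np.nan)
    )
    idx = np.where(~np.isnan(decided), np.arange(v.size), -1)
    np.maximum.accumulate(idx, out=idx)
    state = np.where(idx >= 0, decided[np.maximum(idx, 0)], 0.0)
    frame_s = 1.0 / rate
    bin_s = bin_minutes * 60.0
    t = track.frame_times_s - track.frame_times_s[0]
    bins = np.floor(t / bin_s).astype(int)
    n_bins = int(np.floor((t[-1] + frame_s) / bin_s))
    if n_bins < 1:
        raise ValueError("recording shorter than one bin")
    keep = bins < n_bins
    return np.bincount(bins[keep], weights=state[keep] * frame_s, minlength=n_bins)


@dataclass
class SleepRecord:
    """Per-hour sleep minutes and waking activity.

    ``sleep_minutes + waking minutes = 60`` for every complete hour; waking
    activity is NaN for hours with no awake minute (undefined, not zero).
    """

    sleep_minutes: np.ndarray
    waking_activity: np.ndarray

    def __post_init__(self) -> None:
        self.sleep_minutes = np.asarray(self.sleep_minutes, dtype=float)
        self.waking_activity = np.asarray(self.waking_activity, dtype=float)


def sleep_time(seconds_moving_per_minute: np.ndarray) -> SleepRecord:
    """Hourly sleep minutes (a minute is asleep iff it has zero movement).

    A trailing partial hour is dropped with a warning. Waking activity per
    hour is total movement seconds divided by the number of awake minutes
    (NaN when the hour is fully asleep).
    """
    sec = np.asarray(seconds_moving_per_minute, dtype=float)
    n_hours = sec.size // 60
    if n_hours == 0:
        raise ValueError("need at least one complete hour of minute bins")
    if sec.size % 60:
        warnings.warn("partial trailing hour dropped", RuntimeWarning, stacklevel=2)
        sec = sec[: n_hours * 60]
    by_hour = sec.reshape(n_hours, 60)
    asleep = by_hour == 0.0
    sleep_min = asleep.sum(axis=1).astype(float)
    awake_min = 60.0 - sleep_min
    with np.errstate(invalid="ignore", divide="ignore"):
        waking = by_hour.sum(axis=1) / awake_min
    waking[awake_min == 0] = np.nan
    return SleepRecord(sleep_minutes=sleep_min, waking_activity=waking)


def waking_activity(seconds_moving_per_minute: np.ndarray) -> np.ndarray:
    """Hourly seconds of movement per awake minute (NaN if fully asleep)."""
    return sleep_time(seconds_moving_per_minute).waking_activity


@dataclass
class PeriodogramResult:
    periods_hr: np.ndarray
    qp: np.ndarray
    significance: np.ndarray
    alpha: float
    best_period_hr: float | None


def chi_square_periodogram(
    series: CircadianSeries,
    period_grid_hr: np.ndarray | None = None,
    alpha: float = 0.05,
) -> PeriodogramResult:
    """Enright chi-square periodogram with a chi-square significance line.

    For each trial period P (rounded to a whole number of bins K), the
    series is folded into columns of length K using the largest whole number
    of rows R (trailing remainder dropped), and

        Qp = N * Var(column means) / Var(series),   N = R * K,

    which is ~ chi-square with K - 1 degrees of freedom for white noise. The
    best period is the grid point with the largest Qp among those exceeding
    the chi-square(1 - alpha, K - 1) line, or None if nothing is significant.
    The default grid runs 20-28 hr in steps of one bin width.
    """
    dt = series.dt_hr
    x = series.values
    if period_grid_hr is None:
        period_grid_hr = np.arange(round(20 / dt), round(28 / dt) + 1) * dt
    period_grid_hr = np.asarray(period_grid_hr, dtype=float)
    if np.any(period_grid_hr * 2 > x.size * dt):
        raise ValueError("period grid exceeds half the data span")
    qp = np.empty(period_grid_hr.size)
    sig = np.empty(period_grid_hr.size)
    for i, p in enumerate(period_grid_hr):
        k = int(round(p / dt))
        if k < 2:
            raise ValueError(f"trial period {p} hr shorter than two bins")
        r = x.size // k
        folded = x[: r * k].reshape(r, k)
        col_means = folded.mean(axis=0)
        n = r * k
        fold_var = folded.var()
        qp[i] = 0.0 if fold_var == 0 else n * col_means.var() / fold_var
        sig[i] = stats.chi2.ppf(1 - alpha, df=k - 1)
    above = qp > sig
    best = float(period_grid_hr[np.argmax(np.where(above, qp, -np.inf))]) if above.any() else None
    return PeriodogramResult(
        periods_hr=period_grid_hr, qp=qp, significance=sig, alpha=alpha, best_period_hr=best
    )


def activity_amplitude(
    series: CircadianSeries, target_day: int = 7, recording_start_day: float = 6.0
) -> float:
    """(day-``target_day`` activity peak - preceding trough) / 2.

    Days are counted on the developmental (dpf) clock with window boundaries
    at CT0. The preceding trough is the minimum between the previous day's
    peak and the target day's peak.
    """
    # hours on the dpf clock for each sample
    hours = recording_start_day * 24.0 + series.t0_ct_hr + np.arange(len(series)) * series.dt_hr
    day_lo, day_hi = target_day * 24.0, (target_day + 1) * 24.0
    in_day = (hours >= day_lo) & (hours < day_hi)
    in_prev = (hours >= day_lo - 24.0) & (hours < day_lo)
    if not in_day.any() or not in_prev.any():
        raise ValueError(f"series does not cover day {target_day} and the preceding day")
    day_idx = np.flatnonzero(in_day)
    peak_i = day_idx[np.argmax(series.values[day_idx])]
    prev_idx = np.flatnonzero(in_prev)
    prev_peak_i = prev_idx[np.argmax(series.values[prev_idx])]
    trough = series.values[prev_peak_i : peak_i + 1].min()
    return float((series.values[peak_i] - trough) / 2.0)


def masking_percentages(
    series: CircadianSeries, schedule: LightingSchedule | None = None
) -> tuple[float, float]:
    """Percentage of total activity falling in light vs dark bouts."""
    schedule = schedule or series.schedule
    conds = schedule.conditions_at(series.t_exp)
    total = series.values.sum()
    if total <= 0:
        raise ValueError("zero total activity")
    light = series.values[conds == "light"].sum()
    dark = series.values[conds == "dark"].sum()
    return 100.0 * light / total, 100.0 * dark / total


@dataclass
class PlacePreferenceSeries:
    """Per-bin fractions of larvae in the top/middle/bottom thirds."""

    top: np.ndarray
    middle: np.ndarray
    bottom: np.ndarray
    bin_minutes: float
    group_id: str = ""

    def __post_init__(self) -> None:
        for name in ("top", "middle", "bottom"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))


def zone_of(y: np.ndarray, chamber_height: float) -> np.ndarray:
    """Zone index (0 = top, 1 = middle, 2 = bottom) of y-positions.

    ``y`` is height above the chamber floor; a larva exactly on a zone
    boundary is assigned to the upper zone.
    """
    y = np.asarray(y, dtype=float)
    if chamber_height <= 0:
        raise ValueError("chamber height must be positive")
    bad = np.flatnonzero((y < 0) | (y > chamber_height))
    if bad.size:
        raise ValueError(f"y outside [0, height] at snapshot position {int(bad[0])}")
    depth = 3.0 * (1.0 - y / chamber_height)
    z = np.ceil(depth) - 1
    return np.clip(z, 0, 2).astype(int)


def place_preference(
    snapshot_times_s: np.ndarray,
    positions_y: np.ndarray,
    chamber_height: float,
    bin_minutes: float = 5.0,
    group_id: str = "",
) -> PlacePreferenceSeries:
    """Fractions of larvae per third of the water column, per time bin.

    ``positions_y`` is snapshots x larvae (height above the floor). Zone
    fractions are computed per snapshot and averaged over the snapshots in
    each ``bin_minutes`` bin; the three fractions sum to 1 in every bin.
    """
    t = np.asarray(snapshot_times_s, dtype=float)
    y = np.atleast_2d(np.asarray(positions_y, dtype=float))
    if y.shape[0] != t.size:
        raise ValueError("one row of positions per snapshot required")
    zones = zone_of(y.ravel(), chamber_height).reshape(y.shape)
    frac = np.stack([(zones == z).mean(axis=1) for z in (0, 1, 2)], axis=1)
    bin_s = bin_minutes * 60.0
    bins = np.floor((t - t[0]) / bin_s).astype(int)
    n_bins = bins.max() + 1
    counts = np.bincount(bins, minlength=n_bins)
    means = np.stack(
        [np.bincount(bins, weights=frac[:, z], minlength=n_bins) / counts for z in (0, 1, 2)],
        axis=1,
    )
    return PlacePreferenceSeries(
        top=means[:, 0], middle=means[:, 1], bottom=means[:, 2],
        bin_minutes=bin_minutes, group_id=group_id,
    )


def day_night_summary(
    series: CircadianSeries,
    day_window_ct: tuple[float, float] = (0.0, 12.0),
    night_window_ct: tuple[float, float] = (12.0, 24.0),
) -> tuple[float, float]:
    """(subjective-day mean, subjective-night mean) of a CT-annotated metric.

    Windows are half-open CT intervals; the defaults split the cycle into
    subjective day (CT 0-12) and subjective night (CT 12-24). Narrow
    windows such as CT 5-6 vs CT 17-18 can be passed for paired summaries.
    """
    ct = series.ct
    means = []
    for lo, hi in (day_window_ct, night_window_ct):
        mask = (ct >= lo) & (ct < hi)
        if not mask.any():
            raise ValueError(f"no samples fall in CT window [{lo}, {hi})")
        means.append(float(series.values[mask].mean()))
    return means[0], means[1]
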