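"""Synthetic inputs with the statistical structure of the study's assays.

Every generator is a pure function of its parameters and a seed, and every
generated object comes with its ground truth (planted rhythmic labels,
generating amplitudes), so each pipeline stage can be tested end to end
without any sequencing data. Defaults encode the study conditions: the
12-time-point, 4-hr, two-cycle DD expression design starting at CT14; DD
locomotor amplitudes of 13.4 (control) vs 4.5 (pineal-clock-blocked, dclk)
cm/10 min; group sizes of 24 larvae; melatonin release suppressed to a few
percent of the night peak whenever lights are on (light degrades AANAT2
independently of the clock).

Noise models are the package's own assumptions (the assays' noise is not
characterized upstream): Gaussian on the log scale for expression,
truncated-at-zero Gaussian for activity, lognormal (multiplicative) for
melatonin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .behavior import LarvaTrack
from .timeseries import CircadianSeries, LightingSchedule
from .transcriptome import CANONICAL_CT_LABELS, ExpressionMatrix


@dataclass(frozen=True)
class RhythmSpec:
    """A cosine rhythm: baseline + amplitude * cos(2*pi*(ct - acrophase)/period)."""

    period_hr: float = 24.0
    amplitude: float = 1.0
    acrophase_ct_hr: float = 6.0
    baseline: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.period_hr <= 0:
            raise ValueError("period_hr must be positive")
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise_sd must be nonnegative")

    def expected(self, ct_hr: np.ndarray) -> np.ndarray:
        return self.baseline + self.amplitude * np.cos(
            2 * np.pi * (np.asarray(ct_hr, dtype=float) - self.acrophase_ct_hr) / self.period_hr
        )


@dataclass(frozen=True)
class GenotypeProfile:
    """Named rhythm parameters for one genotype group.

    ``basal_elevation`` models the raised subjective-day baseline of the
    clock-blocked genotype (continuously intermediate-to-high melatonin /
    clock-output levels).
    """

    name: str
    rhythm: RhythmSpec
    basal_elevation: float = 0.0


def control_activity_profile() -> GenotypeProfile:
    """Control larvae under DD: amplitude 13.4 cm/10 min, day-active."""
    return GenotypeProfile(
        "control",
        RhythmSpec(period_hr=24.0, amplitude=13.4, acrophase_ct_hr=6.0,
                   baseline=20.0, noise_sd=6.0),
    )


def dclk_activity_profile() -> GenotypeProfile:
    """Pineal-clock-blocked larvae under DD: amplitude reduced to 4.5."""
    return GenotypeProfile(
        "dclk",
        RhythmSpec(period_hr=24.0, amplitude=4.5, acrophase_ct_hr=6.0,
                   baseline=20.0, noise_sd=6.0),
    )


def control_melatonin_profile() -> GenotypeProfile:
    return GenotypeProfile(
        "control",
        RhythmSpec(period_hr=24.0, amplitude=0.45, acrophase_ct_hr=18.0,
                   baseline=0.55, noise_sd=0.2),
    )


def dclk_melatonin_profile() -> GenotypeProfile:
    """Flattened rhythm with an elevated subjective-day baseline."""
    return GenotypeProfile(
        "dclk",
        RhythmSpec(period_hr=24.0, amplitude=0.1, acrophase_ct_hr=18.0,
                   baseline=0.55, noise_sd=0.2),
        basal_elevation=0.25,
    )


def make_expression_matrix(
    n_rhythmic: int,
    n_null: int,
    snr: float = 2.0,
    noise_sd: float = 1.0,
    baseline: float = 8.0,
    t0_ct_hr: float = 14.0,
    dt_hr: float = 4.0,
    n_timepoints: int = 12,
    seed: int = 0,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Planted-signal expression matrix on the two-cycle DD design.

    Rhythmic rows are ``baseline + A*cos(2*pi*(t - phase)/24) + N(0, sd)``
    with ``A = snr * noise_sd`` and phases drawn uniformly; null rows are
    baseline plus Gaussian noise. Values are on the log scale. Returns the
    matrix and a boolean truth mask (True = planted rhythmic).
    """
    if n_rhythmic < 0 or n_null < 0:
        raise ValueError("counts must be nonnegative")
    if n_rhythmic + n_null == 0:
        raise ValueError("need at least one row")
    if snr < 0:
        raise ValueError("snr must be nonnegative")
    rng = np.random.default_rng(seed)
    t = t0_ct_hr + np.arange(n_timepoints) * dt_hr
    # amplitude tracks the noise floor; in the noiseless limit snr is the amplitude
    amp = snr * noise_sd if noise_sd > 0 else snr
    phases = rng.uniform(0.0, 24.0, size=n_rhythmic)
    signal = amp * np.cos(2 * np.pi * (t[None, :] - phases[:, None]) / 24.0)
    n_total = n_rhythmic + n_null
    values = baseline + rng.normal(0.0, noise_sd, size=(n_total, n_timepoints))
    values[:n_rhythmic] += signal
    genes = [f"rhythmic_{i:05d}" for i in range(n_rhythmic)] + [
        f"null_{i:05d}" for i in range(n_null)
    ]
    labels = (
        CANONICAL_CT_LABELS
        if (n_timepoints == 12 and t0_ct_hr == 14.0 and dt_hr == 4.0)
        else [f"T{i}" for i in range(n_timepoints)]
    )
    matrix = ExpressionMatrix(
        genes=genes, libraries=labels, values=values, scale="log",
        t0_ct_hr=t0_ct_hr, dt_hr=dt_hr,
    )
    truth = np.zeros(n_total, dtype=bool)
    truth[:n_rhythmic] = True
    return matrix, truth


def make_locomotor_track(
    profile: GenotypeProfile,
    schedule: LightingSchedule,
    days: int = 2,
    masking_gain: float = 1.0,
    seed: int = 0,
    larva_id: str = "larva",
    bin_minutes: float = 10.0,
    t0_ct_hr: float = 0.0,
    start_day: float = 6.0,
    emit_frames: bool = True,
    frame_hz: float = 1.0,
) -> LarvaTrack:
    """Simulated larval activity under a lighting schedule.

    Expected activity per bin is the profile's circadian cosine, multiplied
    by ``masking_gain`` during dark epochs and by 1 during light/dim (light
    masking is modeled as multiplicative). Truncated-at-zero Gaussian noise
    is added per bin. When ``emit_frames`` is set, per-frame velocities
    consistent with the binned distances are emitted for sleep scoring: the
    bin's distance is spread over a contiguous run of moving seconds at a
    velocity at or above the movement-start threshold wherever possible.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    rng = np.random.default_rng(seed)
    n_bins = int(round(days * 24 * 60 / bin_minutes))
    dt_hr = bin_minutes / 60.0
    # unwrapped hours so non-24-hr generating periods stay coherent
    hours = t0_ct_hr + np.arange(n_bins) * dt_hr
    mu = profile.rhythm.expected(hours) + profile.basal_elevation
    t_exp = np.arange(n_bins) * dt_hr
    conds = schedule.conditions_at(t_exp)
    gain = np.where(conds == "dark", masking_gain, 1.0)
    mu = np.maximum(mu, 0.0) * gain
    distances = np.maximum(0.0, mu + rng.normal(0.0, profile.rhythm.noise_sd, n_bins))
    activity = CircadianSeries(
        t0_ct_hr=t0_ct_hr, dt_hr=dt_hr, values=distances,
        schedule=schedule, label=larva_id,
    )
    frame_times = frame_vel = None
    if emit_frames:
        frames_per_bin = int(round(bin_minutes * 60 * frame_hz))
        frame_s = 1.0 / frame_hz
        vel = np.zeros(n_bins * frames_per_bin)
        for b in range(n_bins):
            d = distances[b]
            if d <= 0:
                continue
            # moving seconds: enough to keep velocity near 1 cm/s (> start threshold)
            m = max(1, int(round(d)))
            m = min(m, frames_per_bin)
            start = rng.integers(0, frames_per_bin - m + 1)
            vel[b * frames_per_bin + start : b * frames_per_bin + start + m] = (
                d / (m * frame_s)
            )
        frame_times = np.arange(vel.size) * frame_s
        frame_vel = vel
    return LarvaTrack(
        larva_id=larva_id, schedule=schedule, genotype=profile.name,
        frame_times_s=frame_times, frame_velocity_cm_s=frame_vel,
        activity=activity, t0_ct_hr=t0_ct_hr, start_day=start_day,
    )


def make_bioluminescence_trace(
    profile: GenotypeProfile,
    days: int = 2,
    trend_linear_per_day: float = 0.0,
    trend_fast_sd: float = 0.0,
    seed: int = 0,
    dt_hr: float = 1.0,
    t0_ct_hr: float = 0.0,
    label: str = "larva",
) -> tuple[CircadianSeries, RhythmSpec]:
    """Raw luciferase counts: cosine signal + linear drift + fast jitter.

    Returns the trace and the generating rhythm (ground truth).
    """
    rng = np.random.default_rng(seed)
    n = int(round(days * 24 / dt_hr))
    t = np.arange(n) * dt_hr
    signal = profile.rhythm.expected(t0_ct_hr + t)
    drift = trend_linear_per_day * t / 24.0
    jitter = rng.normal(0.0, trend_fast_sd, n) if trend_fast_sd > 0 else 0.0
    values = np.maximum(signal + drift + jitter, 0.0)
    series = CircadianSeries(
        t0_ct_hr=t0_ct_hr, dt_hr=dt_hr, values=values,
        schedule=LightingSchedule.constant("dark"), label=label,
    )
    return series, profile.rhythm


def dl_then_dd_schedule() -> LightingSchedule:
    """One dark-light cycle followed by constant darkness.

    Hours 0-12 dark (subjective night), 12-24 light (lights-on at hour 12
    defines CT0 of the following day), then DD.
    """
    return LightingSchedule(
        epochs=((0.0, "dark"), (12.0, "light"), (24.0, "dark")),
        entrainment_phase_hr=12.0,
    )


def make_melatonin_profiles(
    genotype: GenotypeProfile,
    schedule: LightingSchedule | None = None,
    n_glands: int = 3,
    seed: int = 0,
    dt_hr: float = 1.0,
    days: int = 3,
    light_suppression: float = 0.02,
) -> list[CircadianSeries]:
    """Hourly melatonin release series from cultured pineal glands.

    Under the default schedule (one DL cycle then two DD cycles), lights-on
    forces release to a few percent of the night level regardless of clock
    state (clock-independent suppression); under DD the control genotype
    keeps a high-amplitude night-peaking rhythm while the clock-blocked
    genotype is flattened with an elevated subjective-day baseline. Noise
    is multiplicative lognormal, so the light-epoch contract (values at
    most ~5% of the night maximum) holds for any draw.
    """
    schedule = schedule or dl_then_dd_schedule()
    rng = np.random.default_rng(seed)
    n = int(round(days * 24 / dt_hr))
    t_exp = np.arange(n) * dt_hr
    # CT0 at lights-on: entrainment_phase_hr maps experiment time to CT
    ct = (t_exp - schedule.entrainment_phase_hr) % 24.0
    mu = genotype.rhythm.expected(ct) + genotype.basal_elevation
    mu = np.maximum(mu, 0.01)
    conds = schedule.conditions_at(t_exp)
    mu = np.where(conds == "light", mu * light_suppression, mu)
    out = []
    for i in range(n_glands):
        noise = rng.lognormal(mean=0.0, sigma=genotype.rhythm.noise_sd, size=n)
        values = mu * noise
        out.append(
            CircadianSeries(
                t0_ct_hr=float(ct[0]), dt_hr=dt_hr, values=values,
                schedule=schedule, label=f"{genotype.name}_gland_{i}",
            )
        )
    return out
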