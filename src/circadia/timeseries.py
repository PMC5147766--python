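"""Shared time-series containers and circadian-time bookkeeping.

Everything downstream (the spectral screen, the behavior metrics, the
reporter conditioning) operates on :class:`CircadianSeries`: a uniformly
sampled trace that knows its circadian time (CT, hours in the subjective
day with CT0 = lights-on of the last entrainment cycle) and the lighting
schedule it was recorded under.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

VALID_CONDITIONS = ("light", "dark", "dim")


@dataclass(frozen=True)
class LightingSchedule:
    """Piecewise-constant lighting conditions over an experiment.

    Parameters
    ----------
    epochs
        Ordered ``(start_hr, condition)`` pairs; ``start_hr`` is hours from
        the experiment origin, ``condition`` one of ``light``/``dark``/``dim``.
        Each epoch runs until the next one begins; the last runs forever.
    entrainment_phase_hr
        Clock time (hours from experiment origin, modulo 24) of the lights-on
        that defines CT0.
    """

    epochs: tuple[tuple[float, str], ...]
    entrainment_phase_hr: float = 0.0

    def __post_init__(self) -> None:
        epochs = tuple((float(s), str(c)) for s, c in self.epochs)
        object.__setattr__(self, "epochs", epochs)
        if not epochs:
            raise ValueError("schedule needs at least one epoch")
        if epochs[0][0] != 0.0:
            raise ValueError("first epoch must start at 0")
        starts = [s for s, _ in epochs]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("epoch starts must be strictly increasing")
        for _, cond in epochs:
            if cond not in VALID_CONDITIONS:
                raise ValueError(f"unknown lighting condition {cond!r}")

    def condition_at(self, t_hr: float) -> str:
        """Lighting condition at experiment time ``t_hr`` (hours)."""
        if t_hr < 0:
            raise ValueError("time before experiment origin")
        starts = np.array([s for s, _ in self.epochs])
        idx = int(np.searchsorted(starts, t_hr, side="right")) - 1
        return self.epochs[idx][1]

    def conditions_at(self, t_hr: np.ndarray) -> np.ndarray:
        t_hr = np.asarray(t_hr, dtype=float)
        starts = np.array([s for s, _ in self.epochs])
        idx = np.searchsorted(starts, t_hr, side="right") - 1
        conds = np.array([c for _, c in self.epochs])
        return conds[idx]

    @classmethod
    def constant(cls, condition: str, entrainment_phase_hr: float = 0.0) -> "LightingSchedule":
        return cls(((0.0, condition),), entrainment_phase_hr)

    @classmethod
    def cycles(
        cls,
        first: str,
        second: str,
        half_period_hr: float,
        n_cycles: int,
        then: str | None = None,
        entrainment_phase_hr: float = 0.0,
    ) -> "LightingSchedule":
        """Alternating two-condition cycles, optionally followed by a constant epoch.

        ``cycles("light", "dark", 12, 5, then="dark")`` is five LD cycles
        followed by DD; ``cycles("light", "dark", 3.5, 10)`` is the 3.5-hr
        masking protocol.
        """
        eps: list[tuple[float, str]] = []
        t = 0.0
        for _ in range(n_cycles):
            eps.append((t, first))
            eps.append((t + half_period_hr, second))
            t += 2 * half_period_hr
        if then is not None:
            if eps and eps[-1][1] == then:
                pass  # merge: the trailing half-cycle already is `then`
            else:
                eps.append((t, then))
        return cls(tuple(eps), entrainment_phase_hr)


@dataclass
class CircadianSeries:
    """A uniformly sampled trace with circadian-time annotation.

    ``t0_ct_hr`` is the circadian time of the first sample; ``t0_exp_hr`` its
    time from the experiment origin (used for schedule lookups). Sample ``i``
    sits at CT ``(t0_ct_hr + i * dt_hr) mod 24``.
    """

    t0_ct_hr: float
    dt_hr: float
    values: np.ndarray
    schedule: LightingSchedule = field(
        default_factory=lambda: LightingSchedule.constant("dark")
    )
    label: str = ""
    t0_exp_hr: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt_hr <= 0:
            raise ValueError("dt_hr must be positive")
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a 1-D array of length >= 1")

    def __len__(self) -> int:
        return self.values.size

    @property
    def ct(self) -> np.ndarray:
        """Circadian time of each sample, hours in [0, 24)."""
        return (self.t0_ct_hr + np.arange(len(self)) * self.dt_hr) % 24.0

    @property
    def t_exp(self) -> np.ndarray:
        """Experiment time of each sample (hours from origin)."""
        return self.t0_exp_hr + np.arange(len(self)) * self.dt_hr

    @property
    def span_hr(self) -> float:
        return len(self) * self.dt_hr

    def with_values(self, values: np.ndarray, **changes) -> "CircadianSeries":
        return replace(self, values=np.asarray(values, dtype=float), **changes)


def ct_of_sample(series: CircadianSeries, index: int) -> float:
    """Circadian time (hours in [0, 24)) of sample ``index``."""
    if index < 0 or index >= len(series):
        raise IndexError(f"sample index {index} out of range for length {len(series)}")
    return float((series.t0_ct_hr + index * series.dt_hr) % 24.0)


def bin_distance(
    track_frames: Iterable[tuple[float, float]] | np.ndarray,
    bin_minutes: float,
    t0_ct_hr: float = 0.0,
    schedule: LightingSchedule | None = None,
    label: str = "",
    t0_exp_hr: float = 0.0,
    total_span_minutes: float | None = None,
) -> CircadianSeries:
    """Sum per-frame distances into fixed time bins.

    Bins are half-open ``[k*bin, (k+1)*bin)`` in seconds from time 0. When
    ``total_span_minutes`` is given, only whole bins inside the span are kept
    and frames in the trailing partial bin are dropped; otherwise the bin
    containing the last frame is treated as the final complete bin. Total
    distance is conserved up to the dropped remainder.
    """
    frames = np.asarray(list(track_frames) if not isinstance(track_frames, np.ndarray) else track_frames, dtype=float)
    if frames.size == 0:
        raise ValueError("empty frame input")
    times, dists = frames[:, 0], frames[:, 1]
    if np.any(np.diff(times) < 0):
        raise ValueError("frame times must be nondecreasing")
    if np.any(dists < 0):
        raise ValueError("negative distance in frames")
    if bin_minutes <= 0:
        raise ValueError("bin_minutes must be positive")
    bin_s = bin_minutes * 60.0
    if total_span_minutes is not None:
        n_bins = int(np.floor(total_span_minutes / bin_minutes))
    else:
        n_bins = int(np.floor(times.max() / bin_s)) + 1
    if n_bins == 0:
        raise ValueError("recording shorter than one bin")
    idx = np.floor(times / bin_s).astype(int)
    keep = idx < n_bins
    sums = np.bincount(idx[keep], weights=dists[keep], minlength=n_bins)
    return CircadianSeries(
        t0_ct_hr=t0_ct_hr,
        dt_hr=bin_minutes / 60.0,
        values=sums,
        schedule=schedule or LightingSchedule.constant("dark"),
        label=label,
        t0_exp_hr=t0_exp_hr,
    )


def moving_average(series: CircadianSeries, window_points: int) -> CircadianSeries:
    """Centered sliding mean with edges trimmed (not padded).

    Output length is ``len(series) - window_points + 1``; the time origin
    advances by ``floor((window_points - 1) / 2)`` samples.
    """
    w = int(window_points)
    if w < 1:
        raise ValueError("window_points must be >= 1")
    if w > len(series):
        raise ValueError("window larger than series")
    kernel = np.full(w, 1.0 / w)
    smoothed = np.convolve(series.values, kernel, mode="valid")
    shift = (w - 1) // 2
    return series.with_values(
        smoothed,
        t0_ct_hr=(series.t0_ct_hr + shift * series.dt_hr) % 24.0,
        t0_exp_hr=series.t0_exp_hr + shift * series.dt_hr,
    )


def _running_mean_shrink(values: np.ndarray, window_points: int) -> np.ndarray:
    """Centered running mean; the window shrinks near the edges so the
    output has the same length as the input."""
    n = values.size
    w = window_points
    lo = np.maximum(np.arange(n) - (w - 1) // 2, 0)
    hi = np.minimum(np.arange(n) + w // 2, n - 1)
    csum = np.concatenate(([0.0], np.cumsum(values)))
    return (csum[hi + 1] - csum[lo]) / (hi + 1 - lo)


def running_mean_detrend(
    series: CircadianSeries, window_hr: float, mode: str = "subtract"
) -> CircadianSeries:
    """Remove a running-mean trend, preserving series length.

    The centered running mean uses ``round(window_hr / dt_hr)`` points and
    shrinks its window at the edges. ``mode="subtract"`` removes an additive
    trend; ``mode="divide"`` removes a multiplicative one (errors if the
    running mean is zero anywhere).
    """
    if mode not in ("subtract", "divide"):
        raise ValueError("mode must be 'subtract' or 'divide'")
    if window_hr < 2 * series.dt_hr:
        raise ValueError("window_hr must be at least two sampling intervals")
    w = int(round(window_hr / series.dt_hr))
    trend = _running_mean_shrink(series.values, w)
    if mode == "divide":
        zeros = np.flatnonzero(trend == 0.0)
        if zeros.size:
            raise ZeroDivisionError(
                f"running mean is zero at index {int(zeros[0])}; cannot divide"
            )
        out = series.values / trend
    else:
        out = series.values - trend
    return series.with_values(out)


def running_mean_smooth(series: CircadianSeries, window_hr: float) -> CircadianSeries:
    """Replace values by their centered running mean (shrinking at edges)."""
    if window_hr < 2 * series.dt_hr:
        raise ValueError("window_hr must be at least two sampling intervals")
    w = int(round(window_hr / series.dt_hr))
    return series.with_values(_running_mean_shrink(series.values, w))
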