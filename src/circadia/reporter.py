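"""Bioluminescence and melatonin trace conditioning.

Whole-larva luciferase traces carry two nuisance components: fast counting
noise and a slow multi-day drift (substrate depletion, sensitivity drift).
Conditioning smooths with a 3-hr running mean, divides out a 2-day running
mean, then divides by the trace's own mean so every larva ends up on a
unit-mean scale. Melatonin release series from cultured pineal glands are
normalized per gland by the maximal (subjective-)night level, so the night
peak maps to 1 and glands of different secretory capacity become
comparable. Both feed the G-factor screen in :mod:`circadia.rhythm`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rhythm import GFactorTable, KSComparison, compare_g_distributions, g_factor_rows
from .timeseries import (
    CircadianSeries,
    LightingSchedule,
    running_mean_detrend,
    running_mean_smooth,
)


@dataclass
class ReporterTrace:
    """One larva's bioluminescence trace or one gland's melatonin series."""

    trace_id: str
    series: CircadianSeries
    genotype: str = ""


def condition_bioluminescence(trace: CircadianSeries) -> CircadianSeries:
    """Detrend and normalize a raw bioluminescence trace.

    3-hr running-mean smoothing removes short-term noise; dividing by a
    2-day running mean removes the long-term trend; a final division by the
    trace mean makes the output mean exactly 1.
    """
    if trace.span_hr < 48.0:
        raise ValueError("bioluminescence conditioning needs a span of at least 2 days")
    smoothed = running_mean_smooth(trace, window_hr=3.0)
    detrended = running_mean_detrend(smoothed, window_hr=48.0, mode="divide")
    mean = detrended.values.mean()
    if mean == 0:
        raise ZeroDivisionError("detrended trace has zero mean")
    return detrended.with_values(detrended.values / mean)


def _night_mask(series: CircadianSeries) -> np.ndarray:
    """Samples in (subjective) night: CT in [12, 24)."""
    ct = series.ct
    return (ct >= 12.0) & (ct < 24.0)


def normalize_melatonin(
    traces: list[CircadianSeries], schedule: LightingSchedule | None = None
) -> list[CircadianSeries]:
    """Divide each gland's series by its own maximal night-time level.

    Night means subjective night (CT 12-24) from the schedule's CT
    annotation; the global night maximum over the whole recording is used,
    so that sample maps to exactly 1. Invariant to per-gland rescaling.
    """
    out = []
    for tr in traces:
        mask = _night_mask(tr)
        if not mask.any():
            raise ValueError(f"trace {tr.label!r} has no night-time samples")
        night_max = tr.values[mask].max()
        if night_max <= 0:
            raise ValueError(f"trace {tr.label!r} has no positive night-time level")
        out.append(tr.with_values(tr.values / night_max))
    return out


@dataclass
class ReporterRhythmReport:
    table: GFactorTable
    ks: KSComparison | None
    groups: tuple[str, str] | None


def score_reporter_rhythms(
    traces: list[ReporterTrace],
    dd_window_hr: tuple[float, float],
    target_period_hr: float = 24.0,
) -> ReporterRhythmReport:
    """G-factor table over the DD window plus a between-genotype KS comparison.

    Each trace is restricted to ``dd_window_hr`` (experiment hours) and
    scored; when exactly two genotype labels are present, their G-factor
    distributions are compared by the two-sample Kolmogorov-Smirnov test
    (with group medians).
    """
    lo, hi = dd_window_hr
    if hi - lo < target_period_hr:
        raise ValueError("DD window shorter than one target period")
    rows, labels, genotypes = [], [], []
    n_len = None
    dt = None
    for tr in traces:
        s = tr.series
        mask = (s.t_exp >= lo) & (s.t_exp < hi)
        vals = s.values[mask]
        if vals.size * s.dt_hr < target_period_hr:
            raise ValueError(f"trace {tr.trace_id!r} covers less than one period in the window")
        if n_len is None:
            n_len, dt = vals.size, s.dt_hr
        elif vals.size != n_len or s.dt_hr != dt:
            raise ValueError("traces must share a sampling grid inside the window")
        rows.append(vals)
        labels.append(tr.trace_id)
        genotypes.append(tr.genotype)
    g = g_factor_rows(np.array(rows), dt, target_period_hr)
    g = np.nan_to_num(g, nan=0.0)
    table = GFactorTable(labels=labels, g=g)
    uniq = sorted(set(genotypes))
    ks = None
    groups = None
    if len(uniq) == 2:
        geno = np.array(genotypes)
        a = g[geno == uniq[0]]
        b = g[geno == uniq[1]]
        if a.size >= 2 and b.size >= 2:
            ks = compare_g_distributions(a, b)
            groups = (uniq[0], uniq[1])
    return ReporterRhythmReport(table=table, ks=ks, groups=groups)
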