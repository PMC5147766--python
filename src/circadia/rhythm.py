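"""G-factor spectral scoring with a permutation-calibrated detection rule.

The G-factor of a uniformly sampled trace is the fraction of its non-DC
spectral power that sits at the circadian harmonic: with ``P_k`` the squared
DFT magnitude of the mean-centered series at harmonic ``k = 1..n/2`` and
``k* = round(n*dt / target_period)``,

    g = P_{k*} / sum_{k>=1} P_k .

g is 1 for a pure cosine at the target period on a grid spanning whole
periods, and small for white noise. It is invariant to shifting and to
positive rescaling of the trace.

Detection over a collection of series is calibrated against a permutation
null: each series' time points are shuffled (destroying temporal structure
while preserving its marginal distribution), the shuffled scores form a null
pool, and for each candidate list length L the expected number of null
scores exceeding the L-th ranked observed score estimates the false
detections, hence an estimated true-positive rate 1 - FP(L)/L. The chosen
list is the longest one whose estimated true-positive rate still meets the
nominal level (the study convention is 90%, i.e. a 10% false-detection
rate).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .timeseries import CircadianSeries


class ZeroVarianceError(ValueError):
    """Raised when a constant series is scored (its spectrum has no non-DC power)."""


def _truncate_to_whole_periods(n: int, dt_hr: float, period_hr: float) -> int:
    """Largest sample count <= n whose span is a whole multiple of the period."""
    cycles = int(np.floor(n * dt_hr / period_hr))
    if cycles < 1:
        raise ValueError(
            f"series span {n * dt_hr:g} hr is shorter than one target period ({period_hr:g} hr)"
        )
    return int(round(cycles * period_hr / dt_hr))


def g_factor_rows(
    values: np.ndarray, dt_hr: float, target_period_hr: float = 24.0
) -> np.ndarray:
    """Vectorized G-factor over the rows of a 2-D array.

    Rows are truncated to the largest whole multiple of the target period,
    mean-centered, and scored. Constant rows yield NaN (callers decide how
    to handle them).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = _truncate_to_whole_periods(values.shape[1], dt_hr, target_period_hr)
    x = values[:, :n]
    x = x - x.mean(axis=1, keepdims=True)
    power = np.abs(np.fft.rfft(x, axis=1)) ** 2
    k_star = int(round(n * dt_hr / target_period_hr))
    nonzero = power[:, 1 : n // 2 + 1]
    total = nonzero.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = power[:, k_star] / total
    g[total == 0.0] = np.nan
    return g


def g_factor(
    series: CircadianSeries | np.ndarray,
    target_period_hr: float = 24.0,
    dt_hr: float | None = None,
) -> float:
    """G-factor of a single series (see module docstring for the definition)."""
    if isinstance(series, CircadianSeries):
        values, dt = series.values, series.dt_hr
    else:
        if dt_hr is None:
            raise ValueError("dt_hr required when passing a bare array")
        values, dt = np.asarray(series, dtype=float), dt_hr
    if values.size < 4:
        raise ValueError("need at least 4 samples")
    g = g_factor_rows(values[None, :], dt, target_period_hr)[0]
    if np.isnan(g):
        raise ZeroVarianceError("constant series has no non-DC spectral power")
    return float(g)


@dataclass
class GFactorTable:
    """Observed G-factors plus the permutation null pool that calibrates them."""

    labels: list[str]
    g: np.ndarray
    null_pool: np.ndarray | None = None
    n_permutations: int = 0
    target_harmonic: int = 0
    n_zero_variance: int = 0

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        if self.null_pool is not None:
            self.null_pool = np.asarray(self.null_pool, dtype=float)

    def median(self) -> float:
        return float(np.median(self.g))


def _row_rng(seed: int, label: str) -> np.random.Generator:
    # Keyed by label so results do not depend on row order.
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode("utf-8"))])
    )


def permutation_null(
    series_values: np.ndarray,
    dt_hr: float,
    labels: list[str],
    n_permutations: int = 100,
    seed: int = 0,
    target_period_hr: float = 24.0,
) -> tuple[np.ndarray, int]:
    """Within-series time-label shuffling null.

    For every series and every permutation, the sample order is shuffled
    uniformly at random and the shuffled series is scored. Returns the flat
    null pool (size ``n_series * n_permutations``) and the count of
    zero-variance series (recorded as g = 0 with a warning).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    values = np.atleast_2d(np.asarray(series_values, dtype=float))
    n_series, n = values.shape
    pool = np.empty((n_series, n_permutations))
    n_zero = 0
    for i in range(n_series):
        rng = _row_rng(seed, labels[i])
        shuffled = rng.permuted(
            np.broadcast_to(values[i], (n_permutations, n)).copy(), axis=1
        )
        g = g_factor_rows(shuffled, dt_hr, target_period_hr)
        bad = np.isnan(g)
        if bad.any():
            n_zero += 1
            g = np.where(bad, 0.0, g)
        pool[i] = g
    if n_zero:
        warnings.warn(
            f"{n_zero} zero-variance series recorded as g=0 in the null pool",
            RuntimeWarning,
            stacklevel=2,
        )
    return pool.ravel(), n_zero


def score_series_set(
    series_values: np.ndarray,
    dt_hr: float,
    labels: list[str],
    n_permutations: int = 100,
    seed: int = 0,
    target_period_hr: float = 24.0,
) -> GFactorTable:
    """Score a set of series and build its permutation null pool."""
    values = np.atleast_2d(np.asarray(series_values, dtype=float))
    g = g_factor_rows(values, dt_hr, target_period_hr)
    n_zero_obs = int(np.isnan(g).sum())
    g = np.nan_to_num(g, nan=0.0)
    pool, n_zero_null = permutation_null(
        values, dt_hr, labels, n_permutations, seed, target_period_hr
    )
    n = _truncate_to_whole_periods(values.shape[1], dt_hr, target_period_hr)
    return GFactorTable(
        labels=list(labels),
        g=g,
        null_pool=pool,
        n_permutations=n_permutations,
        target_harmonic=int(round(n * dt_hr / target_period_hr)),
        n_zero_variance=n_zero_obs + n_zero_null,
    )


@dataclass
class CalibrationCurve:
    """Estimated true-positive rate as a function of detected-list length."""

    L: np.ndarray
    tpr_hat: np.ndarray
    chosen_L: int
    tpr_target: float
    order: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def calibration_curve(table: GFactorTable, tpr_target: float = 0.9) -> CalibrationCurve:
    """Permutation-calibrated list-length selection.

    Series are ranked by g descending (stable in input order for ties). For
    each list length L, with g_L the L-th ranked score, the expected number
    of false detections is FP(L) = #{null pool >= g_L} / n_permutations
    (null values tied with g_L count as exceedances — conservative), giving
    tpr_hat(L) = max(0, 1 - FP(L) / L). The chosen length is the largest L
    with tpr_hat >= tpr_target, or 0 if none qualifies.
    """
    if not (0 < tpr_target <= 1):
        raise ValueError("tpr_target must be in (0, 1]")
    if table.null_pool is None or table.null_pool.size == 0:
        raise ValueError("calibration requires a permutation null pool")
    if table.g.size == 0:
        raise ValueError("empty G-factor table")
    # stable descending rank: sort on negated g with mergesort
    order = np.argsort(-table.g, kind="stable")
    g_sorted = table.g[order]
    pool_sorted = np.sort(table.null_pool)
    # exceedances: #pool >= g_L, ties counted
    n_ge = pool_sorted.size - np.searchsorted(pool_sorted, g_sorted, side="left")
    L = np.arange(1, g_sorted.size + 1)
    fp = n_ge / table.n_permutations
    tpr_hat = np.maximum(0.0, 1.0 - fp / L)
    ok = np.flatnonzero(tpr_hat >= tpr_target)
    chosen = int(L[ok[-1]]) if ok.size else 0
    return CalibrationCurve(
        L=L, tpr_hat=tpr_hat, chosen_L=chosen, tpr_target=tpr_target, order=order
    )


@dataclass
class DetectionResult:
    detected: list[str]
    table: GFactorTable
    curve: CalibrationCurve


def detect_circadian(
    matrix,
    tpr_target: float = 0.9,
    n_permutations: int = 100,
    seed: int = 0,
    target_period_hr: float = 24.0,
) -> DetectionResult:
    """Calibrated circadian-transcript detection on an expression matrix.

    ``matrix`` is an :class:`~circadia.transcriptome.ExpressionMatrix` (or
    anything exposing ``values`` (genes x time), ``genes``, ``dt_hr``).
    Returns the top-ranked transcripts at the chosen list length plus the
    full score table and calibration curve. Deterministic given ``seed`` and
    invariant to the input row order.
    """
    values = np.asarray(matrix.values, dtype=float)
    if values.shape[1] < 4:
        raise ValueError("need at least 4 time points")
    labels = list(matrix.genes)
    table = score_series_set(
        values, matrix.dt_hr, labels, n_permutations, seed, target_period_hr
    )
    curve = calibration_curve(table, tpr_target)
    detected = [labels[i] for i in curve.order[: curve.chosen_L]]
    return DetectionResult(detected=detected, table=table, curve=curve)


@dataclass
class KSComparison:
    statistic: float
    pvalue: float
    median_a: float
    median_b: float


def compare_g_distributions(group_a, group_b) -> KSComparison:
    """Two-sample Kolmogorov-Smirnov comparison of G-factor distributions.

    Returns the D statistic (sup ECDF difference), the asymptotic p-value,
    and the two group medians.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    res = stats.ks_2samp(a, b, method="asymp")
    return KSComparison(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
    )
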