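"""Expression time-course preprocessing and circadian gene-list comparison.

The canonical design is 12 libraries sampled every 4 hr over two daily
cycles under constant darkness (CT14, 18, 22, 2, 6, 10 and the same six
labels repeated with a ``b`` suffix). The pipeline order is fixed:
log-transform, quantile-normalize the libraries together, drop transcripts
whose maximum expression falls in the lower quartile, then run the
calibrated G-factor screen (:func:`circadia.rhythm.detect_circadian`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd

CANONICAL_CT_LABELS = [
    "CT14", "CT18", "CT22", "CT2", "CT6", "CT10",
    "CT14b", "CT18b", "CT22b", "CT2b", "CT6b", "CT10b",
]


@dataclass
class ExpressionMatrix:
    """Transcripts x ordered time-point libraries.

    ``values`` is genes x libraries; ``scale`` is ``"raw"`` (nonnegative
    counts) or ``"log"``. ``t0_ct_hr``/``dt_hr`` place the libraries on the
    circadian clock (parsed from CT labels when possible).
    """

    genes: list[str]
    libraries: list[str]
    values: np.ndarray
    scale: str = "raw"
    t0_ct_hr: float = 14.0
    dt_hr: float = 4.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes x libraries)")
        if self.values.shape != (len(self.genes), len(self.libraries)):
            raise ValueError("values shape does not match gene/library labels")
        if np.isnan(self.values).any():
            raise ValueError("missing cells are not allowed")
        if self.scale not in ("raw", "log"):
            raise ValueError("scale must be 'raw' or 'log'")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scale: str = "raw") -> "ExpressionMatrix":
        t0, dt = _infer_ct_grid(list(df.columns))
        return cls(
            genes=list(df.index.astype(str)),
            libraries=list(df.columns.astype(str)),
            values=df.to_numpy(dtype=float),
            scale=scale,
            t0_ct_hr=t0,
            dt_hr=dt,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.libraries)


def _infer_ct_grid(labels: list[str]) -> tuple[float, float]:
    """Parse ``CT<hr>[b...]`` labels into (t0, dt); fall back to 14/4."""
    hrs = []
    for lab in labels:
        m = re.fullmatch(r"CT(\d+(?:\.\d+)?)b*", str(lab))
        if not m:
            return 14.0, 4.0
        hrs.append(float(m.group(1)))
    if len(hrs) < 2:
        return 14.0, 4.0
    dt = (hrs[1] - hrs[0]) % 24.0
    if dt == 0 or any(((b - a) % 24.0) != dt for a, b in zip(hrs, hrs[1:])):
        return 14.0, 4.0
    return hrs[0], dt


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1) per cell; flips the scale flag to ``log``."""
    if matrix.scale != "raw":
        raise ValueError("matrix is already log scale")
    if np.any(matrix.values < 0):
        raise ValueError("negative expression values")
    return replace(matrix, values=np.log2(matrix.values + 1.0), scale="log")


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every library to share the same sorted value multiset.

    Within each library the rank-r value is replaced by the mean across
    libraries of the rank-r values; tied values within a library share the
    mean of their tied ranks' reference values. Idempotent.
    """
    vals = matrix.values
    if vals.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 libraries")
    reference = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = reference
        # ties share the mean reference value of their rank span
        uniq, inv, counts = np.unique(col, return_inverse=True, return_counts=True)
        if np.any(counts > 1):
            sums = np.bincount(inv, weights=assigned)
            assigned = (sums / counts)[inv]
        out[:, j] = assigned
    return replace(matrix, values=out)


def filter_low_max(matrix: ExpressionMatrix) -> tuple[ExpressionMatrix, list[str]]:
    """Drop the floor(N/4) transcripts with the smallest maxima.

    The per-transcript maximum over time points ranks the transcripts; the
    lower quartile (by count, ties broken by stable input order) is removed
    before the spectral screen. Returns (kept matrix, removed labels).
    """
    n = len(matrix.genes)
    if n < 4:
        raise ValueError("need at least 4 transcripts")
    maxima = matrix.values.max(axis=1)
    order = np.argsort(maxima, kind="stable")
    n_drop = n // 4
    dropped = np.sort(order[:n_drop])
    kept = np.sort(order[n_drop:])
    kept_matrix = replace(
        matrix,
        genes=[matrix.genes[i] for i in kept],
        libraries=list(matrix.libraries),
        values=matrix.values[kept],
    )
    return kept_matrix, [matrix.genes[i] for i in dropped]


@dataclass
class GeneListComparison:
    """Set algebra between two circadian gene lists (control vs mutant)."""

    a: set[str]
    b: set[str]
    maintained: set[str] = field(init=False)
    lost: set[str] = field(init=False)
    acquired: set[str] = field(init=False)

    def __post_init__(self) -> None:
        self.a, self.b = set(self.a), set(self.b)
        self.maintained = self.a & self.b
        self.lost = self.a - self.b
        self.acquired = self.b - self.a


def compare_lists(a, b) -> GeneListComparison:
    """Maintained / lost / acquired partition of two rhythmic gene lists."""
    return GeneListComparison(set(a), set(b))


class BasalChange(str, Enum):
    MAINTAINED_RHYTHM = "maintained_rhythm"
    ARRHYTHMIC_HIGH = "arrhythmic_high"
    ARRHYTHMIC_DOWN = "arrhythmic_down"
    ARRHYTHMIC_ABOLISHED = "arrhythmic_abolished"


def classify_basal_change(
    control_profile: np.ndarray,
    mutant_profile: np.ndarray,
    mutant_rhythmic: bool,
    high_fraction: float = 0.5,
    abolished_fraction: float = 0.05,
) -> BasalChange:
    """Qualitative fate of a clock-controlled gene in the mutant.

    A gene still called rhythmic in the mutant is ``maintained_rhythm``
    regardless of level. Otherwise the mutant mean relative to the control
    mean decides: >= ``high_fraction`` is ``arrhythmic_high``, in
    [``abolished_fraction``, ``high_fraction``) is ``arrhythmic_down``, and
    below ``abolished_fraction`` is ``arrhythmic_abolished``. The default
    thresholds (50%, 5%) are package parameters, not measured constants.
    """
    c = np.asarray(control_profile, dtype=float)
    m = np.asarray(mutant_profile, dtype=float)
    if c.shape != m.shape:
        raise ValueError("control and mutant profiles must share a time grid")
    if mutant_rhythmic:
        return BasalChange.MAINTAINED_RHYTHM
    c_mean = c.mean()
    if c_mean <= 0:
        raise ValueError("control mean must be positive to compare basal levels")
    ratio = m.mean() / c_mean
    if ratio >= high_fraction:
        return BasalChange.ARRHYTHMIC_HIGH
    if ratio >= abolished_fraction:
        return BasalChange.ARRHYTHMIC_DOWN
    return BasalChange.ARRHYTHMIC_ABOLISHED


def preprocess(matrix: ExpressionMatrix) -> tuple[ExpressionMatrix, list[str]]:
    """Fixed pipeline order: log2 -> quantile normalize -> lower-quartile filter."""
    logged = log_transform(matrix) if matrix.scale == "raw" else matrix
    normed = quantile_normalize(logged)
    return filter_low_max(normed)
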