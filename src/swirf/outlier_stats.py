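"""Per-wavelength Tukey-fence outliers and the cohort spectra outlier fraction f.

The statistic: pool a cohort's SNV-corrected scans into a scans x
wavelengths matrix, compute Tukey fences (Q1 - k*IQR, Q3 + k*IQR, default
k = 1.5) independently at every wavelength, count the matrix cells falling
strictly outside their wavelength's fences, and divide by the total number
of cells:

    f = (total outlier points) / (n_scans * n_points)

A heterogeneous cohort — one mixing spectrally distinct age classes —
throws more points past the fences than a homogeneous one, so f rises with
the spread of the cohort's (weighted) age distribution.  Differences in f
smaller than the scanning measurement tolerance (estimated from repeated
scans of an aspirin-tablet standard) are not interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .preprocessing import CohortMatrix, snv_transform_matrix
from .spectra_io import ScanSpectrum

__all__ = [
    "FenceSet",
    "CohortResult",
    "Tolerance",
    "PUBLISHED_TOLERANCE",
    "MIN_SCANS",
    "compute_fences",
    "count_outlier_points",
    "cohort_outlier_fraction",
    "cohort_outlier_fraction_matrix",
    "measurement_tolerance",
]

#: Scanning measurement tolerance on the f scale published by the study
#: (from two aspirin-standard trials).
PUBLISHED_TOLERANCE = 0.0008

#: Default minimum cohort size for quartile estimation.
MIN_SCANS = 4


@dataclass
class FenceSet:
    """Per-wavelength quartiles and Tukey fences for one cohort matrix."""

    q1: np.ndarray
    q3: np.ndarray
    k: float

    @property
    def iqr(self) -> np.ndarray:
        return self.q3 - self.q1

    @property
    def lower(self) -> np.ndarray:
        return self.q1 - self.k * self.iqr

    @property
    def upper(self) -> np.ndarray:
        return self.q3 + self.k * self.iqr


@dataclass
class CohortResult:
    """Outlier accounting for one cohort: counts and the fraction f."""

    outlier_points: int
    total_points: int
    n_scans: int
    n_points: int
    k: float = 1.5
    labels: dict = field(default_factory=dict)

    @property
    def f(self) -> float:
        return self.outlier_points / self.total_points

    @property
    def f_rounded(self) -> float:
        """f at the study's 4-decimal reporting precision."""
        return round(self.f, 4)


@dataclass
class Tolerance:
    """Measurement tolerance for f, from repeated scans of a physical standard."""

    value: float
    trials: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("tolerance must be non-negative")


def _tukey_hinges(column: np.ndarray) -> tuple[float, float]:
    # Hinges: medians of the lower/upper halves, the median itself included
    # in both halves when n is odd.
    x = np.sort(column)
    n = x.size
    half = (n + 1) // 2
    return float(np.median(x[:half])), float(np.median(x[n - half:]))


def compute_fences(
    matrix: CohortMatrix | np.ndarray,
    k: float = 1.5,
    method: str = "linear",
    min_scans: int = MIN_SCANS,
) -> FenceSet:
    """Quartiles and Tukey fences per wavelength (column) of a cohort matrix.

    ``method="linear"`` uses linear interpolation between order statistics
    (the mainstream spreadsheet convention); ``method="tukey"`` uses Tukey's
    hinges.  f is sensitive to this choice at small cohort sizes, so it is
    explicit.  Fewer than ``min_scans`` rows is an error: quartiles from
    tiny cohorts are not meaningful.
    """
    values = matrix.values if isinstance(matrix, CohortMatrix) else np.asarray(matrix, float)
    if values.ndim != 2:
        raise ValueError("cohort matrix must be 2-D (scans x wavelengths)")
    if values.shape[0] < min_scans:
        raise ValueError(
            f"cohort has {values.shape[0]} scans; need at least {min_scans} "
            "for quartile estimation"
        )
    if k < 0:
        raise ValueError("fence multiplier k must be non-negative")
    if method == "linear":
        q1, q3 = np.quantile(values, [0.25, 0.75], axis=0, method="linear")
    elif method == "tukey":
        hinges = [_tukey_hinges(values[:, j]) for j in range(values.shape[1])]
        q1 = np.array([h[0] for h in hinges])
        q3 = np.array([h[1] for h in hinges])
    else:
        raise ValueError(f"unknown quartile method {method!r}")
    return FenceSet(q1=q1, q3=q3, k=float(k))


#: Relative numerical guard on the fence comparison.  SNV leaves rounding
#: jitter of order 1e-16 on scans that are affinely identical; without a
#: guard, collapsed fences (IQR = 0) would flag that jitter as outliers.
FENCE_EPS = 1e-12


def count_outlier_points(
    matrix: CohortMatrix | np.ndarray, fences: FenceSet, eps: float = FENCE_EPS
) -> int:
    """Number of matrix cells strictly outside their wavelength's fences.

    Points exactly on a fence are NOT outliers (standard Tukey convention,
    strict inequalities).  ``eps`` is a relative numerical guard: a point
    within ``eps * max(1, |fence|)`` of a fence counts as on it.
    """
    values = matrix.values if isinstance(matrix, CohortMatrix) else np.asarray(matrix, float)
    if values.ndim != 2 or values.shape[1] != fences.q1.size:
        raise ValueError(
            f"matrix has {values.shape[1] if values.ndim == 2 else '?'} columns, "
            f"fences have {fences.q1.size}"
        )
    lower, upper = fences.lower, fences.upper
    tol_lo = eps * np.maximum(1.0, np.abs(lower))
    tol_hi = eps * np.maximum(1.0, np.abs(upper))
    return int(np.count_nonzero((values < lower - tol_lo) | (values > upper + tol_hi)))


def cohort_outlier_fraction_matrix(
    matrix: CohortMatrix | np.ndarray,
    k: float = 1.5,
    method: str = "linear",
    min_scans: int = MIN_SCANS,
    labels: dict | None = None,
) -> CohortResult:
    """f for an already SNV-corrected cohort matrix."""
    values = matrix.values if isinstance(matrix, CohortMatrix) else np.asarray(matrix, float)
    fences = compute_fences(values, k=k, method=method, min_scans=min_scans)
    outliers = count_outlier_points(values, fences)
    n_scans, n_points = values.shape
    return CohortResult(
        outlier_points=outliers,
        total_points=n_scans * n_points,
        n_scans=n_scans,
        n_points=n_points,
        k=k,
        labels=labels or {},
    )


def cohort_outlier_fraction(
    scans: Iterable[ScanSpectrum],
    k: float = 1.5,
    method: str = "linear",
    ddof: int = 1,
    min_scans: int = MIN_SCANS,
    labels: dict | None = None,
) -> CohortResult:
    """SNV-correct a cohort of scans, fence each wavelength, and return f.

    Every scan replicate enters the matrix as its own row (no per-specimen
    averaging); pooled cohorts must be passed pooled, because fences are
    recomputed on the pool and pooled f is not a weighted mean of sub-cohort
    f values.
    """
    matrix = snv_transform_matrix(scans, ddof=ddof)
    return cohort_outlier_fraction_matrix(
        matrix, k=k, method=method, min_scans=min_scans, labels=labels
    )


def measurement_tolerance(trial_fs: Sequence[float], decimals: int = 4) -> Tolerance:
    """Measurement tolerance from f values of repeated standard scans.

    Defined as the maximum pairwise absolute difference in f across the
    trials, rounded to ``decimals`` places.  With the study's two aspirin
    trials this reduces to |f1 - f2|.
    """
    trials = [float(t) for t in trial_fs]
    if len(trials) < 2:
        raise ValueError("measurement tolerance needs at least 2 standard trials")
    value = max(abs(a - b) for a, b in combinations(trials, 2))
    return Tolerance(value=round(value, decimals), trials=trials)
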