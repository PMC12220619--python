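"""Series of simple OLS regressions of f (and changes in f) on study covariates.

Each regression is a univariate ordinary-least-squares fit with intercept;
the reported quantities are the slope, its standard error, the two-sided
t-test p-value and the residual degrees of freedom (n - 2).  The series
mirrors the study design:

* f per collection day ~ day-matched abundance, day-matched number scanned,
  preservation time (months), ambient scanning RH (%) and temperature (C);
* consecutive-day actual differences in f ~ the corresponding *differences*
  in abundance and number scanned, plus the three static covariates;
* consecutive-day relative differences in f (tolerance-gated ratios) ~ the
  corresponding count *ratios*, plus the static covariates;
* the four difference/ratio responses ~ average maximum flight distance,
  with the species lacking a published dispersal range dropped pairwise.

No multiple-testing correction is applied (none is applied in the source
analysis); with n = 11 species these fits are descriptive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort_comparison import difference_table
from .outlier_stats import PUBLISHED_TOLERANCE, Tolerance

__all__ = ["RegressionResult", "simple_ols", "regression_series"]


@dataclass
class RegressionResult:
    coefficient: float
    se: float
    p_value: float
    df: int
    n: int
    intercept: float

    def __post_init__(self) -> None:
        if self.df != self.n - 2:
            raise ValueError("simple regression must have df = n - 2")


def simple_ols(x, y) -> RegressionResult:
    """Least-squares fit of y = a + b*x; slope inference via two-sided t test.

    Pairs with a missing value in either variable are dropped (pairwise
    deletion).  Requires n >= 3 complete pairs and a non-constant predictor.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    se = float(fit.bse[1])
    # exact fit: zero residual variance, slope is certain
    p = 0.0 if se == 0 else float(fit.pvalues[1])
    return RegressionResult(
        coefficient=float(fit.params[1]),
        se=se,
        p_value=p,
        df=int(fit.df_resid),
        n=n,
        intercept=float(fit.params[0]),
    )


def _fit_row(series: list, block: str, response: str, predictor: str, x, y) -> None:
    row = {"block": block, "response": response, "predictor": predictor}
    try:
        res = simple_ols(x, y)
        row.update(
            coefficient=res.coefficient,
            se=res.se,
            p_value=res.p_value,
            df=res.df,
            n=res.n,
            status="ok",
        )
    except ValueError as exc:
        row.update(
            coefficient=np.nan, se=np.nan, p_value=np.nan, df=-1, n=0,
            status=f"failed: {exc}",
        )
    series.append(row)


def regression_series(
    metadata: pd.DataFrame,
    f_table: pd.DataFrame,
    tolerance: Tolerance | float = PUBLISHED_TOLERANCE,
) -> pd.DataFrame:
    """The full grid of covariate regressions on f and its differences.

    ``metadata`` and ``f_table`` are species-indexed (see
    :func:`swirf.spectra_io.load_fixture_metadata` /
    :func:`~swirf.spectra_io.load_fixture_f` for the packaged study tables).
    Returns one row per regression with block / response / predictor keys;
    a failing cell is recorded with ``status`` and the series continues.
    """
    md = metadata.loc[f_table.index]
    diffs = difference_table(f_table, tolerance)
    # full-precision actuals and gated ratios (difference_table rounds for report)
    act = {
        "d1_pre": f_table["f_post_d1"] - f_table["f_pre"],
        "d2_d1": f_table["f_post_d2"] - f_table["f_post_d1"],
    }
    rel = {
        "d1_pre": np.where(
            diffs["gated_d1_pre"], 0.0, f_table["f_post_d1"] / f_table["f_pre"]
        ),
        "d2_d1": np.where(
            diffs["gated_d2_d1"], 0.0, f_table["f_post_d2"] / f_table["f_post_d1"]
        ),
    }
    static = {
        "preservation_months": md["preservation_months"],
        "rh_percent": md["rh_percent"],
        "temp_c": md["temp_c"],
    }
    day_of = {"f_pre": "pre", "f_post_d1": "post_d1", "f_post_d2": "post_d2"}

    rows: list[dict] = []
    # block 1: per-day f ~ day-matched counts + static covariates
    for response, day in day_of.items():
        y = f_table[response]
        _fit_row(rows, "f", response, "abundance", md[f"abundance_{day}"], y)
        _fit_row(rows, "f", response, "scanned", md[f"scanned_{day}"], y)
        for name, x in static.items():
            _fit_row(rows, "f", response, name, x, y)

    # block 2: actual differences ~ count differences + static covariates
    pairs = {"d1_pre": ("post_d1", "pre"), "d2_d1": ("post_d2", "post_d1")}
    for key, (later, earlier) in pairs.items():
        y = act[key]
        _fit_row(
            rows, "actual_diff", f"actual_{key}", "abundance_change",
            md[f"abundance_{later}"] - md[f"abundance_{earlier}"], y,
        )
        _fit_row(
            rows, "actual_diff", f"actual_{key}", "scanned_change",
            md[f"scanned_{later}"] - md[f"scanned_{earlier}"], y,
        )
        for name, x in static.items():
            _fit_row(rows, "actual_diff", f"actual_{key}", name, x, y)

    # block 3: relative differences (gated ratios) ~ count ratios + static
    for key, (later, earlier) in pairs.items():
        y = rel[key]
        _fit_row(
            rows, "relative_diff", f"relative_{key}", "abundance_ratio",
            md[f"abundance_{later}"] / md[f"abundance_{earlier}"], y,
        )
        _fit_row(
            rows, "relative_diff", f"relative_{key}", "scanned_ratio",
            md[f"scanned_{later}"] / md[f"scanned_{earlier}"], y,
        )
        for name, x in static.items():
            _fit_row(rows, "relative_diff", f"relative_{key}", name, x, y)

    # block 4: flight distance vs the four difference/ratio responses
    if "max_flight_km" in md.columns:
        x = md["max_flight_km"]
        for response, y in (
            ("actual_d1_pre", act["d1_pre"]),
            ("actual_d2_d1", act["d2_d1"]),
            ("relative_d1_pre", rel["d1_pre"]),
            ("relative_d2_d1", rel["d2_d1"]),
        ):
            _fit_row(rows, "flight", response, "max_flight_km", x, y)

    return pd.DataFrame(rows)
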