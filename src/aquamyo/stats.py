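"""Reproducibility statistics: t-test, one-way F, ICC and intra-subject CV%.

The land-vs-aquatic comparison is a conventional two-sample t-test
(H0: equal group means; Welch by default) plus a one-way F-test of
between- over within-group variability.  Reproducibility across
environments is an intraclass correlation from the two-way ANOVA mean
squares; precision is the intra-subject coefficient of variation across
repeated sets, expressed as a percentage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst

from .io import ALL_FEATURES, TIME_DOMAIN_FEATURES

__all__ = [
    "TTestResult",
    "FTestResult",
    "ReproducibilityResult",
    "two_sample_t",
    "oneway_f",
    "icc",
    "cv_percent",
    "environment_report",
    "min_aquatic_increase",
]


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    df: float
    p_value: float


@dataclass(frozen=True)
class FTestResult:
    F_statistic: float
    df1: int
    df2: int
    p_value: float


@dataclass(frozen=True)
class ReproducibilityResult:
    feature: str
    icc: float
    cv_percent: float
    icc_ci: tuple[float, float] | None = None


def two_sample_t(
    land: Sequence[float], aquatic: Sequence[float], equal_var: bool = False
) -> TTestResult:
    """Two-sample t-test of land vs aquatic means (Welch unless equal_var)."""
    a = np.asarray(land, dtype=float)
    b = np.asarray(aquatic, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    res = sst.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))


def oneway_f(groups: Sequence[Sequence[float]]) -> FTestResult:
    """One-way ANOVA F: between-group over within-group mean square."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    k = len(gs)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in gs):
        raise ValueError("each group needs at least 2 values")
    n_total = sum(g.size for g in gs)
    grand = np.concatenate(gs).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in gs)
    df1, df2 = k - 1, n_total - k
    msb, msw = ssb / df1, ssw / df2
    if msw == 0.0:
        if msb == 0.0:
            raise ValueError("all groups identical and constant: F undefined (0/0)")
        return FTestResult(math.inf, df1, df2, 0.0)
    F = msb / msw
    return FTestResult(float(F), df1, df2, float(sst.f.sf(F, df1, df2)))


def _two_way_mean_squares(table: np.ndarray) -> tuple[float, float, float, float, int, int]:
    """(MSR, MSC, MSE, MSW, n, k) from a complete subjects × conditions table."""
    n, k = table.shape
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ssr = k * float(np.sum((row_means - grand) ** 2))
    ssc = n * float(np.sum((col_means - grand) ** 2))
    sst_ = float(np.sum((table - grand) ** 2))
    sse = sst_ - ssr - ssc
    ssw = sst_ - ssr  # within-row (one-way) sum of squares
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    msw = ssw / (n * (k - 1))
    return msr, msc, mse, msw, n, k


def icc(measurements: np.ndarray | pd.DataFrame, form: str = "A,1") -> float:
    """Intraclass correlation of a complete subjects × conditions table.

    Forms (single-measurement): ``"1,1"`` one-way random; ``"C,1"``
    two-way consistency; ``"A,1"`` two-way absolute agreement (default).
    """
    table = np.asarray(measurements, dtype=float)
    if table.ndim != 2:
        raise ValueError("measurements must be a 2-D subjects × conditions table")
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    if np.any(~np.isfinite(table)):
        raise ValueError("missing or non-finite cells are not allowed")
    msr, msc, mse, msw, n, k = _two_way_mean_squares(table)
    if form == "1,1":
        denom = msr + (k - 1) * msw
        if denom == 0:
            raise ValueError("degenerate table: ICC undefined")
        return float((msr - msw) / denom)
    if form == "C,1":
        denom = msr + (k - 1) * mse
        if denom == 0:
            raise ValueError("degenerate table: ICC undefined")
        return float((msr - mse) / denom)
    if form == "A,1":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
        if denom == 0:
            raise ValueError("degenerate table: ICC undefined")
        return float((msr - mse) / denom)
    raise ValueError(f"unknown ICC form: {form!r}")


def cv_percent(values: Sequence[float]) -> float:
    """Coefficient of variation, SD/mean × 100, of one subject's value set."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV requires at least 2 values")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("CV undefined for nonpositive mean")
    return float(v.std(ddof=1) / mean * 100.0)


def _subject_env_cells(sub: pd.DataFrame) -> pd.DataFrame:
    """Subject × environment table of mean feature values (reps/sets pooled)."""
    cells = sub.groupby(["subject_id", "environment"])["value"].mean().unstack("environment")
    return cells[["land", "aquatic"]]


def environment_report(
    table: pd.DataFrame,
    equal_var: bool = False,
    icc_form: str = "C,1",
) -> pd.DataFrame:
    """Per feature × protocol land-vs-aquatic comparison and reproducibility.

    ``table`` is a long-format feature table with columns subject_id,
    protocol, environment, reps, set, feature, value.  Each subject's
    per-environment mean enters the t/F tests and the ICC; CV% is the
    intra-subject precision across repeated sets of one condition
    (subject × environment × reps cell), averaged over cells.  The ICC
    defaults to the consistency form, which measures how faithfully the
    aquatic measurements follow the on-land ones without penalizing the
    systematic aquatic intensification (reported separately by the mean
    columns and the t-test).
    """
    required = {"subject_id", "protocol", "environment", "reps", "set", "feature", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    envs = set(table["environment"].unique())
    if not {"land", "aquatic"} <= envs:
        raise ValueError("table must contain both land and aquatic environments")
    if table["subject_id"].nunique() < 2:
        raise ValueError("need at least 2 subjects")

    rows = []
    for (feature, protocol), sub in table.groupby(["feature", "protocol"], sort=False):
        cells = _subject_env_cells(sub)
        if cells.isna().any().any():
            raise ValueError(f"incomplete subject × environment table for {feature}/{protocol}")
        land = cells["land"].to_numpy()
        aqua = cells["aquatic"].to_numpy()
        t_res = two_sample_t(land, aqua, equal_var=equal_var)
        f_res = oneway_f([land, aqua])
        icc_val = icc(cells.to_numpy(), form=icc_form)
        cvs = (
            sub.groupby(["subject_id", "environment", "reps"])["value"]
            .apply(lambda v: cv_percent(v) if len(v) >= 2 else np.nan)
            .dropna()
        )
        rows.append(
            {
                "feature": feature,
                "protocol": protocol,
                "land_mean": land.mean(),
                "land_sd": land.std(ddof=1),
                "aquatic_mean": aqua.mean(),
                "aquatic_sd": aqua.std(ddof=1),
                "t_statistic": t_res.t_statistic,
                "t_df": t_res.df,
                "p_value": t_res.p_value,
                "F_statistic": f_res.F_statistic,
                "F_df1": f_res.df1,
                "F_df2": f_res.df2,
                "F_p_value": f_res.p_value,
                "icc": icc_val,
                "cv_percent": float(cvs.mean()) if len(cvs) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def min_aquatic_increase(
    printed, features: Sequence[str] | None = None
) -> float:
    """Minimum % aquatic-over-land mean increase across printed table cells.

    Iterates every (feature, protocol, reps, arm) cell pair of the
    printed results table; ``features`` defaults to the six time-domain
    features for which the published claim of at least 6% intensification
    holds.
    """
    features = list(features) if features is not None else list(TIME_DOMAIN_FEATURES)
    df = printed.df if hasattr(printed, "df") else printed
    sub = df[df["feature"].isin(features)]
    pivot = sub.pivot_table(
        index=["feature", "protocol", "reps", "arm"], columns="environment", values="mean"
    )
    inc = 100.0 * (pivot["aquatic"] - pivot["land"]) / pivot["land"]
    return float(inc.min())
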