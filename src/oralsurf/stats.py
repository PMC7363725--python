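"""Reliability and comparison statistics.

Implements the two-way absolute-agreement average-measures intraclass
correlation (McGraw & Wong ICC(A,k), with the single-measures ICC(A,1)
variant), Pearson correlation with a t-based two-sided test, one-way ANOVA
from raw vectors or from per-group summary statistics, the interpretation
scales used in the reports, and the group aggregation that turns per-subject
region areas and rater tables into a mean +/- SD / ANOVA / ICC table.

The random- and mixed-model two-way ICC point estimates coincide under
absolute agreement; the declared model is carried as metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MeasurementTable",
    "ICCResult",
    "CorrelationResult",
    "AnovaResult",
    "GroupReport",
    "IccUndefinedError",
    "icc",
    "interpret_icc",
    "pearson_test",
    "p_from_r",
    "interpret_correlation",
    "one_way_anova",
    "aggregate_report",
    "total_from_region_means",
    "median_icc",
]

ALPHA = 0.05
REGION_ORDER = ("palate", "tongue", "hard_tissue", "mucosa")


@dataclass(frozen=True)
class MeasurementTable:
    """Subjects x repeated-measurements (or raters) matrix; NaN marks missing."""

    values: np.ndarray
    column_kind: str = "repeat"  # "repeat" | "rater"
    subject_ids: tuple = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError("measurement table must be 2-D (subjects x columns)")
        object.__setattr__(self, "values", values)
        if self.column_kind not in ("repeat", "rater"):
            raise ValueError(f"column_kind must be 'repeat' or 'rater', got {self.column_kind!r}")
        ids = tuple(self.subject_ids) if self.subject_ids else tuple(range(len(values)))
        if len(ids) != len(values):
            raise ValueError("subject_ids length does not match the number of rows")
        object.__setattr__(self, "subject_ids", ids)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def k_columns(self) -> int:
        return self.values.shape[1]

    def complete_rows(self) -> np.ndarray:
        return self.values[~np.isnan(self.values).any(axis=1)]


class IccUndefinedError(ValueError):
    """ICC estimate is undefined (no between-subject variance)."""


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    model: str  # "two_way_random" | "two_way_mixed"
    definition: str  # "absolute_agreement"
    unit: str  # "single" | "average"
    ms_rows: float
    ms_cols: float
    ms_error: float
    n_subjects: int
    k_columns: int
    n_dropped_rows: int = 0

    @property
    def label(self) -> str:
        return interpret_icc(self.estimate)


def _two_way_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ss_err = np.sum(resid**2)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc(
    table: MeasurementTable,
    model: str = "two_way_random",
    unit: str = "average",
) -> ICCResult:
    """Two-way absolute-agreement ICC of a subjects x columns table.

    Rows containing missing cells are dropped listwise and counted.  With
    mean squares MSR (rows), MSC (columns) and MSE (interaction/error):

    * average measures, ICC(A,k): (MSR - MSE) / (MSR + (MSC - MSE) / n)
    * single measures, ICC(A,1):
      (MSR - MSE) / (MSR + (k - 1) MSE + (k / n)(MSC - MSE))
    """
    if model not in ("two_way_random", "two_way_mixed"):
        raise ValueError(f"unknown ICC model {model!r}")
    if unit not in ("single", "average"):
        raise ValueError(f"unknown ICC unit {unit!r}")
    complete = table.complete_rows()
    n_dropped = table.n_subjects - len(complete)
    n, k = complete.shape
    if n < 2 or k < 2:
        raise ValueError(f"ICC needs >= 2 complete subjects and >= 2 columns, got {n} x {k}")
    msr, msc, mse = _two_way_mean_squares(complete)
    if unit == "average":
        denom = msr + (msc - mse) / n
    else:
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0 or np.isclose(msr, mse) and np.isclose(msr, 0):
        raise IccUndefinedError(
            "no between-subject variance: the absolute-agreement ICC is undefined"
        )
    estimate = (msr - mse) / denom
    return ICCResult(
        estimate=float(estimate),
        model=model,
        definition="absolute_agreement",
        unit=unit,
        ms_rows=msr,
        ms_cols=msc,
        ms_error=mse,
        n_subjects=n,
        k_columns=k,
        n_dropped_rows=n_dropped,
    )


def interpret_icc(value: float) -> str:
    """Reliability label: poor < 0.5 <= moderate <= 0.75 < good <= 0.9 < excellent."""
    if value > 1:
        raise ValueError(f"ICC cannot exceed 1, got {value}")
    if value < 0.5:
        return "poor"
    if value <= 0.75:
        return "moderate"
    if value <= 0.9:
        return "good"
    return "excellent"


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float
    label: str

    @property
    def df(self) -> int:
        return self.n - 2


def p_from_r(r: float, n: int) -> float:
    """Two-sided p of a Pearson r at sample size n via the t transform."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1:
        return 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return float(2 * sps.t.sf(abs(t), df=n - 2))


def pearson_test(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with a two-sided t-test on n - 2 df.

    Pairs with a missing member are dropped (pairwise-complete).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables: r undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    r = min(1.0, max(-1.0, r))
    return CorrelationResult(r=r, n=n, p=p_from_r(r, n), label=interpret_correlation(r))


def interpret_correlation(r: float) -> str:
    """Gap-free strength bins on |r|: negligible, fair, moderate, very strong."""
    a = abs(r)
    if a > 1:
        raise ValueError(f"|r| cannot exceed 1, got {r}")
    if a < 0.3:
        return "negligible"
    if a < 0.5:
        return "fair"
    if a < 0.8:
        return "moderate"
    return "very strong"


@dataclass(frozen=True)
class AnovaResult:
    f: float
    p: float
    df_between: int
    df_within: int

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def _anova_from_summary(summary) -> AnovaResult:
    means = np.array([s[0] for s in summary], dtype=float)
    sds = np.array([s[1] for s in summary], dtype=float)
    ns = np.array([s[2] for s in summary], dtype=float)
    if np.any(ns < 2):
        raise ValueError("each group needs n >= 2")
    total_n = ns.sum()
    grand = float(np.sum(ns * means) / total_n)
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(np.sum((ns - 1) * sds**2))
    df_b = len(summary) - 1
    df_w = int(total_n - len(summary))
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0:
        f = np.inf if ms_b > 0 else 0.0
        p = 0.0 if ms_b > 0 else 1.0
    else:
        f = ms_b / ms_w
        p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(f=float(f), p=p, df_between=df_b, df_within=df_w)


def one_way_anova(groups: Iterable = None, *, summary: Iterable = None) -> AnovaResult:
    """Classical one-way ANOVA.

    Either ``groups`` (raw value vectors per group) or ``summary``
    (``(mean, sd, n)`` triples per group, sd with ddof=1) must be given.
    Summary entry reconstructs the between/within sums of squares exactly,
    so both routes agree on data they both describe.
    """
    if (groups is None) == (summary is None):
        raise ValueError("pass exactly one of groups= or summary=")
    if summary is not None:
        summary = list(summary)
        if len(summary) < 2:
            raise ValueError("need >= 2 groups")
        return _anova_from_summary(summary)
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[~np.isnan(g)] for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    return _anova_from_summary([(g.mean(), g.std(ddof=1), len(g)) for g in groups])


# ---------------------------------------------------------------------------
# report aggregation


def total_from_region_means(region_means: Mapping[str, float]) -> float:
    """Sum of the four region means — the 'total area' row of a report."""
    missing = [r for r in REGION_ORDER if r not in region_means]
    if missing:
        raise KeyError(f"missing region means: {missing}")
    return float(sum(region_means[r] for r in REGION_ORDER))


def median_icc(values: Sequence[float]) -> float:
    """Median of a column of ICC estimates (the headline reliability figure)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("no ICC values")
    if np.any(arr > 1):
        raise ValueError("ICC values cannot exceed 1")
    return float(np.median(arr))


@dataclass(frozen=True)
class GroupReport:
    """Per-region mean +/- SD by group, ANOVA p, ICC, and derived summaries."""

    table: pd.DataFrame
    icc_median: float | None
    soft_tissue_subtotal_mean: float
    soft_tissue_subtotal_sd: float
    per_subject_totals: pd.Series
    notes: tuple[str, ...] = field(default_factory=tuple)

    def to_json_dict(self) -> dict:
        return {
            "rows": self.table.reset_index().to_dict(orient="records"),
            "icc_median": self.icc_median,
            "soft_tissue_subtotal_mean": self.soft_tissue_subtotal_mean,
            "soft_tissue_subtotal_sd": self.soft_tissue_subtotal_sd,
            "notes": list(self.notes),
        }


def aggregate_report(
    areas: pd.DataFrame,
    group_assignments: Mapping | None = None,
    rater_tables: Mapping[str, MeasurementTable] | None = None,
    contrast_groups: tuple[str, str] = ("female", "male"),
) -> GroupReport:
    """Aggregate per-subject region areas into a publication-style table.

    ``areas`` is subjects x regions (columns palate, tongue, hard_tissue,
    mucosa, in cm^2).  Subjects with an unknown group stay in the
    total-cohort column but are excluded from the group contrast.  A
    subject's total is the exact sum of its four region areas.  ``rater_tables``
    optionally supplies a MeasurementTable per row name ('palate', ...,
    'total') from which the between-rater ICC(A,k) is estimated.
    """
    if areas.empty:
        raise ValueError("no subjects to aggregate")
    missing_cols = [r for r in REGION_ORDER if r not in areas.columns]
    if missing_cols:
        raise KeyError(f"areas table lacks region columns: {missing_cols}")
    areas = areas[list(REGION_ORDER)].astype(float)
    totals = areas.sum(axis=1)
    groups = pd.Series(
        {s: (group_assignments or {}).get(s) for s in areas.index}, index=areas.index
    )
    notes = []
    n_unknown = int(groups.isna().sum())
    if n_unknown:
        notes.append(f"{n_unknown} subject(s) with unknown group excluded from the contrast")

    rows = {}
    for name in list(REGION_ORDER) + ["total"]:
        series = totals if name == "total" else areas[name]
        row: dict[str, float | None] = {
            "mean": float(series.mean()),
            "sd": float(series.std(ddof=1)) if len(series) > 1 else np.nan,
            "n": int(len(series)),
        }
        group_vectors = []
        for g in contrast_groups:
            sel = series[groups == g]
            row[f"mean_{g}"] = float(sel.mean()) if len(sel) else np.nan
            row[f"sd_{g}"] = float(sel.std(ddof=1)) if len(sel) > 1 else np.nan
            row[f"n_{g}"] = int(len(sel))
            group_vectors.append(sel.to_numpy())
        if all(len(g) >= 2 for g in group_vectors):
            row["anova_p"] = one_way_anova(group_vectors).p
        else:
            row["anova_p"] = np.nan
        if rater_tables and name in rater_tables:
            row["icc"] = icc(rater_tables[name], model="two_way_random", unit="average").estimate
        else:
            row["icc"] = np.nan
        rows[name] = row

    table = pd.DataFrame.from_dict(rows, orient="index")
    icc_col = table["icc"].dropna()
    subtotal = totals - areas["hard_tissue"]
    return GroupReport(
        table=table,
        icc_median=float(icc_col.median()) if len(icc_col) else None,
        soft_tissue_subtotal_mean=float(subtotal.mean()),
        soft_tissue_subtotal_sd=float(subtotal.std(ddof=1)) if len(subtotal) > 1 else np.nan,
        per_subject_totals=totals,
        notes=tuple(notes),
    )
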