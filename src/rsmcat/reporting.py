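"""Study summaries: efficiency gain, paired t, Pearson r, chi-square, descriptives.

Everything here operates on simulation output (a per-person records table)
or on plain count tables; the heavy lifting is delegated to scipy.stats.
Chi-square statistics are the uncorrected Pearson form (no Yates
continuity correction), which is the form that reproduces the published
demographic tables from their printed counts.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedT",
    "ChiSquare",
    "Anova",
    "Descriptives",
    "ComparisonReport",
    "efficiency_gain",
    "paired_t",
    "pearson_r",
    "chi_square_independence",
    "descriptives",
    "anova_oneway",
    "build_report",
    "render_report",
]


def efficiency_gain(cat_total_responses: int, nat_total_responses: int) -> float:
    """1 − (total CAT responses / total NAT responses): fraction of items saved."""
    if nat_total_responses <= 0:
        raise ValueError("nat_total_responses must be positive")
    if cat_total_responses > nat_total_responses:
        raise ValueError("CAT cannot administer more responses than NAT")
    return 1.0 - cat_total_responses / nat_total_responses


@dataclass(frozen=True)
class PairedT:
    t: float
    df: int
    p: float
    degenerate: bool = False  # zero difference variance with nonzero mean


def paired_t(x: Sequence[float], y: Sequence[float]) -> PairedT:
    """Two-sided paired t test; df = n − 1.

    A constant nonzero difference has no within-pair variance: the statistic
    is reported as signed infinity with the ``degenerate`` flag set instead
    of raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be 1-d and of equal length")
    n = x.size
    if n < 2:
        raise ValueError("paired t needs at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    mean = d.mean()
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return PairedT(t=0.0, df=df, p=1.0)
        return PairedT(t=math.copysign(math.inf, mean), df=df, p=0.0, degenerate=True)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return PairedT(t=float(t), df=df, p=float(p))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation."""
    return float(stats.pearsonr(np.asarray(x, float), np.asarray(y, float)).statistic)


@dataclass(frozen=True)
class ChiSquare:
    chi2: float
    df: int
    p: float


def chi_square_independence(table: Sequence[Sequence[float]]) -> ChiSquare:
    """Pearson chi-square of independence on an r×c count table, uncorrected."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need an r×c table with r, c >= 2")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if (arr.sum(axis=0) <= 0).any() or (arr.sum(axis=1) <= 0).any():
        raise ValueError("all margins must be positive")
    res = stats.chi2_contingency(arr, correction=False)
    return ChiSquare(chi2=float(res.statistic), df=int(res.dof), p=float(res.pvalue))


@dataclass(frozen=True)
class Descriptives:
    mean: float
    sd: float
    median: float
    skewness: float  # nan when undefined (constant sample)
    kurtosis: float  # excess kurtosis; nan when undefined
    n: int


def descriptives(values: Sequence[float]) -> Descriptives:
    """Mean, sample SD (n−1), median, bias-corrected skewness and excess kurtosis."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    if sd == 0.0:
        skew = kurt = math.nan
    else:
        skew = float(stats.skew(v, bias=False))
        kurt = float(stats.kurtosis(v, bias=False))
    return Descriptives(
        mean=float(v.mean()),
        sd=sd,
        median=float(np.median(v)),
        skewness=skew,
        kurtosis=kurt,
        n=int(v.size),
    )


@dataclass(frozen=True)
class Anova:
    f: float
    df_between: int
    df_within: int
    p: float


def anova_oneway(values: Sequence[float], groups: Sequence) -> Anova:
    """One-way ANOVA of a measure across group labels."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if v.size != g.size:
        raise ValueError("values and groups must align")
    samples = [v[g == lab] for lab in pd.unique(g)]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    res = stats.f_oneway(*samples)
    return Anova(
        f=float(res.statistic),
        df_between=len(samples) - 1,
        df_within=int(v.size - len(samples)),
        p=float(res.pvalue),
    )


@dataclass(frozen=True)
class ComparisonReport:
    """CAT-versus-NAT comparison of one simulated (or observed) cohort."""

    n_persons: int
    nat_length: int
    cat_total_responses: int
    nat_total_responses: int
    efficiency_gain: float
    mean_cat_length: float
    paired_t_length: PairedT
    paired_t_measure: PairedT
    pearson_r: float
    cat_descriptives: Descriptives
    chi_square_tables: dict[str, ChiSquare] = field(default_factory=dict)


def build_report(
    records: pd.DataFrame, demographics: pd.DataFrame | None = None
) -> ComparisonReport:
    """Assemble the comparison report from per-person study records.

    ``records`` needs columns cat_theta, nat_theta, cat_length and a NAT
    length implied by the bank size column ``nat_length``.  Optional
    ``demographics`` (columns person, gender, plus categorical variables)
    adds gender-association chi-square tables.
    """
    required = {"cat_theta", "nat_theta", "cat_length", "nat_length"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns {sorted(missing)}")
    n = len(records)
    if n == 0:
        raise ValueError("no records")
    cat_total = int(records["cat_length"].sum())
    nat_total = int(records["nat_length"].sum())
    if n >= 2:
        t_len = paired_t(records["cat_length"], records["nat_length"])
        t_meas = paired_t(records["cat_theta"], records["nat_theta"])
        r = pearson_r(records["cat_theta"], records["nat_theta"])
    else:
        t_len = t_meas = PairedT(t=math.nan, df=0, p=math.nan, degenerate=True)
        r = math.nan
    chis: dict[str, ChiSquare] = {}
    if demographics is not None and len(demographics) > 0:
        for col in demographics.columns:
            if col in ("person", "gender"):
                continue
            table = pd.crosstab(demographics["gender"], demographics[col])
            chis[col] = chi_square_independence(table.to_numpy())
    return ComparisonReport(
        n_persons=n,
        nat_length=int(records["nat_length"].iloc[0]),
        cat_total_responses=cat_total,
        nat_total_responses=nat_total,
        efficiency_gain=efficiency_gain(cat_total, nat_total),
        mean_cat_length=float(records["cat_length"].mean()),
        paired_t_length=t_len,
        paired_t_measure=t_meas,
        pearson_r=r,
        cat_descriptives=descriptives(records["cat_theta"]),
        chi_square_tables=chis,
    )


def render_report(report: ComparisonReport) -> str:
    """Human-readable text rendering of a comparison report."""
    d = report.cat_descriptives
    lines = [
        "CAT versus NAT comparison",
        "=" * 41,
        f"persons:                 {report.n_persons}",
        f"total responses (CAT):   {report.cat_total_responses}",
        f"total responses (NAT):   {report.nat_total_responses}",
        f"mean CAT test length:    {report.mean_cat_length:.2f} / {report.nat_length}",
        f"efficiency gain:         {report.efficiency_gain:.2f}"
        f" ({100 * report.efficiency_gain:.1f}%)",
        f"Pearson r (CAT, NAT):    {report.pearson_r:.3f}",
        (
            f"paired t, test length:   t({report.paired_t_length.df}) = "
            f"{report.paired_t_length.t:.2f}, p = {report.paired_t_length.p:.3g}"
            + (" [degenerate]" if report.paired_t_length.degenerate else "")
        ),
        (
            f"paired t, measures:      t({report.paired_t_measure.df}) = "
            f"{report.paired_t_measure.t:.2f}, p = {report.paired_t_measure.p:.3g}"
            + (" [degenerate]" if report.paired_t_measure.degenerate else "")
        ),
        (
            f"CAT measures:            mean {d.mean:.2f}, SD {d.sd:.2f}, "
            f"median {d.median:.2f}, skew {d.skewness:.3f}, kurtosis {d.kurtosis:.2f}"
        ),
    ]
    if report.chi_square_tables:
        lines.append("gender associations (uncorrected Pearson chi-square):")
        for name, c in report.chi_square_tables.items():
            lines.append(
                f"  {name:<14} chi2({c.df}) = {c.chi2:.2f}, p = {c.p:.3f}"
            )
    return "\n".join(lines) + "\n"
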