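"""Cohort-level diagnostic statistics for the hypoperfused-flap predictor.

Cross-tabulates the binary predictor (hypoperfused flap yes/no) against the
outcome (skin-flap necrosis yes/no), computes sensitivity, specificity, PPV
and NPV with exact Clopper-Pearson confidence intervals, and runs the two
classical small-sample tests: the two-sided Fisher exact test (probability
-mass convention) for categorical comparisons and the two-sample Student
t test computable from printed summary statistics (mean, SD, n).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionTable",
    "DiagnosticSummary",
    "GroupComparison",
    "build_confusion",
    "diagnostic_metrics",
    "fisher_exact_two_sided",
    "summary_ttest",
    "cohort_report",
    "format_p",
]


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts: predictor (+/-) against outcome (+/-)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion table must contain at least one case")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fp], [self.fn, self.tn]])


@dataclass(frozen=True)
class DiagnosticSummary:
    """Point estimates with 95% exact CIs; undefined metrics are None."""

    table: ConfusionTable
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    sensitivity_ci: tuple[float, float] | None
    specificity_ci: tuple[float, float] | None
    ppv_ci: tuple[float, float] | None
    npv_ci: tuple[float, float] | None
    prevalence: float
    level: float


@dataclass(frozen=True)
class GroupComparison:
    """One row of a cohort report: a variable, its group summaries, a test."""

    variable: str
    summaries: Mapping[str, object]
    test: str | None
    p_value: float | None

    def __post_init__(self) -> None:
        if self.p_value is not None and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


def build_confusion(
    cohort: pd.DataFrame | Iterable[Mapping],
    predictor_field: str = "predictor_positive",
    outcome_field: str = "necrosis",
) -> ConfusionTable:
    """Cross-tabulate a boolean predictor against a boolean outcome."""
    df = pd.DataFrame(cohort)
    for col in (predictor_field, outcome_field):
        if col not in df.columns:
            raise ValueError(f"cohort is missing column {col!r}")
        bad = df.index[~df[col].isin([True, False, 0, 1])].tolist()
        if bad:
            raise ValueError(f"column {col!r} has non-boolean values in rows {bad}")
    pred = df[predictor_field].astype(bool).to_numpy()
    out = df[outcome_field].astype(bool).to_numpy()
    return ConfusionTable(
        tp=int((pred & out).sum()),
        fp=int((pred & ~out).sum()),
        fn=int((~pred & out).sum()),
        tn=int((~pred & ~out).sum()),
    )


def _proportion(num: int, den: int, level: float):
    """Point estimate and Clopper-Pearson CI; (None, None) when undefined."""
    if den == 0:
        return None, None
    lo, hi = proportion_confint(num, den, alpha=1 - level, method="beta")
    return num / den, (float(lo), float(hi))


def diagnostic_metrics(table: ConfusionTable, level: float = 0.95) -> DiagnosticSummary:
    """Sensitivity, specificity, PPV, NPV with exact binomial CIs.

    Metrics with a zero denominator (e.g. sensitivity with no diseased
    cases) are reported as missing rather than 0, with a warning.
    """
    sens, sens_ci = _proportion(table.tp, table.tp + table.fn, level)
    spec, spec_ci = _proportion(table.tn, table.tn + table.fp, level)
    ppv, ppv_ci = _proportion(table.tp, table.tp + table.fp, level)
    npv, npv_ci = _proportion(table.tn, table.tn + table.fn, level)
    for name, value in [
        ("sensitivity", sens), ("specificity", spec), ("ppv", ppv), ("npv", npv)
    ]:
        if value is None:
            warnings.warn(f"{name} undefined (zero denominator); reported missing")
    return DiagnosticSummary(
        table=table,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        sensitivity_ci=sens_ci,
        specificity_ci=spec_ci,
        ppv_ci=ppv_ci,
        npv_ci=npv_ci,
        prevalence=(table.tp + table.fn) / table.total,
        level=level,
    )


def fisher_exact_two_sided(table: ConfusionTable | np.ndarray) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Uses the probability-mass convention: with margins fixed, the p-value
    sums the hypergeometric probabilities of every table at most as probable
    as the observed one (up to a small relative tolerance for floating-point
    ties) -- the definition used by mainstream statistical software.
    """
    arr = table.as_array() if isinstance(table, ConfusionTable) else np.asarray(table)
    p = st.fisher_exact(arr, alternative="two-sided").pvalue
    return float(min(max(p, 0.0), 1.0))


def summary_ttest(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variant: str = "pooled",
) -> float:
    """Two-sided two-sample t-test p-value from summary statistics.

    ``pooled`` is the classical Student t test (equal variances assumed);
    ``welch`` drops that assumption.  Degenerate zero-variance inputs are
    resolved by limits: equal means give p = 1, unequal means p = 0.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    if sd1 == 0 and sd2 == 0:
        if math.isclose(mean1, mean2):
            return 1.0
        warnings.warn("zero variance with unequal means: p = 0 by convention")
        return 0.0
    res = st.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=(variant == "pooled")
    )
    return float(res.pvalue)


def format_p(p: float | None, threshold: float = 0.001) -> str:
    """Render a p-value to 3 decimals, with ``<0.001`` below the threshold."""
    if p is None:
        return "NA"
    if p < threshold:
        return f"<{threshold:g}"
    return f"{p:.3f}"


def cohort_report(
    cohort: pd.DataFrame,
    variables: Mapping[str, str],
    group_field: str = "necrosis",
) -> list[GroupComparison]:
    """Per-variable group comparisons in the style of a demographics table.

    ``variables`` maps column name -> kind (``"continuous"`` uses the pooled
    t test on per-group mean/SD/n; ``"categorical"`` uses the Fisher exact
    test on a levels x groups contingency table, restricted to 2x2).  With a
    single outcome group only descriptive summaries are produced.
    """
    for var in variables:
        if var not in cohort.columns:
            raise ValueError(f"unknown variable {var!r}")
    groups = sorted(cohort[group_field].astype(bool).unique())
    two_groups = len(groups) == 2
    rows: list[GroupComparison] = []
    for var, kind in variables.items():
        by = cohort.groupby(cohort[group_field].astype(bool))[var]
        if kind == "continuous":
            summ = {
                str(g): {"mean": float(s.mean()), "sd": float(s.std(ddof=1)), "n": int(s.size)}
                for g, s in by
            }
            p = None
            if two_groups:
                a, b = (summ[str(g)] for g in groups)
                p = summary_ttest(a["mean"], a["sd"], a["n"], b["mean"], b["sd"], b["n"])
            rows.append(GroupComparison(var, summ, "student_t" if two_groups else None, p))
        elif kind == "categorical":
            ct = pd.crosstab(cohort[var], cohort[group_field].astype(bool))
            summ = {str(level): ct.loc[level].to_dict() for level in ct.index}
            p = None
            if two_groups and ct.shape == (2, 2):
                p = fisher_exact_two_sided(ct.to_numpy())
            rows.append(
                GroupComparison(var, summ, "fisher_exact" if p is not None else None, p)
            )
        else:
            raise ValueError(f"unknown variable kind {kind!r} for {var!r}")
    return rows
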