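"""Statistics for the donor-energetics arm.

Summaries of metabolite time courses (ATP, ADP, AMP, hypoxanthine per
group and timepoint), DCD-vs-DBD group comparisons (Welch t by default,
Mann-Whitney optionally), and the Pearson correlation between immediate
post-perfusion ATP and recipient peak AST.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass
from scipy import stats

from .simulate import ENERGETICS_TIMEPOINTS


@dataclass
class CorrelationResult:
    r: float
    r_squared: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("r out of [-1, 1]")
        if abs(self.r_squared - self.r ** 2) > 1e-12:
            raise ValueError("r_squared must equal r**2")


def timecourse_summary(table: pd.DataFrame,
                       metabolites=("ATP", "ADP", "AMP", "hypoxanthine"),
                       timepoints=ENERGETICS_TIMEPOINTS) -> pd.DataFrame:
    """Mean, sd and n per (group, timepoint, metabolite) cell.

    Cells with no observations are absent from the output rather than
    reported as zero.
    """
    rows = []
    for metab in metabolites:
        for tp in timepoints:
            col = f"{metab}_{tp}"
            if col not in table.columns:
                continue
            for grp, sub in table.groupby("group"):
                vals = sub[col].dropna().to_numpy(dtype=float)
                if vals.size == 0:
                    continue
                rows.append((grp, tp, metab, vals.mean(),
                             vals.std(ddof=1) if vals.size > 1 else 0.0, vals.size))
    return pd.DataFrame(rows, columns=["group", "timepoint", "metabolite",
                                       "mean", "sd", "n"])


def compare_groups(x, y, method: str = "welch") -> float:
    """Two-sided p-value comparing two independent groups.

    ``method`` is ``'welch'`` (unequal-variance t test) or
    ``'mannwhitney'``.  Identical constant groups return p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 values per group")
    if x.var() == 0 and y.var() == 0 and x.mean() == y.mean():
        return 1.0
    if method == "welch":
        return float(stats.ttest_ind(x, y, equal_var=False).pvalue)
    if method == "mannwhitney":
        return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    raise ValueError(f"unknown method {method!r}")


def correlate(x, y) -> CorrelationResult:
    """Pearson correlation of ATP vs peak AST with the t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the inputs")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(r=r, r_squared=r * r, p_value=float(res.pvalue), n=len(x))


def atp_ast_correlation(table: pd.DataFrame, atp_column: str = "ATP_0h") -> CorrelationResult:
    """Correlation between post-perfusion ATP and recipient peak AST over
    transplanted donors with both values present."""
    sub = table[table["transplanted"]].dropna(subset=[atp_column, "peak_ast"])
    return correlate(sub[atp_column].to_numpy(), sub["peak_ast"].to_numpy())
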