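"""Group-comparison statistics for the clinical characteristics table.

Categorical covariates are compared with the two-sided Fisher exact test
(summing all tables with the observed margins that are at most as probable
as the observed one); numeric covariates with a Shapiro-gated two-sample
t-test or Mann-Whitney test; summary-level t-tests are available when only
group means/SDs are published.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .univariate import SHAPIRO_ALPHA, normality_gate, two_group_test

#: relative slack when comparing table probabilities to the observed one
FISHER_RELATIVE_TOLERANCE = 1e-7


class ClinicalStatsError(ValueError):
    pass


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table of nonnegative integers.

    Sums the hypergeometric probabilities (margins fixed) of every table
    whose probability is at most the observed one, within a relative
    tolerance of 1e-7 on the comparison.
    """
    m = np.asarray(table)
    if m.shape != (2, 2):
        raise ClinicalStatsError("table must be 2x2")
    if np.any(m != np.floor(m)) or np.any(m < 0) or not np.all(np.isfinite(m.astype(float))):
        raise ClinicalStatsError("counts must be nonnegative integers")
    a, b = int(m[0, 0]), int(m[0, 1])
    c, d = int(m[1, 0]), int(m[1, 1])
    N, r1, c1 = a + b + c + d, a + b, a + c
    if N == 0:
        return 1.0
    lo, hi = max(0, c1 - (N - r1)), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, N, r1, c1)
    p_obs = pmf[support == a][0]
    p = float(pmf[pmf <= p_obs * (1.0 + FISHER_RELATIVE_TOLERANCE)].sum())
    return min(p, 1.0)


@dataclass(frozen=True)
class GroupSummary:
    """Published per-group summary: mean, SD, n."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ClinicalStatsError("group size must be >= 2")
        if self.sd < 0:
            raise ClinicalStatsError("sd must be nonnegative")


def t_from_summary(
    g1: GroupSummary, g2: GroupSummary, flavor: str = "pooled"
) -> tuple[float, float]:
    """Two-sided two-sample t-test from summary statistics."""
    if flavor == "pooled":
        df = g1.n + g2.n - 2
        sp2 = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / df
        se = np.sqrt(sp2 * (1 / g1.n + 1 / g2.n))
    elif flavor == "welch":
        v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    else:
        raise ClinicalStatsError(f"unknown t-test flavor {flavor!r}")
    if se == 0:
        return 0.0, 1.0
    t = (g1.mean - g2.mean) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def compare_groups(
    subject_table: pd.DataFrame,
    covariates: list[tuple[str, str]] | None = None,
    group_col: str = "group",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Characteristics-table report: one tested row per covariate.

    ``covariates`` lists (column, kind) with kind "binary"/"categorical"
    (Fisher exact) or "numeric" (Shapiro gate at p > 0.10, then pooled t
    or Mann-Whitney).  Defaults to every non-group column, treating 0/1
    integer columns as binary.
    """
    groups = sorted(subject_table[group_col].unique())
    if len(groups) != 2:
        raise ClinicalStatsError(f"need two groups, got {groups}")
    g1_rows = subject_table[group_col] == groups[0]
    if covariates is None:
        covariates = []
        for col in subject_table.columns:
            if col == group_col:
                continue
            vals = subject_table[col].dropna().unique()
            kind = "binary" if set(np.asarray(vals).tolist()) <= {0, 1} else "numeric"
            covariates.append((col, kind))
    rows = []
    for name, kind in covariates:
        v1 = subject_table.loc[g1_rows, name].dropna()
        v2 = subject_table.loc[~g1_rows, name].dropna()
        if kind in ("binary", "categorical"):
            tab = [
                [int((v1 == 1).sum()), int((v1 != 1).sum())],
                [int((v2 == 1).sum()), int((v2 != 1).sum())],
            ]
            p = fisher_exact_two_sided(tab)
            summary1 = f"{tab[0][0]} ({100 * tab[0][0] / max(len(v1), 1):.0f}%)"
            summary2 = f"{tab[1][0]} ({100 * tab[1][0] / max(len(v2), 1):.0f}%)"
            method, est = "fisher_exact", np.nan
        elif kind == "numeric":
            by_group = {str(groups[0]): v1.to_numpy(), str(groups[1]): v2.to_numpy()}
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                method = normality_gate(by_group)
                est, p = two_group_test(by_group, method)
            if method == "t_test":
                summary1 = f"{v1.mean():.1f} ({v1.std(ddof=1):.1f})"
                summary2 = f"{v2.mean():.1f} ({v2.std(ddof=1):.1f})"
            else:
                summary1 = f"{v1.median():.1f} [{v1.quantile(0.75) - v1.quantile(0.25):.1f}]"
                summary2 = f"{v2.median():.1f} [{v2.quantile(0.75) - v2.quantile(0.25):.1f}]"
        else:
            raise ClinicalStatsError(f"unknown covariate kind {kind!r}")
        rows.append((name, kind, summary1, summary2, method, est, p, p < alpha))
    return pd.DataFrame(
        rows,
        columns=["covariate", "kind", str(groups[0]), str(groups[1]),
                 "method", "statistic", "p_value", "significant"],
    ).set_index("covariate")
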