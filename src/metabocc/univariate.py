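"""Normality-gated per-feature two-group testing with BH FDR control.

Each feature is tested case vs control with a two-sample t-test when both
groups look Gaussian (Shapiro-Wilk p > 0.10 in each group) and with the
Mann-Whitney U test otherwise; p-values are adjusted across features by
the Benjamini-Hochberg step-up procedure and features with q <= delta are
declared relevant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import FeatureTable

SHAPIRO_ALPHA = 0.10  # gate: "normal" means Shapiro-Wilk p above this in both groups


class UnivariateError(ValueError):
    pass


@dataclass(frozen=True)
class TestResult:
    feature_id: str
    method: str          # "t_test" | "mann_whitney"
    statistic: float
    p_value: float
    q_value: float
    relevant: bool
    direction: str       # "SEPSIS > CTRL" | "CTRL > SEPSIS" | "none"


def normality_gate(values_by_group: dict[str, np.ndarray]) -> str:
    """Choose ``t_test`` iff every group passes Shapiro-Wilk at p > 0.10.

    Constant (zero-variance) groups route to ``mann_whitney`` with a
    warning, since the Shapiro statistic is undefined there.
    """
    for g, v in values_by_group.items():
        v = np.asarray(v, dtype=float)
        if v.size < 3:
            raise UnivariateError(f"group {g!r} has {v.size} < 3 observations")
        if np.ptp(v) == 0:
            warnings.warn(f"group {g!r} is constant; Shapiro-Wilk undefined")
            return "mann_whitney"
        if stats.shapiro(v).pvalue <= SHAPIRO_ALPHA:
            return "mann_whitney"
    return "t_test"


def two_group_test(
    values_by_group: dict[str, np.ndarray], method: str
) -> tuple[float, float]:
    """Two-sided two-group test; returns (statistic, p).

    The t-test pools variances; Mann-Whitney uses the exact null when both
    groups have n <= 20 and there are no ties, otherwise the tie- and
    continuity-corrected normal approximation.
    """
    (a, b) = (np.asarray(v, dtype=float) for v in values_by_group.values())
    if a.size == 0 or b.size == 0:
        raise UnivariateError("empty group")
    if method == "t_test":
        res = stats.ttest_ind(a, b, equal_var=True)
        return float(res.statistic), float(res.pvalue)
    if method == "mann_whitney":
        ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        mw_method = "exact" if (a.size <= 20 and b.size <= 20 and not ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=mw_method)
        return float(res.statistic), float(res.pvalue)
    if method == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    raise UnivariateError(f"unknown test method {method!r}")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_(i) = min_{j>=i} (m/j) p_(j)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise UnivariateError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def relevant_features(
    table: FeatureTable | pd.DataFrame,
    delta: float = 0.10,
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Gate -> test -> BH over all features; relevant means q <= delta.

    Accepts a preprocessed :class:`FeatureTable` (groups from its sample
    metadata) or a plain samples x features DataFrame plus ``groups``.
    Returns a DataFrame indexed by feature_id with columns method,
    statistic, p_value, q_value, relevant and direction (sign of the
    case-control mean difference, for the annotation stage).
    """
    if isinstance(table, FeatureTable):
        study = table.study()
        X = study.intensities
        groups = study.sample_meta["group"]
    else:
        X = table
        if groups is None:
            raise UnivariateError("groups required with a plain DataFrame")
        groups = groups.loc[X.index]
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise UnivariateError(f"need exactly two groups, got {labels}")
    case_ids = groups.index[groups == "case"] if "case" in labels else groups.index[groups == labels[0]]
    ctrl_ids = groups.index[groups == "control"] if "control" in labels else groups.index[groups == labels[1]]

    rows = []
    for fid in X.columns:
        a = X.loc[case_ids, fid].dropna().to_numpy()
        b = X.loc[ctrl_ids, fid].dropna().to_numpy()
        by_group = {"case": a, "control": b}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            method = normality_gate(by_group)
            stat, p = two_group_test(by_group, method)
        direction = "SEPSIS > CTRL" if a.mean() > b.mean() else "CTRL > SEPSIS"
        if a.mean() == b.mean():
            direction = "none"
        rows.append((fid, method, stat, p, direction))
    out = pd.DataFrame(
        rows, columns=["feature_id", "method", "statistic", "p_value", "direction"]
    ).set_index("feature_id")
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out["relevant"] = out["q_value"] <= delta
    return out[["method", "statistic", "p_value", "q_value", "relevant", "direction"]]
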