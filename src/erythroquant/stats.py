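"""Statistical procedures used by every analysis stage.

Implements, from their textbook definitions, the two-sample Welch t-test and
the Holm–Šidák step-down familywise correction, and wraps one-way ANOVA with
Dunnett's many-to-one comparison.  All tests are two-tailed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import ValidationError

ALPHA_DEFAULT = 0.05


@dataclass
class TestResult:
    """Outcome of one hypothesis test within a family."""

    statistic: float
    df: float
    p_raw: float
    p_adj: float
    significant: bool
    family_id: str = ""
    label: str = ""


@dataclass
class WelchResult:
    statistic: float
    df: float
    pvalue: float
    mean_diff: float


def welch_t(sample1, sample2) -> WelchResult:
    """Unpaired two-tailed t-test with Welch's correction.

    t = (x1 - x2) / sqrt(s1^2/n1 + s2^2/n2), with Welch–Satterthwaite
    degrees of freedom.  Degenerate zero-variance inputs: equal means give
    p = 1 by convention; unequal means give p -> 0 with a warning.
    """
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValidationError("welch_t needs >= 2 observations per sample")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("welch_t needs finite samples")
    m1, m2 = x.mean(), y.mean()
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    diff = m1 - m2
    if se2 == 0.0:
        if diff == 0.0:
            return WelchResult(0.0, float(n1 + n2 - 2), 1.0, 0.0)
        warnings.warn("zero variance with unequal means; p -> 0", stacklevel=2)
        return WelchResult(np.inf if diff > 0 else -np.inf,
                           float(n1 + n2 - 2), 0.0, diff)
    t = diff / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(min(p, 1.0)), float(diff))


def holm_sidak(p_values, alpha: float = ALPHA_DEFAULT):
    """Holm–Šidák step-down adjustment.

    With ordered raw p-values p(1) <= ... <= p(m), the adjusted value at
    rank k is max over j <= k of 1 - (1 - p(j))**(m - j + 1), capped at 1.
    Returns (p_adjusted, reject) in the original input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    p_adj = np.empty(m)
    p_adj[order] = adj_sorted
    return p_adj, p_adj < alpha


def family_results(p_values, labels=None, alpha: float = ALPHA_DEFAULT,
                   statistics=None, dfs=None, family_id: str = "") -> list[TestResult]:
    """Bundle raw p-values of one family into adjusted :class:`TestResult`."""
    p = np.asarray(p_values, dtype=float)
    p_adj, reject = holm_sidak(p, alpha)
    out = []
    for i in range(p.size):
        out.append(
            TestResult(
                statistic=float(statistics[i]) if statistics is not None else np.nan,
                df=float(dfs[i]) if dfs is not None else np.nan,
                p_raw=float(p[i]),
                p_adj=float(p_adj[i]),
                significant=bool(reject[i]),
                family_id=family_id,
                label=str(labels[i]) if labels is not None else str(i),
            )
        )
    return out


def one_way_anova(groups) -> tuple[float, float]:
    """Ordinary one-way ANOVA F statistic and p-value.

    Degenerate case of zero within-group variance: equal group means give
    F = 0, p = 1; unequal means give F = inf, p -> 0 with a warning.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValidationError("ANOVA needs >= 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValidationError("ANOVA needs >= 2 observations per group")
    n = sum(len(g) for g in groups)
    k = len(groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n - k
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, 1.0
        warnings.warn("zero within-group variance; F -> inf", stacklevel=2)
        return np.inf, 0.0
    f = (ssb / df_b) / (ssw / df_w)
    return float(f), float(sps.f.sf(f, df_b, df_w))


def anova_dunnett(groups, control_index: int = 0, alpha: float = ALPHA_DEFAULT,
                  labels=None) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA plus Dunnett many-to-one comparisons vs control.

    Returns (F, p_anova, table); the table holds one row per treated group
    with the Dunnett statistic and multiplicity-adjusted p-value computed
    from the pooled (common-MSE) multivariate-t distribution.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    f, p_anova = one_way_anova(groups)
    control = groups[control_index]
    treated = [g for i, g in enumerate(groups) if i != control_index]
    if labels is None:
        labels = [f"group_{i}" for i in range(len(groups))]
    treated_labels = [l for i, l in enumerate(labels) if i != control_index]
    if all(g.var(ddof=1) == 0 for g in groups):
        stats_ = np.where(
            [g.mean() != control.mean() for g in treated], np.inf, 0.0
        )
        p_adj = np.where(stats_ == 0.0, 1.0, 0.0)
    else:
        # the multivariate-t integration is randomized; pin its stream so
        # identical inputs give identical adjusted p-values
        res = sps.dunnett(*treated, control=control,
                          rng=np.random.default_rng(0))
        stats_ = np.asarray(res.statistic, dtype=float)
        p_adj = np.asarray(res.pvalue, dtype=float)
    table = pd.DataFrame(
        {
            "comparison": [f"{l} vs {labels[control_index]}" for l in treated_labels],
            "statistic": stats_,
            "p_adj": p_adj,
            "significant": p_adj < alpha,
        }
    )
    return f, p_anova, table


def sem(x) -> float:
    """Standard error of the mean (ddof = 1); 0 for a single observation."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return 0.0
    return float(x.std(ddof=1) / np.sqrt(x.size))


def results_table(results: list[TestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "family_id": [r.family_id for r in results],
            "label": [r.label for r in results],
            "statistic": [r.statistic for r in results],
            "df": [r.df for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adj": [r.p_adj for r in results],
            "significant": [r.significant for r in results],
        }
    )
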