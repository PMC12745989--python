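"""Group-level statistics: Welch ANOVA, Games-Howell, BH-FDR.

Welch's ANOVA and the Games-Howell post hoc test are used throughout
because the per-quality groups have unequal variances.  They are
implemented directly from the textbook formulas (Welch-Satterthwaite
denominator df; studentized-range reference distribution) so that the
Monte-Carlo calibration suites stay fast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class WelchAnovaResult:
    f: float
    df1: float
    df2: float
    p: float


def welch_anova(groups: list[np.ndarray]) -> WelchAnovaResult:
    """Welch's heteroscedastic one-way ANOVA.

    F* = sum(w_j (m_j - m_w)^2) / (k-1) / (1 + 2(k-2)/(k^2-1) * A) with
    w_j = n_j / s_j^2, m_w the weighted grand mean, and
    A = sum((1 - w_j/W)^2 / (n_j - 1)); df2 = (k^2 - 1) / (3A).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    n = np.array([len(g) for g in groups], dtype=float)
    if (n < 2).any():
        raise ValueError("every group needs at least two observations")
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    if (v == 0).any():
        if (v == 0).all() and np.unique(m).size == 1:
            return WelchAnovaResult(f=0.0, df1=float(k - 1), df2=np.inf, p=1.0)
        raise ValueError("a group has zero variance; Welch weights undefined")
    w = n / v
    mw = (w * m).sum() / w.sum()
    a = (((1 - w / w.sum()) ** 2) / (n - 1)).sum()
    num = (w * (m - mw) ** 2).sum() / (k - 1)
    den = 1 + 2 * (k - 2) / (k**2 - 1) * a
    f = num / den
    df1 = k - 1
    df2 = (k**2 - 1) / (3 * a)
    p = stats.f.sf(f, df1, df2)
    return WelchAnovaResult(f=float(f), df1=float(df1), df2=float(df2), p=float(p))


def games_howell(groups: list[np.ndarray],
                 labels: list[str] | None = None) -> pd.DataFrame:
    """Games-Howell pairwise comparisons for unequal-variance groups.

    For each pair (i, j): t = |m_i - m_j| / sqrt(s_i^2/n_i + s_j^2/n_j),
    Welch-Satterthwaite df, and p from the studentized-range distribution
    with q = t * sqrt(2).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    labels = labels or [str(i) for i in range(k)]
    n = np.array([len(g) for g in groups], dtype=float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se2 = v[i] / n[i] + v[j] / n[j]
            if se2 == 0:
                raise ValueError(
                    f"pair ({labels[i]}, {labels[j]}) has zero pooled variance"
                )
            t = (m[i] - m[j]) / np.sqrt(se2)
            df = se2**2 / (
                (v[i] / n[i]) ** 2 / (n[i] - 1) + (v[j] / n[j]) ** 2 / (n[j] - 1)
            )
            p = stats.studentized_range.sf(abs(t) * np.sqrt(2), k, df)
            rows.append(
                {
                    "A": labels[i],
                    "B": labels[j],
                    "mean_diff": m[i] - m[j],
                    "t": float(t),
                    "df": float(df),
                    "p": float(np.clip(p, 0, 1)),
                }
            )
    return pd.DataFrame(rows)


def bh_fdr(pvals, q: float = 0.1):
    """Benjamini-Hochberg step-up: (reject flags, adjusted p-values)."""
    reject, p_adj, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject, p_adj


def welch_ttest(a, b) -> tuple[float, float]:
    """Two-sided Welch two-sample t-test: (t, p)."""
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
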