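"""Cohort-level inference: 2x2 chi-square, repeated-measures ANOVA with
Tukey HSD, pooled-variance t-tests, and proportion summaries.

Statistics are computed from their sums-of-squares / contingency
formulas directly (tail probabilities come from scipy's distributions),
so every number is auditable against a textbook worked example.  The
default chi-square applies no Yates continuity correction; on sparse
2x2 tables the corrected variant is available via ``correction=True``
and the two can differ noticeably.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


def chi_square_2x2(table, correction: bool = False) -> dict:
    """Pearson chi-square test of independence on a 2x2 table.

    Rows are cohorts, columns a category vs the rest.  Returns the
    statistic, df=1 and the chi-square tail probability; a zero margin
    makes the test undefined (flagged, with NaN statistic).
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2) or (obs < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    total = obs.sum()
    if total <= 0:
        raise ValueError("empty table")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    if (row == 0).any() or (col == 0).any():
        log.warning("zero margin: chi-square undefined")
        return {"statistic": float("nan"), "df": 1, "p": float("nan"),
                "undefined": True}
    expected = row @ col / total
    diff = np.abs(obs - expected)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    statistic = float((diff ** 2 / expected).sum())
    return {"statistic": statistic, "df": 1,
            "p": float(stats.chi2.sf(statistic, 1)), "undefined": False}


def repeated_measures_compare(per_cell_series) -> dict:
    """One-way repeated-measures ANOVA with Tukey HSD post-hoc.

    ``per_cell_series`` is an (n_cells x n_conditions) array (or
    DataFrame) of within-cell measurements across conditions.  Rows with
    missing values are excluded listwise (and logged).  Returns the F
    statistic with its degrees of freedom, the p-value, and a pairwise
    Tukey table whose q statistics are referenced to the studentized
    range with the ANOVA error df.
    """
    if isinstance(per_cell_series, pd.DataFrame):
        names = [str(c) for c in per_cell_series.columns]
        data = per_cell_series.to_numpy(dtype=float)
    else:
        data = np.asarray(per_cell_series, dtype=float)
        names = [str(i) for i in range(data.shape[1])]
    complete = np.isfinite(data).all(axis=1)
    if (~complete).any():
        log.warning("excluding %d cells with missing conditions",
                    int((~complete).sum()))
        data = data[complete]
    n, k = data.shape
    if k < 2 or n < 3:
        raise ValueError("need >= 2 conditions and >= 3 complete cells")
    grand = data.mean()
    ss_total = ((data - grand) ** 2).sum()
    ss_subject = k * ((data.mean(axis=1) - grand) ** 2).sum()
    ss_cond = n * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_error = ss_total - ss_subject - ss_cond
    df_cond, df_error = k - 1, (n - 1) * (k - 1)
    ms_cond = ss_cond / df_cond
    ms_error = ss_error / df_error
    if ms_error <= 0:
        f_stat, p = (0.0, 1.0) if ms_cond == 0 else (float("inf"), 0.0)
    else:
        f_stat = float(ms_cond / ms_error)
        p = float(stats.f.sf(f_stat, df_cond, df_error))
    means = data.mean(axis=0)
    se = np.sqrt(ms_error / n) if ms_error > 0 else 0.0
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(means[i] - means[j])
            if se > 0:
                q = abs(diff) / se
                p_q = float(stats.studentized_range.sf(q, k, df_error))
            else:
                q, p_q = (0.0, 1.0) if diff == 0 else (float("inf"), 0.0)
            rows.append({"a": names[i], "b": names[j], "diff": diff,
                         "q": q, "p": p_q})
    return {"F": f_stat, "df": (df_cond, df_error), "p": p,
            "n": n, "tukey": pd.DataFrame(rows)}


def two_sample_t(group1, group2) -> dict:
    """Classical pooled-variance independent-samples t-test."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    v1, v2 = g1.var(ddof=1), g2.var(ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    denom = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    t = float((g1.mean() - g2.mean()) / denom) if denom > 0 else 0.0
    return {"t": t, "df": df, "p": float(2 * stats.t.sf(abs(t), df))}


def summarize_proportions(counts: Mapping[str, int],
                          total: int | None = None,
                          decimals: int = 0) -> dict[str, float]:
    """Category counts as percentages, rounded as reported (integers by
    default)."""
    if total is None:
        total = sum(counts.values())
    if total <= 0:
        raise ValueError("total must be positive")
    return {k: round(100.0 * v / total, decimals) if decimals
            else float(round(100.0 * v / total))
            for k, v in counts.items()}
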