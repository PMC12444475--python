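"""Differential methylation/expression testing and enrichment statistics.

Per-feature group contrasts (periodontitis vs healthy) use Welch's unequal-
variance t-test — methylation on M-values, expression on log2(CPM+1) —
followed by Benjamini-Hochberg control of the false discovery rate at 0.05.
Effect sizes are reported on the interpretable scale (delta-beta for
probes, log2 fold change for genes).  The 2x2 enrichment odds ratio uses a
Haldane 0.5 correction for empty cells and a two-sided Fisher exact p-value
computed by full hypergeometric enumeration in exact integer arithmetic.
"""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from .omics import beta_to_m

__all__ = ["welch_t", "bh_fdr", "run_dmp", "run_deg", "enrichment_or"]

FDR_ALPHA = 0.05


def welch_t(x, y):
    """Welch t-statistic with Satterthwaite df and two-sided p.

    Degenerate zero-variance inputs are resolved explicitly: equal means
    give (0, df, 1); unequal means with zero pooled variance give infinite
    t and p = 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = x.size, y.size
    se2 = vx / nx + vy / ny
    diff = x.mean() - y.mean()
    if se2 == 0:
        df = float(nx + ny - 2)
        if diff == 0:
            return 0.0, df, 1.0
        return float(np.sign(diff) * np.inf), df, 0.0
    t = diff / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def bh_fdr(p_values):
    """Benjamini-Hochberg step-up q-values, order preserved.

    ``q_(i) = min_{j >= i} (m * p_(j) / j)`` capped at 1, where p_(j) is
    the j-th smallest p-value of m.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def _welch_rows(a: np.ndarray, b: np.ndarray):
    """Row-wise Welch test of matrix a vs matrix b (samples in columns)."""
    res = sps.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.asarray(res.statistic, float)
    p = np.asarray(res.pvalue, float)
    df = np.asarray(res.df, float)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        eq = degenerate & np.isclose(a.mean(axis=1), b.mean(axis=1))
        t[eq], p[eq] = 0.0, 1.0
        ne = degenerate & ~eq
        t[ne] = np.sign(a.mean(axis=1) - b.mean(axis=1))[ne] * np.inf
        p[ne] = 0.0
        df[degenerate] = a.shape[1] + b.shape[1] - 2
    return t, df, p


def _diff_frame(index, effect, t, df, p):
    q = bh_fdr(p)
    return pd.DataFrame(
        {
            "feature_id": index,
            "effect": effect,
            "t": t,
            "df": df,
            "p": p,
            "q": q,
            "significant": q < FDR_ALPHA,
        }
    )


def run_dmp(cohort, use_m_values: bool = True) -> pd.DataFrame:
    """Probe-level differential methylation, periodontitis vs healthy.

    The test runs on M-values (variance-stabilised logit scale) by default;
    the reported effect is always delta-beta on the beta scale.
    """
    perio = cohort.group_mask("periodontitis")
    healthy = cohort.group_mask("healthy")
    beta = cohort.beta.to_numpy()
    mat = beta_to_m(beta) if use_m_values else beta
    t, df, p = _welch_rows(mat[:, perio], mat[:, healthy])
    effect = beta[:, perio].mean(axis=1) - beta[:, healthy].mean(axis=1)
    return _diff_frame(list(cohort.beta.index), effect, t, df, p)


def run_deg(normexpr, groups) -> pd.DataFrame:
    """Gene-level differential expression on log2(CPM+1), perio vs healthy."""
    g = np.asarray(groups)
    perio, healthy = g == "periodontitis", g == "healthy"
    if not perio.any() or not healthy.any():
        raise ValueError("need samples in both periodontitis and healthy groups")
    mat = normexpr.log_cpm.to_numpy()
    t, df, p = _welch_rows(mat[:, perio], mat[:, healthy])
    effect = mat[:, perio].mean(axis=1) - mat[:, healthy].mean(axis=1)
    return _diff_frame(list(normexpr.log_cpm.index), effect, t, df, p)


def fisher_exact_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Enumerates the full hypergeometric support in exact integer arithmetic:
    all tables with the observed margins whose probability does not exceed
    the observed table's are summed.
    """
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    # probabilities share the denominator C(n, col1); compare numerators
    num_obs = comb(row1, a) * comb(n - row1, col1 - a)
    total = 0
    for k in range(lo, hi + 1):
        num_k = comb(row1, k) * comb(n - row1, col1 - k)
        if num_k <= num_obs:
            total += num_k
    return total / comb(n, col1)


def enrichment_or(hits_in_region: int, hits_out: int,
                  nonhits_in: int, nonhits_out: int):
    """Odds ratio and two-sided Fisher exact p for a 2x2 enrichment table.

    The Haldane correction (adding 0.5 to every cell) is applied to the
    odds ratio when any cell is zero; the p-value always uses the raw
    counts.
    """
    cells = (hits_in_region, hits_out, nonhits_in, nonhits_out)
    if any(c < 0 for c in cells):
        raise ValueError("counts must be non-negative")
    if sum(cells) == 0:
        raise ValueError("empty table")
    a, b, c, d = (float(v) for v in cells)
    if min(cells) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    oddsratio = (a * d) / (b * c)
    p = fisher_exact_p(*cells)
    return float(oddsratio), float(p)
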