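"""Welch tests, BH-FDR, Fisher enrichment, and differential analyses."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

import eplink
from eplink.stats import bh_fdr, enrichment_or, fisher_exact_p, welch_t


# ---------------------------------------------------------------------------
# Welch t


def test_welch_identical_groups():
    t, _, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == 0.0 and p == 1.0


def test_welch_closed_form_example():
    t, df, p = welch_t([1, 2, 3], [4, 5, 6])
    assert t == pytest.approx(-3.6742346, abs=1e-6)
    assert df == pytest.approx(4.0, abs=1e-12)
    assert p == pytest.approx(0.021312, abs=1e-5)


def test_welch_shift_invariance():
    x, y = [1.0, 2.5, 3.0, 4.5], [2.0, 2.2, 5.1]
    t1, df1, p1 = welch_t(x, y)
    t2, df2, p2 = welch_t([v + 10 for v in x], [v + 10 for v in y])
    assert (t1, df1, p1) == pytest.approx((t2, df2, p2), abs=1e-12)


def test_welch_zero_variance_equal_means():
    t, _, p = welch_t([2.0, 2.0], [2.0, 2.0])
    assert t == 0.0 and p == 1.0


@pytest.mark.parametrize("seed", range(3))
def test_welch_matches_scipy(seed):
    rng = np.random.default_rng(seed)
    x, y = rng.normal(size=8), rng.normal(1, 2, size=5)
    t, df, p = welch_t(x, y)
    ref = sps.ttest_ind(x, y, equal_var=False)
    assert t == pytest.approx(ref.statistic, abs=1e-12)
    assert p == pytest.approx(ref.pvalue, abs=1e-12)


# ---------------------------------------------------------------------------
# BH-FDR


def bh_oracle(p):
    """Literal step-up definition: q_i = min over p_(j) >= p_i of m p_(j)/j."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    for pos, i in enumerate(order):
        best = min(p[order[j]] * m / (j + 1) for j in range(pos, m))
        q[i] = min(1.0, best)
    return q


def test_bh_single_and_equal():
    assert bh_fdr([0.03]) == pytest.approx([0.03])
    np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])


@pytest.mark.parametrize("seed", range(5))
def test_bh_matches_stepup_oracle_exactly(seed):
    rng = np.random.default_rng(seed)
    p = rng.random(int(rng.integers(1, 21)))
    got = bh_fdr(p)
    assert list(got) == bh_oracle(p)


def test_bh_matches_statsmodels():
    rng = np.random.default_rng(10)
    p = rng.random(50)
    np.testing.assert_allclose(
        bh_fdr(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
    )


def test_bh_monotone_in_p_rank():
    rng = np.random.default_rng(2)
    p = rng.random(40)
    q = bh_fdr(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-15).all()


def test_bh_rejects_invalid_p():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.2])


def test_bh_controls_fdr_under_uniform_null():
    rng = np.random.default_rng(0)
    fdrs = []
    for _ in range(100):
        p = rng.random(200)
        rejected = bh_fdr(p) < 0.05
        fdrs.append(rejected.sum() / max(rejected.sum(), 1) if rejected.any() else 0.0)
    assert np.mean(fdrs) <= 0.05 + 0.02


# ---------------------------------------------------------------------------
# Fisher / odds ratio


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exact rational hypergeometric enumeration."""
    n, row1, col1 = a + b + c + d, a + b, a + c
    obs = Fraction(comb(row1, a) * comb(n - row1, col1 - a), comb(n, col1))
    total = Fraction(0)
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        pk = Fraction(comb(row1, k) * comb(n - row1, col1 - k), comb(n, col1))
        if pk <= obs:
            total += pk
    return float(total)


def test_enrichment_balanced_table():
    oratio, p = enrichment_or(10, 10, 10, 10)
    assert oratio == 1.0 and p == 1.0


def test_enrichment_example_with_oracle():
    oratio, p = enrichment_or(8, 2, 1, 5)
    assert oratio == pytest.approx(20.0)
    assert p == fisher_oracle(8, 2, 1, 5)


def test_enrichment_transpose_inverts_odds_ratio():
    o1, _ = enrichment_or(8, 2, 1, 5)
    o2, _ = enrichment_or(2, 8, 5, 1)
    assert o1 == pytest.approx(1 / o2)


@pytest.mark.parametrize("seed", range(5))
def test_fisher_matches_exact_enumeration(seed):
    rng = np.random.default_rng(seed)
    for _ in range(20):
        a, b, c, d = (int(v) for v in rng.integers(0, 13, size=4))
        if a + b + c + d == 0:
            continue
        assert fisher_exact_p(a, b, c, d) == fisher_oracle(a, b, c, d)


def test_fisher_close_to_scipy():
    rng = np.random.default_rng(1)
    for _ in range(20):
        a, b, c, d = (int(v) + 1 for v in rng.integers(0, 10, size=4))
        ours = fisher_exact_p(a, b, c, d)
        ref = sps.fisher_exact([[a, b], [c, d]])[1]
        assert ours == pytest.approx(ref, rel=1e-6, abs=1e-12)


def test_enrichment_haldane_correction_on_zero_cell():
    oratio, _ = enrichment_or(5, 0, 2, 7)
    assert oratio == pytest.approx((5.5 * 7.5) / (0.5 * 2.5))


def test_enrichment_rejects_negative_counts():
    with pytest.raises(ValueError):
        enrichment_or(-1, 2, 3, 4)


# ---------------------------------------------------------------------------
# differential analyses


def test_dmp_row_count_and_effect_scale(small_synthetic):
    dmp = eplink.run_dmp(small_synthetic.cohort)
    assert len(dmp) == small_synthetic.cohort.beta.shape[0]
    assert dmp["effect"].abs().max() <= 1.0  # delta-beta stays on beta scale
    assert dmp["p"].between(0, 1).all() and dmp["q"].between(0, 1).all()


def test_dmp_recovers_planted_probes(small_synthetic):
    co = small_synthetic.cohort
    dmp = eplink.run_dmp(co).set_index("feature_id")
    planted_enh = {p.enhancer_id for p in small_synthetic.truth_pairs if p.label == 1}
    planted = co.probe_annot.index[co.probe_annot["enhancer_id"].isin(planted_enh)]
    assert dmp.loc[planted, "significant"].mean() >= 0.8
    assert dmp.loc[planted, "effect"].mean() < -0.2  # hypomethylation


def test_dmp_null_cohort_controls_fdr():
    fracs = []
    for seed in range(3):
        cfg = eplink.SimConfig(n_enhancers=30, n_genes=45, n_true_pairs=24,
                               n_null_pairs=24, n_background_probes=30,
                               chrom_length=3_000_000, delta_beta=0.0, seed=seed)
        sc = eplink.generate_cohort(cfg)
        fracs.append(eplink.run_dmp(sc.cohort)["significant"].mean())
    assert np.mean(fracs) <= 0.07


def _deg_recovery(coupling, seed):
    """Fraction of planted target genes significant, and the null hit rate.

    Planted DE genes are kept a minority (30 of 300) so TMM's assumption
    that most genes are not differentially expressed holds.
    """
    cfg = eplink.SimConfig(n_genes=300, n_true_pairs=30, n_null_pairs=30,
                           n_enhancers=60, n_background_probes=10,
                           coupling_log2fc=coupling, seed=seed)
    sc = eplink.generate_cohort(cfg)
    ne = eplink.filter_and_log(sc.cohort.counts,
                               eplink.tmm_normalise(sc.cohort.counts))
    deg = eplink.run_deg(ne, sc.cohort.groups.loc[sc.cohort.samples].to_numpy())
    sig = deg.set_index("feature_id")["significant"]
    targets = {p.gene_id for p in sc.truth_pairs if p.label == 1}
    rec = np.mean([bool(sig.get(g, False)) for g in targets])
    null_rate = deg[~deg["feature_id"].isin(targets)]["significant"].mean()
    return rec, null_rate


def test_deg_discoveries_concentrate_on_planted_targets():
    """At the default coupling (planted log2FC ~ 0.6, near the 12-vs-12
    detection limit) discoveries must still be enriched in planted genes."""
    recs, nulls = zip(*(_deg_recovery(2.0, seed) for seed in range(3)))
    assert np.mean(recs) > 5 * max(np.mean(nulls), 0.01)


def test_deg_recovers_targets_at_study_scale_fold_changes():
    """At fold changes like those the study reports for its inflammatory
    genes (log2FC ~ 2.4), >= 80% of planted targets reach q < 0.05."""
    recs, _ = zip(*(_deg_recovery(8.0, seed) for seed in range(3)))
    assert np.mean(recs) >= 0.8


def test_deg_effect_antisymmetric_under_group_swap(small_synthetic, small_normexpr):
    groups = small_synthetic.cohort.groups.loc[small_synthetic.cohort.samples].to_numpy()
    swapped = np.where(groups == "healthy", "periodontitis",
                       np.where(groups == "periodontitis", "healthy", groups))
    d1 = eplink.run_deg(small_normexpr, groups)
    d2 = eplink.run_deg(small_normexpr, swapped)
    np.testing.assert_allclose(d1["effect"].to_numpy(), -d2["effect"].to_numpy(),
                               atol=1e-12)
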