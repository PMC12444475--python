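"""Cohort container, file formats, and normalisation transforms.

This module holds the paired-omics cohort (methylation betas, expression
counts, element annotations, sample groups), readers/writers for the
plain-text formats the package exchanges (TSV matrices, BED enhancers),
and the two normalisation steps applied before any pair is scored:

* methylation: the beta -> M logit transform, ``M = log2(beta / (1 - beta))``;
* expression: TMM scaling factors, a CPM-based low-expression filter, and
  a ``log2(CPM + 1)`` transform.

Coordinates are 0-based half-open internally; BED is native and gene TSS
values are converted from 1-based on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import rankdata

GROUPS = ("healthy", "gingivitis", "periodontitis")

__all__ = [
    "OmicsCohort",
    "NormalisedExpression",
    "beta_to_m",
    "m_to_beta",
    "tmm_normalise",
    "filter_and_log",
    "read_cohort",
    "write_matrix_tsv",
    "read_matrix_tsv",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class OmicsCohort:
    """Aligned methylation betas, expression counts and annotations.

    Attributes
    ----------
    beta : DataFrame, probes x samples, values in [0, 1]
    counts : DataFrame, genes x samples, non-negative integers
    probe_annot : DataFrame indexed by probe id with columns
        ``chrom``, ``pos`` (0-based) and ``enhancer_id`` (NaN if the probe
        falls outside every enhancer interval)
    gene_annot : DataFrame indexed by gene id with columns
        ``chrom``, ``tss`` (0-based) and ``strand``
    enhancers : DataFrame indexed by enhancer id with columns
        ``chrom``, ``start``, ``end`` (0-based half-open)
    samples : ordered sample ids (column order of both matrices)
    groups : Series mapping sample id -> group label
    """

    beta: pd.DataFrame
    counts: pd.DataFrame
    probe_annot: pd.DataFrame
    gene_annot: pd.DataFrame
    enhancers: pd.DataFrame
    samples: list[str]
    groups: pd.Series

    def __post_init__(self):
        if list(self.beta.columns) != list(self.samples):
            raise ValueError("beta columns do not match sample order")
        if list(self.counts.columns) != list(self.samples):
            raise ValueError("counts columns do not match sample order")
        missing = [s for s in self.samples if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        bad = set(self.groups.loc[list(self.samples)]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        b = self.beta.to_numpy()
        if np.nanmin(b) < 0 or np.nanmax(b) > 1:
            raise ValueError("beta values outside [0, 1]")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    def group_mask(self, group: str) -> np.ndarray:
        return (self.groups.loc[list(self.samples)] == group).to_numpy()


@dataclass
class NormalisedExpression:
    """TMM factors plus the filtered ``log2(CPM + 1)`` matrix."""

    log_cpm: pd.DataFrame
    tmm_factors: pd.Series
    kept_genes: list[str] = field(default_factory=list)

    def __post_init__(self):
        if (self.tmm_factors <= 0).any():
            raise ValueError("TMM factors must be positive")
        if not np.isfinite(self.log_cpm.to_numpy()).all():
            raise ValueError("non-finite log-CPM values")


# ---------------------------------------------------------------------------
# methylation transform


def beta_to_m(beta, eps: float = 1e-6):
    """Logit transform of methylation betas, ``log2(beta / (1 - beta))``.

    Betas are clipped into ``[eps, 1 - eps]`` first so boundary values stay
    finite.  Strictly increasing in beta and odd around beta = 0.5.
    """
    if not 0 < eps < 0.5:
        raise ValueError("eps must lie in (0, 0.5)")
    b = np.clip(np.asarray(beta, dtype=float), eps, 1 - eps)
    return np.log2(b / (1 - b))


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: ``beta = 2^M / (1 + 2^M)``."""
    m = np.asarray(m, dtype=float)
    return 1.0 / (1.0 + np.exp2(-m))


# ---------------------------------------------------------------------------
# TMM normalisation

_LOGRATIO_TRIM = 0.3
_SUM_TRIM = 0.05


def tmm_normalise(counts: pd.DataFrame) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, one per sample.

    Follows the canonical published algorithm: the reference sample is the
    one whose upper-quartile count rate is closest to the mean upper
    quartile; per sample, gene-wise log2 ratios against the reference
    (library-size normalised) are trimmed by 30% on the ratio and 5% on
    average log intensity, then combined by inverse-variance weighting.
    Factors are renormalised to geometric mean 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if (lib <= 0).any():
        bad = list(counts.columns[lib <= 0])
        raise ValueError(f"all-zero libraries: {bad}")

    with np.errstate(divide="ignore", invalid="ignore"):
        rate = x / lib
    f75 = np.quantile(rate, 0.75, axis=0)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    log_factors = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        if j == ref:
            continue
        log_factors[j] = _tmm_pair(x[:, j], lib[j], x[:, ref], lib[ref])
    factors = 2.0**log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def _tmm_pair(obs, n_obs, ref, n_ref) -> float:
    """Trimmed, weighted mean of M-values of one sample against the reference."""
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        return 0.0
    p, q = obs[pos] / n_obs, ref[pos] / n_ref
    logr = np.log2(p / q)
    abse = 0.5 * (np.log2(p) + np.log2(q))
    # asymptotic (delta-method) variance of each M-value
    v = (n_obs - obs[pos]) / (n_obs * obs[pos]) + (n_ref - ref[pos]) / (n_ref * ref[pos])

    n = logr.size
    lo_l = np.floor(n * _LOGRATIO_TRIM) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * _SUM_TRIM) + 1
    hi_s = n + 1 - lo_s
    rank_l = rankdata(logr)
    rank_s = rankdata(abse)
    keep = (rank_l >= lo_l) & (rank_l <= hi_l) & (rank_s >= lo_s) & (rank_s <= hi_s)
    if not keep.any():
        return 0.0
    f = np.sum(logr[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 0.0
    return f


def filter_and_log(counts: pd.DataFrame, factors: pd.Series) -> NormalisedExpression:
    """CPM filter on effective library sizes, then ``log2(CPM + 1)``.

    CPM uses effective library sizes (raw total x TMM factor).  A gene is
    removed when its CPM is below 1 in strictly more than half the samples;
    CPM >= 1 in exactly half the samples keeps the gene.
    """
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    eff = lib * factors.loc[counts.columns].to_numpy()
    cpm = counts.to_numpy(dtype=float) / eff * 1e6
    low = (cpm < 1).sum(axis=1)
    keep = low <= counts.shape[1] / 2
    kept = list(counts.index[keep])
    log_cpm = pd.DataFrame(
        np.log2(cpm[keep] + 1.0), index=kept, columns=counts.columns
    )
    return NormalisedExpression(log_cpm=log_cpm, tmm_factors=factors, kept_genes=kept)


# ---------------------------------------------------------------------------
# file formats


def write_matrix_tsv(df: pd.DataFrame, path, index_label: str) -> None:
    df.to_csv(path, sep="\t", index_label=index_label, lineterminator="\n")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_enhancer_bed(path) -> pd.DataFrame:
    """BED3+name.  Returns a frame indexed by enhancer id."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 BED columns")
            chrom, start, end, name = parts[:4]
            try:
                start, end = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}: line {lineno}: start >= end")
            rows.append((name, chrom, start, end))
    df = pd.DataFrame(rows, columns=["enhancer_id", "chrom", "start", "end"])
    return df.set_index("enhancer_id")


def assign_probes_to_enhancers(probe_annot: pd.DataFrame,
                               enhancers: pd.DataFrame) -> pd.Series:
    """Map each probe to the enhancer interval containing it (or NaN).

    A probe at 0-based position ``p`` matches ``[start, end)`` iff
    ``start <= p < end``.  If intervals overlap, the lexicographically
    smallest enhancer id wins.
    """
    trees: dict[str, IntervalTree] = {}
    for eid, row in enhancers.iterrows():
        trees.setdefault(row["chrom"], IntervalTree()).addi(
            int(row["start"]), int(row["end"]), eid
        )
    out = []
    for _, row in probe_annot.iterrows():
        tree = trees.get(row["chrom"])
        hits = sorted(iv.data for iv in tree[int(row["pos"])]) if tree else []
        out.append(hits[0] if hits else np.nan)
    return pd.Series(out, index=probe_annot.index, name="enhancer_id")


def read_cohort(beta_path, counts_path, enhancer_bed, gene_tsv, sample_sheet,
                probe_tsv=None) -> OmicsCohort:
    """Assemble an :class:`OmicsCohort` from its on-disk fixture files.

    ``probe_tsv`` (columns ``probe_id``, ``chrom``, ``pos`` 1-based) supplies
    probe coordinates; when omitted, probe ids of the form ``chrom:pos``
    (1-based) are parsed instead.  Probes overlapping an enhancer interval
    receive its id.
    """
    beta = read_matrix_tsv(beta_path)
    counts = read_matrix_tsv(counts_path)
    sheet = pd.read_csv(sample_sheet, sep="\t")
    samples = list(sheet["sample_id"])
    groups = pd.Series(sheet["group"].to_numpy(), index=samples, name="group")

    for name, cols in (("beta", beta.columns), ("counts", counts.columns)):
        missing = sorted(set(samples) - set(cols))
        extra = sorted(set(cols) - set(samples))
        if missing or extra:
            raise ValueError(
                f"sample sheet and {name} matrix disagree: "
                f"missing from {name}: {missing}; not in sheet: {extra}"
            )
    beta = beta[samples]
    counts = counts[samples]

    enhancers = read_enhancer_bed(enhancer_bed)

    genes = pd.read_csv(gene_tsv, sep="\t").set_index("gene_id")
    genes["tss"] = genes["tss"].astype(int) - 1  # 1-based on disk -> 0-based

    if probe_tsv is not None:
        probes = pd.read_csv(probe_tsv, sep="\t").set_index("probe_id")
        probes["pos"] = probes["pos"].astype(int) - 1
    else:
        parts = [pid.rsplit(":", 1) for pid in beta.index]
        probes = pd.DataFrame(
            {"chrom": [p[0] for p in parts],
             "pos": [int(p[1]) - 1 for p in parts]},
            index=beta.index,
        )
    probes = probes.loc[beta.index, ["chrom", "pos"]].copy()
    probes["enhancer_id"] = assign_probes_to_enhancers(probes, enhancers)

    return OmicsCohort(
        beta=beta,
        counts=counts,
        probe_annot=probes,
        gene_annot=genes[["chrom", "tss", "strand"]],
        enhancers=enhancers,
        samples=samples,
        groups=groups,
    )
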