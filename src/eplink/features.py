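"""Per-pair feature vectors consumed by the classifier.

Each candidate pair is described by eleven features: methylation summary
statistics over the enhancer's probes (mean beta, SD, and the
periodontitis-vs-healthy difference delta-beta), expression summaries of
the target gene on the log2(CPM+1) scale (mean, SD, log2 fold change),
three methylation-expression correlations (Pearson, Spearman, and partial
correlation controlling for ordinal disease severity), the log10 genomic
distance, and the interaction term delta_beta x log2FC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pairs import CandidatePair

log = logging.getLogger(__name__)

FEATURE_NAMES = [
    "mean_beta", "sd_beta", "delta_beta", "mean_expr", "sd_expr", "log2fc",
    "pearson_r", "spearman_rho", "partial_r", "log_dist", "interaction",
]

SEVERITY = {"healthy": 0.0, "gingivitis": 1.0, "periodontitis": 2.0}

__all__ = ["FEATURE_NAMES", "FeatureTable", "enhancer_methylation_profile",
           "delta_beta", "log2_fold_change", "correlations", "assemble_features"]


@dataclass
class FeatureTable:
    """Raw feature matrix for a set of pairs plus standardisation state.

    ``mu``/``sigma`` are fitted from a training subset only (via
    :meth:`fit_standardiser`) and applied to every row; columns with zero
    spread get sigma 1 so standardised values stay finite.
    """

    pairs: list[CandidatePair]
    X: np.ndarray                       # n_pairs x 11, raw
    labels: np.ndarray                  # 1 / 0 / -1 (unknown)
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))
    mu: np.ndarray | None = None
    sigma: np.ndarray | None = None

    def __len__(self):
        return len(self.pairs)

    def fit_standardiser(self, train_idx: np.ndarray) -> None:
        sub = self.X[np.asarray(train_idx)]
        self.mu = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=0)
        self.sigma = np.where(sd > 0, sd, 1.0)

    @property
    def X_std(self) -> np.ndarray:
        if self.mu is None:
            raise ValueError("standardiser not fitted; call fit_standardiser first")
        return (self.X - self.mu) / self.sigma

    def subset(self, idx) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(
            pairs=[self.pairs[i] for i in idx],
            X=self.X[idx].copy(),
            labels=self.labels[idx].copy(),
            feature_names=list(self.feature_names),
            mu=None if self.mu is None else self.mu.copy(),
            sigma=None if self.sigma is None else self.sigma.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "enhancer_id": [p.enhancer_id for p in self.pairs],
                "gene_id": [p.gene_id for p in self.pairs],
                "distance_bp": [p.distance_bp for p in self.pairs],
            }
        )
        for j, name in enumerate(self.feature_names):
            df[name] = self.X[:, j]
        if self.mu is not None:
            std = self.X_std
            for j, name in enumerate(self.feature_names):
                df[f"{name}_std"] = std[:, j]
        df["label"] = self.labels
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# single-pair building blocks


def enhancer_methylation_profile(enhancer_id: str, cohort) -> np.ndarray:
    """Per-sample mean beta over the enhancer's probes."""
    mask = cohort.probe_annot["enhancer_id"] == enhancer_id
    if not mask.any():
        raise ValueError(f"enhancer {enhancer_id} has no probes")
    return cohort.beta.loc[mask.to_numpy()].to_numpy().mean(axis=0)


def _group_means(values: np.ndarray, groups: np.ndarray):
    out = {}
    for g in ("healthy", "periodontitis"):
        sel = groups == g
        if not sel.any():
            raise ValueError(f"no samples in group {g!r}")
        out[g] = float(values[sel].mean())
    return out


def delta_beta(beta_vec: np.ndarray, groups: np.ndarray) -> float:
    """Mean beta in periodontitis minus healthy (negative = hypomethylation)."""
    m = _group_means(np.asarray(beta_vec, float), np.asarray(groups))
    return m["periodontitis"] - m["healthy"]


def log2_fold_change(logexpr_vec: np.ndarray, groups: np.ndarray) -> float:
    """Mean log2(CPM+1) in periodontitis minus healthy."""
    m = _group_means(np.asarray(logexpr_vec, float), np.asarray(groups))
    return m["periodontitis"] - m["healthy"]


def correlations(beta_vec, logexpr_vec, groups):
    """(Pearson r, Spearman rho, partial r given ordinal disease severity).

    Constant inputs give 0 rather than NaN so the classifier always sees
    finite values; a degenerate severity correlation (|r| = 1) makes the
    partial correlation 0 as well.
    """
    x = np.asarray(beta_vec, float)
    y = np.asarray(logexpr_vec, float)
    if x.size < 4:
        raise ValueError("need at least 4 samples for correlations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("constant vector in correlation; reporting zeros")
        return 0.0, 0.0, 0.0
    pear = float(stats.pearsonr(x, y).statistic)
    spear = float(stats.spearmanr(x, y).statistic)
    z = np.array([SEVERITY[g] for g in groups])
    if np.ptp(z) == 0:
        return pear, spear, 0.0
    r_xz = float(stats.pearsonr(x, z).statistic)
    r_yz = float(stats.pearsonr(y, z).statistic)
    denom = (1 - r_xz**2) * (1 - r_yz**2)
    if denom <= 0:
        partial = 0.0
    else:
        partial = (pear - r_xz * r_yz) / np.sqrt(denom)
    return pear, spear, float(np.clip(partial, -1.0, 1.0))


# ---------------------------------------------------------------------------
# table assembly


def assemble_features(catalogue: list[CandidatePair], cohort, normexpr,
                      train_idx=None) -> FeatureTable:
    """Compute the 11 features for every pair that survives filtering.

    Pairs whose enhancer has no probes or whose gene was removed by the
    CPM filter are dropped (counts logged).  When ``train_idx`` is given,
    standardisation statistics are fitted on those rows immediately.
    """
    groups = cohort.groups.loc[list(cohort.samples)].to_numpy()
    kept_genes = set(normexpr.kept_genes)
    profile_cache: dict[str, np.ndarray | None] = {}

    rows, kept_pairs, labels = [], [], []
    n_no_probe = n_filtered = 0
    for pair in catalogue:
        if pair.enhancer_id not in profile_cache:
            try:
                profile_cache[pair.enhancer_id] = enhancer_methylation_profile(
                    pair.enhancer_id, cohort)
            except ValueError:
                profile_cache[pair.enhancer_id] = None
        bvec = profile_cache[pair.enhancer_id]
        if bvec is None:
            n_no_probe += 1
            continue
        if pair.gene_id not in kept_genes:
            n_filtered += 1
            continue
        evec = normexpr.log_cpm.loc[pair.gene_id].to_numpy()

        db = delta_beta(bvec, groups)
        fc = log2_fold_change(evec, groups)
        pear, spear, partial = correlations(bvec, evec, groups)
        rows.append([
            float(bvec.mean()), float(bvec.std(ddof=1)), db,
            float(evec.mean()), float(evec.std(ddof=1)), fc,
            pear, spear, partial,
            float(np.log10(pair.distance_bp + 1)),
            db * fc,
        ])
        kept_pairs.append(pair)
        labels.append(-1 if pair.label is None else pair.label)

    if n_no_probe:
        log.warning("dropped %d pairs whose enhancer has no probes", n_no_probe)
    if n_filtered:
        log.warning("dropped %d pairs whose gene failed the CPM filter", n_filtered)
    if not rows:
        raise ValueError("no pairs survive feature assembly")

    table = FeatureTable(
        pairs=kept_pairs,
        X=np.asarray(rows, dtype=float),
        labels=np.asarray(labels, dtype=int),
    )
    if train_idx is not None:
        table.fit_standardiser(train_idx)
    return table
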