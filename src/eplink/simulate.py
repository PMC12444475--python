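"""Seeded synthetic cohorts with planted enhancer-promoter couplings.

The generator emulates the study design the package targets: a 12/12/12
healthy / gingivitis / periodontitis cohort with paired EPIC-style
methylation betas and RNA-seq counts on one synthetic chromosome.  A
subset of enhancers is hypomethylated in disease (betas shifted down by
``delta_beta`` in periodontitis, half that in gingivitis, matching the
ordered separation seen between the three groups) and each such enhancer
drives upregulation of target genes within 1 Mb: the gene's negative-
binomial log2 mean is raised by ``coupling_log2fc`` per unit of beta lost.
Null pairs draw their enhancer and gene from elements that carry no
disease effect, so their betas and counts are independent.

Betas are simulated as Gaussian noise on the logit scale pushed through
the inverse logit, guaranteeing values in (0, 1); counts are negative
binomial with log-normal library sizes, which gives the TMM/CPM machinery
realistic input.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .omics import OmicsCohort, write_matrix_tsv
from .pairs import CandidatePair, pair_distance, MAX_DISTANCE_BP

__all__ = ["SimConfig", "SyntheticCohort", "generate_cohort", "write_fixture_set"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic cohort.

    Defaults describe the study conditions the package is exercised under:
    12 samples per group, 200 enhancers and 300 genes on a 10 Mb synthetic
    chromosome, 200 planted (true) and 200 null pairs, disease
    hypomethylation of 0.30 on the beta scale and an expression coupling of
    2.0 log2 units per unit beta change.
    """

    n_per_group: int = 12
    n_enhancers: int = 200
    n_genes: int = 300
    n_true_pairs: int = 200
    n_null_pairs: int = 200
    chrom_length: int = 10_000_000
    probes_per_enhancer: int = 3
    n_background_probes: int = 200
    delta_beta: float = 0.30
    coupling_log2fc: float = 2.0
    beta_noise_sd: float = 0.5
    nb_dispersion: float = 0.1
    lib_size_mean: float = 1e6
    lib_size_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self):
        for name in ("n_per_group", "n_enhancers", "n_genes", "n_true_pairs",
                     "n_null_pairs", "chrom_length", "probes_per_enhancer"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not -1 < self.delta_beta < 1:
            raise ValueError("delta_beta must lie in (-1, 1)")
        if self.beta_noise_sd < 0 or self.nb_dispersion <= 0:
            raise ValueError("noise parameters must be positive")
        if self.n_background_probes < 0:
            raise ValueError("n_background_probes must be >= 0")


@dataclass
class SyntheticCohort:
    """A generated cohort plus its planted truth pairs and provenance."""

    cohort: OmicsCohort
    truth_pairs: list[CandidatePair]
    provenance: SimConfig


_CHROM = "chrS"


def _logit(p):
    return np.log(p / (1 - p))


def _inv_logit(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate one seeded cohort; identical config implies identical output."""
    rng = np.random.default_rng(config.seed)
    c = config

    samples, groups = [], []
    for prefix, group in (("H", "healthy"), ("G", "gingivitis"), ("P", "periodontitis")):
        for i in range(c.n_per_group):
            samples.append(f"{prefix}{i + 1:02d}")
            groups.append(group)
    groups = pd.Series(groups, index=samples, name="group")
    n_samples = len(samples)

    # --- element placement: non-overlapping enhancers on a slot grid -------
    slot = c.chrom_length // c.n_enhancers
    widths = rng.integers(200, min(2001, slot), size=c.n_enhancers)
    offsets = rng.integers(0, slot - widths + 1)
    starts = np.arange(c.n_enhancers) * slot + offsets
    ends = starts + widths
    enh_ids = [f"enh{i + 1:04d}" for i in range(c.n_enhancers)]
    enhancers = pd.DataFrame(
        {"chrom": _CHROM, "start": starts, "end": ends}, index=pd.Index(enh_ids)
    )

    tss = np.sort(rng.integers(0, c.chrom_length, size=c.n_genes))
    gene_ids = [f"gene{i + 1:04d}" for i in range(c.n_genes)]
    strands = rng.choice(["+", "-"], size=c.n_genes)
    gene_annot = pd.DataFrame(
        {"chrom": _CHROM, "tss": tss, "strand": strands}, index=pd.Index(gene_ids)
    )

    # --- probes: several per enhancer plus intergenic background ----------
    probe_rows = []
    for i, eid in enumerate(enh_ids):
        pos = np.sort(rng.integers(starts[i], ends[i], size=c.probes_per_enhancer))
        for p in pos:
            probe_rows.append((f"{_CHROM}:{p + 1}", int(p), eid))
    occupied = np.zeros(c.chrom_length, dtype=bool) if c.chrom_length <= 50_000_000 else None
    for i in range(c.n_enhancers):
        if occupied is not None:
            occupied[starts[i]:ends[i]] = True
    n_bg = 0
    while n_bg < c.n_background_probes:
        p = int(rng.integers(0, c.chrom_length))
        if occupied is not None and occupied[p]:
            continue
        probe_rows.append((f"{_CHROM}:{p + 1}", p, np.nan))
        n_bg += 1
    probe_annot = pd.DataFrame(
        probe_rows, columns=["probe_id", "pos", "enhancer_id"]
    ).set_index("probe_id")
    probe_annot.insert(0, "chrom", _CHROM)

    # --- choose planted and null pairs -------------------------------------
    perm = rng.permutation(c.n_enhancers)
    n_disease_enh = max(1, c.n_enhancers // 2)
    disease_enh = [enh_ids[i] for i in perm[:n_disease_enh]]
    null_enh = [enh_ids[i] for i in perm[n_disease_enh:]]
    if not null_enh:
        raise ValueError("need at least 2 enhancers to host both pair classes")

    in_window: dict[str, list[str]] = {}
    for eid in enh_ids:
        s, e = int(enhancers.loc[eid, "start"]), int(enhancers.loc[eid, "end"])
        in_window[eid] = [
            gid for gid in gene_ids
            if pair_distance(_CHROM, s, e, _CHROM, int(gene_annot.loc[gid, "tss"]))
            <= MAX_DISTANCE_BP
        ]

    def _draw_pairs(enh_pool, gene_ok, n_pairs, allow_gene_reuse):
        pairs, used_genes, used_keys = [], set(), set()
        attempts = 0
        i = 0
        while len(pairs) < n_pairs:
            attempts += 1
            if attempts > 50 * n_pairs:
                raise ValueError(
                    "infeasible pair placement: not enough enhancer-gene "
                    "combinations within 1 Mb"
                )
            eid = enh_pool[i % len(enh_pool)]
            i += 1
            cand = [g for g in in_window[eid]
                    if gene_ok(g) and (eid, g) not in used_keys
                    and (allow_gene_reuse or g not in used_genes)]
            if not cand and allow_gene_reuse:
                cand = [g for g in in_window[eid]
                        if gene_ok(g) and (eid, g) not in used_keys]
            if not cand:
                continue
            gid = cand[int(rng.integers(0, len(cand)))]
            used_keys.add((eid, gid))
            used_genes.add(gid)
            pairs.append((eid, gid))
        return pairs, used_genes

    true_pairs, true_genes = _draw_pairs(
        disease_enh, lambda g: True, c.n_true_pairs, allow_gene_reuse=False
    )
    null_pairs, _ = _draw_pairs(
        null_enh, lambda g: g not in true_genes, c.n_null_pairs, allow_gene_reuse=True
    )

    # --- methylation betas --------------------------------------------------
    group_offsets = {"healthy": 0.0, "gingivitis": c.delta_beta / 2,
                     "periodontitis": c.delta_beta}
    offset_vec = np.array([group_offsets[groups[s]] for s in samples])

    disease_set = set(disease_enh)
    n_probes = len(probe_annot)
    base_beta = np.empty(n_probes)
    is_disease_probe = np.zeros(n_probes, dtype=bool)
    for k, (pid, row) in enumerate(probe_annot.iterrows()):
        if row["enhancer_id"] in disease_set:
            is_disease_probe[k] = True
    # disease-enhancer probes start high so the downward shift stays in (0,1)
    lo = np.where(is_disease_probe, max(0.55, c.delta_beta + 0.2), 0.2)
    hi = np.where(is_disease_probe, 0.85, 0.8)
    base_beta = lo + (hi - lo) * rng.random(n_probes)

    target = base_beta[:, None] - np.where(is_disease_probe[:, None],
                                           offset_vec[None, :], 0.0)
    target = np.clip(target, 0.02, 0.98)
    noise = rng.normal(0.0, c.beta_noise_sd, size=(n_probes, n_samples))
    beta = _inv_logit(_logit(target) + noise)
    beta_df = pd.DataFrame(beta, index=probe_annot.index, columns=samples)

    # --- expression counts --------------------------------------------------
    # planted target genes are drawn from the expressed range so the CPM
    # filter does not remove them; other genes span a wider range
    base_logcpm = 1.0 + 8.0 * rng.random(c.n_genes)
    gene_pos_idx = {g: i for i, g in enumerate(gene_ids)}
    for _, gid in true_pairs:
        base_logcpm[gene_pos_idx[gid]] = max(base_logcpm[gene_pos_idx[gid]], 3.0)

    shift = np.zeros((c.n_genes, n_samples))
    for eid, gid in true_pairs:
        gi = gene_pos_idx[gid]
        shift[gi, :] += c.coupling_log2fc * offset_vec

    lib = rng.lognormal(np.log(c.lib_size_mean), c.lib_size_sigma, size=n_samples)
    mu = (lib[None, :] / 1e6) * 2.0 ** (base_logcpm[:, None] + shift)
    r = 1.0 / c.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids), columns=samples)

    cohort = OmicsCohort(
        beta=beta_df,
        counts=counts_df,
        probe_annot=probe_annot[["chrom", "pos", "enhancer_id"]],
        gene_annot=gene_annot,
        enhancers=enhancers,
        samples=samples,
        groups=groups,
    )

    truth: list[CandidatePair] = []
    for label, plist in ((1, true_pairs), (0, null_pairs)):
        for eid, gid in plist:
            d = pair_distance(
                _CHROM, int(enhancers.loc[eid, "start"]), int(enhancers.loc[eid, "end"]),
                _CHROM, int(gene_annot.loc[gid, "tss"]),
            )
            truth.append(CandidatePair(eid, gid, _CHROM, d, label))
    return SyntheticCohort(cohort=cohort, truth_pairs=truth, provenance=config)


# ---------------------------------------------------------------------------
# fixture export


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture_set(sc: SyntheticCohort, directory) -> dict:
    """Write the cohort as plain-text fixtures plus a JSON manifest.

    Emits beta and count TSV matrices, the enhancer BED, gene and probe
    annotation TSVs, the sample sheet, the truth-pair table, and
    ``manifest.json`` carrying the generating config and per-file SHA-256
    checksums.  Returns the manifest dict.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    co = sc.cohort

    write_matrix_tsv(co.beta, directory / "beta.tsv", "probe_id")
    write_matrix_tsv(co.counts, directory / "counts.tsv", "gene_id")

    with open(directory / "enhancers.bed", "w") as fh:
        for eid, row in co.enhancers.iterrows():
            fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\t{eid}\n")

    genes = co.gene_annot.copy()
    genes["tss"] = genes["tss"].astype(int) + 1  # 0-based -> 1-based on disk
    genes.to_csv(directory / "genes.tsv", sep="\t", index_label="gene_id",
                 lineterminator="\n")

    probes = co.probe_annot[["chrom", "pos"]].copy()
    probes["pos"] = probes["pos"].astype(int) + 1
    probes.to_csv(directory / "probes.tsv", sep="\t", index_label="probe_id",
                  lineterminator="\n")

    pd.DataFrame({"sample_id": co.samples,
                  "group": [co.groups[s] for s in co.samples]}).to_csv(
        directory / "samples.tsv", sep="\t", index=False, lineterminator="\n")

    pd.DataFrame(
        {
            "enhancer_id": [p.enhancer_id for p in sc.truth_pairs],
            "gene_id": [p.gene_id for p in sc.truth_pairs],
            "distance_bp": [p.distance_bp for p in sc.truth_pairs],
            "label": [p.label for p in sc.truth_pairs],
        }
    ).to_csv(directory / "truth_pairs.tsv", sep="\t", index=False,
             lineterminator="\n")

    files = ["beta.tsv", "counts.tsv", "enhancers.bed", "genes.tsv",
             "probes.tsv", "samples.tsv", "truth_pairs.tsv"]
    manifest = {
        "config": asdict(sc.provenance),
        "checksums": {f: _sha256(directory / f) for f in files},
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
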