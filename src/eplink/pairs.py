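"""Candidate enhancer-gene pair enumeration under the 1 Mb distance rule.

Most validated enhancer-promoter contacts in human tissue fall within a
1 Mb window, so candidate pairs are every same-chromosome enhancer/gene
combination whose genomic distance is at most ``max_dist`` (inclusive).
Distance is anchored at the enhancer midpoint by default; a nearest-edge
variant is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

MAX_DISTANCE_BP = 1_000_000

__all__ = ["CandidatePair", "pair_distance", "build_candidates",
           "catalogue_to_frame", "write_catalogue", "read_catalogue"]


@dataclass(frozen=True)
class CandidatePair:
    """One enhancer-gene pairing; ``label`` is 1/0 or None when unknown."""

    enhancer_id: str
    gene_id: str
    chrom: str
    distance_bp: int
    label: int | None = None


def pair_distance(enh_chrom: str, start: int, end: int,
                  tss_chrom: str, tss: int, anchor: str = "midpoint") -> int:
    """Genomic distance between an enhancer interval and a TSS.

    ``anchor='midpoint'``: |floor((start+end)/2) - tss|, zero when the TSS
    lies inside the (0-based half-open) interval.  ``anchor='edge'``:
    distance to the nearest interval edge.
    """
    if enh_chrom != tss_chrom:
        raise ValueError(
            f"enhancer on {enh_chrom} and TSS on {tss_chrom}: different chromosomes"
        )
    if start <= tss < end:
        return 0
    if anchor == "midpoint":
        return abs((start + end) // 2 - tss)
    if anchor == "edge":
        return start - tss if tss < start else tss - (end - 1)
    raise ValueError(f"unknown anchor {anchor!r}")


def build_candidates(cohort, max_dist: int = MAX_DISTANCE_BP,
                     anchor: str = "midpoint") -> list[CandidatePair]:
    """All same-chromosome pairs within ``max_dist`` (inclusive), sorted by
    (enhancer_id, gene_id)."""
    out: list[CandidatePair] = []
    genes = cohort.gene_annot
    for eid in sorted(cohort.enhancers.index):
        erow = cohort.enhancers.loc[eid]
        same = genes[genes["chrom"] == erow["chrom"]]
        for gid in sorted(same.index):
            d = pair_distance(erow["chrom"], int(erow["start"]), int(erow["end"]),
                              erow["chrom"], int(same.loc[gid, "tss"]), anchor)
            if d <= max_dist:
                out.append(CandidatePair(eid, gid, erow["chrom"], d))
    return out


def catalogue_to_frame(pairs: list[CandidatePair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "enhancer_id": [p.enhancer_id for p in pairs],
            "gene_id": [p.gene_id for p in pairs],
            "chrom": [p.chrom for p in pairs],
            "distance_bp": [p.distance_bp for p in pairs],
            "label": [(-1 if p.label is None else p.label) for p in pairs],
        }
    )


def write_catalogue(pairs: list[CandidatePair], path) -> None:
    catalogue_to_frame(pairs).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_catalogue(path) -> list[CandidatePair]:
    df = pd.read_csv(path, sep="\t")
    return [
        CandidatePair(r.enhancer_id, r.gene_id, r.chrom, int(r.distance_bp),
                      None if r.label == -1 else int(r.label))
        for r in df.itertuples()
    ]
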