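"""Bipartite enhancer -> gene network of accepted interactions.

Scored pairs whose probability clears a threshold (the Youden threshold
from evaluation, or 0.5) become edges; nodes are the enhancers and genes
those edges touch.  Summaries report edge/node counts, the median
enhancer-promoter distance (lower median for even edge counts), the mean
stored Pearson correlation, and degree distributions; hubs are nodes of
highest degree.  A Circos-style links file (two coordinate triples plus
the score per edge) can be exported for plotting elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = ["EPNetwork", "build_network", "summarise", "top_hubs", "export_links"]

EDGE_COLUMNS = ["enhancer_id", "gene_id", "score", "pearson_r", "distance_bp"]


@dataclass
class EPNetwork:
    """Edge table plus optional node coordinates for link export."""

    edges: pd.DataFrame
    enhancer_coords: pd.DataFrame | None = None   # enhancer_id -> chrom/start/end
    gene_coords: pd.DataFrame | None = None       # gene_id -> chrom/tss (0-based)

    def __post_init__(self):
        missing = [c for c in EDGE_COLUMNS if c not in self.edges.columns]
        if missing:
            raise ValueError(f"edge table missing columns: {missing}")
        keys = self.edges[["enhancer_id", "gene_id"]]
        if keys.duplicated().any():
            raise ValueError("duplicate edge keys")

    @property
    def enhancers(self) -> set[str]:
        return set(self.edges["enhancer_id"])

    @property
    def genes(self) -> set[str]:
        return set(self.edges["gene_id"])

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from((f"E:{e}" for e in self.enhancers), bipartite="enhancer")
        g.add_nodes_from((f"G:{x}" for x in self.genes), bipartite="gene")
        for row in self.edges.itertuples():
            g.add_edge(f"E:{row.enhancer_id}", f"G:{row.gene_id}",
                       score=row.score, pearson_r=row.pearson_r,
                       distance_bp=row.distance_bp)
        return g

    def to_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False, lineterminator="\n")


def build_network(scored_pairs: pd.DataFrame, score_threshold: float = 0.5,
                  enhancer_coords: pd.DataFrame | None = None,
                  gene_coords: pd.DataFrame | None = None) -> EPNetwork:
    """Edges are the pairs with ``score >= score_threshold``.

    ``scored_pairs`` must carry the columns enhancer_id, gene_id, score,
    pearson_r and distance_bp.  An empty network is allowed.
    """
    keep = scored_pairs["score"] >= score_threshold
    edges = (scored_pairs.loc[keep, EDGE_COLUMNS]
             .sort_values(["enhancer_id", "gene_id"])
             .reset_index(drop=True))
    return EPNetwork(edges=edges, enhancer_coords=enhancer_coords,
                     gene_coords=gene_coords)


def summarise(network: EPNetwork) -> dict:
    """Counts, lower-median distance, mean correlation, degree distributions.

    An empty network reports zero counts and ``None`` for the median and
    mean.
    """
    e = network.edges
    if len(e) == 0:
        return {"n_edges": 0, "n_enhancers": 0, "n_genes": 0,
                "median_distance_bp": None, "mean_pearson_r": None,
                "gene_degrees": {}, "enhancer_degrees": {}}
    dists = sorted(int(d) for d in e["distance_bp"])
    median = dists[(len(dists) - 1) // 2]  # lower median for even n
    return {
        "n_edges": int(len(e)),
        "n_enhancers": int(e["enhancer_id"].nunique()),
        "n_genes": int(e["gene_id"].nunique()),
        "median_distance_bp": median,
        "mean_pearson_r": float(e["pearson_r"].mean()),
        "gene_degrees": e["gene_id"].value_counts().to_dict(),
        "enhancer_degrees": e["enhancer_id"].value_counts().to_dict(),
    }


def top_hubs(network: EPNetwork, k: int, side: str = "gene"):
    """Top-k nodes by degree (ties broken lexicographically by id)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    col = {"gene": "gene_id", "enhancer": "enhancer_id"}.get(side)
    if col is None:
        raise ValueError("side must be 'gene' or 'enhancer'")
    counts = network.edges[col].value_counts()
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(name, int(deg)) for name, deg in ranked[:k]]


def export_links(network: EPNetwork, path) -> None:
    """Circos-compatible links TSV: enhancer triple, gene triple, score.

    Gene promoters are written as 1 bp intervals at the TSS.  Every edge
    node must have coordinates.
    """
    if network.enhancer_coords is None or network.gene_coords is None:
        raise ValueError("network carries no node coordinates")
    lines = []
    for row in network.edges.itertuples():
        if row.enhancer_id not in network.enhancer_coords.index:
            raise KeyError(f"no coordinates for enhancer {row.enhancer_id}")
        if row.gene_id not in network.gene_coords.index:
            raise KeyError(f"no coordinates for gene {row.gene_id}")
        erow = network.enhancer_coords.loc[row.enhancer_id]
        grow = network.gene_coords.loc[row.gene_id]
        tss = int(grow["tss"])
        lines.append("\t".join(map(str, [
            erow["chrom"], int(erow["start"]), int(erow["end"]),
            grow["chrom"], tss, tss + 1,
            repr(float(row.score)),
        ])))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))
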