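"""End-to-end orchestration: cohort -> normalisation -> features -> model
-> evaluation -> network.

`run_pipeline` wires the stages together the way the package's intended
analysis runs: expression counts are TMM-normalised, filtered and logged;
the labelled pairs are featurised and split 80/20 with standardisation
fitted on the training rows; the adversarially regularised classifier is
trained with early stopping; held-out scores give the evaluation report
and permutation feature importance; optionally the full distance-filtered
candidate catalogue is scored and thresholded (Youden) into a bipartite
network.  A single seed drives every random choice, so a repeated run is
byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluate as ev
from .features import FeatureTable, assemble_features
from .model import (TrainConfig, TrainedModel, GeneratorSpec, predict,
                    save_checkpoint, train)
from .network import EPNetwork, build_network, export_links, summarise
from .omics import filter_and_log, tmm_normalise
from .pairs import build_candidates
from .simulate import SimConfig, SyntheticCohort, generate_cohort

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    synthetic: SyntheticCohort
    table: FeatureTable
    train_table: FeatureTable
    test_table: FeatureTable
    model: TrainedModel
    test_scores: np.ndarray
    report: ev.EvalReport
    network: EPNetwork | None
    network_summary: dict | None


def _scored_frame(table: FeatureTable, scores: np.ndarray) -> pd.DataFrame:
    idx = table.feature_names.index("pearson_r")
    return pd.DataFrame(
        {
            "enhancer_id": [p.enhancer_id for p in table.pairs],
            "gene_id": [p.gene_id for p in table.pairs],
            "score": scores,
            "pearson_r": table.X[:, idx],
            "distance_bp": [p.distance_bp for p in table.pairs],
        }
    )


def run_pipeline(sim_config: SimConfig | None = None,
                 train_config: TrainConfig | None = None,
                 gspec: GeneratorSpec | None = None,
                 seed: int = 0,
                 permute_labels: bool = False,
                 score_candidates: bool = False,
                 importance_repeats: int = 20,
                 outdir=None) -> PipelineResult:
    """Run the full analysis on a synthetic cohort.

    ``seed`` is threaded through cohort generation, the train/test split,
    training and permutation importance unless the corresponding config
    already pins its own seed.  ``permute_labels`` shuffles the truth
    labels before splitting (a null control: the classifier should find
    nothing).  ``score_candidates`` scores every candidate pair within
    1 Mb and assembles the thresholded network.
    """
    sim_config = sim_config if sim_config is not None else SimConfig(seed=seed)
    train_config = train_config if train_config is not None else TrainConfig(seed=seed)

    synthetic = generate_cohort(sim_config)
    cohort = synthetic.cohort

    factors = tmm_normalise(cohort.counts)
    normexpr = filter_and_log(cohort.counts, factors)

    table = assemble_features(synthetic.truth_pairs, cohort, normexpr)
    if permute_labels:
        rng = np.random.default_rng(seed + 7)
        table.labels = rng.permutation(table.labels)

    train_table, test_table = ev.split_train_test(table, ratio=0.8, seed=seed)
    model = train(train_table, gspec=gspec, config=train_config)

    test_scores = predict(model, test_table)
    importance = None
    if importance_repeats > 0:
        importance = ev.permutation_importance(model, test_table,
                                               n_repeats=importance_repeats, seed=seed)
    report = ev.evaluate_scores(test_scores, test_table.labels,
                                feature_importance=importance)

    network = network_summary = None
    if score_candidates:
        catalogue = build_candidates(cohort)
        full = assemble_features(catalogue, cohort, normexpr)
        full.mu, full.sigma = table.mu.copy(), table.sigma.copy()
        full_scores = predict(model, full)
        network = build_network(
            _scored_frame(full, full_scores),
            score_threshold=report.threshold,
            enhancer_coords=cohort.enhancers,
            gene_coords=cohort.gene_annot,
        )
        network_summary = summarise(network)

    result = PipelineResult(
        synthetic=synthetic, table=table, train_table=train_table,
        test_table=test_table, model=model, test_scores=test_scores,
        report=report, network=network, network_summary=network_summary,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(res: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    save_checkpoint(res.model, outdir / "model.ckpt")
    res.report.to_json(outdir / "report.json")
    res.table.to_tsv(outdir / "features.tsv")
    losses = pd.DataFrame({k: pd.Series(v) for k, v in res.model.history.items()})
    losses.to_csv(outdir / "losses.tsv", sep="\t", index_label="epoch",
                  lineterminator="\n", float_format="%.10g")
    if res.network is not None:
        res.network.to_tsv(outdir / "network_edges.tsv")
        export_links(res.network, outdir / "network_links.tsv")
        with open(outdir / "network_summary.json", "w") as fh:
            json.dump(res.network_summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
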