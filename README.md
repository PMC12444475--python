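# eplink

Prediction of functional enhancer–promoter (E–P) interactions from paired
DNA-methylation and gene-expression cohorts, with periodontal disease as
the motivating setting.

Chronic inflammatory diseases such as periodontitis are driven in part by
distal regulatory elements: enhancers that lose methylation in disease and
upregulate inflammatory genes over tens to hundreds of kilobases. Without
chromatin-conformation data (Hi-C, ChIA-PET), functional E–P coupling must
be inferred from covariation between enhancer methylation and target-gene
expression together with genomic proximity. `eplink` implements that
inference end to end for a three-group cohort design (healthy /
gingivitis / periodontitis, 12 samples each):

- **Normalisation.** Methylation betas β ∈ [0,1] are transformed to
  M-values, M = log2(β/(1−β)), for testing; RNA-seq counts are scaled by
  trimmed-mean-of-M-values (TMM) factors, genes with CPM < 1 in more than
  half the samples are removed, and expression is analysed as
  log2(CPM + 1).
- **Candidate pairs.** Every same-chromosome enhancer–gene combination
  whose midpoint-to-TSS distance is at most 1 Mb.
- **Features.** Eleven per-pair features: mean/SD/Δβ of enhancer
  methylation, mean/SD/log2FC of target expression, Pearson, Spearman and
  partial correlation (conditioning on ordinal disease severity), log10
  genomic distance, and the interaction term Δβ × log2FC.
- **Classifier.** A Transformer encoder generator (input 11 → hidden 64,
  two encoder layers with two attention heads, head 64 → 32 → 1, sigmoid)
  outputs P(interaction). A label-conditioned discriminator (12 → 64 → 32
  → 1, LeakyReLU 0.2, dropout 0.3) distinguishes (features, true label)
  from (features, generated score); the generator minimises
  BCE(G(x), y) + λ·BCE(D(x, G(x)), 1), which regularises its score
  distribution. Adam (lr 2·10⁻⁴, β₁ 0.5, β₂ 0.999), class-balanced
  batches of 32, 20 epochs with early stopping on validation BCE. The
  network is implemented in numpy on a small in-repo reverse-mode
  autodiff engine, so training is exactly reproducible from a seed.
- **Evaluation.** AUC-ROC (Mann–Whitney), AUC-PRC (average precision),
  Youden-threshold operating point, confusion metrics, and permutation
  feature importance on held-out pairs.
- **Statistics.** Welch tests per probe (M-values) and gene (log2 CPM)
  with Benjamini–Hochberg FDR, and a Fisher exact enrichment odds ratio
  of hypomethylated probes in enhancer regions.
- **Network.** Pairs scoring above the operating threshold form a
  bipartite enhancer → gene graph with degree/hub summaries, the median
  E–P distance, the mean methylation–expression correlation, and a
  Circos-style links export.

A seeded synthetic-cohort generator (`eplink.simulate`) plants
hypomethylated enhancers coupled to upregulated target genes so that every
stage is testable without external data.

## Worked example

```python
import eplink
res = eplink.run_pipeline(seed=1, score_candidates=True)
```

or, as narrative scripts, `python examples/train_and_evaluate.py` and
`python examples/build_network.py`, which print:

```
held-out AUC-ROC 1.000, AUC-PRC 1.000
Youden threshold 0.971: sensitivity 1.00, specificity 1.00, accuracy 1.00
top features by permutation importance:
  sd_beta       92.8%
  delta_beta     7.2%
network: 4266 E-P pairs, 100 enhancers, 251 genes
median enhancer-promoter distance: 481.3 kb
mean methylation-expression correlation over edges: -0.098
```

Read: on the default synthetic cohort the planted −0.30 beta shift with a
2.0 log2/β expression coupling is fully separable on held-out pairs
(AUC 1.0), the model leans on the methylation-dispersion and Δβ features,
and thresholding the full 1 Mb candidate catalogue at the Youden point
yields a bipartite network whose edges all involve the planted disease
enhancers. `examples/` contains one script per capability (simulation,
normalisation/features, training, differential statistics, network).

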