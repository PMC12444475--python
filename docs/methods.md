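# Methods

## Problem and model

`eplink` infers functional enhancer–promoter (E–P) interactions from
paired DNA-methylation and RNA-seq profiles of the same samples, in a
three-group inflammatory-disease design (healthy / gingivitis /
periodontitis). Because no chromatin-conformation data are assumed, an
interaction is operationalised as statistical coupling between enhancer
methylation and target-gene expression within a 1 Mb window, learned by a
binary classifier over engineered per-pair features.

The classifier is a Transformer-encoder generator regularised by an
adversarial discriminator. The generator projects the 11 standardised
features to a 64-dimensional vector, passes it through two encoder layers
(two attention heads, feed-forward width 128, dropout 0.1,
post-layer-norm) and a 64→32→1 head (ReLU, dropout 0.2, sigmoid), giving
P(interaction) ∈ (0,1). By default the projected vector enters the encoder
as a length-1 sequence, under which self-attention degenerates to a gated
feed-forward path; a feature-as-token variant (11 tokens, learned
per-feature embedding and bias, mean pooling) is available via
`GeneratorSpec(token_layout="per_feature")`. No positional encoding is
used (the default sequence has length 1; the token variant's per-feature
bias plays that role).

The discriminator is an MLP over the 11 features concatenated with a
scalar: the true label ("real") or the generator's score ("generated");
layers 12→64→32→1 with LeakyReLU slope 0.2 and dropout 0.3. Training
alternates per batch: one Adam step on
BCE(D(x,y),1) + BCE(D(x,G(x)),0) with G frozen (G evaluated without
dropout so the discriminator step consumes no generator randomness), then
one step on BCE(G(x),y) + λ·BCE(D(x,G(x)),1) with D frozen and evaluated
without dropout. The two loss terms are combined in a single generator
step rather than alternated. λ defaults to 1; λ = 0 (or
`adversarial=False`) reduces training to a plain supervised classifier,
bitwise identical between the two settings because batching, generator
initialisation and generator dropout draw from separate seeded streams.

Training uses Adam (lr 2·10⁻⁴, β₁ 0.5, β₂ 0.999), batch size 32, at most
20 epochs. Batches are class-balanced: ⌈b/2⌉ positives and ⌊b/2⌋
negatives, majority class consumed once per epoch without replacement,
minority recycled through reshuffled repetitions, and a proportional
partial batch drains the remainder. Early stopping monitors validation
BCE (a stratified 12.5 % cut of the training split, so the overall layout
is ≈ 70/10/20 train/validation/test) with patience 5 and minimum
improvement 10⁻⁴; the best-epoch generator parameters are restored.
Parameters are initialised fan-in-scaled uniform (±1/√fan_in). The model
is small enough that the whole network runs on a compact in-repo
reverse-mode autodiff engine over numpy arrays (`eplink.autodiff`),
checked against central finite differences in the test suite; this keeps
training single-threaded, fast at this scale, and exactly seeded.

## Normalisation and statistics

* **Methylation.** Betas are clipped to [ε, 1−ε] (ε = 10⁻⁶) before the
  M-value transform M = log2(β/(1−β)). Differential methylation tests run
  on M-values; effects are reported as Δβ on the beta scale.
* **Expression.** TMM factors follow the canonical published algorithm:
  reference = sample whose upper-quartile count rate is closest to the
  mean upper quartile; per sample, gene-wise log2 ratios against the
  reference are trimmed 30 % on the ratio and 5 % on average log
  intensity and combined by inverse-variance weighting; factors are
  renormalised to geometric mean 1 (verified against edgeR on a frozen
  toy matrix). CPM uses effective library sizes (total × factor); genes
  with CPM < 1 in **strictly more than** half the samples are removed
  (the boundary case, CPM ≥ 1 in exactly half, is kept); retained values
  are log2(CPM+1). Whether the CPM filter should precede or follow TMM is
  ambiguous in common practice; here factors are computed first and the
  filter uses effective library sizes.
* **Group tests.** Welch's unequal-variance t with Satterthwaite df,
  periodontitis vs healthy (gingivitis excluded from the contrast). This
  is a deliberate, documented replacement for moderated (empirical-Bayes)
  tests: shrinkage machinery belongs to the upstream packages, and at 12
  vs 12 samples Welch is well calibrated; the interface leaves room for a
  moderated variant. Multiple testing uses Benjamini–Hochberg
  (q(i) = min over j ≥ i of m·p(j)/j, capped at 1) at FDR 0.05.
* **Enrichment.** The 2×2 odds ratio uses a Haldane 0.5 correction when
  any cell is zero; the two-sided Fisher p-value enumerates the
  hypergeometric support in exact integer arithmetic (so tests can match
  an exact-rational oracle bit for bit).

## Features and pair catalogue

Distance is anchored at the enhancer midpoint, floor((start+end)/2), to
the TSS, zero when the TSS falls inside the interval; a nearest-edge
anchor is available. Coordinates are 0-based half-open internally; BED is
native, gene TSS converted from 1-based on read. The candidate catalogue
is every same-chromosome pair with distance ≤ 1 Mb inclusive.

Probe-to-enhancer aggregation is the per-sample mean over the enhancer's
probes. Δβ and log2FC contrast periodontitis vs healthy. The partial
correlation conditions on ordinal disease severity (healthy 0,
gingivitis 1, periodontitis 2) via
r_xy·z = (r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²)); the conditioning
variable is configurable in principle since the analysis it mirrors does
not name one. Distance enters as log10(d+1). Correlations of constant
vectors are defined as 0 (not NaN) so the classifier always receives
finite input. Standardisation (z-scores) is fitted on training rows only
and applied to all rows.

The operating threshold for both the confusion metrics and network
construction maximises Youden's J = sensitivity + specificity − 1 over
observed scores (ties: higher specificity, then lower threshold);
prediction uses score ≥ threshold. AUC-PRC uses the average-precision
step rule rather than trapezoidal interpolation, which avoids optimistic
interpolation between operating points. Feature importance is permutation
importance on held-out data (mean AUC drop over 20 seeded shuffles per
feature, negatives clipped to zero, normalised to percentages); the
underlying analysis reports only percentages, so the attribution method
is this package's choice. Network summaries use the lower median for even
edge counts.

## Synthetic cohorts

The generator emulates the motivating study design: 12 samples per group,
paired 850K-style betas and RNA-seq counts, one synthetic chromosome
(10 Mb) carrying 200 non-overlapping enhancers (3 probes each, plus 200
intergenic background probes) and 300 genes. Half the enhancers are
"disease" enhancers: their probes' betas shift down by `delta_beta`
(default 0.30) in periodontitis and half that in gingivitis — the ordered
intermediate mirrors the graded separation between the three groups — with
Gaussian noise (sd 0.5) added on the logit scale and mapped back through
the inverse logit, guaranteeing β ∈ (0,1). Each of the 200 true pairs
couples a disease enhancer (round-robin, so enhancers host about two
target genes, giving mild hub structure) to a distinct gene within 1 Mb,
whose negative-binomial log2 mean rises by `coupling_log2fc` (default
2.0) per unit of beta lost in that group. The 200 null pairs draw
enhancers and genes that carry no effect, so their betas and counts are
independent. Counts are negative binomial (dispersion 0.1) with
log-normal library sizes around 10⁶ reads (σ = 0.2); baseline abundances
span log2 CPM 1–9, with planted targets kept ≥ 3 so the CPM filter cannot
remove them. Placement failures (more requested pairs than enhancer–gene
combinations within 1 Mb) raise rather than silently truncating.

What the generator does **not** emulate: array control probes and
detection noise, SNP/cross-reactive artefacts, batch effects, cell-type
composition, genome-scale probe density, or any microbial covariate.
Passing tests therefore demonstrate the pipeline's internal correctness
and its ability to recover planted covariation — not performance on real
tissue data, where effect sizes are smaller and confounding is real.

## Numerical and design notes

* Realised beta shifts differ slightly from `delta_beta` (≈ −0.284 for a
  configured −0.30) because the mean of an inverse-logit of Gaussian noise
  is not the inverse-logit of the mean; tests allow ±0.05.
* With the default cohort, 200 of 300 genes are upregulated; TMM's
  assumption that most genes are not differentially expressed is then
  violated, and the trimmed mean absorbs much of the composition shift.
  Relative separation between true and null pairs (what the classifier
  uses) is preserved, but absolute fold changes shrink. Power checks for
  the differential-expression test therefore use cohorts where planted
  genes are a minority (30 of 300).
* A planted log2FC of 0.6 (coupling 2.0 × Δβ 0.30) sits near the
  detection limit of a 12-vs-12 Welch test at NB dispersion 0.1
  (noncentrality ≈ 2.5), so FDR-corrected gene-level recovery is low by
  construction at that effect size; recovery exceeds 80 % at the fold
  changes the motivating analyses report for inflammatory genes
  (log2FC ≈ 2–3). Probe-level methylation recovery does not share this
  limit (M-value shifts are ≈ 1.8 at Δβ = 0.30) and exceeds 80 % at
  default settings.
* Everything is deterministic given the seed: batching/splits, generator
  and discriminator initialisation and dropout each use an independent
  stream spawned from it, and checkpoints/reports/exports are written in
  canonical forms, so identical runs are byte-identical.
* Problem sizes used in tests and the acceptance script are the default
  study-scale cohort (36 samples, 800 probes, 300 genes, 400 labelled
  pairs, ≈ 4 000–12 000 candidate pairs); the reduced cohorts some unit
  tests use (30–60 enhancers) exercise identical code paths.

## Known limitations

* Partial correlation conditions on a single ordinal covariate; richer
  confounder sets (age, smoking, cell composition) are out of scope.
* Welch replaces moderated/voom tests; at very small n or strong
  mean–variance trends a moderated variant would be preferable.
* The network threshold inherits the Youden point from a labelled test
  set; with no labels a fixed 0.5 is used, and neither choice calibrates
  edge counts against an external truth.
* The adversarial term regularises score distributions; it is not a
  data-synthesis GAN and no claim is made about generating realistic
  pairs.
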