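"""Generate a synthetic periodontitis cohort and inspect the planted signal.

Creates a 12/12/12 healthy/gingivitis/periodontitis cohort with paired
methylation betas and RNA-seq counts, writes it as plain-text fixtures,
and verifies that the planted enhancer hypomethylation matches the
configured effect size.
"""

import numpy as np

import eplink
from eplink.features import enhancer_methylation_profile

cfg = eplink.SimConfig(seed=1)
sc = eplink.generate_cohort(cfg)
co = sc.cohort

print(f"cohort: {co.beta.shape[0]} probes, {co.counts.shape[0]} genes, "
      f"{len(co.samples)} samples")
print(f"truth pairs: {sum(p.label == 1 for p in sc.truth_pairs)} true, "
      f"{sum(p.label == 0 for p in sc.truth_pairs)} null")

perio, healthy = co.group_mask("periodontitis"), co.group_mask("healthy")
diffs = [enhancer_methylation_profile(e, co)[perio].mean()
         - enhancer_methylation_profile(e, co)[healthy].mean()
         for e in sorted({p.enhancer_id for p in sc.truth_pairs if p.label == 1})]
print(f"mean disease-vs-healthy beta shift at planted enhancers: "
      f"{np.mean(diffs):+.3f} (configured {-cfg.delta_beta:+.2f})")
# the realised shift sits close to the configured hypomethylation effect;
# the small gap is the inverse-logit of the Gaussian noise being nonlinear

manifest = eplink.write_fixture_set(sc, "scratch/example_cohort")
print(f"wrote {len(manifest['checksums'])} fixture files to scratch/example_cohort/")
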