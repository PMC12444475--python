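"""Train the adversarially regularised Transformer classifier and score it.

Runs the full supervised path: stratified 80/20 split, class-balanced
minibatches, generator/discriminator alternation with early stopping,
then held-out ranking metrics, the Youden operating point, and
permutation feature importance.
"""

import eplink

res = eplink.run_pipeline(seed=1)
r = res.report

print(f"epochs run: {len(res.model.history['val_loss'])} "
      f"(best epoch {res.model.best_epoch + 1})")
print(f"held-out AUC-ROC {r.auc_roc:.3f}, AUC-PRC {r.auc_prc:.3f}")
print(f"Youden threshold {r.threshold:.3f}: sensitivity {r.sensitivity:.2f}, "
      f"specificity {r.specificity:.2f}, accuracy {r.accuracy:.2f}")
top = sorted(r.feature_importance.items(), key=lambda kv: -kv[1])[:3]
print("top features by permutation importance:")
for name, pct in top:
    print(f"  {name:12s} {pct:5.1f}%")
# AUC near 1 means the planted methylation-expression coupling is easy to
# separate at this effect size; the importance ranking shows which of the
# 11 features the model actually relies on
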