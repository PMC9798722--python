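"""Diagnostic-accuracy meta-analysis on simulated cohorts.

Simulates nine cohorts with a strongly up-regulated target gene, derives a
ROC curve and Youden-optimal cutoff per cohort, pools sensitivity and
specificity across the resulting 2x2 tables, fits a summary ROC curve, and
converts a 20% pre-test probability through the pooled likelihood ratios
(Fagan nomogram).
"""

from cohortmeta import (
    fagan,
    pool_accuracy,
    roc_curve,
    simulate_cohorts,
    sroc,
    to_two_by_two,
    youden_cutoff,
)
from cohortmeta.simulate import SimulationSpec

cohorts, _ = simulate_cohorts(SimulationSpec(seed=42, n_genes=200, n_up=20,
                                             n_down=20, coexpr_block=20))

tables = []
for cohort in cohorts:
    values = cohort.values_for("TARGET").to_numpy()
    labels = cohort.group.to_numpy()
    roc = roc_curve(values, labels)
    cutoff, sens, spec = youden_cutoff(roc)
    tables.append(to_two_by_two(values, labels, cutoff, label=cohort.cohort_id))
    print(f"{cohort.cohort_id}: AUC {roc.auc:.3f}, cutoff {cutoff:.2f} "
          f"(sens {sens:.2f}, spec {spec:.2f})")

pooled = pool_accuracy(tables)
curve = sroc(tables)
print(f"\npooled sensitivity {pooled.pooled_sens:.3f} "
      f"({pooled.sens_ci[0]:.3f}-{pooled.sens_ci[1]:.3f})")
print(f"pooled specificity {pooled.pooled_spec:.3f} "
      f"({pooled.spec_ci[0]:.3f}-{pooled.spec_ci[1]:.3f})")
print(f"LR+ {pooled.lr_pos:.2f}, LR- {pooled.lr_neg:.3f}, DOR {pooled.dor:.1f}")
print(f"summary ROC AUC {curve.auc:.3f}  (>0.9: strong discrimination)")

post_pos, post_neg = fagan(0.20, pooled.pooled_sens, pooled.pooled_spec)
print(f"\nFagan at 20% pre-test: positive result -> {post_pos:.1%}, "
      f"negative result -> {post_neg:.1%}")
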