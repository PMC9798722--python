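# Methods

This note records the statistical models `cohortmeta` implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical corner cases.

## Conventions

Group 1 is always the tumor/case group; every signed statistic (t, SMD,
log2FC) is tumor minus control. Gene identifiers are uppercased symbols;
duplicate matrix rows are collapsed by arithmetic mean (the
least-surprising aggregate, and idempotent). Expression is analysed on the
log2 scale; `log2_transform` applies `log2(x + 1)` (the +1 guards zeros)
and a scale flag makes the transform idempotent.

## Preprocessing

FPKM→TPM is the per-sample renormalization `tpm = fpkm / Σ fpkm × 10⁶`.
Same-platform cohorts are merged by column concatenation on the common gene
set, keeping each sample's source cohort as a batch label. Batch handling
is deliberately simple: per gene and batch, subtract the batch mean and add
the grand mean. This is a location-only adjustment — no scale matching, no
empirical-Bayes shrinkage, no surrogate variables — chosen because it is
exactly invertible in expectation, preserves each gene's grand mean to
machine precision, and cannot leak group structure. Batches of one sample
are left untouched (centering would delete them). The fixed order is
TPM → log2 → merge → center.

## Effect-size meta-analysis

Cohen's d uses the pooled SD
`s_p² = ((n₁−1)s₁² + (n₀−1)s₀²)/(n₁+n₀−2)`; Hedges' g multiplies by
`J = 1 − 3/(4(n₁+n₀−2) − 1)`. The sampling variance is the usual
large-sample form `(n₁+n₀)/(n₁n₀) + d²/(2(n₁+n₀))`. Cohen's d is the
default flavor; both are exposed. Heterogeneity is Cochran's Q with
`I² = max(0, (Q−df)/Q)`. Random-effects pooling uses the
DerSimonian–Laird moment estimator `τ² = max(0, (Q−df)/C)`,
`C = Σw − Σw²/Σw` — the classic choice in the Stata `metan` lineage, not
REML, so results are deterministic and closed-form. Model selection
("auto") is the printed rule: random iff I² > 50% or the Q-test p < 0.05.
Pooled CIs use normal quantiles. A singleton subgroup is reported as the
study's own effect and CI rather than "pooled", matching forest-plot
practice. Fixed and DL pooling are cross-checked in the tests against
`statsmodels.stats.meta_analysis.combine_effects` (which, unlike this
implementation, leaves a negative DL τ² unclipped).

Begg–Mazumdar: deviates `(eᵢ − ē_fixed)/√(vᵢ − 1/Σw)` are Kendall-rank
correlated with the variances; ties count toward neither P nor Q; the z
statistic applies the `|P−Q| − 1` continuity correction. The correction,
plus the weak negative coupling of deviates through the estimated pooled
mean, makes the test mildly conservative under the null — visible as a
small surplus of large p-values in the calibration test, and consistent
with this test's reputation for low power at small k.

Correlations pool on the Fisher-z scale (`z = atanh r`, `se = 1/√(n−3)`)
and transform back with tanh; `se`, Q, I² and τ² in the returned result
remain on the z scale, the scale on which they were computed.

## Diagnostic-accuracy meta-analysis

The ROC positive class is tumor, larger marker values more positive; the
trapezoidal AUC equals the tie-aware Mann–Whitney statistic (asserted to
1e-9 in the tests). The cutoff criterion is Youden's J (the source
workflow only says a cutoff was determined; J is the standard default),
with ties broken toward the lower cutoff, i.e. higher sensitivity, and
positivity at value ≥ cutoff.

Sensitivity and specificity are pooled on the logit scale with the same
inverse-variance machinery as the effect sizes (per-study variance
`1/a + 1/b` from the relevant 2×2 cells), after a 0.5 continuity
correction added to all four cells of any study containing a zero cell —
standard diagnostic-test-accuracy practice. The summary ROC is
Moses–Littenberg: regress `D = ln DOR` on `S = logit(sens) + logit(FPR)`,
back-transform over FPR ∈ (0,1), trapezoid AUC on 1001 grid points.
This is deterministic and adequate at the ~10-study scale; it is not the
bivariate Reitsma/HSROC mixed model, and known Moses–Littenberg caveats
(no within-study weighting, cutoff-variation conflation) apply. Identical
studies give a zero slope and a symmetric curve. Fagan post-test
probabilities convert pre-test odds through LR+ = sens/(1−spec) and
LR− = (1−sens)/spec.

## Screening

Differential expression uses a per-gene Welch t test with within-cohort
Benjamini–Hochberg adjustment. This stands in for a moderated-t workflow:
at the simulated n ≥ 10 per group the difference is modest, and at the
tiny end (3v3 cohorts) both are underpowered — the cross-cohort vote is
what carries the inference. Thresholds are applied with the strict
inequalities as printed: |log2FC| > 1, adjusted p < 0.05, |r| ≥ 0.3,
p < 0.05. Co-expression runs across all samples of a cohort (tumor and
control together). Vote counting requires the same direction in at least
`min_repetition` (default 5) cohorts; repetition counts cohorts, not
probes, and conflicting directions tally separately. SMD confirmation
pools each candidate's per-cohort summaries (auto model) and confirms up
when the 95% CI lies above 0, down when below. Set A is confirmed-up ∩
positive-r, set B confirmed-down ∩ negative-r, target excluded.

## Downstream

The immunoreactivity score of a field is intensity (0–3) × proportion
category (0–4); a specimen aggregates its ~10 fields by mean (median via a
flag). The printed proportion bins leave 10–11% unassigned; implemented as
half-open bins (0, 10%] → 1, (10%, 50%] → 2, (50%, 80%] → 3, (80%, 1] → 4.

Survival splits at the median (ties to the high group), fits Kaplan–Meier
curves per group (via lifelines), computes the log-rank chi-square with
the hypergeometric variance, and reports the Mantel–Haenszel hazard ratio
`(O₁/E₁)/(O₂/E₂)` with the high group in the numerator — the closed-form
estimator of the GraphPad-style workflow, needing no iterative fitting.
Caveat: this O/E ratio attenuates hazard ratios far from 1; at a true HR
of 4 with near-complete follow-up its probability limit is ≈ 3. The test
suite therefore validates the generator with a Cox oracle (lifelines) and
the estimator against its own large-sample limit. A Cox model is
deliberately out of scope.

Hub ranking is plain degree on the loaded network (ties at the k-boundary
all included, then lexicographic). Enrichment is the hypergeometric upper
tail of the query/term overlap within a user-supplied universe, BH-adjusted
across terms — a generic ORA over user GMT files; no ontology databases are
bundled.

## Synthetic-data generator

Per gene g, sample s, cohort c:

```
x = baseline_g + batch_c + Δ_g·1[tumor] + λ_g·f_s + ε,   f ~ N(0,1), ε ~ N(0, σ²)
```

Defaults define the emulated study: nine cohorts at tumor/control sizes
(159,4), (58,17), (7,4), (3,3), (25,3), (3,3), (25,8), (18,18), (10,6);
1000 genes; target SMD 3.0 (the mean shift is `target_smd·√(λ_t²+σ²)` so
the planted SMD is on the within-group-SD scale); 50 up and 50 down DEGs at
±2 log2 units; a 50-gene latent block at loading 0.7; per-cohort batch
shift N(0,1); noise SD 1.0. The implied block-target correlation has the
closed form `λ_bλ_t/√((λ_b²+σ²)(λ_t²+σ²+p(1−p)Δ_t²))` (exposed as
`expected_coexpr_r`), used as the oracle in calibration tests. A stage
effect on the target (extra shift in stage III/IV tumors) exists but
defaults to 0 so that `target_smd = 0` really is a null target; tests
plant it explicitly. IHC fields draw intensity and proportion categories
independently from group multinomials calibrated to expected specimen IRS
≈ 6.8 (tumor, n=110) and ≈ 2.2 (control, n=47). Survival times are
exponential with the hazard multiplied by `hazard_ratio` (default 4)
above the median target expression, censored by an independent exponential
(default rate 0.005/month against a baseline hazard of 0.02/month).

What the generator does **not** emulate: count-level noise and
mean-variance coupling (values are normal on the log2 scale, matching the
t/SMD assumptions downstream), platform-specific probe effects, real
per-study IHC heterogeneity (fields are i.i.d. within specimen, so
between-specimen IRS spread is narrower than real tissue), correlated
censoring, or any real GEO marginal distribution. Green tests therefore
certify the statistical machinery under its own assumptions, not
performance on raw public data.

## Problem sizes and determinism

All randomness flows from one root seed (`numpy.random.default_rng`);
derived streams use `SeedSequence` keys, and the pipeline's outputs are
byte-identical across re-runs with the same config. Replicate-heavy checks
run the nine-cohort design with a reduced gene count (the target-gene
statistics do not depend on how many null genes surround it): SMD recovery
and null coverage use 200 replicates × 9 cohorts × 8 genes; FDR calibration
uses 100 cohorts × 1001 genes at n=20/20; null calibration uses 500
simulations each for the log-rank (n=60) and Begg (k=40) tests; the null
summary-ROC band uses ten replicate sets of nine 25v25 cohorts with each
study's cutoff held fixed while labels are permuted (re-optimizing the
cutoff on permuted labels would re-introduce the selection bias the
permutation is meant to remove — measured, that bias alone lifts the null
AUC to ~0.66).

## Known limitations

- Moses–Littenberg sROC and the O/E hazard ratio are first-generation
  methods kept for determinism; both are biased in known directions
  relative to their mixed-model successors (documented above).
- The batch stand-in cannot remove batch-by-gene scale effects.
- Vote counting treats cohorts as exchangeable votes regardless of size;
  a 3v3 cohort counts as much as 159v4.
- The IHC generator's i.i.d. fields understate specimen-level variance;
  group means are calibrated, SDs are not.
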