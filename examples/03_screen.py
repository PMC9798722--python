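"""DEG / co-expression screening with cross-cohort vote counting.

Simulates nine cohorts with planted up/down-regulated blocks and a latent
co-expression block, screens each cohort for differential expression
(|log2FC| > 1, BH-adjusted p < 0.05) and for correlation with the target
(|r| >= 0.3, p < 0.05), keeps genes passing in >= 5 cohorts with a
consistent direction, confirms DEG candidates by pooled-SMD confidence
intervals, and intersects the confirmed lists into gene sets A and B.
"""

from cohortmeta import (
    ceg_screen,
    de_screen,
    intersect_sets,
    simulate_cohorts,
    smd_confirm,
    summarize_group,
    vote_count,
)
from cohortmeta.screen import accepted_genes
from cohortmeta.simulate import SimulationSpec

cohorts, truth = simulate_cohorts(SimulationSpec(seed=1, n_genes=300, n_up=30,
                                                 n_down=30, coexpr_block=30))

de_frames = [de_screen(c) for c in cohorts]
ceg_frames = [ceg_screen(c, "TARGET") for c in cohorts]
de_votes = vote_count(de_frames, min_repetition=5)
ceg_votes = vote_count(ceg_frames, min_repetition=5)

up = accepted_genes(de_votes, "up")
down = accepted_genes(de_votes, "down")
pos = accepted_genes(ceg_votes, "pos")
neg = accepted_genes(ceg_votes, "neg")
print(f"vote-counted DEGs: {len(up)} up, {len(down)} down "
      f"(planted: {(truth['role'] == 'up').sum()} up, {(truth['role'] == 'down').sum()} down)")
print(f"vote-counted CEGs: {len(pos)} positive-r, {len(neg)} negative-r")

summaries = {
    gene: [summarize_group(c, gene) for c in cohorts] for gene in sorted(up | down)
}
confirmed = smd_confirm(summaries)
confirmed_up = set(confirmed.index[confirmed["status"] == "up"])
confirmed_down = set(confirmed.index[confirmed["status"] == "down"])
print(f"SMD-confirmed: {len(confirmed_up)} up, {len(confirmed_down)} down "
      "(pooled 95% CI entirely above/below 0)")

set_a, set_b = intersect_sets(confirmed_up, confirmed_down, pos, neg, target="TARGET")
print(f"gene set A (up and +r): {len(set_a)} genes")
print(f"gene set B (down and -r): {len(set_b)} genes")
# planted DEGs carry no latent loading, so A/B stay small by design: only
# genes whose group shift also induces a mixed-sample correlation intersect
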