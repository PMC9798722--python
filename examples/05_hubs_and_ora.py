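"""Hub-gene ranking and over-representation analysis.

Builds a small interaction network (a dense cell-cycle-like module plus
scattered edges), ranks genes by degree (the cytoHubba 'degree' criterion),
and tests a query gene list for enrichment against two gene sets with the
hypergeometric upper tail.
"""

from cohortmeta import hub_rank, ora
from cohortmeta.types import EdgeList, GeneSetCollection

cycle = ["CDK1", "CCNB1", "CDC6", "MCM2", "CHEK1"]
edges = EdgeList(
    edges=[(a, b, 0.9) for i, a in enumerate(cycle) for b in cycle[i + 1:]]
    + [("CDK1", "AURKA", 0.7), ("GAPDH", "ACTB", 0.5)]
)
print("top hub genes by degree:")
print(hub_rank(edges, k=3).to_string(index=False))
# CDK1 leads: it touches every module member plus AURKA

universe = cycle + ["AURKA", "GAPDH", "ACTB", "TP53", "EGFR", "MYC", "VIM"]
sets = GeneSetCollection(sets={
    "CELL_CYCLE": ("cell cycle", frozenset(cycle + ["AURKA"])),
    "HOUSEKEEPING": ("housekeeping", frozenset(["GAPDH", "ACTB"])),
})
query = ["CDK1", "CCNB1", "CDC6", "MCM2"]
result = ora(query, universe, sets)
print("\nenrichment of the query list:")
print(result.to_string(index=False))
# CELL_CYCLE: all 4 query genes fall in a 6-gene set -> tiny p;
# HOUSEKEEPING overlaps nothing -> p = 1
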