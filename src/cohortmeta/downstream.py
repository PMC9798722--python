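"""Downstream analyses: IHC scoring, clinical subgroups, survival, hubs, ORA.

The immunoreactivity score (IRS) of a stained field is the product of its
staining intensity (0-3) and stained-cell proportion category (0-4), giving
0-12; a specimen's score aggregates its fields (mean by default). Survival
uses a median split of marker expression with Kaplan-Meier curves, the
log-rank test, and a Mantel-Haenszel (O/E) hazard ratio. Hub genes are
ranked by degree on a provided interaction network, and over-representation
analysis is a hypergeometric upper-tail test against user gene sets.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from . import meta_diagnostic, meta_effect
from .screen import bh_adjust
from .types import EdgeList, GeneSetCollection, GroupSummary, IHCRecord, StudyEffect


def irs(intensity: int, proportion_category: int) -> int:
    """Immunoreactivity score of one field: intensity x proportion, 0-12."""
    if intensity not in (0, 1, 2, 3):
        raise ValueError(f"intensity {intensity} outside 0-3")
    if proportion_category not in (0, 1, 2, 3, 4):
        raise ValueError(f"proportion category {proportion_category} outside 0-4")
    return intensity * proportion_category


def proportion_category(fraction_stained: float) -> int:
    """Map a stained-cell fraction to its 0-4 category.

    0 when no cells stain; 1 for (0, 10%]; 2 for (10%, 50%]; 3 for
    (50%, 80%]; 4 above 80%. The printed bins leave 10-11% unassigned;
    the implemented bins are half-open at the printed upper bounds.
    """
    if not 0.0 <= fraction_stained <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if fraction_stained == 0.0:
        return 0
    if fraction_stained <= 0.10:
        return 1
    if fraction_stained <= 0.50:
        return 2
    if fraction_stained <= 0.80:
        return 3
    return 4


def specimen_irs(record: IHCRecord, aggregate: str = "mean") -> float:
    """Aggregate a specimen's per-field IRS values (mean by default)."""
    if len(record.fields) == 0:
        raise ValueError(f"specimen {record.specimen_id!r} has no fields")
    scores = [irs(i, p) for i, p in record.fields]
    if aggregate == "mean":
        return float(np.mean(scores))
    if aggregate == "median":
        return float(np.median(scores))
    raise ValueError("aggregate must be 'mean' or 'median'")


def ihc_group_summary(records: Sequence[IHCRecord], aggregate: str = "mean") -> GroupSummary:
    """GroupSummary of specimen IRS scores (tumor vs control)."""
    tumor = [specimen_irs(r, aggregate) for r in records if r.group == "tumor"]
    control = [specimen_irs(r, aggregate) for r in records if r.group == "control"]
    if not tumor or not control:
        raise ValueError("need specimens in both groups")
    return GroupSummary(
        n1=len(tumor),
        mean1=float(np.mean(tumor)),
        sd1=float(np.std(tumor, ddof=1)) if len(tumor) > 1 else 0.0,
        n0=len(control),
        mean0=float(np.mean(control)),
        sd0=float(np.std(control, ddof=1)) if len(control) > 1 else 0.0,
    )


class ClinicalEffect(NamedTuple):
    summary: GroupSummary
    t: float
    df: float
    p: float
    effect: StudyEffect


def clinical_subgroup_effect(
    values: Sequence[float],
    in_stratum_1: Sequence[bool],
    variant: str = "welch",
    correction: str = "cohen",
) -> ClinicalEffect:
    """Compare a marker between two clinical strata (t test + SMD).

    ``in_stratum_1`` flags the stratum treated as group 1; signs follow
    stratum 1 minus stratum 2.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(in_stratum_1, dtype=bool)
    a, b = values[mask], values[~mask]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both strata need >= 2 samples")
    summary = GroupSummary(
        n1=len(a),
        mean1=float(np.mean(a)),
        sd1=float(np.std(a, ddof=1)),
        n0=len(b),
        mean0=float(np.mean(b)),
        sd0=float(np.std(b, ddof=1)),
    )
    t_res = meta_diagnostic.two_sample_t(summary, variant=variant)
    effect = meta_effect.smd(summary, correction=correction)
    return ClinicalEffect(summary=summary, t=t_res.t, df=t_res.df, p=t_res.p, effect=effect)


class SurvivalResult(NamedTuple):
    chi2: float
    p: float
    hr: float
    o_high: float
    e_high: float
    o_low: float
    e_low: float
    km_high: pd.DataFrame
    km_low: pd.DataFrame
    n_high: int
    n_low: int


def _logrank_table(
    time: np.ndarray, event: np.ndarray, high: np.ndarray
) -> tuple[float, float, float, float, float]:
    """Observed/expected log-rank tally. Returns (O1, E1, O2, E2, V)."""
    order = np.argsort(time, kind="stable")
    time, event, high = time[order], event[order], high[order]
    o1 = float(event[high].sum())
    o2 = float(event[~high].sum())
    e1 = 0.0
    var = 0.0
    event_times = np.unique(time[event == 1])
    for t in event_times:
        at_risk = time >= t
        n = float(at_risk.sum())
        n1 = float((at_risk & high).sum())
        d = float(((time == t) & (event == 1)).sum())
        e1 += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1.0 - n1 / n) * (n - d) / (n - 1.0)
    e2 = (o1 + o2) - e1
    return o1, e1, o2, e2, var


def survival_median_split(
    values: Sequence[float],
    time: Sequence[float],
    event: Sequence[int],
    compute_km: bool = True,
) -> SurvivalResult:
    """Median-split survival analysis of a marker.

    Samples at or above the median form the high group. Kaplan-Meier
    curves are fitted per group; the log-rank chi-square uses the standard
    hypergeometric variance, and the hazard ratio is the Mantel-Haenszel
    ratio of observed/expected events, (O1/E1)/(O2/E2), with the high group
    in the numerator.
    """
    values = np.asarray(values, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if not (len(values) == len(time) == len(event)):
        raise ValueError("values, time and event must align")
    if event.sum() < 2:
        raise ValueError("need at least 2 observed events")
    high = values >= np.median(values)
    if high.all() or not high.any():
        raise ValueError("median split produced an empty group")

    o1, e1, o2, e2, var = _logrank_table(time, event, high)
    chi2 = (o1 - e1) ** 2 / var if var > 0 else 0.0
    p = float(stats.chi2.sf(chi2, 1))
    hr = (o1 / e1) / (o2 / e2) if (e1 > 0 and e2 > 0 and o2 > 0) else float("inf")

    km_high = km_low = pd.DataFrame()
    if compute_km:
        kmf = KaplanMeierFitter()
        kmf.fit(time[high], event[high], label="high")
        km_high = kmf.survival_function_.reset_index()
        kmf.fit(time[~high], event[~high], label="low")
        km_low = kmf.survival_function_.reset_index()
    return SurvivalResult(
        chi2=float(chi2),
        p=p,
        hr=float(hr),
        o_high=o1,
        e_high=e1,
        o_low=o2,
        e_low=e2,
        km_high=km_high,
        km_low=km_low,
        n_high=int(high.sum()),
        n_low=int((~high).sum()),
    )


def hub_rank(edges: EdgeList, k: int) -> pd.DataFrame:
    """Top-k genes by network degree (the cytoHubba 'degree' criterion).

    Ties at the rank-k boundary are all included; within equal degree,
    genes sort lexicographically.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if len(edges) == 0:
        raise ValueError("empty edge list")
    graph = nx.Graph()
    graph.add_edges_from((a, b) for a, b, _ in edges.edges)
    ranked = sorted(graph.degree, key=lambda item: (-item[1], item[0]))
    if len(ranked) > k:
        boundary = ranked[k - 1][1]
        ranked = [item for item in ranked if item[1] >= boundary]
    return pd.DataFrame(ranked, columns=["gene", "degree"])


def ora(
    query: Sequence[str],
    universe: Sequence[str],
    gene_sets: GeneSetCollection,
) -> pd.DataFrame:
    """Hypergeometric over-representation analysis against a GMT collection.

    For each term, the upper-tail probability of drawing at least the
    observed overlap when sampling |query| genes from the universe; BH
    adjustment across terms; ascending p. Terms are intersected with the
    universe first. The query must be a subset of the universe.
    """
    query_set = {g.upper() for g in query}
    universe_set = {g.upper() for g in universe}
    if not query_set:
        raise ValueError("empty query gene list")
    outside = query_set - universe_set
    if outside:
        raise ValueError(f"query gene(s) outside the universe, e.g. {sorted(outside)[0]!r}")
    M, N = len(universe_set), len(query_set)
    rows = []
    for term, (name, members) in gene_sets.items():
        members_in = members & universe_set
        if not members_in:
            continue
        K = len(members_in)
        overlap = len(query_set & members_in)
        p = float(stats.hypergeom.sf(overlap - 1, M, K, N))
        rows.append(
            {"term": term, "name": name, "overlap": overlap, "set_size": K, "p": p}
        )
    frame = pd.DataFrame(rows, columns=["term", "name", "overlap", "set_size", "p"])
    if len(frame):
        frame["padj"] = bh_adjust(frame["p"].to_numpy())
        frame = frame.sort_values(["p", "term"]).reset_index(drop=True)
    else:
        frame["padj"] = pd.Series(dtype=float)
    return frame
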