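"""DEG / co-expressed gene screening with cross-cohort vote counting.

Per cohort: differential expression is called on the log2 scale with a
per-gene Welch t test and Benjamini-Hochberg adjustment
(|log2FC| > 1 and adjusted p < 0.05); co-expression with the target gene
is called with Pearson correlation across all samples (|r| >= 0.3 and
p < 0.05), split by the sign of r. Across cohorts a gene must pass with
the same direction in at least ``min_repetition`` cohorts (vote counting);
DEG candidates are then confirmed by a pooled SMD whose 95% CI excludes 0.
Set A = confirmed-up DEGs intersected with +r genes, set B = confirmed-down
DEGs intersected with -r genes.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import meta_effect
from .types import CONTROL, TUMOR, ExpressionCohort, GroupSummary, warn

UP, DOWN = "up", "down"


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_screen(
    cohort: ExpressionCohort,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Differential-expression screen of one log-scale cohort.

    Returns a gene-indexed frame with log2fc (tumor - control on the log
    scale), Welch t, p, BH-adjusted p, direction and a strict pass flag
    (|log2FC| > threshold AND adjusted p < alpha). Genes with zero variance
    in both groups get NaN statistics and never pass.
    """
    if not cohort.is_log_scale:
        raise ValueError("de_screen requires a log-scale cohort; transform first")
    tumor = cohort.matrix.loc[:, cohort.group == TUMOR].to_numpy(dtype=float)
    control = cohort.matrix.loc[:, cohort.group == CONTROL].to_numpy(dtype=float)
    if tumor.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError("de_screen needs >= 2 samples per group")

    log2fc = tumor.mean(axis=1) - control.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(tumor, control, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    padj = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        padj[ok] = bh_adjust(p[ok])

    passed = ok & (np.abs(log2fc) > lfc_threshold) & (padj < alpha)
    direction = np.where(log2fc > 0, UP, DOWN)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "padj": padj,
            "direction": direction,
            "passed": passed,
        },
        index=cohort.matrix.index,
    )


def ceg_screen(
    cohort: ExpressionCohort,
    target: str,
    r_threshold: float = 0.3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Co-expression screen: Pearson r of every gene against the target.

    Correlations run across all samples of the cohort (tumor and control
    together). p-values use t = r sqrt((n-2)/(1-r^2)). Pass requires
    |r| >= threshold and p < alpha; the target itself is excluded, and
    constant genes are skipped with a warning (r undefined).
    """
    target = target.upper()
    y = cohort.values_for(target).to_numpy(dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError("co-expression screen needs >= 4 samples")
    X = cohort.matrix.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    x_ss = (Xc**2).sum(axis=1)
    y_ss = float((yc**2).sum())
    if y_ss == 0:
        raise ValueError(f"target {target!r} is constant; correlation undefined")
    constant = x_ss == 0
    if constant.any():
        warn(f"{int(constant.sum())} constant gene(s) skipped in co-expression screen")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ yc) / np.sqrt(x_ss * y_ss)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)

    frame = pd.DataFrame(
        {
            "r": r,
            "p": p,
            "direction": np.where(r > 0, "pos", "neg"),
            "passed": (~constant) & (np.abs(r) >= r_threshold) & (p < alpha),
        },
        index=cohort.matrix.index,
    )
    frame.loc[constant, ["r", "p"]] = np.nan
    return frame.drop(index=target)


def vote_count(
    per_cohort: Sequence[Mapping[str, str] | pd.DataFrame],
    min_repetition: int = 5,
) -> pd.DataFrame:
    """Cross-cohort vote counting of screened genes.

    Each element is either a mapping gene -> direction or a screen frame
    (only rows with ``passed`` are counted). A gene passes when it appears
    with the SAME direction in at least ``min_repetition`` cohorts;
    conflicting directions are tallied separately and can each pass.
    Returns all (gene, direction) tallies with an ``accepted`` flag.
    """
    if len(per_cohort) < min_repetition:
        raise ValueError(
            f"{len(per_cohort)} cohorts supplied but min_repetition is {min_repetition}"
        )
    counts: dict[tuple[str, str], int] = {}
    for entry in per_cohort:
        if isinstance(entry, pd.DataFrame):
            passed = entry[entry["passed"]]
            pairs = zip(passed.index, passed["direction"])
        else:
            pairs = entry.items()
        for gene, direction in pairs:
            counts[(gene, direction)] = counts.get((gene, direction), 0) + 1
    rows = [
        {"gene": g, "direction": d, "n_cohorts": c, "accepted": c >= min_repetition}
        for (g, d), c in counts.items()
    ]
    frame = pd.DataFrame(rows, columns=["gene", "direction", "n_cohorts", "accepted"])
    return frame.sort_values(
        ["accepted", "n_cohorts", "gene"], ascending=[False, False, True]
    ).reset_index(drop=True)


def accepted_genes(votes: pd.DataFrame, direction: str) -> set[str]:
    """Genes accepted by vote counting for one direction."""
    mask = votes["accepted"] & (votes["direction"] == direction)
    return set(votes.loc[mask, "gene"])


def smd_confirm(
    summaries: Mapping[str, Sequence[GroupSummary]],
    model: str = "auto",
    correction: str = "cohen",
) -> pd.DataFrame:
    """Confirm screened genes via pooled SMD confidence intervals.

    ``summaries`` maps gene -> per-cohort GroupSummary list. A gene is
    confirmed up when the pooled 95% CI lies above 0 and down when below 0.
    Genes with fewer than 2 usable cohorts are skipped with a warning.
    """
    rows = []
    skipped = []
    for gene, per_cohort in summaries.items():
        usable = [s for s in per_cohort if s.usable_for_variance and (s.sd1 > 0 or s.sd0 > 0)]
        if len(usable) < 2:
            skipped.append(gene)
            continue
        effects = [meta_effect.smd(s, correction=correction) for s in usable]
        result = meta_effect.pool(effects, model)
        status = UP if result.ci_low > 0 else (DOWN if result.ci_high < 0 else "none")
        rows.append(
            {
                "gene": gene,
                "pooled_smd": result.pooled,
                "ci_low": result.ci_low,
                "ci_high": result.ci_high,
                "n_cohorts": len(usable),
                "status": status,
            }
        )
    if skipped:
        warn(f"{len(skipped)} gene(s) skipped by smd_confirm (needs >= 2 cohorts)")
    return pd.DataFrame(
        rows, columns=["gene", "pooled_smd", "ci_low", "ci_high", "n_cohorts", "status"]
    ).set_index("gene")


def intersect_sets(
    confirmed_up: set[str],
    confirmed_down: set[str],
    pos_corr: set[str],
    neg_corr: set[str],
    target: str | None = None,
) -> tuple[set[str], set[str]]:
    """Set A = up DEGs intersect +r genes; set B = down DEGs intersect -r genes.

    The target gene is excluded from both sets.
    """
    set_a = set(confirmed_up) & set(pos_corr)
    set_b = set(confirmed_down) & set(neg_corr)
    if target is not None:
        set_a.discard(target.upper())
        set_b.discard(target.upper())
    if not set_a and not set_b:
        warn("both intersection gene sets are empty")
    return set_a, set_b
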