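"""Expression-scale normalization, same-platform merging and batch handling.

The fixed preprocessing order for raw RNA-seq style input is
FPKM -> TPM -> log2(x+1) -> same-platform merge -> per-batch centering.
Batch handling is a deliberate simplification: a gene-wise location
adjustment per batch (subtract batch mean, add grand mean) with no scale
adjustment or empirical-Bayes shrinkage.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd

from .types import ExpressionCohort, GroupSummary, warn


def fpkm_to_tpm(values: np.ndarray | pd.Series) -> np.ndarray:
    """Rescale one sample's FPKM vector to TPM (sums to 1e6).

    tpm_i = fpkm_i / sum_j fpkm_j * 1e6, applied per sample.
    """
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValueError("FPKM values must be nonnegative")
    total = arr.sum()
    if total <= 0:
        raise ValueError("all-zero sample: TPM undefined")
    return arr / total * 1e6


def fpkm_to_tpm_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Column-wise FPKM -> TPM for a genes x samples matrix."""
    totals = matrix.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero) > 0:
        raise ValueError(f"all-zero sample: TPM undefined for {zero.index[0]!r}")
    return matrix / totals * 1e6


def log2_transform(cohort: ExpressionCohort) -> ExpressionCohort:
    """Apply x -> log2(x + 1) and flag the cohort as log scale.

    A no-op (with warning) on a cohort already flagged as log scale, so the
    transform is idempotent through the flag guard.
    """
    if cohort.is_log_scale:
        warn(f"cohort {cohort.cohort_id!r} already log scale; log2 skipped")
        return cohort
    if (cohort.matrix.values < 0).any():
        raise ValueError("negative values: cannot log2-transform")
    return replace(cohort, matrix=np.log2(cohort.matrix + 1.0), is_log_scale=True)


def merge_same_platform(cohorts: Sequence[ExpressionCohort], merged_id: str) -> ExpressionCohort:
    """Column-concatenate same-platform cohorts on their common gene set.

    Per-sample batch labels (the source cohort ids) are retained so that
    batch centering and batch-aware meta-analysis remain possible.
    """
    if len(cohorts) < 2:
        raise ValueError("need at least 2 cohorts to merge")
    platforms = {c.platform_id for c in cohorts}
    if len(platforms) != 1:
        raise ValueError(f"cannot merge across platforms {sorted(platforms)}")
    if len({s for c in cohorts for s in c.sample_ids}) != sum(len(c.sample_ids) for c in cohorts):
        raise ValueError("duplicate sample ids across cohorts to merge")
    scales = {c.is_log_scale for c in cohorts}
    if len(scales) != 1:
        raise ValueError("cohorts to merge are on mixed scales")

    common = cohorts[0].matrix.index
    for c in cohorts[1:]:
        common = common.intersection(c.matrix.index)
    if len(common) == 0:
        raise ValueError("empty gene intersection; nothing to merge")
    common = sorted(common)

    matrix = pd.concat([c.matrix.loc[common] for c in cohorts], axis=1)
    group = pd.concat([c.group for c in cohorts])
    batch = pd.concat(
        [pd.Series(c.cohort_id, index=c.sample_ids) for c in cohorts]
    )
    covs = [c.covariates for c in cohorts if c.covariates is not None]
    covariates = pd.concat(covs) if covs else None
    if covariates is not None:
        covariates = covariates.reindex(matrix.columns)
    return ExpressionCohort(
        cohort_id=merged_id,
        platform_id=cohorts[0].platform_id,
        matrix=matrix,
        group=group,
        covariates=covariates,
        is_log_scale=cohorts[0].is_log_scale,
        batch=batch,
    )


def batch_center(cohort: ExpressionCohort, batch: pd.Series | None = None) -> ExpressionCohort:
    """Per gene, per batch: subtract the batch mean and add the grand mean.

    Leaves each gene's grand mean exactly unchanged and does not touch group
    proportions. Batches of size 1 are left uncentered with a warning (their
    mean would be removed entirely).
    """
    if batch is None:
        batch = cohort.batch
    if batch is None:
        raise ValueError("no batch labels available for centering")
    batch = batch.loc[cohort.sample_ids]
    labels = batch.unique()
    if len(labels) < 2:
        return cohort  # single batch: identity

    matrix = cohort.matrix.copy()
    grand = matrix.mean(axis=1)
    for label in labels:
        cols = batch.index[batch == label]
        if len(cols) == 1:
            warn(f"batch {label!r} has a single sample; left uncentered")
            continue
        batch_mean = matrix[cols].mean(axis=1)
        matrix[cols] = matrix[cols].sub(batch_mean, axis=0).add(grand, axis=0)
    return replace(cohort, matrix=matrix, batch=batch)


def summarize_group(cohort: ExpressionCohort, gene: str) -> GroupSummary:
    """(n, mean, SD) per group for one gene, on the cohort's stored scale.

    SDs use the n-1 denominator. Summaries with a group of size 1 are still
    produced (SD 0 by convention) but flagged unusable for t/SMD through
    :attr:`GroupSummary.usable_for_variance`.
    """
    tumor, control = cohort.split_groups(gene)
    if len(tumor) == 0 or len(control) == 0:
        raise ValueError(f"gene {gene!r}: a group is empty in {cohort.cohort_id!r}")
    return GroupSummary(
        n1=len(tumor),
        mean1=float(np.mean(tumor)),
        sd1=float(np.std(tumor, ddof=1)) if len(tumor) > 1 else 0.0,
        n0=len(control),
        mean0=float(np.mean(control)),
        sd0=float(np.std(control, ddof=1)) if len(control) > 1 else 0.0,
    )
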