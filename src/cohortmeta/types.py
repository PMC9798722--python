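"""Domain types shared across the pipeline.

The atoms here mirror how multi-cohort biomarker studies are organised:
an :class:`ExpressionCohort` is one study's genes x samples log-expression
matrix with tumor/control labels; a :class:`GroupSummary` is the (n, mean,
SD) pair of group summaries that every meta-analytic statistic is built
from; a :class:`StudyEffect` is one cohort's standardized mean difference;
a :class:`DiagnosticStudy` is the 2x2 classification table derived from a
ROC cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

TUMOR = "tumor"
CONTROL = "control"
GROUP_LABELS = (TUMOR, CONTROL)


@dataclass
class GroupSummary:
    """Per-group summary statistics for one gene in one cohort.

    Group 1 is always the tumor/case group; all effect signs downstream are
    tumor minus control. SDs are sample SDs (n-1 denominator).
    """

    n1: int
    mean1: float
    sd1: float
    n0: int
    mean0: float
    sd0: float

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n0 < 1:
            raise ValueError("group sizes must be >= 1")
        if self.sd1 < 0 or self.sd0 < 0:
            raise ValueError("standard deviations must be nonnegative")

    @property
    def usable_for_variance(self) -> bool:
        """True when both groups support variance-based statistics (t, SMD)."""
        return self.n1 >= 2 and self.n0 >= 2


@dataclass
class StudyEffect:
    """One cohort's standardized mean difference with sampling variance."""

    estimate: float
    variance: float
    ci_low: float
    ci_high: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise ValueError("effect variance must be positive")
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("CI must bracket the estimate")


@dataclass
class MetaResult:
    """A pooled effect with heterogeneity diagnostics.

    ``I2 = max(0, (Q - df) / Q)`` and ``tau2`` is the DerSimonian-Laird
    between-study variance (0 under the fixed-effect model).
    """

    pooled: float
    se: float
    ci_low: float
    ci_high: float
    Q: float
    df: int
    I2: float
    tau2: float
    model: str  # "fixed" or "random"
    k: int = 0
    het_p: float = float("nan")

    def __post_init__(self) -> None:
        if self.tau2 < 0:
            raise ValueError("tau2 must be nonnegative")
        if not (0.0 <= self.I2 < 1.0 or np.isnan(self.I2)):
            raise ValueError("I2 must lie in [0, 1)")


@dataclass
class DiagnosticStudy:
    """A 2x2 classification table (tumor positive at value >= cutoff)."""

    tp: int
    fp: int
    fn: int
    tn: int
    cutoff: float = float("nan")
    label: str = ""

    def __post_init__(self) -> None:
        for cell in (self.tp, self.fp, self.fn, self.tn):
            if cell < 0:
                raise ValueError("2x2 cells must be nonnegative")

    @property
    def n_tumor(self) -> int:
        return self.tp + self.fn

    @property
    def n_control(self) -> int:
        return self.fp + self.tn

    @property
    def sensitivity(self) -> float:
        return self.tp / self.n_tumor

    @property
    def specificity(self) -> float:
        return self.tn / self.n_control


@dataclass
class DiagnosticMeta:
    """Pooled diagnostic accuracy of a marker across cohorts."""

    pooled_sens: float
    sens_ci: tuple[float, float]
    pooled_spec: float
    spec_ci: tuple[float, float]
    lr_pos: float
    lr_neg: float
    dor: float
    sens_meta: Optional[MetaResult] = None
    spec_meta: Optional[MetaResult] = None
    sroc_auc: Optional[float] = None


@dataclass
class CorrelationStudy:
    """One cohort's Pearson correlation between two genes."""

    r: float
    n: int
    label: str = ""

    def __post_init__(self) -> None:
        if not abs(self.r) < 1:
            raise ValueError("|r| must be < 1 for the Fisher z transform")
        if self.n < 4:
            raise ValueError("n must be >= 4 (se of z requires n - 3 > 0)")


@dataclass
class IHCRecord:
    """One specimen's immunohistochemistry field scores.

    Each field is an (intensity, proportion_category) pair with intensity in
    0-3 and proportion category in 0-4; the immunoreactivity score of a
    field is their product (0-12).
    """

    specimen_id: str
    group: str
    fields: Sequence[tuple[int, int]]
    covariates: Optional[Mapping[str, object]] = None

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise ValueError(f"group must be one of {GROUP_LABELS}")
        for intensity, proportion in self.fields:
            if intensity not in (0, 1, 2, 3):
                raise ValueError(f"intensity {intensity} outside 0-3")
            if proportion not in (0, 1, 2, 3, 4):
                raise ValueError(f"proportion category {proportion} outside 0-4")


@dataclass
class EdgeList:
    """Undirected scored gene-gene interaction edges (scores in [0, 1])."""

    edges: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        cleaned: dict[tuple[str, str], float] = {}
        for a, b, s in self.edges:
            if a == b:
                continue
            key = (a, b) if a <= b else (b, a)
            # duplicate pairs collapse keeping the max score
            if key not in cleaned or s > cleaned[key]:
                cleaned[key] = s
        self.edges = [(a, b, s) for (a, b), s in sorted(cleaned.items())]

    def __len__(self) -> int:
        return len(self.edges)

    def nodes(self) -> list[str]:
        seen: set[str] = set()
        for a, b, _ in self.edges:
            seen.add(a)
            seen.add(b)
        return sorted(seen)


@dataclass
class GeneSetCollection:
    """term_id -> (term_name, member gene symbols), members uppercase."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, (name, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {term!r} has no members")
            self.sets[term] = (name, frozenset(g.upper() for g in members))

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, term: str) -> tuple[str, frozenset[str]]:
        return self.sets[term]

    def items(self):
        return self.sets.items()


@dataclass
class ExpressionCohort:
    """One cohort's genes x samples expression matrix with sample metadata.

    ``matrix`` rows are uppercase gene symbols (unique), columns are sample
    ids. ``group`` maps each sample to tumor/control. ``covariates`` may hold
    age (years), sex, stage (I-IV), and survival time (months) / event (0/1)
    columns, indexed by sample. ``batch`` records each sample's source cohort
    after a same-platform merge.
    """

    cohort_id: str
    platform_id: str
    matrix: pd.DataFrame
    group: pd.Series
    covariates: Optional[pd.DataFrame] = None
    is_log_scale: bool = True
    batch: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        self.matrix.index = self.matrix.index.astype(str).str.upper()
        if self.matrix.index.duplicated().any():
            dup = self.matrix.index[self.matrix.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}; collapse before constructing")
        missing = [s for s in self.matrix.columns if s not in self.group.index]
        if missing:
            raise ValueError(f"sample {missing[0]!r} has no group label")
        self.group = self.group.loc[self.matrix.columns]
        bad = set(self.group.unique()) - set(GROUP_LABELS)
        if bad:
            raise ValueError(f"unknown group label(s) {sorted(bad)}")
        if self.covariates is not None:
            self.covariates = self.covariates.reindex(self.matrix.columns)
        if self.batch is not None:
            self.batch = self.batch.loc[self.matrix.columns]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def n_tumor(self) -> int:
        return int((self.group == TUMOR).sum())

    @property
    def n_control(self) -> int:
        return int((self.group == CONTROL).sum())

    def values_for(self, gene: str) -> pd.Series:
        gene = gene.upper()
        if gene not in self.matrix.index:
            raise KeyError(f"gene {gene!r} not present in cohort {self.cohort_id!r}")
        return self.matrix.loc[gene]

    def split_groups(self, gene: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (tumor values, control values) for one gene."""
        values = self.values_for(gene)
        return (
            values[self.group == TUMOR].to_numpy(dtype=float),
            values[self.group == CONTROL].to_numpy(dtype=float),
        )


def collapse_duplicate_genes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Uppercase gene symbols and collapse duplicate rows by arithmetic mean.

    Idempotent: applying twice equals applying once.
    """
    matrix = matrix.copy()
    matrix.index = matrix.index.astype(str).str.upper()
    if matrix.index.duplicated().any():
        matrix = matrix.groupby(level=0, sort=False).mean()
    return matrix


def warn(message: str) -> None:
    """Single chokepoint for non-fatal data issues."""
    warnings.warn(message, UserWarning, stacklevel=3)
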