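"""File I/O for expression cohorts, gene sets (GMT) and interaction edges.

Expression input is a TSV/CSV with the first column holding gene symbols and
the remaining columns one sample each, plus a sidecar sample sheet mapping
``sample_id`` to ``group`` (tumor/control) and optional clinical covariates
(age, sex, stage, time, event; blanks allowed).
"""

from __future__ import annotations

import os
from typing import Optional

import pandas as pd

from .types import (
    EdgeList,
    ExpressionCohort,
    GeneSetCollection,
    collapse_duplicate_genes,
    warn,
)

COVARIATE_COLUMNS = ("age", "sex", "stage", "time", "event")


def _sep_for(path: str) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_sample_sheet(path: str) -> pd.DataFrame:
    """Read a sample sheet TSV indexed by sample_id."""
    sheet = pd.read_csv(path, sep=_sep_for(path), dtype={"sample_id": str})
    if "sample_id" not in sheet.columns or "group" not in sheet.columns:
        raise ValueError("sample sheet needs 'sample_id' and 'group' columns")
    return sheet.set_index("sample_id")


def read_expression_cohort(
    path: str,
    sample_sheet: str | pd.DataFrame,
    cohort_id: Optional[str] = None,
    platform_id: str = "",
    is_log_scale: bool = True,
) -> ExpressionCohort:
    """Load a genes x samples matrix and its sample sheet into a cohort.

    Duplicate gene symbols are collapsed by arithmetic mean and symbols are
    uppercased. A sample present in the matrix but absent from the sample
    sheet is a hard error naming the sample, as is any non-numeric cell.
    """
    matrix = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    for col in matrix.columns:
        if matrix[col].dtype == object:
            coerced = pd.to_numeric(matrix[col], errors="coerce")
            bad = coerced.isna() & matrix[col].notna()
            if bad.any():
                gene = matrix.index[bad.to_numpy().nonzero()[0][0]]
                raise ValueError(
                    f"non-numeric expression value at gene {gene!r}, sample {col!r}"
                )
            matrix[col] = coerced
    matrix = collapse_duplicate_genes(matrix.astype(float))

    sheet = (
        read_sample_sheet(sample_sheet)
        if isinstance(sample_sheet, (str, os.PathLike))
        else sample_sheet
    )
    missing = [s for s in matrix.columns if s not in sheet.index]
    if missing:
        raise ValueError(f"sample {missing[0]!r} missing from sample sheet")

    covariate_cols = [c for c in COVARIATE_COLUMNS if c in sheet.columns]
    covariates = sheet.loc[matrix.columns, covariate_cols] if covariate_cols else None
    if cohort_id is None:
        cohort_id = os.path.splitext(os.path.basename(str(path)))[0]
    return ExpressionCohort(
        cohort_id=cohort_id,
        platform_id=platform_id,
        matrix=matrix,
        group=sheet.loc[matrix.columns, "group"],
        covariates=covariates,
        is_log_scale=is_log_scale,
    )


def write_expression_cohort(cohort: ExpressionCohort, matrix_path: str, sheet_path: str) -> None:
    """Write a cohort back to a matrix TSV plus sample sheet TSV.

    Uses pandas' default float formatting, which round-trips doubles exactly.
    """
    out = cohort.matrix.copy()
    out.index.name = "gene"
    out.to_csv(matrix_path, sep=_sep_for(matrix_path))
    sheet = pd.DataFrame({"sample_id": cohort.sample_ids, "group": cohort.group.values})
    if cohort.covariates is not None:
        for col in cohort.covariates.columns:
            sheet[col] = cohort.covariates[col].values
    sheet.to_csv(sheet_path, sep=_sep_for(sheet_path), index=False)


def read_gmt(path: str) -> GeneSetCollection:
    """Read a GMT file (term, description, tab-separated member symbols)."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line {lineno}: fewer than 3 fields")
            term, description = parts[0], parts[1]
            members = frozenset(g.strip().upper() for g in parts[2:] if g.strip())
            if not members:
                warn(f"GMT term {term!r} (line {lineno}) has no members; dropped")
                continue
            sets[term] = (description, members)
    return GeneSetCollection(sets=sets)


def read_edge_list(path: str, min_score: float = 0.4) -> EdgeList:
    """Read a STRING-style interaction TSV (node1, node2, combined_score).

    Scores are accepted either already in [0, 1] or on STRING's 0-1000 scale;
    any score above 1 triggers division of all scores by 1000. Edges with
    score <= ``min_score`` are dropped, self-loops removed, and duplicate
    pairs collapsed keeping the maximum score.
    """
    table = pd.read_csv(path, sep=_sep_for(path))
    if table.shape[1] < 3:
        raise ValueError("edge list needs at least 3 columns (node1, node2, score)")
    a = table.iloc[:, 0].astype(str).str.upper()
    b = table.iloc[:, 1].astype(str).str.upper()
    score = pd.to_numeric(table.iloc[:, 2], errors="raise").astype(float)
    if (score > 1).any():
        score = score / 1000.0
    keep = score > min_score
    edges = EdgeList(edges=list(zip(a[keep], b[keep], score[keep])))
    if len(edges) == 0:
        warn(f"no edges survive min_score {min_score} in {path}")
    return edges


def write_edge_list(edges: EdgeList, path: str) -> None:
    pd.DataFrame(edges.edges, columns=["node1", "node2", "combined_score"]).to_csv(
        path, sep=_sep_for(path), index=False
    )
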