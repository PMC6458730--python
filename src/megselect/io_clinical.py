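"""Reading, validation and writing of the tab-separated interchange files.

Expression: TSV, UTF-8, genes in rows; the first column holds gene
identifiers (header ``gene_id``) and the header row holds sample
identifiers. Clinical: TSV with at least sample_id, subtype, stage,
os_time, event, age. Results: TSV with one row per gene x direction,
ordered ascending by q-value (ties by DE_total, then gene id) so output
files are diffable.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ClinicalTable, ExpressionMatrix
from .exceptions import (
    AlignmentError,
    EmptyInputError,
    MalformedHeaderError,
    NonNumericValueError,
)
from .mfselector import MEGResults

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ("gene", "direction", "de_total", "p_value", "q_value", "significant")


def read_expression_matrix(path: str | Path, transposed: bool = False) -> ExpressionMatrix:
    """Read a TSV expression matrix (genes in rows unless ``transposed``).

    Duplicate identifiers, non-numeric cells (including NA -- no imputation
    is performed) and empty files are rejected with distinct errors.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise EmptyInputError(f"{path} is empty")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path} has no parseable content") from exc
    if df.shape[1] == 0:
        raise MalformedHeaderError(
            f"{path}: expected a tab-separated header with sample identifiers"
        )
    if transposed:
        df = df.T
    bad = df.columns[df.columns.astype(str).str.match(r"Unnamed: \d+")]
    if len(bad):
        raise MalformedHeaderError(f"{path}: header has unnamed columns {list(bad)}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any():
        rows = df.index[numeric.isna().any(axis=1)].tolist()
        raise NonNumericValueError(
            f"{path}: non-numeric or missing expression values in rows {rows[:5]}"
        )
    return ExpressionMatrix(numeric.astype(float))


def read_clinical_table(path: str | Path) -> ClinicalTable:
    """Read and validate a TSV clinical table."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise EmptyInputError(f"{path} is empty")
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype={"sample_id": str, "stage": str})
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path} has no parseable content") from exc
    return ClinicalTable(df)


def align_samples(
    expr: ExpressionMatrix, clin: ClinicalTable
) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Restrict both objects to their shared samples, in the expression order.

    Dropped identifiers are logged; an empty intersection is an error.
    The operation is idempotent.
    """
    expr_ids = expr.sample_ids
    clin_ids = set(clin.sample_ids)
    shared = [s for s in expr_ids if s in clin_ids]
    if not shared:
        raise AlignmentError("expression and clinical tables share no samples")
    dropped_expr = [s for s in expr_ids if s not in clin_ids]
    dropped_clin = sorted(clin_ids - set(expr_ids))
    if dropped_expr:
        logger.info("align_samples: dropping %d expression-only samples: %s",
                    len(dropped_expr), dropped_expr[:5])
    if dropped_clin:
        logger.info("align_samples: dropping %d clinical-only samples: %s",
                    len(dropped_clin), dropped_clin[:5])
    return expr.subset_samples(shared), clin.subset(shared)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write a TSV matrix with >= 10 significant digits per value."""
    out = expr.data.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def write_clinical_table(clin: ClinicalTable, path: str | Path) -> None:
    clin.data.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_results_table(results: MEGResults, path: str | Path) -> None:
    """Write scan results as TSV, sorted by (q_value, de_total, gene).

    Floats are written with shortest round-trip precision, so reading the
    file back reproduces the values bit-exactly.
    """
    table = results.table
    out = table.loc[:, list(RESULT_COLUMNS)].sort_values(
        ["q_value", "de_total", "gene"], kind="stable"
    )
    out.to_csv(path, sep="\t", index=False)


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results_table`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedHeaderError(f"{path}: results table missing columns {missing}")
    if len(df):
        df["significant"] = df["significant"].astype(bool)
        df["de_total"] = df["de_total"].astype(int)
    else:
        df = df.astype(
            {"de_total": int, "p_value": float, "q_value": float, "significant": bool},
            errors="ignore",
        )
    return df.reset_index(drop=True)
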