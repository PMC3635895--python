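"""Readers and writers for the pipeline's tabular text formats.

Conventions: expression matrices are tab-delimited with a ``probe_id``
header column; everything else is plain CSV. The missing-value token is
the literal string ``NA`` in all formats.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    CohortTable,
    DrugPanel,
    ExpressionMatrix,
    InvasionProfile,
    ProbeMap,
    ValidationError,
)

log = logging.getLogger("invasig")

NA_TOKEN = "NA"


def _parse_numeric_block(raw: pd.DataFrame, path: str) -> pd.DataFrame:
    """Convert a string-typed frame to float, reporting the offending cell."""
    out = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        column = raw[col].to_numpy()
        for i, cell in enumerate(column):
            text = str(cell).strip()
            if text == NA_TOKEN or text == "":
                out[i, j] = np.nan
                continue
            try:
                out[i, j] = float(text)
            except ValueError:
                raise ValidationError(
                    f"{path}: non-numeric cell {text!r} at row {raw.index[i]!r}, "
                    f"column {col!r}"
                ) from None
    return pd.DataFrame(out, index=raw.index, columns=raw.columns)


def read_expression_matrix(path: str | Path, platform_id: str) -> ExpressionMatrix:
    """Read a tab-delimited probes x samples matrix.

    First column must be probe IDs under a ``probe_id`` header; remaining
    header cells are sample IDs. ``NA`` cells become missing values.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.columns[0] != "probe_id":
        raise ValidationError(f"{path}: first column must be 'probe_id', got {raw.columns[0]!r}")
    raw = raw.set_index("probe_id")
    dup = raw.index[raw.index.duplicated()].unique()
    if len(dup):
        raise ValidationError(f"{path}: duplicate probe IDs: {sorted(map(str, dup))}")
    values = _parse_numeric_block(raw, str(path))
    return ExpressionMatrix(platform_id=platform_id, values=values)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="probe_id", na_rep=NA_TOKEN)


def read_probe_map(path: str | Path) -> ProbeMap:
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ProbeMap.REQUIRED:
        if col not in table.columns:
            raise ValidationError(f"{path}: probe map missing column {col!r}")
    return ProbeMap(table[list(ProbeMap.REQUIRED)])


def write_probe_map(pmap: ProbeMap, path: str | Path) -> None:
    pmap.table.to_csv(path, index=False)


def read_invasion_profile(path: str | Path) -> InvasionProfile:
    table = pd.read_csv(path, dtype={"cell_line": str, "tissue_group": str})
    for col in ("cell_line", "icc", "tissue_group"):
        if col not in table.columns:
            raise ValidationError(f"{path}: invasion profile missing column {col!r}")
    return InvasionProfile(table.set_index("cell_line"))


def write_invasion_profile(profile: InvasionProfile, path: str | Path) -> None:
    profile.table.to_csv(path, index_label="cell_line")


def read_drug_panel(path: str | Path) -> DrugPanel:
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("drug_id", "mechanism_class"):
        if col not in raw.columns:
            raise ValidationError(f"{path}: drug panel missing column {col!r}")
    raw = raw.set_index("drug_id")
    mechanism = raw["mechanism_class"]
    block = raw.drop(columns=["mechanism_class"])
    sensitivity = _parse_numeric_block(block, str(path))
    return DrugPanel(sensitivity=sensitivity, mechanism=mechanism)


def write_drug_panel(panel: DrugPanel, path: str | Path) -> None:
    out = panel.sensitivity.copy()
    out.insert(0, "mechanism_class", panel.mechanism)
    out.to_csv(path, index_label="drug_id", na_rep=NA_TOKEN)


def read_cohort_table(
    path: str | Path,
    gene_cols: Sequence[str],
    covariate_cols: Sequence[str] | None = None,
) -> CohortTable:
    """Read a cohort CSV.

    ``gene_cols`` must be declared; covariates default to every remaining
    column after patient_id/time/event/genes (unknown columns are kept as
    opaque covariates).
    """
    table = pd.read_csv(path, na_values=[NA_TOKEN])
    for col in ("patient_id", "time", "event"):
        if col not in table.columns:
            raise ValidationError(f"{path}: cohort table missing column {col!r}")
    table = table.set_index("patient_id")
    if covariate_cols is None:
        covariate_cols = [
            c for c in table.columns if c not in ("time", "event") and c not in set(gene_cols)
        ]
    return CohortTable(
        data=table,
        gene_cols=tuple(gene_cols),
        covariate_cols=tuple(covariate_cols),
    )


def write_cohort_table(cohort: CohortTable, path: str | Path) -> None:
    cohort.data.to_csv(path, index_label="patient_id", na_rep=NA_TOKEN)
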