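"""Core data containers shared across the pipeline.

All tabular payloads are pandas objects; the dataclasses wrap them with
schema validation so that every reader/simulator hands downstream code a
checked, uniform structure.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """An input table violates its schema contract."""


@dataclass
class ExpressionMatrix:
    """Probes x samples log2-intensity matrix for one platform.

    Parameters
    ----------
    platform_id
        Free-form label identifying the array platform.
    values
        DataFrame indexed by probe ID with sample IDs as columns.
        NaN marks a missing measurement.
    """

    platform_id: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        dup = self.values.index[self.values.index.duplicated()].unique()
        if len(dup):
            raise ValidationError(f"duplicate probe IDs: {sorted(map(str, dup))}")
        dup = self.values.columns[self.values.columns.duplicated()].unique()
        if len(dup):
            raise ValidationError(f"duplicate sample IDs: {sorted(map(str, dup))}")
        self.values = self.values.astype(float)

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_probes(self, probes: Sequence[str]) -> "ExpressionMatrix":
        missing = [p for p in probes if p not in self.values.index]
        if missing:
            raise KeyError(f"probes absent from matrix: {missing}")
        return ExpressionMatrix(self.platform_id, self.values.loc[list(probes)])


@dataclass
class ProbeMap:
    """Cross-platform probe pairing with gene annotation.

    ``table`` has columns ``probe_a``, ``probe_b``, ``gene_symbol``;
    many-to-many pairings are allowed, exact duplicate pairs are not.
    """

    table: pd.DataFrame

    REQUIRED = ("probe_a", "probe_b", "gene_symbol")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValidationError(f"probe map missing column {col!r}")
        dup = self.table.duplicated(subset=["probe_a", "probe_b"])
        if dup.any():
            pairs = self.table.loc[dup, ["probe_a", "probe_b"]].values.tolist()
            raise ValidationError(f"duplicate probe pairs: {pairs}")

    def __len__(self) -> int:
        return len(self.table)

    def gene_of(self) -> Mapping[str, str]:
        """probe_a -> gene symbol lookup (first annotation wins)."""
        return dict(zip(self.table["probe_a"], self.table["gene_symbol"]))


@dataclass
class InvasionProfile:
    """Per-cell-line invaded cell count (ICC) with tissue-group label.

    ``table`` is indexed by cell line and has columns ``icc`` and
    ``tissue_group``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("icc", "tissue_group"):
            if col not in self.table.columns:
                raise ValidationError(f"invasion profile missing column {col!r}")
        dup = self.table.index[self.table.index.duplicated()].unique()
        if len(dup):
            raise ValidationError(f"duplicate cell lines: {sorted(map(str, dup))}")
        icc = self.table["icc"].astype(float)
        if (icc < 0).any():
            bad = self.table.index[icc < 0].tolist()
            raise ValidationError(f"negative ICC for cell lines: {bad}")
        self.table = self.table.assign(icc=icc)

    @property
    def cell_lines(self) -> pd.Index:
        return self.table.index

    @property
    def icc(self) -> pd.Series:
        return self.table["icc"]

    @property
    def tissue_group(self) -> pd.Series:
        return self.table["tissue_group"]


@dataclass
class DrugPanel:
    """Drugs x cell lines sensitivity panel (-log10 GI50 / IC50 scale).

    ``sensitivity`` is indexed by drug ID with cell lines as columns;
    ``mechanism`` maps drug ID -> mechanism class.
    """

    sensitivity: pd.DataFrame
    mechanism: pd.Series

    def __post_init__(self) -> None:
        dup = self.sensitivity.index[self.sensitivity.index.duplicated()].unique()
        if len(dup):
            raise ValidationError(f"duplicate drug IDs: {sorted(map(str, dup))}")
        if not self.sensitivity.index.equals(self.mechanism.index):
            self.mechanism = self.mechanism.reindex(self.sensitivity.index)
            if self.mechanism.isna().any():
                bad = self.mechanism.index[self.mechanism.isna()].tolist()
                raise ValidationError(f"drugs without mechanism class: {bad}")
        self.sensitivity = self.sensitivity.astype(float)

    @property
    def drug_ids(self) -> pd.Index:
        return self.sensitivity.index

    @property
    def cell_lines(self) -> pd.Index:
        return self.sensitivity.columns

    def subset(self, drugs: Sequence[str]) -> "DrugPanel":
        return DrugPanel(self.sensitivity.loc[list(drugs)], self.mechanism.loc[list(drugs)])


@dataclass
class CohortTable:
    """Per-patient survival outcome, covariates and signature-gene expression.

    ``data`` is indexed by patient ID and carries ``time`` (positive,
    months), ``event`` (0/1), the declared covariate columns and the
    declared gene columns.
    """

    data: pd.DataFrame
    gene_cols: tuple[str, ...] = ()
    covariate_cols: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise ValidationError(f"cohort table missing column {col!r}")
        time = self.data["time"].astype(float)
        if (time <= 0).any():
            bad = self.data.index[time <= 0].tolist()
            raise ValidationError(f"non-positive survival time for patients: {bad}")
        event = self.data["event"]
        if not event.isin([0, 1]).all():
            bad = self.data.index[~event.isin([0, 1])].tolist()
            raise ValidationError(f"event outside {{0,1}} for patients: {bad}")
        for col in tuple(self.gene_cols) + tuple(self.covariate_cols):
            if col not in self.data.columns:
                raise ValidationError(f"declared column {col!r} absent from cohort")
        self.gene_cols = tuple(self.gene_cols)
        self.covariate_cols = tuple(self.covariate_cols)

    def __len__(self) -> int:
        return len(self.data)
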