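"""Rank-based normal-score transformation and cross-platform probe matching."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, ProbeMap


@dataclass
class TransformedVector:
    """Normal-scored vector with the (tie-averaged) source ranks kept."""

    values: np.ndarray
    source_ranks: np.ndarray


def normal_score_transform(x) -> TransformedVector:
    """Map values to standard-normal quantiles by rank.

    A non-missing value with average rank r among the m non-missing
    entries maps to ``Phi^-1(r / (m + 1))`` (van der Waerden scores).
    Missing entries stay missing; ties share the same output.

    Raises
    ------
    ValueError
        If fewer than 3 non-missing values are present.
    """
    x = np.asarray(x, dtype=float)
    mask = ~np.isnan(x)
    m = int(mask.sum())
    if m < 3:
        raise ValueError(f"normal score transform needs >= 3 non-missing values, got {m}")
    ranks = stats.rankdata(x[mask], method="average")
    values = np.full(x.shape, np.nan)
    values[mask] = stats.norm.ppf(ranks / (m + 1))
    source_ranks = np.full(x.shape, np.nan)
    source_ranks[mask] = ranks
    return TransformedVector(values=values, source_ranks=source_ranks)


def normal_score_rows(X: np.ndarray) -> np.ndarray:
    """Row-wise normal-score transform of a 2-D array (NaN-aware, vectorized).

    Each row is transformed on its own non-missing support; rows with
    fewer than 3 non-missing entries come back all-NaN.
    """
    X = np.asarray(X, dtype=float)
    ranks = stats.rankdata(X, axis=1, nan_policy="omit")
    m = np.sum(~np.isnan(X), axis=1, keepdims=True).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = stats.norm.ppf(ranks / (m + 1))
    out[np.repeat(m < 3, X.shape[1], axis=1)] = np.nan
    return out


@dataclass
class MatchedPairs:
    """Probe pairs usable across two platforms plus their shared samples."""

    pairs: pd.DataFrame  # columns: probe_a, probe_b, gene_symbol
    shared_samples: list[str]

    def __len__(self) -> int:
        return len(self.pairs)


def match_probes(
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    probe_map: ProbeMap,
) -> MatchedPairs:
    """Restrict a probe map to pairs present on both matrices.

    Many-to-many pairs are all retained; downstream stages decide how to
    resolve them. Requires >= 3 shared sample IDs.
    """
    shared = [s for s in matrix_a.sample_ids if s in set(matrix_b.sample_ids)]
    if len(shared) < 3:
        raise ValueError(
            f"matrices share only {len(shared)} samples; >= 3 required"
        )
    in_a = probe_map.table["probe_a"].isin(matrix_a.probe_ids)
    in_b = probe_map.table["probe_b"].isin(matrix_b.probe_ids)
    pairs = probe_map.table.loc[in_a & in_b].reset_index(drop=True)
    return MatchedPairs(pairs=pairs, shared_samples=shared)
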