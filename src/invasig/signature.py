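"""Sequential signature derivation (intersection -> platform -> SD ->
direction-consistency) and the averaged risk score."""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix
from .pharmaco import GeneDrugMatrix

log = logging.getLogger("invasig")


@dataclass
class SignatureDefinition:
    """Final gene signature: one source probe per gene plus metadata.

    ``table`` has columns gene, probe, sd; ``class_signs`` maps drug
    mechanism class -> expected correlation sign (+1/-1).
    """

    table: pd.DataFrame
    class_signs: dict[str, int]

    @property
    def genes(self) -> list[str]:
        return self.table["gene"].tolist()

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class RiskScoreTable:
    """Per-sample averaged signature score with high/low group assignment."""

    table: pd.DataFrame  # index sample_id; columns score, group
    threshold: float
    threshold_rule: str

    @property
    def scores(self) -> pd.Series:
        return self.table["score"]

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]


def intersect_drug_correlated(
    probe_sets: Mapping[str, set[str]], drugs: Sequence[str]
) -> set[str]:
    """Probes significantly correlated with every named drug."""
    unknown = [d for d in drugs if d not in probe_sets]
    if unknown:
        raise KeyError(f"no significant-probe set for drugs: {unknown}")
    if not drugs:
        raise ValueError("at least one drug required")
    common = set(probe_sets[drugs[0]])
    for d in drugs[1:]:
        common &= probe_sets[d]
    return common


def filter_platform(probes: Sequence[str], membership: Mapping[str, bool]) -> list[str]:
    """Keep probes flagged as present on the designated chip, preserving order."""
    unknown = [p for p in probes if p not in membership]
    if unknown:
        raise KeyError(f"probes with unknown platform membership: {unknown}")
    kept = [p for p in probes if membership[p]]
    if probes and not kept:
        log.warning("platform filter removed all %d candidate probes", len(probes))
    return kept


def probe_sds(expr: ExpressionMatrix) -> pd.Series:
    """Per-probe standard deviation across all samples (raw log2 scale)."""
    return expr.values.std(axis=1, ddof=1)


def filter_by_sd(
    expr: ExpressionMatrix, probes: Sequence[str], quantile: float = 0.9
) -> list[str]:
    """Keep candidates whose SD ranks in the top (1 - quantile) of ALL probes.

    The cutoff is the k-th largest SD on the full matrix with
    k = ceil(n_probes * (1 - quantile)); candidates with SD >= cutoff are
    retained (deterministic at boundaries).
    """
    if not 0 < quantile < 1:
        raise ValueError(f"quantile must be in (0,1), got {quantile}")
    sds = probe_sds(expr)
    missing = [p for p in probes if p not in sds.index]
    if missing:
        raise KeyError(f"candidate probes absent from matrix: {missing}")
    k = max(1, math.ceil(len(sds) * (1.0 - quantile)))
    cutoff = np.sort(sds.to_numpy())[::-1][k - 1]
    return [p for p in probes if sds[p] >= cutoff]


def filter_direction_consistency(
    probes: Sequence[str],
    gene_drug: GeneDrugMatrix,
    expected: Mapping[str, int],
) -> list[str]:
    """Keep probes whose gene-drug correlation sign matches the expected
    sign for every in-scope drug.

    ``expected`` maps drug ID -> +1/-1. A missing correlation cell for an
    in-scope drug rejects the probe (logged).
    """
    for drug in expected:
        if drug not in gene_drug.drugs:
            raise KeyError(f"drug {drug!r} absent from gene-drug matrix")
    kept = []
    for probe in probes:
        ok = True
        for drug, sign in expected.items():
            r = gene_drug.r.at[probe, drug]
            if np.isnan(r):
                log.info("probe %s rejected: missing correlation for drug %s", probe, drug)
                ok = False
                break
            if np.sign(r) != sign:
                ok = False
                break
        if ok:
            kept.append(probe)
    return kept


def collapse_probes_to_genes(
    probes: Sequence[str],
    annotation: Mapping[str, str],
    sds: pd.Series,
    class_signs: Mapping[str, int] | None = None,
) -> SignatureDefinition:
    """One probe per gene: the max-SD probe wins.

    ``annotation`` maps probe -> gene symbol; every probe must be
    annotated and have an SD.
    """
    unannotated = [p for p in probes if p not in annotation]
    if unannotated:
        raise KeyError(f"unannotated probes: {unannotated}")
    if not probes:
        log.warning("empty probe set; signature is empty")
    best: dict[str, tuple[str, float]] = {}
    for probe in probes:
        gene = annotation[probe]
        sd = float(sds[probe])
        if gene not in best or sd > best[gene][1]:
            best[gene] = (probe, sd)
    rows = [(g, p, s) for g, (p, s) in sorted(best.items())]
    table = pd.DataFrame(rows, columns=["gene", "probe", "sd"])
    return SignatureDefinition(table=table, class_signs=dict(class_signs or {}))


def compute_risk_score(
    expr: pd.DataFrame,
    genes: Sequence[str],
    standardize: bool = False,
    threshold_rule: str = "mean",
) -> RiskScoreTable:
    """Average the signature-gene values per sample and dichotomize.

    Parameters
    ----------
    expr
        Genes x samples frame (an :class:`ExpressionMatrix` ``values``
        block or a cohort's gene columns transposed).
    genes
        Signature gene order is irrelevant to the score.
    standardize
        Z-score each gene across the cohort before averaging.
    threshold_rule
        'mean' or 'median' of the per-sample scores; group is 'high' iff
        score > threshold.
    """
    if threshold_rule not in ("mean", "median"):
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise KeyError(f"signature genes absent from expression: {missing}")
    block = expr.loc[list(genes)]
    if block.isna().any().any():
        bad = block.index[block.isna().any(axis=1)].tolist()
        raise ValueError(f"missing expression values for signature genes: {bad}")
    if standardize:
        mu = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        block = block.sub(mu, axis=0).div(sd, axis=0)
    scores = block.mean(axis=0)
    threshold = float(scores.mean() if threshold_rule == "mean" else scores.median())
    groups = pd.Series(np.where(scores > threshold, "high", "low"), index=scores.index)
    table = pd.DataFrame({"score": scores, "group": groups})
    table.index.name = "sample_id"
    return RiskScoreTable(table=table, threshold=threshold, threshold_rule=threshold_rule)
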