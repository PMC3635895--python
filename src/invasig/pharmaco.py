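"""Gene-drug correlation profiling over the IA probes.

Sign convention throughout: sensitivity is on the -log10 GI50 / IC50
scale, so a positive gene-drug correlation means cell lines with higher
expression are more sensitive to the drug.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corrstats import pearson_rows
from .datatypes import DrugPanel, ExpressionMatrix, InvasionProfile
from .preprocess import normal_score_rows, normal_score_transform

log = logging.getLogger("invasig")


@dataclass
class GeneDrugMatrix:
    """IA probes x drugs correlation results (r, two-sided P, n per cell)."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    @property
    def probes(self) -> pd.Index:
        return self.r.index

    @property
    def drugs(self) -> pd.Index:
        return self.r.columns


@dataclass
class DrugCountSummary:
    """Per-drug significant-probe counts with per-mechanism-class means."""

    counts: pd.Series  # drug -> count
    class_means: pd.Series  # mechanism class -> mean count
    mechanism: pd.Series  # drug -> mechanism class
    alpha: float


def filter_inactive_drugs(panel: DrugPanel) -> DrugPanel:
    """Drop drugs whose sensitivity profile is constant or entirely missing."""
    values = panel.sensitivity
    n_distinct = values.nunique(axis=1, dropna=True)
    inactive = values.index[n_distinct <= 1]
    if len(inactive):
        log.info("excluding %d inactive drugs: %s", len(inactive), sorted(inactive.tolist()))
    if len(inactive) == len(values):
        log.warning("all drugs inactive; returning empty panel")
    keep = values.index.difference(inactive, sort=False)
    return DrugPanel(values.loc[keep], panel.mechanism.loc[keep])


def gene_drug_correlations(
    expr: ExpressionMatrix,
    panel: DrugPanel,
    transform: bool = True,
) -> GeneDrugMatrix:
    """Pearson correlation of every probe with every drug profile.

    Cell-line universe is the intersection of expression samples and
    panel cell lines. With ``transform`` on, probes and drug profiles are
    normal-scored before correlating. Cells with < 3 complete pairs stay
    missing.
    """
    shared = [s for s in expr.sample_ids if s in set(panel.cell_lines)]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared cell lines; >= 3 required")
    log.info("gene-drug correlation on %d shared cell lines", len(shared))
    X = expr.values[shared].to_numpy()
    if transform:
        X = normal_score_rows(X)
    r_cols, p_cols, n_cols = {}, {}, {}
    for drug in panel.drug_ids:
        y = panel.sensitivity.loc[drug, shared].to_numpy(dtype=float)
        if transform:
            try:
                y = normal_score_transform(y).values
            except ValueError:
                y = np.full_like(y, np.nan)
        r, p, n = pearson_rows(X, y)
        r_cols[drug], p_cols[drug], n_cols[drug] = r, p, n
    idx = expr.probe_ids
    return GeneDrugMatrix(
        r=pd.DataFrame(r_cols, index=idx),
        p=pd.DataFrame(p_cols, index=idx),
        n=pd.DataFrame(n_cols, index=idx),
    )


def count_significant(matrix: GeneDrugMatrix, mechanism: pd.Series, alpha: float = 0.05) -> DrugCountSummary:
    """Count per drug the probes with P < alpha; mean count per class."""
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0,1], got {alpha}")
    counts = (matrix.p < alpha).sum(axis=0)
    mech = mechanism.reindex(counts.index)
    class_means = counts.groupby(mech).mean()
    return DrugCountSummary(counts=counts, class_means=class_means, mechanism=mech, alpha=alpha)


def significant_probe_sets(matrix: GeneDrugMatrix, alpha: float = 0.05) -> dict[str, set[str]]:
    """Per-drug set of probes with gene-drug P < alpha."""
    sig = matrix.p < alpha
    return {drug: set(matrix.probes[sig[drug]]) for drug in matrix.drugs}


def drug_profile_similarity(matrix: GeneDrugMatrix, drugs=None) -> pd.DataFrame:
    """Column-to-column Pearson correlation of gene-drug r profiles.

    Symmetric with unit diagonal; cells with < 3 jointly non-missing
    probes stay missing.
    """
    cols = matrix.r if drugs is None else matrix.r[list(drugs)]
    sim = cols.corr(method="pearson", min_periods=3)
    np.fill_diagonal(sim.values, 1.0)
    return sim


def invasion_drug_correlation(
    invasion: InvasionProfile,
    panel: DrugPanel,
    transform: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlate the invasion profile with every drug-sensitivity profile.

    Returns a DataFrame indexed by drug with columns r, p_two_sided,
    n_used, significant (P < alpha). Constant drugs are dropped.
    """
    shared = [s for s in panel.cell_lines if s in set(invasion.cell_lines)]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared cell lines; >= 3 required")
    y = invasion.icc.loc[shared].to_numpy(dtype=float)
    X = panel.sensitivity[shared].to_numpy()
    if transform:
        X = normal_score_rows(X)
        y = normal_score_transform(y).values
    r, p, n = pearson_rows(X, y)
    out = pd.DataFrame(
        {"r": r, "p_two_sided": p, "n_used": n}, index=panel.drug_ids
    ).dropna(subset=["r"])
    out["significant"] = out["p_two_sided"] < alpha
    return out
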