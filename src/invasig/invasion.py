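"""Invasion-heterogeneity statistics and the two-stage invasion-associated
(IA) probe screen with its confirmation-stage FDR estimator."""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .corrstats import pearson_rows
from .datatypes import ExpressionMatrix, InvasionProfile
from .preprocess import normal_score_rows, normal_score_transform

log = logging.getLogger("invasig")

IA_COLUMNS = [
    "probe_discovery",
    "probe_confirm",
    "gene_symbol",
    "r_discovery",
    "p_discovery",
    "r_confirm",
    "p_confirm",
    "direction",
]


@dataclass
class GroupStats:
    """One-way ANOVA of ICC across tissue groups plus per-line deviations."""

    group_means: pd.Series
    deviations: pd.Series  # per cell line, ICC minus its group mean
    f_statistic: float
    p_value: float
    groups_used: list[str]
    groups_excluded: list[str]


@dataclass
class FdrEstimate:
    """Confirmation-stage FDR: m_confirm_tested * alpha_confirm / k_passed."""

    m_confirm_tested: int
    alpha_confirm: float
    k_passed: int
    fdr: float


def estimate_confirmation_fdr(m_confirm_tested: int, alpha_confirm: float, k_passed: int) -> FdrEstimate:
    """Expected-false-positive FDR estimate for the confirmation stage.

    ``m_confirm_tested`` probes were each tested at the one-sided cutoff
    ``alpha_confirm`` (with sign consistency); ``k_passed`` passed. The
    estimate is m * alpha / k, NaN when nothing passed.
    """
    if not 0 < alpha_confirm < 1:
        raise ValueError(f"alpha_confirm must be in (0,1), got {alpha_confirm}")
    if m_confirm_tested < 0 or k_passed < 0:
        raise ValueError("counts must be nonnegative")
    fdr = math.nan if k_passed == 0 else m_confirm_tested * alpha_confirm / k_passed
    return FdrEstimate(
        m_confirm_tested=int(m_confirm_tested),
        alpha_confirm=float(alpha_confirm),
        k_passed=int(k_passed),
        fdr=fdr,
    )


def invasion_group_stats(profile: InvasionProfile) -> GroupStats:
    """Group means, per-line deviations from group mean and one-way ANOVA.

    The ANOVA runs on the raw ICC scale. Groups with a single cell line
    are excluded from the test with a warning; >= 2 usable groups required.
    """
    icc = profile.icc.astype(float)
    groups = profile.tissue_group
    sizes = groups.value_counts()
    excluded = sorted(sizes.index[sizes < 2].tolist())
    if excluded:
        log.warning("excluding single-line tissue groups from ANOVA: %s", excluded)
    used = sorted(sizes.index[sizes >= 2].tolist())
    if len(used) < 2:
        raise ValueError(f"ANOVA needs >= 2 groups with >= 2 lines, got {len(used)}")
    arrays = [icc[groups == g].to_numpy() for g in used]
    f_stat, p_value = stats.f_oneway(*arrays)
    group_means = icc.groupby(groups).mean()
    deviations = icc - groups.map(group_means)
    return GroupStats(
        group_means=group_means,
        deviations=deviations,
        f_statistic=float(f_stat),
        p_value=float(p_value),
        groups_used=used,
        groups_excluded=excluded,
    )


def correlate_profile(
    expr: ExpressionMatrix,
    phenotype: pd.Series,
    transform: bool = True,
) -> pd.DataFrame:
    """Pearson correlation of every probe with a per-sample phenotype.

    Samples are aligned on the intersection of the matrix columns and the
    phenotype index. With ``transform`` on, each probe and the phenotype
    are normal-scored on their own non-missing support before the
    (pairwise-complete) correlation. Probes with < 3 complete pairs or
    zero variance are dropped and logged.

    Returns a DataFrame indexed by probe with columns r, p_two_sided,
    n_used.
    """
    shared = [s for s in expr.sample_ids if s in set(phenotype.index)]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared samples; >= 3 required")
    X = expr.values[shared].to_numpy()
    y = phenotype.loc[shared].to_numpy(dtype=float)
    if transform:
        X = normal_score_rows(X)
        y = normal_score_transform(y).values
    r, p, n = pearson_rows(X, y)
    out = pd.DataFrame(
        {"r": r, "p_two_sided": p, "n_used": n}, index=expr.probe_ids
    )
    dropped = out.index[out["r"].isna()]
    if len(dropped):
        log.info("dropping %d probes with <3 complete pairs or zero variance", len(dropped))
    return out.dropna(subset=["r"])


def two_stage_ia_selection(
    records_discovery: pd.DataFrame,
    records_confirm: pd.DataFrame,
    pairs: pd.DataFrame,
    p_disc: float = 0.05,
    p_conf: float = 0.025,
) -> tuple[pd.DataFrame, FdrEstimate | None]:
    """Two-stage sign-consistent IA probe selection.

    Stage 1 keeps discovery probes with two-sided ``p < p_disc``. Stage 2
    (confirmation) keeps those whose best mapped partner — largest
    ``|r_confirm|`` among partners with matching sign — satisfies the
    one-sided criterion ``p_confirm < 2 * p_conf`` (two-sided scale) with
    sign agreement. The FDR estimate uses m = probes entering
    confirmation, alpha = ``p_conf``, k = probes passing.

    Parameters
    ----------
    records_discovery, records_confirm
        Output of :func:`correlate_profile` for the two platforms.
    pairs
        DataFrame with columns probe_a (discovery), probe_b (confirm),
        gene_symbol, e.g. :attr:`MatchedPairs.pairs`.
    """
    if not (0 < p_disc < 1 and 0 < p_conf < 1):
        raise ValueError("thresholds must be in (0,1)")
    stage1 = records_discovery.index[records_discovery["p_two_sided"] < p_disc]
    empty = pd.DataFrame(columns=IA_COLUMNS)
    if len(stage1) == 0:
        log.warning("stage 1 retained no probes; FDR undefined")
        return empty, None

    # candidates: stage-1 probes with at least one mapped, measured partner
    cand = pairs[pairs["probe_a"].isin(stage1) & pairs["probe_b"].isin(records_confirm.index)]
    m = cand["probe_a"].nunique()
    if m == 0:
        log.warning("no stage-1 probe has a measured confirmation partner; FDR undefined")
        return empty, None

    rows = []
    for probe_a, grp in cand.groupby("probe_a", sort=True):
        r_d = records_discovery.at[probe_a, "r"]
        p_d = records_discovery.at[probe_a, "p_two_sided"]
        sign_d = 1 if r_d > 0 else -1
        partners = records_confirm.loc[grp["probe_b"].unique()]
        same_sign = partners[np.sign(partners["r"]) == sign_d]
        if same_sign.empty:
            continue
        best = same_sign["r"].abs().idxmax()
        r_c = records_confirm.at[best, "r"]
        p_c = records_confirm.at[best, "p_two_sided"]
        if p_c < 2 * p_conf:
            gene = grp.loc[grp["probe_b"] == best, "gene_symbol"].iloc[0]
            rows.append((probe_a, best, gene, r_d, p_d, r_c, p_c, sign_d))

    table = pd.DataFrame(rows, columns=IA_COLUMNS)
    fdr = estimate_confirmation_fdr(m, p_conf, len(table))
    return table, fdr


def partition_by_sign(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split an IA table into (negative, positive) panels.

    Panels are disjoint, their union is the input, and each is ordered by
    ``|r_discovery|`` descending.
    """
    if table.empty:
        raise ValueError("IA table is empty")
    order = table["r_discovery"].abs().sort_values(ascending=False, kind="mergesort").index
    ordered = table.loc[order]
    negative = ordered[ordered["direction"] < 0]
    positive = ordered[ordered["direction"] > 0]
    return negative, positive
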