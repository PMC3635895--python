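"""Validation of the signature on labeled cell-line panels and survival
cohorts: two-group t-tests, Kaplan-Meier / log-rank, multivariate Cox."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CohortTable

log = logging.getLogger("invasig")


@dataclass
class GroupComparison:
    """Two-sample t-test result between labeled groups of scores."""

    group_labels: tuple[str, str]
    means: tuple[float, float]
    t_statistic: float
    p_two_sided: float
    n: tuple[int, int]
    welch: bool


@dataclass
class CoxResult:
    """Per-covariate Cox fit summary; ``converged`` is False on failure."""

    summary: pd.DataFrame | None  # columns: coef, hr, ci_low, ci_high, p
    converged: bool
    n: int
    n_events: int
    message: str = ""


@dataclass
class SurvivalReport:
    """KM curves per risk group plus log-rank test, optionally a Cox fit."""

    km: dict[str, pd.DataFrame]
    logrank_chi2: float
    logrank_p: float
    cox: CoxResult | None = None


def compare_groups(
    scores: pd.Series, labels: pd.Series, welch: bool = True
) -> GroupComparison:
    """Two-sided two-sample t-test of scores between two labeled groups.

    Welch (unequal variance) by default; set ``welch=False`` for the
    pooled-variance Student form. Both groups need >= 2 members.
    """
    labels = labels.loc[scores.index]
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError(f"exactly 2 group labels required, got {uniq}")
    a = scores[labels == uniq[0]].to_numpy(dtype=float)
    b = scores[labels == uniq[1]].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"both groups need >= 2 members, got {len(a)} and {len(b)}")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return GroupComparison(
        group_labels=(uniq[0], uniq[1]),
        means=(float(a.mean()), float(b.mean())),
        t_statistic=float(t),
        p_two_sided=float(p),
        n=(len(a), len(b)),
        welch=welch,
    )


def remove_overlap_and_retest(
    scores: pd.Series,
    labels: pd.Series,
    exclude_ids,
    welch: bool = True,
) -> GroupComparison:
    """Re-run the group comparison after excluding overlapping samples."""
    exclude = set(exclude_ids)
    keep = [s for s in scores.index if s not in exclude]
    removed = len(scores) - len(keep)
    if removed:
        log.info("removed %d overlapping samples before re-test", removed)
    return compare_groups(scores.loc[keep], labels.loc[keep], welch=welch)


def km_curve(times, events) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns one row per distinct event time with columns time, n_at_risk,
    n_events, survival. The curve starts at 1 before the first event and
    is nonincreasing.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    order = np.argsort(times, kind="mergesort")
    times, events = times[order], events[order]
    rows = []
    surv = 1.0
    n = len(times)
    for t in np.unique(times[events == 1]):
        at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        surv *= 1.0 - d / at_risk
        rows.append((float(t), at_risk, d, surv))
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Unstratified two-group log-rank test (1 df chi-square).

    Uses the standard observed-minus-expected statistic with the
    hypergeometric variance at each distinct event time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {len(uniq)}")
    g1 = groups == uniq[0]
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n_tot = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        d_tot = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & g1).sum())
        e1 = d_tot * n1 / n_tot
        o_minus_e += d1 - e1
        if n_tot > 1:
            var += d_tot * (n1 / n_tot) * (1 - n1 / n_tot) * (n_tot - d_tot) / (n_tot - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def km_logrank(cohort: CohortTable, groups: pd.Series) -> SurvivalReport:
    """KM curves per risk group and the two-group log-rank test.

    Warns when a group has no events; the test still runs as long as at
    least one event exists overall.
    """
    data = cohort.data
    groups = groups.loc[data.index]
    km = {}
    for g, sub in data.groupby(groups):
        if sub["event"].sum() == 0:
            log.warning("group %r has no events", g)
        km[str(g)] = km_curve(sub["time"], sub["event"])
    if data["event"].sum() < 1:
        raise ValueError("no events in cohort; log-rank undefined")
    chi2, p = logrank_test(data["time"], data["event"], groups)
    return SurvivalReport(km=km, logrank_chi2=chi2, logrank_p=p)


def cox_multivariate(
    cohort: CohortTable,
    covariates,
    ties: str = "efron",
    alpha: float = 0.05,
) -> CoxResult:
    """Multivariate Cox proportional-hazards fit via partial likelihood.

    Complete-case analysis on the listed covariate columns; Efron tie
    handling by default ('breslow' available). Non-convergence is flagged
    in the result rather than raised.
    """
    import lifelines
    from lifelines.exceptions import ConvergenceError

    covariates = list(covariates)
    df = cohort.data[["time", "event"] + covariates].dropna()
    n_excluded = len(cohort.data) - len(df)
    if n_excluded:
        log.info("complete-case Cox analysis excluded %d patients", n_excluded)
    for cov in covariates:
        col = df[cov]
        if not pd.api.types.is_numeric_dtype(col):
            raise ValueError(f"covariate {cov!r} must be numeric (encode factors first)")
        if col.nunique() <= 1:
            raise ValueError(f"covariate {cov!r} is constant")
    n_events = int(df["event"].sum())
    if n_events < len(covariates) + 5:
        raise ValueError(
            f"too few events ({n_events}) for {len(covariates)} covariates"
        )
    fitter = lifelines.CoxPHFitter(alpha=alpha)
    try:
        fitter.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, ValueError) as exc:
        log.warning("Cox fit failed to converge: %s", exc)
        return CoxResult(summary=None, converged=False, n=len(df), n_events=n_events, message=str(exc))
    s = fitter.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "ci_low": np.exp(s["coef lower 95%"]),
            "ci_high": np.exp(s["coef upper 95%"]),
            "p": s["p"],
        }
    )
    return CoxResult(summary=summary, converged=True, n=len(df), n_events=n_events)


def control_cohort_run(cohorts, score_groups) -> tuple[dict[str, SurvivalReport], pd.DataFrame]:
    """Run the identical KM/log-rank pipeline over several cohorts.

    Parameters
    ----------
    cohorts
        Mapping name -> (CohortTable, treated flag).
    score_groups
        Mapping name -> per-patient high/low group Series.

    Returns per-cohort reports plus a specificity summary table
    (cohort, treated, logrank_p, status); per-cohort failures are
    recorded, not propagated.
    """
    reports: dict[str, SurvivalReport] = {}
    rows = []
    for name, (cohort, treated) in cohorts.items():
        try:
            report = km_logrank(cohort, score_groups[name])
            reports[name] = report
            rows.append((name, bool(treated), report.logrank_p, "ok"))
        except (ValueError, KeyError) as exc:
            log.warning("cohort %s skipped: %s", name, exc)
            rows.append((name, bool(treated), np.nan, f"skipped: {exc}"))
    summary = pd.DataFrame(rows, columns=["cohort", "treated", "logrank_p", "status"])
    return reports, summary
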