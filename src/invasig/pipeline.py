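"""Pipeline configuration and the end-to-end orchestrator."""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clinical, invasion, pharmaco, signature
from .preprocess import match_probes
from .simulate import StudyBundle, simulate_study

log = logging.getLogger("invasig")


class ConfigError(ValueError):
    """A pipeline configuration value is out of range."""


@dataclass
class PipelineConfig:
    """Every threshold and switch of a full run, loadable from one YAML file."""

    seed: int = 0
    p_discovery: float = 0.05
    p_confirmation: float = 0.025
    p_gene_drug: float = 0.05
    sd_quantile: float = 0.9
    transform_phenotype: bool = True
    transform_drug: bool = True
    discovery_platform: str = "A"
    standardize_risk: bool = True
    threshold_rule: str = "mean"
    welch: bool = True
    simulation: dict = field(default_factory=dict)

    def validate(self) -> "PipelineConfig":
        for name in ("p_discovery", "p_confirmation", "p_gene_drug", "sd_quantile"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must be in (0,1), got {v}")
        if self.discovery_platform not in ("A", "B"):
            raise ConfigError(f"discovery_platform must be 'A' or 'B', got {self.discovery_platform!r}")
        if self.threshold_rule not in ("mean", "median"):
            raise ConfigError(f"threshold_rule must be 'mean' or 'median', got {self.threshold_rule!r}")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw).validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


STAGE_ORDER = ("simulate", "invasion_assoc", "gene_drug", "signature", "validate_cells", "survival")


def run_pipeline(
    config: PipelineConfig,
    outdir,
    bundle: StudyBundle | None = None,
    until: str | None = None,
) -> dict:
    """Run the pipeline stages in order on a (simulated) study.

    Writes to ``outdir``: ia_table.csv, gene_drug_r.csv, gene_drug_p.csv,
    drug_counts.csv, signature.csv, risk_scores.csv, survival_report.csv
    (plus survival_km.csv and validation_ttest.csv). Returns a dict of
    in-memory results. Any stage failure raises :class:`StageError`
    naming the stage. ``until`` stops after the named stage.
    """
    config.validate()
    if until is not None and until not in STAGE_ORDER:
        raise ConfigError(f"unknown stage {until!r}; choose from {STAGE_ORDER}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    def _sim():
        nonlocal bundle
        if bundle is None:
            log.info("simulating study with seed %d", config.seed)
            bundle = simulate_study(seed=config.seed, **config.simulation)
        results["bundle"] = bundle

    def _ia():
        try:
            gs = invasion.invasion_group_stats(bundle.invasion)
            log.info("invasion ANOVA: F=%.3f, P=%.4f", gs.f_statistic, gs.p_value)
        except ValueError as exc:
            log.warning("invasion group ANOVA skipped: %s", exc)
        disc, conf = bundle.expr_a, bundle.expr_b
        pairs = match_probes(disc, conf, bundle.probe_map).pairs
        if config.discovery_platform == "B":
            disc, conf = conf, disc
            pairs = pairs.rename(columns={"probe_a": "probe_b", "probe_b": "probe_a"})
        log.info("discovery platform: %s", disc.platform_id)
        rec_d = invasion.correlate_profile(disc, bundle.invasion.icc, transform=config.transform_phenotype)
        rec_c = invasion.correlate_profile(conf, bundle.invasion.icc, transform=config.transform_phenotype)
        log.info(
            "two-stage selection at p_disc=%g, p_conf=%g", config.p_discovery, config.p_confirmation
        )
        ia_table, fdr = invasion.two_stage_ia_selection(
            rec_d, rec_c, pairs, config.p_discovery, config.p_confirmation
        )
        if fdr is not None:
            log.info("confirmation FDR = %d*%g/%d = %.4f", fdr.m_confirm_tested, fdr.alpha_confirm, fdr.k_passed, fdr.fdr)
        results["ia_table"], results["fdr"] = ia_table, fdr
        ia_table.to_csv(outdir / "ia_table.csv", index=False)

    def _gd():
        panel = pharmaco.filter_inactive_drugs(bundle.drugs)
        results["drug_panel"] = panel
        probes = results["ia_table"]["probe_discovery"].tolist()
        if not probes:
            raise ValueError("no IA probes; cannot correlate with drugs")
        expr = (bundle.expr_a if config.discovery_platform == "A" else bundle.expr_b).subset_probes(probes)
        gdm = pharmaco.gene_drug_correlations(expr, panel, transform=config.transform_drug)
        counts = pharmaco.count_significant(gdm, panel.mechanism, config.p_gene_drug)
        results["gene_drug"], results["counts"] = gdm, counts
        gdm.r.to_csv(outdir / "gene_drug_r.csv", index_label="probe")
        gdm.p.to_csv(outdir / "gene_drug_p.csv", index_label="probe")
        out = pd.DataFrame({"mechanism_class": counts.mechanism, "n_significant": counts.counts})
        out.to_csv(outdir / "drug_counts.csv", index_label="drug_id")
        focal = [d for d in bundle.focal_drugs if d in gdm.drugs]
        if len(focal) >= 2:
            sim = pharmaco.drug_profile_similarity(gdm, focal)
            sim.to_csv(outdir / "drug_similarity.csv", index_label="drug_id")
        inv_drug = pharmaco.invasion_drug_correlation(
            bundle.invasion, panel, transform=config.transform_drug
        )
        inv_drug.to_csv(outdir / "invasion_drug.csv", index_label="drug_id")
        results["invasion_drug"] = inv_drug

    def _sig():
        gdm = results["gene_drug"]
        sets = pharmaco.significant_probe_sets(gdm, config.p_gene_drug)
        common = signature.intersect_drug_correlated(sets, bundle.focal_drugs)
        log.info("%d probes common to all %d focal drugs", len(common), len(bundle.focal_drugs))
        ordered = [p for p in results["ia_table"]["probe_discovery"] if p in common]
        on_chip = signature.filter_platform(ordered, bundle.chip_membership)
        log.info("%d probes on the designated chip", len(on_chip))
        expr = bundle.expr_a if config.discovery_platform == "A" else bundle.expr_b
        high_sd = signature.filter_by_sd(expr, on_chip, config.sd_quantile)
        log.info("%d probes pass the SD top-%d%% filter", len(high_sd), round(100 * (1 - config.sd_quantile)))
        consistent = signature.filter_direction_consistency(high_sd, gdm, bundle.expected_signs)
        log.info("%d probes direction-consistent across focal drugs", len(consistent))
        annotation = bundle.probe_map.gene_of()
        if config.discovery_platform == "B":
            annotation = dict(zip(bundle.probe_map.table["probe_b"], bundle.probe_map.table["gene_symbol"]))
        class_signs = {"tubulin_binding": -1, "targeted": +1}
        sig = signature.collapse_probes_to_genes(
            consistent, annotation, signature.probe_sds(expr), class_signs
        )
        results["signature"] = sig
        out = sig.table.copy()
        for cls, sgn in sig.class_signs.items():
            out[f"sign_{cls}"] = sgn
        out.to_csv(outdir / "signature.csv", index=False)

    def _val():
        sig = results["signature"]
        avail = [g for g in sig.genes if g in bundle.validation_expr.probe_ids]
        if not avail:
            raise ValueError("no signature gene measured on the validation panel")
        if len(avail) < len(sig.genes):
            log.warning("validation panel misses %d signature genes", len(sig.genes) - len(avail))
        scores = signature.compute_risk_score(
            bundle.validation_expr.values, avail,
            standardize=config.standardize_risk, threshold_rule=config.threshold_rule,
        )
        comparison = clinical.compare_groups(scores.scores, bundle.validation_labels, welch=config.welch)
        results["validation_scores"], results["validation_ttest"] = scores, comparison
        out = scores.table.copy()
        out["label"] = bundle.validation_labels
        out.to_csv(outdir / "risk_scores.csv", index_label="sample_id")
        pd.DataFrame(
            [{
                "group_a": comparison.group_labels[0], "group_b": comparison.group_labels[1],
                "mean_a": comparison.means[0], "mean_b": comparison.means[1],
                "t": comparison.t_statistic, "p_two_sided": comparison.p_two_sided,
                "n_a": comparison.n[0], "n_b": comparison.n[1],
            }]
        ).to_csv(outdir / "validation_ttest.csv", index=False)

    def _surv():
        sig = results["signature"]
        cohort = bundle.cohort
        avail = [g for g in sig.genes if g in cohort.gene_cols]
        if not avail:
            raise ValueError("no signature gene measured on the cohort")
        scores = signature.compute_risk_score(
            cohort.data[avail].T, avail,
            standardize=config.standardize_risk, threshold_rule=config.threshold_rule,
        )
        log.info("risk threshold (%s) = %.4f", scores.threshold_rule, scores.threshold)
        report = clinical.km_logrank(cohort, scores.groups)
        cohort_cox = cohort.data.assign(high_risk=(scores.groups == "high").astype(int))
        from .datatypes import CohortTable

        cox_cohort = CohortTable(cohort_cox, cohort.gene_cols, cohort.covariate_cols)
        report.cox = clinical.cox_multivariate(
            cox_cohort, ["high_risk", *cohort.covariate_cols]
        )
        results["survival"] = report
        km_rows = []
        for grp, curve in sorted(report.km.items()):
            km_rows.append(curve.assign(group=grp))
        pd.concat(km_rows, ignore_index=True).to_csv(outdir / "survival_km.csv", index=False)
        lines = [{"variable": "logrank_chi2", "value": report.logrank_chi2},
                 {"variable": "logrank_p", "value": report.logrank_p}]
        frame = pd.DataFrame(lines)
        if report.cox.converged:
            cox_out = report.cox.summary.reset_index(names="variable")
            frame = pd.concat([frame, cox_out], ignore_index=True)
        frame.to_csv(outdir / "survival_report.csv", index=False)

    stages = {
        "simulate": _sim,
        "invasion_assoc": _ia,
        "gene_drug": _gd,
        "signature": _sig,
        "validate_cells": _val,
        "survival": _surv,
    }
    for name in STAGE_ORDER:
        log.info("stage %s starting", name)
        try:
            stages[name]()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise StageError(name, exc) from exc
        if name == until:
            break
    return results
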