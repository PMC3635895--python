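"""Synthetic input generators with planted, recorded ground truth.

A single latent invasion variable per cell line drives the invaded cell
count (log-normal with small tissue-group offsets) and every planted
probe on both platforms. Drug sensitivities are planted against the
standardized signature score so that gene-drug correlations hit a
requested population value with a per-mechanism-class sign (the
anti-microtubule vs targeted-therapy sign flip). All generators are pure
functions of (parameters, seed).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datatypes import CohortTable, DrugPanel, ExpressionMatrix, InvasionProfile, ProbeMap

DEFAULT_VALIDATION_GENES = tuple(f"G{i}" for i in range(1, 9))


@dataclass
class DrugAssoc:
    """Planted gene-drug association for one mechanism class."""

    sign: int  # expected correlation sign between signature genes and the class
    effect_r: float  # target population gene-drug correlation magnitude
    probes: tuple[str, ...] = ()


@dataclass
class SimulationTruth:
    """Everything that was planted, for downstream parameter-recovery tests."""

    planted_ia_probes: set[tuple[str, int]] = field(default_factory=set)
    planted_drug_assoc: dict[str, set[tuple[str, int]]] = field(default_factory=dict)
    signature_genes: list[str] = field(default_factory=list)
    signature_probes: list[str] = field(default_factory=list)
    class_signs: dict[str, int] = field(default_factory=dict)
    score_shift: float | None = None
    cohort_log_hazard: float | None = None
    latents: dict[str, pd.Series] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Flat (item, kind, sign, effect) view for writing alongside inputs."""
        rows = [("ia_probe", p, s, np.nan) for p, s in sorted(self.planted_ia_probes)]
        for drug, assoc in sorted(self.planted_drug_assoc.items()):
            for probe, sign in sorted(assoc):
                rows.append(("drug_assoc:" + drug, probe, sign, np.nan))
        for gene in self.signature_genes:
            rows.append(("signature_gene", gene, 0, np.nan))
        if self.score_shift is not None:
            rows.append(("score_shift", "", 0, self.score_shift))
        if self.cohort_log_hazard is not None:
            rows.append(("cohort_log_hazard", "", 0, self.cohort_log_hazard))
        return pd.DataFrame(rows, columns=["kind", "item", "sign", "effect"])


def _cell_line_ids(n: int) -> list[str]:
    return [f"CL{i:03d}" for i in range(1, n + 1)]


def simulate_cell_line_panel(
    n_lines: int = 53,
    n_groups: int = 8,
    n_probes_a: int = 2000,
    n_probes_b: int = 2000,
    n_planted: int = 50,
    effect_r: float = 0.6,
    seed: int = 0,
    n_signature: int = 0,
    signature_scale: float = 3.0,
    frac_many_to_many: float = 0.0,
    group_offset_sd: float = 0.2,
) -> tuple[ExpressionMatrix, ExpressionMatrix, ProbeMap, InvasionProfile, SimulationTruth]:
    """Two probe-mapped expression platforms plus an invasion profile.

    The first ``n_signature`` planted probes form a positive-sign,
    high-variance signature block; the rest get random signs. Planted
    probes have population correlation ``+/- effect_r`` with the latent
    invasion variable on BOTH platforms with matching sign. Platform-B
    values undergo a per-probe affine distortion, so only rank structure
    is shared across platforms.
    """
    if min(n_lines, n_groups, n_probes_a, n_probes_b) <= 0:
        raise ValueError("counts must be positive")
    n_genes = min(n_probes_a, n_probes_b)
    if n_planted > n_genes:
        raise ValueError(f"n_planted={n_planted} exceeds mapped gene count {n_genes}")
    if n_signature > n_planted:
        raise ValueError(f"n_signature={n_signature} exceeds n_planted={n_planted}")
    if not 0 < effect_r < 1:
        raise ValueError(f"effect_r must be in (0,1), got {effect_r}")
    rng = np.random.default_rng(seed)

    lines = _cell_line_ids(n_lines)
    groups = [f"T{(i % n_groups) + 1}" for i in range(n_lines)]
    u = rng.standard_normal(n_lines)  # latent invasion variable
    offsets = rng.normal(0.0, group_offset_sd, n_groups)
    log_icc = 6.5 + np.array([offsets[int(g[1:]) - 1] for g in groups]) + u
    invasion = InvasionProfile(
        pd.DataFrame(
            {"icc": np.exp(log_icc), "tissue_group": groups},
            index=pd.Index(lines, name="cell_line"),
        )
    )

    genes = [f"GENE{i:05d}" for i in range(1, n_genes + 1)]
    probes_a = [f"A{i:05d}_at" for i in range(1, n_probes_a + 1)]
    probes_b = [f"B{i:05d}_at" for i in range(1, n_probes_b + 1)]

    signs = np.zeros(n_probes_a, dtype=int)
    signs[:n_signature] = 1
    signs[n_signature:n_planted] = rng.choice([-1, 1], size=n_planted - n_signature)

    def platform_block(n_probes: int) -> np.ndarray:
        noise = rng.standard_normal((n_probes, n_lines))
        X = noise.copy()
        k = math.sqrt(1.0 - effect_r**2)
        for j in range(n_planted):
            X[j] = signs[j] * effect_r * u + k * noise[j]
        X[:n_signature] *= signature_scale
        return X

    Xa = platform_block(n_probes_a)
    Xb = platform_block(n_probes_b)
    # platform-specific affine distortion: positive scale + shift per probe
    scale_b = rng.uniform(0.5, 2.0, n_probes_b)[:, None]
    shift_b = rng.normal(0.0, 1.0, n_probes_b)[:, None]
    Xb = scale_b * Xb + shift_b

    expr_a = ExpressionMatrix("A", pd.DataFrame(Xa, index=probes_a, columns=lines))
    expr_b = ExpressionMatrix("B", pd.DataFrame(Xb, index=probes_b, columns=lines))

    map_rows = [(probes_a[i], probes_b[i], genes[i]) for i in range(n_genes)]
    if frac_many_to_many > 0:
        n_extra = int(round(frac_many_to_many * n_genes))
        extra_idx = rng.choice(n_genes, size=n_extra, replace=False)
        for i in sorted(extra_idx):
            # second platform-B probe for the same gene: independent draw
            dup_id = f"B{i + 1:05d}x_at"
            if i < n_planted:
                vals = signs[i] * effect_r * u + math.sqrt(1 - effect_r**2) * rng.standard_normal(n_lines)
            else:
                vals = rng.standard_normal(n_lines)
            expr_b.values.loc[dup_id] = vals
            map_rows.append((probes_a[i], dup_id, genes[i]))
    probe_map = ProbeMap(pd.DataFrame(map_rows, columns=["probe_a", "probe_b", "gene_symbol"]))

    truth = SimulationTruth(
        planted_ia_probes={(probes_a[j], int(signs[j])) for j in range(n_planted)},
        signature_genes=genes[:n_signature],
        signature_probes=probes_a[:n_signature],
        latents={"invasion": pd.Series(u, index=lines)},
    )
    if n_signature:
        sig_block = Xa[:n_signature].mean(axis=0)
        score = (sig_block - sig_block.mean()) / sig_block.std(ddof=1)
        truth.latents["signature_score"] = pd.Series(score, index=lines)
    return expr_a, expr_b, probe_map, invasion, truth


def score_gene_correlation(effect_r: float, n_genes: int) -> float:
    """Population correlation between the mean of ``n_genes`` equally
    loaded probes and any single one of them."""
    return math.sqrt(effect_r**2 + (1.0 - effect_r**2) / n_genes)


def simulate_drug_panel(
    n_drugs: int = 106,
    mechanism_classes: Mapping[str, int] | None = None,
    n_inactive: int = 7,
    assoc_spec: Mapping[str, DrugAssoc] | None = None,
    seed: int = 0,
    cell_lines: Sequence[str] | None = None,
    latent: pd.Series | None = None,
    latent_gene_corr: float = 1.0,
    truth: SimulationTruth | None = None,
) -> tuple[DrugPanel, SimulationTruth]:
    """Drug-sensitivity panel with planted per-class gene-drug structure.

    Exactly ``n_inactive`` drugs get a constant (floor) profile. For a
    class with an :class:`DrugAssoc`, each active drug is generated as
    ``sign * rho * latent + noise`` with ``rho = effect_r /
    latent_gene_corr``, so its population correlation with each planted
    probe equals ``sign * effect_r`` (``latent_gene_corr`` is the
    latent-to-probe correlation, 1.0 when the latent IS the probe signal).
    """
    if mechanism_classes is None:
        if n_drugs < 17:
            raise ValueError("default mechanism classes need n_drugs >= 17")
        mechanism_classes = {
            "tubulin_binding": 8,
            "targeted": 9,
            "other": n_drugs - 17,
        }
    if sum(mechanism_classes.values()) != n_drugs:
        raise ValueError(
            f"class sizes sum to {sum(mechanism_classes.values())}, expected {n_drugs}"
        )
    if n_inactive > n_drugs:
        raise ValueError(f"n_inactive={n_inactive} exceeds n_drugs={n_drugs}")
    assoc_spec = dict(assoc_spec or {})
    rng = np.random.default_rng(seed)

    if cell_lines is None:
        cell_lines = _cell_line_ids(53 if latent is None else len(latent))
    cell_lines = list(cell_lines)
    n_lines = len(cell_lines)
    if latent is None:
        latent = pd.Series(rng.standard_normal(n_lines), index=cell_lines)
    S = latent.loc[cell_lines].to_numpy(dtype=float)

    drug_ids: list[str] = []
    mech: list[str] = []
    for cls, size in mechanism_classes.items():
        for i in range(1, size + 1):
            drug_ids.append(f"{cls}_{i:03d}")
            mech.append(cls)
    inactive_ids = set(drug_ids[-n_inactive:]) if n_inactive else set()

    values = np.empty((n_drugs, n_lines))
    for i, (drug, cls) in enumerate(zip(drug_ids, mech)):
        if drug in inactive_ids:
            values[i] = 4.0  # constant floor: inactive in every cell line
            continue
        assoc = assoc_spec.get(cls)
        if assoc is not None:
            rho = assoc.effect_r / latent_gene_corr
            if rho > 1:
                raise ValueError(
                    f"effect_r={assoc.effect_r} unreachable with latent_gene_corr={latent_gene_corr}"
                )
            values[i] = 5.0 + assoc.sign * rho * S + math.sqrt(1 - rho**2) * rng.standard_normal(n_lines)
        else:
            values[i] = 5.0 + rng.standard_normal(n_lines)

    panel = DrugPanel(
        sensitivity=pd.DataFrame(values, index=pd.Index(drug_ids, name="drug_id"), columns=cell_lines),
        mechanism=pd.Series(mech, index=pd.Index(drug_ids, name="drug_id"), name="mechanism_class"),
    )
    truth = truth or SimulationTruth()
    for drug, cls in zip(drug_ids, mech):
        assoc = assoc_spec.get(cls)
        if assoc is not None and drug not in inactive_ids:
            truth.planted_drug_assoc[drug] = {(p, assoc.sign) for p in assoc.probes}
            truth.class_signs[cls] = assoc.sign
    return panel, truth


def simulate_validation_panel(
    n_sensitive: int,
    n_resistant: int,
    score_shift: float,
    seed: int = 0,
    genes: Sequence[str] = DEFAULT_VALIDATION_GENES,
    direction: int = 1,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Sensitive/resistant cell-line panel over the signature genes.

    Per-gene expression is standard normal; the sensitive group's mean is
    shifted so the average-of-genes score differs by ``score_shift``
    standard deviations of the score (direction configurable).
    """
    if n_sensitive <= 0 or n_resistant <= 0:
        raise ValueError("group sizes must be positive")
    rng = np.random.default_rng(seed)
    genes = list(genes)
    k = len(genes)
    n = n_sensitive + n_resistant
    samples = [f"V{i:03d}" for i in range(1, n + 1)]
    labels = pd.Series(
        ["sensitive"] * n_sensitive + ["resistant"] * n_resistant,
        index=samples,
        name="label",
    )
    X = rng.standard_normal((k, n))
    # score = mean of k iid genes has sd 1/sqrt(k); per-gene shift of
    # score_shift/sqrt(k) moves the score by score_shift score-SDs
    X[:, :n_sensitive] += direction * score_shift / math.sqrt(k)
    expr = ExpressionMatrix("validation", pd.DataFrame(X, index=genes, columns=samples))
    return expr, labels


def simulate_survival_cohort(
    n: int,
    log_hr_per_unit_score: float,
    censoring_rate: float = 0.3,
    covariate_spec: Mapping[str, Callable[[np.random.Generator, int], np.ndarray]] | None = None,
    seed: int = 0,
    genes: Sequence[str] = DEFAULT_VALIDATION_GENES,
) -> CohortTable:
    """Survival cohort with a planted proportional-hazards score effect.

    Event times are exponential with hazard proportional to
    ``exp(log_hr_per_unit_score * score)`` for a standard-normal score;
    censoring is independent Uniform(0, M) with M solved so the realized
    censoring fraction approximates ``censoring_rate``. Signature-gene
    columns are noisy copies of the score; covariates are independent of
    the score by default. The true score is kept as column
    ``true_score``.
    """
    if n < 10:
        raise ValueError(f"cohort size must be >= 10, got {n}")
    if not 0 <= censoring_rate < 1:
        raise ValueError(f"censoring_rate must be in [0,1), got {censoring_rate}")
    rng = np.random.default_rng(seed)
    score = rng.standard_normal(n)
    base_rate = 1.0 / 24.0  # per month
    rate = base_rate * np.exp(log_hr_per_unit_score * score)
    T = rng.exponential(1.0 / rate)

    if censoring_rate > 0:
        def realized(M: float) -> float:
            return float(np.mean(np.minimum(T / M, 1.0))) - censoring_rate

        M = brentq(realized, 1e-9, float(T.max()) * 1e6)
        C = rng.uniform(0.0, M, n)
        time = np.minimum(T, C)
        event = (T <= C).astype(int)
    else:
        time, event = T, np.ones(n, dtype=int)

    patients = [f"P{i:04d}" for i in range(1, n + 1)]
    data = pd.DataFrame({"time": time, "event": event}, index=pd.Index(patients, name="patient_id"))
    if covariate_spec is None:
        covariate_spec = {
            "age": lambda r, m: np.round(r.normal(60, 10, m)),
            "stage": lambda r, m: r.integers(1, 3, m),
            "nodal": lambda r, m: r.integers(0, 2, m),
            "er": lambda r, m: r.integers(0, 2, m),
        }
    for name, gen in covariate_spec.items():
        data[name] = gen(rng, n)
    genes = list(genes)
    for g in genes:
        data[g] = score + 0.5 * rng.standard_normal(n)
    data["true_score"] = score
    return CohortTable(
        data=data,
        gene_cols=tuple(genes),
        covariate_cols=tuple(covariate_spec.keys()),
    )


@dataclass
class StudyBundle:
    """All pipeline inputs for one synthetic end-to-end study."""

    expr_a: ExpressionMatrix
    expr_b: ExpressionMatrix
    probe_map: ProbeMap
    invasion: InvasionProfile
    drugs: DrugPanel
    chip_membership: dict[str, bool]
    focal_drugs: list[str]
    expected_signs: dict[str, int]  # focal drug -> expected correlation sign
    validation_expr: ExpressionMatrix
    validation_labels: pd.Series
    cohort: CohortTable
    truth: SimulationTruth


def simulate_study(
    n_lines: int = 53,
    n_groups: int = 8,
    n_probes_a: int = 2000,
    n_probes_b: int = 2000,
    n_planted: int = 8,
    n_signature: int = 8,
    effect_r: float = 0.6,
    drug_effect_r: float = 0.6,
    n_drugs: int = 30,
    n_inactive: int = 2,
    n_validation: tuple[int, int] = (15, 15),
    score_shift: float = 1.5,
    cohort_n: int = 200,
    cohort_log_hr: float = math.log(2.5),
    censoring_rate: float = 0.3,
    frac_offchip: float = 0.2,
    seed: int = 0,
) -> StudyBundle:
    """Compose every generator into one coherent study with shared truth.

    The drug panel is planted against the signature score; tubulin-binding
    drugs get negative, targeted-therapy drugs positive gene-drug
    correlations (the sign-flip block). Five focal drugs (two anti-MT,
    three targeted) drive the signature derivation downstream.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=5)

    expr_a, expr_b, probe_map, invasion, truth = simulate_cell_line_panel(
        n_lines=n_lines,
        n_groups=n_groups,
        n_probes_a=n_probes_a,
        n_probes_b=n_probes_b,
        n_planted=n_planted,
        effect_r=effect_r,
        seed=int(seeds[0]),
        n_signature=n_signature,
    )
    sig_probes = tuple(truth.signature_probes)
    if n_signature:
        latent = truth.latents["signature_score"]
        latent_gene_corr = score_gene_correlation(effect_r, n_signature)
        assoc_spec = {
            "tubulin_binding": DrugAssoc(sign=-1, effect_r=drug_effect_r, probes=sig_probes),
            "targeted": DrugAssoc(sign=+1, effect_r=drug_effect_r, probes=sig_probes),
        }
    else:
        latent, latent_gene_corr, assoc_spec = None, 1.0, {}

    n_other = n_drugs - 17
    if n_other < 0:
        raise ValueError("n_drugs must be >= 17 for the default class layout")
    drugs, truth = simulate_drug_panel(
        n_drugs=n_drugs,
        mechanism_classes={"tubulin_binding": 8, "targeted": 9, "other": n_other},
        n_inactive=n_inactive,
        assoc_spec=assoc_spec,
        seed=int(seeds[1]),
        cell_lines=list(invasion.cell_lines),
        latent=latent,
        latent_gene_corr=latent_gene_corr,
        truth=truth,
    )
    focal = ["tubulin_binding_001", "tubulin_binding_002", "targeted_001", "targeted_002", "targeted_003"]
    expected_signs = {d: (-1 if d.startswith("tubulin") else +1) for d in focal}

    # chip membership: signature probes always on-chip, others drop out
    # with probability frac_offchip (models the U133A/U133B split);
    # covers both platforms so either can serve as discovery
    sig_genes = set(truth.signature_genes)
    sig_any = set(sig_probes) | set(
        probe_map.table.loc[probe_map.table["gene_symbol"].isin(sig_genes), "probe_b"]
    )
    membership = {}
    mrng = np.random.default_rng(int(seeds[2]))
    for probe in list(expr_a.probe_ids) + list(expr_b.probe_ids):
        membership[probe] = (probe in sig_any) or (mrng.random() >= frac_offchip)

    validation_expr, validation_labels = simulate_validation_panel(
        n_validation[0],
        n_validation[1],
        score_shift,
        seed=int(seeds[3]),
        genes=truth.signature_genes or DEFAULT_VALIDATION_GENES,
    )
    truth.score_shift = score_shift

    cohort = simulate_survival_cohort(
        cohort_n,
        cohort_log_hr,
        censoring_rate=censoring_rate,
        seed=int(seeds[4]),
        genes=truth.signature_genes or DEFAULT_VALIDATION_GENES,
    )
    truth.cohort_log_hazard = cohort_log_hr

    return StudyBundle(
        expr_a=expr_a,
        expr_b=expr_b,
        probe_map=probe_map,
        invasion=invasion,
        drugs=drugs,
        chip_membership=membership,
        focal_drugs=focal,
        expected_signs=expected_signs,
        validation_expr=validation_expr,
        validation_labels=validation_labels,
        cohort=cohort,
        truth=truth,
    )
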