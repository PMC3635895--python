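"""Write/read a simulated study bundle as plain text files.

File layout inside a bundle directory::

    expr_a.tsv, expr_b.tsv      expression matrices (tab-delimited)
    probe_map.csv               probe_a, probe_b, gene_symbol
    invasion.csv                cell_line, icc, tissue_group
    drugs.csv                   drug_id, mechanism_class, <cell lines...>
    chip_membership.csv         probe, on_chip
    validation_expr.tsv         signature-gene expression of the panel
    validation_labels.csv       sample_id, label
    cohort.csv                  patient_id, time, event, covariates, genes
    study.yaml                  focal drugs, expected signs, gene columns
    truth.csv                   planted ground truth (kind, item, sign, effect)
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from . import io as iomod
from .simulate import SimulationTruth, StudyBundle


def write_bundle(bundle: StudyBundle, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    iomod.write_expression_matrix(bundle.expr_a, outdir / "expr_a.tsv")
    iomod.write_expression_matrix(bundle.expr_b, outdir / "expr_b.tsv")
    iomod.write_probe_map(bundle.probe_map, outdir / "probe_map.csv")
    iomod.write_invasion_profile(bundle.invasion, outdir / "invasion.csv")
    iomod.write_drug_panel(bundle.drugs, outdir / "drugs.csv")
    pd.DataFrame(
        {"probe": list(bundle.chip_membership), "on_chip": [int(v) for v in bundle.chip_membership.values()]}
    ).to_csv(outdir / "chip_membership.csv", index=False)
    iomod.write_expression_matrix(bundle.validation_expr, outdir / "validation_expr.tsv")
    bundle.validation_labels.rename("label").to_csv(outdir / "validation_labels.csv", index_label="sample_id")
    iomod.write_cohort_table(bundle.cohort, outdir / "cohort.csv")
    meta = {
        "focal_drugs": list(bundle.focal_drugs),
        "expected_signs": {k: int(v) for k, v in bundle.expected_signs.items()},
        "cohort_gene_cols": list(bundle.cohort.gene_cols),
        "cohort_covariate_cols": list(bundle.cohort.covariate_cols),
    }
    with open(outdir / "study.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    bundle.truth.to_frame().to_csv(outdir / "truth.csv", index=False)


def read_bundle(indir) -> StudyBundle:
    indir = Path(indir)
    with open(indir / "study.yaml") as fh:
        meta = yaml.safe_load(fh)
    membership_df = pd.read_csv(indir / "chip_membership.csv")
    labels = pd.read_csv(indir / "validation_labels.csv", index_col="sample_id")["label"]
    return StudyBundle(
        expr_a=iomod.read_expression_matrix(indir / "expr_a.tsv", "A"),
        expr_b=iomod.read_expression_matrix(indir / "expr_b.tsv", "B"),
        probe_map=iomod.read_probe_map(indir / "probe_map.csv"),
        invasion=iomod.read_invasion_profile(indir / "invasion.csv"),
        drugs=iomod.read_drug_panel(indir / "drugs.csv"),
        chip_membership=dict(zip(membership_df["probe"], membership_df["on_chip"].astype(bool))),
        focal_drugs=list(meta["focal_drugs"]),
        expected_signs={k: int(v) for k, v in meta["expected_signs"].items()},
        validation_expr=iomod.read_expression_matrix(indir / "validation_expr.tsv", "validation"),
        validation_labels=labels,
        cohort=iomod.read_cohort_table(
            indir / "cohort.csv", meta["cohort_gene_cols"], meta["cohort_covariate_cols"]
        ),
        truth=SimulationTruth(),  # planted truth lives in truth.csv, not reloaded
    )
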