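# invasig

Integration pipeline for three cell-line data layers — an invasion
phenotype (invaded cell counts), cross-platform gene-expression matrices,
and anti-cancer drug-sensitivity panels — ending in a gene-signature risk
score validated on labeled cell-line panels and survival cohorts.

The pipeline stages:

1. **Invasion-associated (IA) probe screen** — normal-score (rank-based
   inverse normal) transformation, probe-vs-phenotype Pearson
   correlations on two probe-mapped platforms, and a two-stage
   discovery/confirmation selection requiring sign consistency, with a
   confirmation-stage FDR estimate `m x alpha / k`.
2. **Gene–drug profiling** — exclusion of all-inactive drugs, an
   IA-probe x drug correlation matrix (positive r = higher expression,
   more sensitive), per-drug significant-probe counts with
   mechanism-class summaries, drug–drug column correlations, and direct
   invasion–drug correlations.
3. **Signature derivation** — four sequential filters: intersection of
   per-drug significant sets over focal drugs, chip-membership filter,
   top-decile standard-deviation filter over the whole matrix, and
   per-class correlation-sign consistency; probes collapse to one
   max-SD probe per gene.
4. **Validation** — unweighted average risk score, mean-threshold
   dichotomization, Welch/Student t-tests on sensitive-vs-resistant
   panels (with overlap-removal re-test), Kaplan–Meier curves, two-group
   log-rank tests, and multivariate Cox regression (Efron ties).

A first-class synthetic-data module generates every input with planted,
recorded ground truth (latent invasion variable, signed IA probes, a
high-variance signature block, a mechanism-class sign-flip in the drug
panel, score-shifted validation panels, proportional-hazards cohorts), so
every stage has parameter-recovery and null-calibration tests.

## CLI

```sh
invasig run-all --seed 3 --outdir out/            # simulate + all stages
invasig simulate --seed 3 --outdir out/           # write inputs + truth
invasig invasion-assoc --outdir out/              # stages run on the files
invasig gene-drug --outdir out/                   # written by `simulate`
invasig signature --outdir out/
invasig validate-cells --outdir out/
invasig survival --outdir out/
```

All thresholds and switches live in one YAML config (`--config`), e.g.:

```yaml
seed: 3
p_discovery: 0.05
p_confirmation: 0.025
p_gene_drug: 0.05
sd_quantile: 0.9
discovery_platform: A
simulation:
  n_lines: 53
  n_probes_a: 2000
```

Outputs: `ia_table.csv`, `gene_drug_r.csv` / `gene_drug_p.csv`,
`drug_counts.csv`, `drug_similarity.csv`, `invasion_drug.csv`,
`signature.csv`, `risk_scores.csv`, `validation_ttest.csv`,
`survival_km.csv`, `survival_report.csv`. Runs are deterministic given
(config, seed); thresholds are logged to stderr.

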