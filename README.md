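# twinmeth

Twin-based variance decomposition of DNA methylation. Given a beta-value
matrix (CpG sites × individuals), a twin-pair manifest (MZ/DZ, same-sex
pairs) and optional probe annotation / covariates, the package:

- classifies probes as **variable** (middle-80% beta range > 5%) and
  **intermediate** (mean beta in [20%, 80%]), overall and per sex;
- computes per-pair whole-profile correlations and per-site double-entered
  MZ/DZ twin correlations, with an exact binomial sign test evaluated in
  log space (finite `log10 p` even far below float range);
- fits the **ACE model** per site — additive genetic (A), shared
  environment (C), unique environment (E) — by full-information maximum
  likelihood on raw pairs (path-coefficient parameterization, nonnegative
  components by construction), by a summary-statistic fit on the two twin
  correlations, and by the Falconer closed form
  `h2 = 2(rMZ − rDZ)`; X-linked sites are fitted per sex, Y-linked sites
  skipped; arbitrary phenotypes (epigenetic age, cell proportions) are
  accepted in place of sites;
- compares A/C/E distributions across probe strata (Mann–Whitney),
  builds sliding-window positional profiles around the TSS and moving-mean
  level profiles, and tests enrichment against per-probe mQTL flags and
  cross-tissue covariation scores (log-space Fisher exact);
- runs a site-wise exposure **EWAS with cluster-robust (CR1) standard
  errors** over family clusters, and profiles the heritability of the
  resulting DMPs (including the sign test restricted to
  concordant-unexposed pairs);
- generates **synthetic twin cohorts** with known per-site A/C/E truth,
  Hardy–Weinberg mQTL genotypes (MZ-identical, DZ half-shared) and
  family-concordant exposure effects, so every stage can be validated
  against ground truth.

## CLI

Every stage is a subcommand; with no `--config` a bundled fully-simulated
demo config is used (200 sites, 100 MZ / 80 DZ pairs; runs in seconds):

```sh
twinmeth all --out demo_out --seed 1
twinmeth ace --config my_config.yaml
twinmeth --version
```

Outputs land in a fixed layout: `tables/` (ACE results, twin correlations,
probe classes, sign tests, EWAS results, …), `profiles/`, `logs/run.json`
(every count and skipped-stage reason) and `config-echo.yaml`. Reruns with
the same seed are byte-identical. See `src/twinmeth/data/demo.yaml` for the
config schema; `inputs:` (paths to TSV/CSV tables) and `simulation:` are
mutually exclusive. Probe annotation accepts Illumina 450K manifest column
names (`IlmnID`, `CHR`, `MAPINFO`, `UCSC_RefGene_Group`,
`Relation_to_UCSC_CpG_Island`).

## Layout

```
src/twinmeth/
  io.py         validated containers + TSV/CSV readers and writers
  simulate.py   synthetic twin cohorts, sibling genotypes, exposure spikes
  probes.py     per-site summaries, variable/intermediate classification
  similarity.py twin correlations, exact sign test, Welch-on-Fisher-z
  ace.py        FIML / summary / Falconer ACE fits, genome-wide driver
  strata.py     stratum comparisons, profiles, enrichment tests
  ewas.py       cluster-robust OLS, EWAS, DMP heritability report
  pipeline.py   config-driven orchestration
  cli.py        click entry point (`twinmeth`)
tests/          unit, property and acceptance suites (pytest)
scripts/acceptance.py
```
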