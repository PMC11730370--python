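# gutdyn

Temporal analysis of longitudinal gut-microbiome cohorts. `gutdyn`
implements the full analysis graph for a repeated-measures 16S study of
host phenotype divergence — for example, variable antinociceptive
tolerance under chronic drug exposure — together with a synthetic cohort
generator so that every stage is testable without external data.

## What's inside

| Module | Purpose |
| --- | --- |
| `gutdyn.synthetic_cohort` | Longitudinal cohort generator: Dirichlet-multinomial counts with archetype-driven effects (shared dysbiosis drift, group-divergent taxa, phase-specific variance inflation, staggered diversity drops), a random coalescent phylogeny, behavioral and qPCR copy-number tables, and a truth record of every injected effect. Also provides step-series and power-law fixtures. |
| `gutdyn.tables_io` | Count-table data model, taxonomic/abundance filters, genus agglomeration, relative/CLR/presence transforms, shared-membership (Venn) counts, TSV I/O. |
| `gutdyn.diversity` | Shannon diversity, Bray-Curtis, unweighted/weighted (normalized) UniFrac, PCoA, PERMANOVA with pairwise BH-adjusted comparisons, multivariate-dispersion homogeneity test. |
| `gutdyn.changepoint` | Barry-Hartigan product-partition Bayesian change-point model (Gibbs sampler), posterior change-probability flagging, cohort series extraction. |
| `gutdyn.stability` | Taylor power-law fits (`V = aM^b`): Type I cross-population and Type IV within-individual extensions, standardized change-in-slope instability statistic. |
| `gutdyn.diffabund` | Beta-binomial regression with logit links for mean and overdispersion; Wald abundance test, likelihood-ratio variability test, BH FDR, effect-size biomarker ranking. |
| `gutdyn.indicators` | Group-size-corrected indicator values (`sqrt(A*B)`), permutation significance, combinatorial (≤3 taxa) indicator search with pruning, cross-cohort exposure prediction. |
| `gutdyn.phenotype` | %MPE from tail-flick latencies, tolerance classification, dose-response ED50 shift, consumption correlation, butyrate gene-copy capacity. |
| `gutdyn.pipeline_cli` | End-to-end orchestration with per-stage TSV outputs, a consensus biomarker summary, and the `gutdyn` CLI. |

## Test

```bash
python -m pytest -q tests/
```

Unit tests per module plus `tests/test_acceptance.py`, which checks each
acceptance criterion (worked indicator-value examples, the %MPE formula,
power-law and change-point recovery, type-I error calibration of all
permutation/likelihood tests, beta-binomial parameter recovery,
cross-cohort prediction, and end-to-end biomarker recovery). The
statistical criteria use simulation and take a few minutes.

## CLI

```bash
# generate a synthetic cohort (counts, metadata, tree, behavior,
# copy numbers, truth record)
gutdyn simulate --seed 1 --outdir cohort/

# run the full pipeline on a synthetic cohort
gutdyn run --seed 1 --outdir out/
gutdyn run --config pipeline.yaml          # YAML PipelineConfig
gutdyn run --seed 1 --stages diversity,stability --outdir out/

# single-series change-point analysis
gutdyn changepoint --series series.tsv --threshold 0.70 --seed 1

# beta-binomial differential screen on user tables
gutdyn diffabund --counts counts.tsv --metadata metadata.tsv \
    --covariate tolerance --controls phase,batch
```

`gutdyn run` writes one TSV per stage (each with a `# stage=...` header
recording parameters), a run log, and `consensus.tsv` listing taxa
flagged by at least two independent methods.

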