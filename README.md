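# epimsap

Population epigenetics of methylation-sensitive AFLP (MSAP) data.

MSAP profiles each sample twice with the isoschizomers HpaII and MspI,
which share the CCGG recognition site but differ in cytosine-methylation
sensitivity. `epimsap` converts the paired presence/absence fragment
panels into a three-state *epilocus* matrix (nonmethylated / internally
methylated / externally methylated, with an ambiguous fourth state that
carries no presence call) and runs the downstream population-epigenetic
analyses on it:

- **scoring** — size-range filtering (100–600 bp), duplicate-run
  reproducibility filtering, dual-enzyme truth-table scoring, expanded
  binary epilocus views (`epimsap.scoring`);
- **simulation** — a synthetic-study generator with four combined groups
  (two cytotypes × reproduction modes), group-specific epilocus
  frequencies, planted environmental candidate loci and group-private
  markers, replicate noise, and full generating truth
  (`epimsap.simulate`);
- **diversity** — per-group/per-panel polymorphic, private and Shannon
  statistics, per-individual polymorphic-epilocus counts, chi-square
  goodness of fit (`epimsap.diversity`);
- **differentiation** — one-factor and pairwise ANOVA (Holm-adjusted),
  one-level and hierarchical AMOVA with permutation Phi-statistics,
  locus-by-locus AMOVA, non-metric MDS on Jaccard distances
  (`epimsap.differentiation`);
- **spatial** — haversine distances, stratified Mantel tests, per-locus
  Moran's I with permutation p, Anselin's local Geary's C, geographic and
  environmental weighting schemes (`epimsap.spatial`);
- **environmental association** — per-epilocus univariate logistic
  regression (IRLS) with Wald + likelihood-ratio G model selection and
  Bonferroni/BH multiplicity control (`epimsap.env_assoc`);
- **pipeline/CLI** — a config-driven end-to-end runner with validated
  inputs and byte-reproducible TSV outputs (`epimsap.pipeline`,
  `epimsap.cli`).

## CLI

```sh
# generate a synthetic study (4 panel TSVs + metadata + truth JSON)
epimsap simulate --out demo/

# score dual-enzyme panels (duplicates enable the reproducibility filter)
epimsap score --hpa demo/hpa_rep1.tsv --hpa2 demo/hpa_rep2.tsv \
              --msp demo/msp_rep1.tsv --msp2 demo/msp_rep2.tsv --out scored/

# individual analyses
epimsap diversity --matrix scored/epiloci_expanded.tsv --metadata demo/metadata.tsv --out diversity.tsv
epimsap amova     --matrix scored/epiloci_expanded.tsv --metadata demo/metadata.tsv --out amova.tsv
epimsap nmds      --matrix scored/epiloci_expanded.tsv --out nmds.tsv
epimsap spatial   --matrix scored/epiloci_expanded.tsv --metadata demo/metadata.tsv --out spatial/
epimsap envassoc  --matrix scored/epiloci_expanded.tsv --metadata demo/metadata.tsv --out envassoc.tsv

# or everything from one YAML config
epimsap run --config config.yaml --out results/
```

A minimal config for a fully simulated run:

```yaml
simulate: {}          # default study: 123 samples, 1088 epiloci
n_permutations: 999
seed: 42
```

Real data instead of simulation:

```yaml
inputs:
  hpa_rep1: data/hpa_rep1.tsv
  hpa_rep2: data/hpa_rep2.tsv   # optional duplicate run
  msp_rep1: data/msp_rep1.tsv
  msp_rep2: data/msp_rep2.tsv
  metadata: data/metadata.tsv
```

Panel files are TSV: first column sample IDs, header row locus IDs
(optionally `locus:size_bp`), values 0/1. Metadata needs `group`,
`longitude`, `latitude` plus `ploidy`/`reproduction_mode` and any
environmental columns (`elevation`, `amt`, `ap`).

All output tables are TSV with `#`-prefixed headers carrying the package
version, config hash and seed; reruns with the same config are
byte-identical.

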