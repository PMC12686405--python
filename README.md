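# nitrosip

Analysis pipeline for comparing ammonia- and urea-driven nitrification and
nitrogen assimilation across marine environments:

- **`nitrosip.kinetics`** — oxidation rates from ¹⁵N-product time series:
  OLS slope with a one-sided t test, labeling-fraction correction,
  minimum-detectable-slope detection limits, censoring of non-significant
  rates (to LOD or zero), duplicate-bottle reconciliation, and
  urea-oxidation percentage of total nitrification.
- **`nitrosip.sip`** — single-cell stable-isotope-probing quantification from
  NanoSIMS ROI ion counts: plane-accumulated ¹⁵N/(¹⁴N+¹⁵N) ratios,
  Poisson counting-error and background QC, mean + k·SD ratio detection
  limits, atom-percent excess, and N-based growth rates (linear model,
  exponential behind a switch).
- **`nitrosip.genes`** — marker-gene read classification with the BLAST
  score ratio (accept iff bitscore ≥ 100, identity ≥ 90 %, BSR ≥ 0.9),
  lineage-subset reassignment, RPKM quantification, group gene:amoA
  ratios, and exact-match oligonucleotide probe coverage.
- **`nitrosip.stats`** — urea-N fractions with below-detection policies,
  a two-sample Mann–Whitney–Wilcoxon test (exact null distribution for
  small tie-free samples, tie/continuity-corrected normal approximation
  otherwise), boxplot summaries with two whisker conventions, mean ± SE.
- **`nitrosip.synthetic`** — seeded generators for every input table with
  ground truth attached: linear ¹⁵N accumulation with truncated Gaussian
  noise, Poisson/binomial ion counts, class-conditional alignment hit
  tables, and log-normal nutrient profiles with analytical LOD censoring.
- **`nitrosip.io` / `nitrosip.config` / `nitrosip.pipeline` /
  `nitrosip.cli`** — TSV/FASTA/BLAST-tabular readers and writers, strict
  YAML configuration, atomic end-to-end orchestration and the CLI.

## CLI

```sh
nitrosip run --config config.yaml          # simulate → rates → sip → genes → stats
nitrosip simulate --config config.yaml     # any stage can run individually
nitrosip rates --config config.yaml
nitrosip report --config config.yaml       # print the run report JSON
```

A minimal configuration:

```yaml
outdir: run_output
seed: 1
incubations:
  - {true_rate: 1.0, ambient_substrate: 10.0, tracer_added: 100.0,
     tracer_purity: 0.99, noise_sd: 0.05, timepoints: [0, 3, 6, 12, 24],
     n_replicates: 2, region: Angola_Gyre, treatment: NH4_15N, depth_m: 100}
regions:
  Angola_Gyre: {censoring_policy: lod, reconcile_duplicates: true}
```

Unknown configuration keys are rejected by name; every knob that affects
numbers is explicit in the YAML. All outputs appear atomically in
`outdir` together with `run_report.json` (row counts, QC exclusions with
their triggering rule, config hash).

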