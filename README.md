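# mimicevo

Trait-based mimicry-accuracy scoring and phylogenetic comparative analysis of
continuous trait evolution.

The package covers an end-to-end workflow for studying how a composite
morphological index (here: ant-mimicry accuracy in spiders, scored from nine
biometric traits) evolves on time-calibrated phylogenies:

- **`mimicevo.traits`** — nine per-trait scores in [0, 1] from linear
  specimen measurements and three color-illusion flags, overall accuracy
  (mean of the nine), accuracy categories (nonmimic < 0.15, inaccurate
  0.15–<0.30 split into low/moderate, accurate ≥ 0.30), and cohort summary
  statistics (min/max/mean/sample SD, category and constriction counts).
- **`mimicevo.phylo`** — Newick/NEXUS parsing (dendropy-backed), shared-path
  covariance, OU/EB/lambda branch-length transforms, rerooting at arbitrary
  internal nodes.
- **`mimicevo.models`** — exact ML fitting of BM, single-optimum fixed-root
  OU, early-burst, and white-noise models (Cholesky likelihoods, profile
  optimization with seeded multi-starts), AICc comparison with Akaike
  weights, and phylogenetic half-life ln(2)/α.
- **`mimicevo.fpk`** — bounded trait diffusion under a quartic potential
  V(x) = a·x⁴ + b·x² + c·x on a discretized grid: reversible tridiagonal
  generator, matrix-exponential pruning likelihood, ML fitting, and the
  adaptive landscape ∝ exp(−V) with its optimum.
- **`mimicevo.ancestral`** — ancestral character estimation by rerooting the
  model-transformed tree at each node (GLS root state), Pagel's lambda (ML)
  and Blomberg's K.
- **`mimicevo.sensitivity`** — replication of all fits across a posterior
  tree sample with spread summaries and failure logging.
- **`mimicevo.simulate`** — seeded birth–death tree simulation, exact
  branchwise trait simulation under every supported model (including the FPK
  jump chain), measurement-table synthesis that inverts the scoring formulas
  exactly, and posterior-like branch-length jitter.

## Command line

A `mimicevo` console script exposes the stages:

```sh
mimicevo score       --measurements meas.csv --out scores.tsv
mimicevo fit         --tree tree.nwk --measurements meas.csv --models BM,OU,EB,WN
mimicevo ace         --tree tree.nwk --measurements meas.csv --model OU:0.5
mimicevo signal      --tree tree.nwk --measurements meas.csv
mimicevo landscape   --tree tree.nwk --measurements meas.csv --grid 50
mimicevo sensitivity --trees posterior.nwk --measurements meas.csv --sample-size 100
mimicevo simulate    --n-tips 100 --model OU --alpha 1.0 --seed 7
mimicevo run-all     --config run.yaml        # flags override config keys
```

`run-all` emits a per-specimen score table, a model-comparison table (AICc,
ΔAICc, weights), ancestral node states, signal estimates, the fitted
landscape grid, optional tree-sample sensitivity tables, and a
`manifest.json` carrying the seed and a configuration hash; identical
configurations reproduce byte-identical numeric outputs.

Measurement tables are comma- or tab-separated with the header documented in
`mimicevo.traits.MEASUREMENT_COLUMNS` (one row per specimen: `specimen_id`,
optional `clade`, the thirteen linear measurements in mm, and three 0/1 or
true/false illusion flags).

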