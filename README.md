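# gdref

Two-color microarray expression analysis against a **g**enomic-**D**NA
common **ref**erence, built as a tested, reusable pipeline:

- **Probe processing** — background correction with a surrogate-intensity
  rule (background pixel SD stands in when foreground − background is
  negative or smaller than that SD), log2 Cy3-cDNA / Cy5-gDNA ratios
  (*Mg*), and validity weights (1 for unique gene probes, 10⁻⁶ for
  cross-hybridizing and intergenic probes).
- **Normalization** — weighted cyclic loess (span 0.3, 3 iterations,
  tricube × probe weights) followed by weighted median scaling.
- **Differential expression** — weighted probe-to-gene averaging, one-way
  per-gene linear models over the four developmental stages, empirical-
  Bayes moderated t-statistics (method-of-moments prior on log residual
  variances), and Benjamini–Hochberg FDR per contrast.
- **Selection cascade** — all-contrasts reliability filter (p < 0.05 in
  every MII/MI comparison), ±1 significance threshold, the conserved
  unknown-function candidate tier (±2, conservation > 75%), the ±3 top
  tier, fold-change conversion with mixed reporting precision, MII
  sign-consistency, and transcript–protein concordance classes.
- **qPCR** — ΔΔCt relative quantification (efficiency 2, technical-then-
  biological averaging) and array-vs-qPCR regression concordance.
- **Simulator** — probe-level two-color datasets with known per-gene
  truth (gDNA reference channel, intensity-dependent dye bias, surrogate-
  rule triggering, qPCR Ct tables), written as FeatureExtraction-style TSV.
- **Packaged reference tables** — the printed primer table and the three
  printed per-gene log2 abundance tables, used as fixtures throughout.

## Command line

```sh
# simulate a dataset with known truth
gdref simulate --seed 1 --n-genes 100 --noise-sd 0.2 \
    --effects "{'G0001': {'MII24': 3.0, 'MII48': 3.0, 'MII72': 3.0}}" \
    --out scratch/sim

# run the full pipeline (probe processing -> normalization -> diffexp -> filters)
gdref run --scan-dir scratch/sim/scans --annotation scratch/sim/annotation.tsv \
    --out-dir scratch/sim/out

# or from a flat key=value config file
gdref report --config pipeline.cfg

# apply the top-tier |log2| >= 3 filter to an abundance table
gdref filter --table table3.tsv --top-abs 3

# ddCt relative quantification
gdref qpcr --ct-table ct.tsv --target SCO5898 --reference SCO3878 \
    --calibrator MI16
```

Subcommands `normalize` and `diffexp` operate on the TSV matrix dialect
written by the pipeline (`gdref <cmd> --help` for options).

## Layout

```
src/gdref/
  probes.py     background correction, Mg, weights, matrix assembly
  normalize.py  weighted loess, cyclic loess, weighted median scaling
  diffexp.py    gene summarization, linear models, moderated t, BH
  filters.py    reliability / candidate / top tiers, fold changes, concordance
  qpcr.py       ddCt and platform concordance
  simulate.py   synthetic scan + Ct datasets with known truth
  datasets.py   packaged printed reference tables
  pipeline.py   end-to-end runner and flat config parsing
  cli.py        click entry points
  data/         packaged TSV fixtures
tests/          unit, property and acceptance suites
scripts/acceptance.py
```
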