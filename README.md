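# gliascope

Cell-type-aware transcriptome analysis of mixed CNS tissue microarrays.

## The problem

Bulk expression profiling of spinal cord (or any mixed neural tissue)
confounds two things: *which* cell type drives an mRNA change, and shifts
in the tissue's cell composition itself — in ALS-model mice, motor
neurons are lost while astrocytes and microglia proliferate. `gliascope`
implements the analysis strategy of measuring expression changes in the
mixed tissue, then interpreting every differential gene against an
*integrated cell-type-specific reference*: independently measured
expression profiles of motor neurons, neurons, astrocytes, microglia and
oligodendrocytes placed on a common scale. It also detects *ectopic*
disease expression — a gene induced in a cell type that is not its
healthy home — by contrasting a gene's fold change in an isolated-cell
dataset against the contamination envelope of foreign-type markers.

The package is aimed at computational biologists who want the full chain
as reusable, tested components, exercised end-to-end on synthetic
probe-level data with planted ground truth.

## What it computes

* **MAS5-style normalization** (`gliascope.mas5`): per probeset, the
  signal is `2^B(log2 max(PM_i − IM_i, δ))` where `B` is a one-step Tukey
  biweight and `IM` the ideal mismatch; the detection p-value is a
  one-sided Wilcoxon signed-rank test of the discrimination scores
  `R_i = (PM_i − MM_i)/(PM_i + MM_i)` against `τ = 0.015`, computed by
  exact enumeration of all `2^n` sign assignments for `n ≤ 12` pairs;
  P/M/A calls use `α₁ = 0.04`, `α₂ = 0.06`; each array is scaled so its
  2%-trimmed mean equals 500 — strictly per array, so adding samples
  never changes samples already analyzed.
* **DEG extraction** (`gliascope.deg`): per comparison, probesets must be
  P/M in ≥ 3 of the 6 pooled samples (FLAG-call criterion) and change
  more than 2-fold; Welch t-tests with Benjamini–Hochberg q-values are
  reported, and an FDR gate is optional. Probesets changed in the same
  direction in every comparison are intersected and deduplicated to genes.
* **Cell-type classification** (`gliascope.celltypes`): a gene is enriched
  in a cell type when its reference signal there is ≥ 4× every other
  type's (the Human Protein Atlas criterion, inclusive boundary).
* **Ectopic detection** (`gliascope.ectopic`): gene `g` with home class
  `c` is flagged in a foreign host dataset when
  `FC_g > k · max(FC of c's markers)` and `FC_g > floor`
  (defaults `k = 3`, `floor = 10`).
* **Over-representation** (`gliascope.enrichment`): per category,
  expected `e = m·n/N`, fold enrichment `f = k/e`, upper-tail
  hypergeometric p and BH q.
* **Synthetic data** (`gliascope.synthetic_data`): probe-level simulator
  with planted enriched genes, planted DEGs, composition shifts,
  contamination and ectopic inductions — the ground truth all recovery
  tests score against.

## Worked example

```sh
gliascope run --seed 11 --out-dir demo
```

runs simulate → normalize → DEGs → reference → classify → cross-reference
→ enrichment on a 2,000-gene demo study (60 planted DEGs, three 3v3
comparisons) and prints

```
sensitivity=0.95 fdp=0.0 -> demo/report.json
```

meaning 95% of planted differential genes were recovered with no false
discoveries. `demo/report.json` contains the full scorecard; with seed 11
the recovered 57 genes classify as

```
microglia 31, astrocyte 12, Unclassified 9, motor_neuron 3,
neuron 1, oligodendrocyte 1
```

(the planted majority-microglial mix), the planted ectopic gene is
flagged with no false positives, and the top enrichment row is the
microglial program (fold enrichment ≈ 13.6, q ≈ 3×10⁻³⁰). The same chain
is available programmatically:

```python
from gliascope import RunConfig, run_pipeline
report = run_pipeline(RunConfig(seed=11), "demo")
```

Individual stages are exposed both as library functions
(`normalize_dataset`, `comparison_degs`, `build_reference`,
`detect_ectopic`, `overrepresentation_test`, …) and as CLI subcommands
(`gliascope normalize --intensities X.tsv --layout L.tsv --out expr`,
`gliascope enrich …`).

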