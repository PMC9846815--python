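# Methods

## Normalization model

`gliascope.mas5` implements the classic Affymetrix statistical-algorithms
pipeline for PM/MM expression arrays.

**Signal.** For a probeset with pairs `(PM_i, MM_i)` the specific
background `SB` is the one-step Tukey biweight of `log2(PM_i/MM_i)`
(tuning constant `c = 5`, guard `ε = 1e-4`). The ideal mismatch is
`IM_i = MM_i` when `MM_i < PM_i`; otherwise `PM_i / 2^SB` when
`SB > contrast_tau (0.03)`, else
`PM_i / 2^(contrast_tau / (1 + (contrast_tau − SB)/scale_tau))` with
`scale_tau = 10`, which guarantees `IM_i < PM_i`. The signal is
`2^B(log2 max(PM_i − IM_i, 2⁻²⁰))`. The biweight is one-step (median/MAD
based, no iteration); its denominator is always positive because at least
half the points lie within one MAD of the median.

**Detection.** The discrimination scores `R_i = (PM_i − MM_i)/(PM_i + MM_i)`
are tested one-sidedly against `τ = 0.015` with a Wilcoxon signed-rank
test. Pairs with `R_i = τ` exactly are dropped before ranking (the
standard signed-rank zero convention); midranks break ties. For up to 12
informative pairs — which covers the 11-pair production case — the
p-value is exact: when ranks are untied it is read from the enumerated
null distribution of subset sums of `{1..m}` (equivalent to enumerating
all `2^m` sign assignments, computed once per `m` by dynamic
programming), and tied cases are enumerated directly. Above 12 pairs a
tie- and continuity-corrected normal approximation is used; at the
crossover (`m = 12`) the two agree within 0.01. Calls are P below
`α₁ = 0.04`, M below `α₂ = 0.06`, A otherwise.

**Scaling.** Each array is multiplied by `target / trimmed_mean(signals)`
with a 2% trim that removes `floor(0.02·n)` values from each tail
(deterministic for small `n`) and `target = 500`. Scaling is strictly
per-array — the global-normalization assumption that total measured mRNA
is constant per sample — so previously analyzed arrays are invariant
under dataset growth, which is the property that makes independently
published datasets comparable after re-normalization.

All constants live in `Mas5Params` and can be overridden per run. Zone-
based background correction of the full Affymetrix specification is not
implemented; the simulator's additive background is left in the probe
intensities, with consequences noted under *Limitations*.

## DEG extraction

Each comparison contrasts a mutant against a control group (3 vs 3 by
default). A probeset qualifies when (i) it is called P or M in at least 3
of the 6 pooled samples, (ii) its ratio of group means exceeds 2 in
either direction, and optionally (iii) its Welch-t BH q-value is below
0.05 (`require_fdr`, off by default: the fold-change-plus-detection
filter defines the candidate set, with the test statistics always
reported). The t-test is Welch's (unequal variances) as the conservative
reading of an unspecified unpaired t-test; the degenerate all-constant
case returns p = 1 for equal means and 0 otherwise, by documented
convention. Probesets passing in every comparison *with the same
direction* are intersected (direction consistency is the default reading
of "commonly changed" and can be disabled), then collapsed to genes: per
gene the representative probeset is the one with the largest mean
|log2 FC| across comparisons; probesets without annotation are routed to
an `unannotated` bucket, logged and excluded.

## Integrated cell-type reference

One MAS5-scaled dataset per cell type (motor neurons, neurons,
astrocytes, microglia, oligodendrocytes) is averaged over samples,
collapsed to genes (maximum over a gene's probesets, conservative
against probe dropout) and joined. Classification: a gene belongs to the
cell type whose value is at least `factor = 4` times the runner-up —
inclusive at exactly 4×, since the criterion reads "at least fourfold";
a zero runner-up with a positive maximum classifies to the maximum; ties
at the top and everything else are Unclassified. Classification is
invariant to scaling a gene's whole row but *not* to rescaling one cell
type's column, which is why a common scaling target across datasets is a
validated precondition.

## Ectopic-expression detection

In an isolated-cell dataset contaminated by adjacent cell types, a
foreign-class gene can rise purely through contamination. Markers of the
gene's home class bound that effect: the *contamination envelope* is the
(max, min) fold change of ≥ 2 home-class markers in the host dataset. A
gene is flagged ectopic iff its fold change exceeds `k · envelope_max`
and an absolute floor, with defaults `k = 3` and `floor = 10`. The
multiplier-over-envelope rule is this package's formalization of a
qualitative argument (a ~290-fold rise against a 0.6–8.5-fold marker
envelope); both knobs are exposed. Group means are floored at 4% of the
scaling target before ratios are taken, so genes below the reliable
detection range cannot produce arbitrarily inflated fold changes — the
floor scales with the target, keeping flag decisions invariant to the
common scaling target.

## Over-representation analysis

Flat gene→category maps (categories may overlap; no hierarchy-aware
correction). Per category of size `m` in a universe of `N`, with `n`
input genes and `k` hits: expected `e = m·n/N`, fold enrichment
`f = k/e`, `p = P(X ≥ k)` upper-tail hypergeometric, BH q across the
tested categories. With the whole universe as input, `f = 1` and `p = 1`
for every category.

## Synthetic data: what it emulates

The generator plants known structure at the probe level so every
downstream stage can be scored against truth.

* **Profiles.** Gene base abundances are log-normal (median 200 units,
  σ = 1 in log-e — roughly a 2.7-fold geometric spread, a plausible
  dynamic range on the 500-target scale). A chosen fraction of genes is
  *enriched*: one cell type is set to exactly `enrichment_factor` (default
  5) times the maximum of the other four; all other genes have per-type
  multipliers in U[1, 1.9], so no unenriched gene approaches the 4×
  classification boundary.
* **Tissue samples.** Per-gene abundance is the composition-weighted sum
  over cell types of profile × disease fold change. The default control
  composition (MN 6%, neurons 30%, astrocytes 28%, microglia 10%,
  oligodendrocytes 26%) treats motor neurons as the small minority they
  are in cord; the gliosis composition (2/27/35/18/18) encodes
  motor-neuron loss with astro-/microglial proliferation, and a validator
  enforces that ordering. In the DEG-recovery study both conditions use
  the control weights and planted effects apply uniformly across cell
  types, so the planted tissue fold change equals the planted factor and
  truth is unambiguous; composition-driven marker shifts are exercised by
  their own property test.
* **Probe level.** Each probeset has 11 PM/MM pairs; per-pair affinities
  are drawn once from a log-normal (σ = 0.3) and frozen in the layout, so
  probeset summarization is a genuinely heterogeneous-probe problem.
  `PM = abundance × affinity × LN(cv)` plus an exponential background
  (mean 50 by default); `MM = 0.2 × the realized PM-specific part` plus
  its own background draw, so MM < PM typically but not always and the
  ideal-mismatch branches are exercised. A 5% fraction of genes carries a
  second probeset to exercise deduplication.
* **Isolated cells.** Abundance is `(1 − f) × target profile + f ×
  uniform mixture of the other four types`, `f < 0.5`; disease effects
  apply per cell type before mixing, which is what lets a planted ectopic
  induction escape the contamination envelope.
* **Determinism.** One master integer seed; all sub-streams spawn from a
  `SeedSequence`, making every dataset bit-identical across runs.

What the simulator does **not** model: spatial chip artifacts, RNA
degradation, probe-sequence effects, cross-hybridization between
different genes, and biological replicate-to-replicate variation beyond
the multiplicative noise. Passing recovery tests therefore demonstrate
the correctness and calibration of the analysis chain under its own
assumptions, not performance on real arrays.

## Study sizes and numerical choices

The DEG-recovery study uses 10,000 genes, 200 planted two-sided ≥2.5-fold
effects, three 3v3 comparisons, cv = 0.15 and background 50, averaged
over 20 seeds; the null study is identical with zero planted effects.
The classifier study uses 3,000 genes with 20% planted 5-fold enrichment
and isolated pure datasets, varying cv ∈ {0, 0.1}. The ectopic study uses
1,500 genes with 500 pure home-class genes, 10% contamination, a planted
50-fold induction and home-class marker fold changes spanning 0.6–8.5.
The demonstration pipeline uses 2,000 genes and 60 planted DEGs so a full
run completes in seconds. Fold-change and intersection tie-breaks are
deterministic (stable sorts, lexicographic gene order); trimmed means
trim `floor(trim·n)` per tail; TSV floats are written with 10 significant
digits so stage re-runs are byte-reproducible.

## Limitations

* Without zone background correction, additive background inflates weak
  signals through the ideal-mismatch branch and compresses large
  cross-cell-type ratios for genes whose minority-type expression is
  comparable to the background; with background comparable to a gene's
  weak-type signal, a true 5× enrichment can measure below the 4×
  boundary. The classifier study therefore isolates multiplicative noise;
  the fold-change floor protects ratio-based stages from the same regime.
* The enrichment classifier is a hard threshold; genes near 4× flip
  class under small perturbations by construction, and no uncertainty is
  attached to class labels.
* The ectopic rule assumes the marker panel spans the contamination
  behaviour of its class; a panel of atypical markers shifts the envelope
  and hence the calls. Panels are configurable inputs, not estimates.
* The contamination level of isolated-cell data is a free simulation
  parameter (default 0.1), not an estimate of any real protocol.
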