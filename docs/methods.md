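# Methods

This note records the models, parameter choices and numerical
conventions behind `omproteome`, and what the synthetic benchmarks do
and do not establish about real data.

## Abundance model and imputation

LFQ intensities are treated as a proxy for absolute protein abundance
and stored on the log10 scale; all compositional arithmetic happens on
the linear scale (`10^x`).  A protein's *share* in a sample is its
linear intensity over the sample total; a compartment's share sums the
shares of proteins assigned to it; the *enrichment factor* of a
compartment between two fractions is the ratio of its shares.  Shares
rather than raw sums are compared so that differing total protein loads
between fractions cancel — fraction composition is inherently
compositional.

Cells not quantified by the upstream search engine are imputed as

```
imputed = max(min_detected(sample) − offset, floor)
```

i.e. a value lower than the least abundant quantified protein of that
sample.  The offset defaults to 0.5 log10 units (the convention states
only "lower than"; half a decade keeps imputed points visually and
numerically below the detected cloud without distorting ratios more
than necessary) and the floor to 4.0, the display value for undetected
proteins.  Share denominators exclude undetected cells by default
(`detected_only=True`) so imputation cannot dominate sparse samples;
fold changes, by contrast, use the imputed floors (absent proteins must
contribute a finite ratio) and carry a separate exclusivity flag so
ratio-vs-floor cases remain distinguishable from true ratios.

## Classifier conventions

* "above 8.5" is a strict inequality on log10 LFQ, applied per sample
  (a protein qualifies if any sarkosyl OM sample exceeds it);
  configurable (`strict_threshold`, `lfq_threshold`).
* The preliminary list is the **union** of the LFQ arm and the
  predictor arm (either localization predictor calling OM); an
  intersection would exclude the abundant intracellular proteins the
  fraction demonstrably contains, which is the population the
  confirmation step is designed to filter.
* Criteria: C1 = both localization predictors OM; C2 = lipoprotein
  class (SpII); signal-peptidase-I-cleaved proteins are *not*
  lipoproteins; C3 = beta-barrel category ≥ 1; C4 = no signal peptide
  AND non-classical secretion score > 0.5 (the tool's conventional
  Gram-negative cutoff).  All four are independent; any may fire.
* Fallback: signal peptide without criteria ⇒ periplasmic; otherwise
  the primary (CELLO-style) label is retained.  Proteins with
  extracellular labels are reported under that label, not folded into
  the OM set.
* The genome screen applies the same criteria to proteins never
  detected in a sarkosyl OM sample and flags the resulting calls
  `detected_in_proteomics=False`.

The classifier contains no randomness; identical inputs give identical
calls.

## Condition comparison

One sample per condition is the reference design (replicate averaging
of log10 values is available but off by default).  The fold change is
`10^(log10_a − log10_b)`; "responsive" means strictly greater than
10-fold in either direction.  With single samples the observed log10
difference of a protein with true effect Δ is N(Δ, 2σ²), so the
detection power of the rule is `Φ̄((1−Δ)/σ√2) + Φ((−1−Δ)/σ√2)` — the
closed form the tests check recovered counts against.

## Synthetic generator

The generator is the package's ground-truth instrument, not a fixture.
Defaults define the benchmark study conditions:

| parameter | default | rationale |
|---|---|---|
| n_proteins | 2176 | proteome size of the motivating organism |
| OM proportion | 0.04 | ≈4% of genes encode OM proteins |
| lfq_sd | 0.4 log10 | typical spread of LFQ replicates/mixtures |
| detection limit | 6.0 log10 | realistic censoring; floor stays 4.0 |
| OM mean, sarkosyl fraction | 8.3 (vs 7.0 baseline) | +1.3 log10 ⇒ ~18-fold share enrichment |
| cytoplasmic mean, sarkosyl fraction | 6.0 | detergent depletes cytoplasmic carry-over |
| n_responsive | 23 | responsive OM proteins, ±1.3 log10 (20-fold) |
| n_exclusive_per_condition | 2 | condition-exclusive OM proteins |
| n_pepcterm | 23 | planted sorting signals |
| predictor_error_rate | 0.05 | plausible per-field tool error |

Intensities are log-normal: log10 value ~ N(μ(compartment, fraction) +
condition effect, σ), left-censored at the detection limit (censored ⇒
undetected).  Condition effects are additive on the log10 scale and
applied to mucin-condition samples; glucose is the reference state, so
glucose-side samples follow the unperturbed mixture and admit exact
closed-form expectations.  Exclusive proteins are forced undetected in
the off condition (detection-limit semantics, not zero intensity).  If
censoring empties a sample, the single largest underlying value is
uncensored so every sample retains a detection minimum.

True predictor fields derive from the compartment (OM proteins: both
localization labels OM, barrel with p=0.6, lipoprotein with p=0.3,
signal peptide with p=0.7, non-classical score 0.8 when unsignalled;
periplasmic/extracellular: signal peptide; inner membrane: 2–11 TM
helices).  Corruption replaces a field, with probability ε per field,
by a uniform draw over the other admissible values (booleans flip; the
secretion score resamples Uniform(0, 1)).  The recovery probability of
a true OM protein then has a closed form by enumerating the Bernoulli
attribute combinations against the criteria logic; the tests hold
observed recovery within 3 binomial SD of it.

Sequences are drawn from a fixed background amino-acid frequency table;
planted PEP-CTERM constructs append a hydrophilic linker, the literal
motif, an 18-residue L/I/V/F segment and four K/R residues — inside
every scanner threshold with margin.

**What passing these benchmarks does not show:** real LFQ data have
correlated, intensity-dependent missingness, shared-peptide effects and
between-run normalization issues; real predictor errors are correlated
with sequence properties, not independent per field; real OM proteomes
contain moonlighting cytoplasmic proteins that no statistical model
plants.  The benchmarks validate the *arithmetic and decision logic*,
not biological error rates.

## PEP-CTERM scanner

A transparent heuristic, deliberately not a profile HMM: the canonical
domain models live in curated databases, and counts from this scanner
on real proteomes are not expected to reproduce model-based screens.
Detection requires, within the C-terminal 35 residues: the literal
`PEP` motif; a transmembrane segment starting ≤5 residues after it;
and ≥2 K/R within 10 residues after the segment.  TM segments are
maximal runs of 11-residue Kyte–Doolittle window means ≥1.6 (runs
separated by ≤2 sub-threshold positions are merged), mapped to sequence
coordinates, trimmed of flanking residues with negative per-residue
hydropathy (window smoothing otherwise drags charged flanks into the
segment), and kept when 15–25 (+5 slack) residues long.  Window 11 and
threshold 1.6 are standard sliding-window TM-prediction practice; the
length band covers a single membrane-spanning helix.  Ties go to the
leftmost qualifying motif.  Coordinates are 0-based half-open
internally, 1-based closed in GFF3 output.

## Numerical conventions and edge cases

* Compartment shares must sum to 1 within 1e-9; enrichment requires a
  strictly positive reference share (a zero reference is an error,
  "undefined enrichment", not infinity).
* A sample with no detected values cannot be imputed (no minimum
  exists) and is an error.
* The sucrose-gradient monotonicity sign is the sign of the Spearman
  rank correlation of OM share against gradient index; constant
  profiles give 0.  Duplicate gradient indices are rejected.
* Fold-change thresholds must exceed 1; exactly 10-fold is *not*
  responsive under the strict rule.
* Summary percentages: OM share of the proteome is rounded to one
  decimal; the uncharacterized share of genome-only calls to the
  nearest integer.
* Benchmark problem sizes (2176-protein scenarios, 100-sequence scanner
  controls, 1000-instance invariant sweeps) were chosen so the whole
  suite validates the full paper-scale design in seconds.

## Known limitations

* Single-replicate fold changes have no significance test by design;
  the >10-fold rule is descriptive.
* The enrichment closed form used in tests treats per-compartment
  counts at their expectations (delta method); its SD slightly
  understates multinomial variability, which the 3-SD band absorbs.
* The scanner's hydropathy heuristic cannot distinguish a C-terminal TM
  anchor from a genuine PEP-CTERM context beyond the motif and basic
  cluster; specificity on real proteomes rests on the motif/anatomy
  conjunction, not on evolutionary information.
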