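# Methods

This note documents the models, defaults and design choices behind
`memscreen`, and what the synthetic generators do and do not emulate.

## Triage model

Raw ensemble prediction scores live in [0, 1]; a score of exactly 0 is a
negative prediction. Quantization is done **per model**: zeros map to Q = 0,
and strictly positive scores are ranked (average ranks for ties) among that
model's positive covered scores and binned by empirical quartile,
Q = ⌈4·rank/n⌉/4 ∈ {0.25, 0.5, 0.75, 1}. Consequences worth knowing:

* quantization is scale-free — any strictly increasing transform of a
  model's positive scores leaves its Q column unchanged;
* quartiles are computed within **covered** positive scores of each model,
  not over a fixed target universe; a model that covers few genes spreads
  those few over the four bins.

Aggregation uses the sample standard deviation (divisor c−1, defined as 0
at coverage 1); the population variant is available via
`aggregate_quantiles(..., population_sd=True)`. Genes with zero coverage are
omitted and logged.

Categorization thresholds (defaults): positive mean ≥ 0.5; negative mean
exactly 0 — with Q ≥ 0 this is equivalent to unanimity among covering
models; variable window [0.1, 0.25] inclusive with sd strictly above the
0.9 quantile of sd over genes meeting the coverage floor (7 models). The sd
cutoff is computed with linear interpolation over the eligible genes only,
because the coverage floor applies to every class. With the default windows
the classes are disjoint; a positive > negative > variable precedence
guards custom thresholds. Exclusion (essential genes, genes already
annotated to the target term) relabels to uncategorized; selection is
uniform without replacement within each class, in the fixed class order
positive, negative, variable, from one seeded generator.

## Screen model

Observations are raw egg counts per vial; vials are the biological
replicates. The test is Welch's two-tailed t-test on raw counts per period —
raw counts are the only reading that yields two samples per comparison.
α = 0.05 with no multiple-testing correction across lines by default (the
per-line decision mimics how such screens are scored); Benjamini–Hochberg
q-values are available in the enrichment stage where list-wise control is
conventional. Degenerate inputs: two constant samples with equal means give
t = 0, p = 1; constant samples with different means give t = ±∞, p = 0. The
Welch–Satterthwaite df is computed from the normalized variance fractions
(a + b = 1) so near-constant samples cannot underflow the ratio.

Directionality: a call is Y only for a significant **decrease**; a
significant increase is biologically real (it occurs in the packaged
fixture for the ft- and knrl-like lines) but is scored N with
`direction = increase` retained, since the screen's phenotype is depression.
Genes with acute N are classed acute-required and their memory calls are
reported but not counted as memory-required — without an acute response the
memory contribution cannot be separated. The class partition
(acute-required + memory-required + wild-type = tested) is asserted on every
fit.

Normalized responses for reporting: percent = 100·mean(exposed)/
mean(unexposed); the SEM is the standard error of the per-replicate values
100·exposedᵢ/mean(unexposed). Normalizing each exposed replicate by the
unexposed **mean** (not pairing replicates) is a choice — vials are not
paired in the design — and is recorded in the output metadata.

## Synthetic generators: what they emulate

`simulate_screen` draws negative-binomial counts (size = `dispersion`,
default 10; `math.inf` gives Poisson) around `baseline_mean` = 40 eggs /
vial / 24 h, with 12 replicates per condition. Egg counts per vial are
over-dispersed relative to Poisson — vials share females, food and
micro-environment — hence the negative binomial. Effects are multiplicative
on the exposed mean: 0.5 for a true depression, 1.5 for a true increase.
These magnitudes are not published for the assay; they were fixed once so
that the n = 12 design has power ≈ 0.98 per comparison, comfortably above
0.9, and they are configurable. The memory-period baseline equals the
acute-period baseline (no day-to-day drift is modeled). The generator does
not model within-vial social effects, time courses inside a 24 h bin, or
female mortality.

The packaged 29-gene ground truth plants 3 lines without acute depression
(two of them with an oviposition increase), 12 lines with acute depression
but no memory retention (one flagged as previously implicated in the
paradigm), and 14 wild-type lines, plus five wild-type control lines
(wild-type stock, driver-only outcrosses, white-RNAi in both drivers)
flagged `is_control`.

`simulate_scores` plants per-gene score mixtures: positives draw
U(0.7, 1.0) in every covering model; negatives score exactly 0; background
genes score 0 with probability 0.5 and otherwise U(0.02, 0.5); variable
genes receive exactly ⌈n_models/5⌉ randomly placed high scores (U(0.7, 1.0))
among zeros. The fixed dissenting-model count is deliberate: the variable
class is defined by a *joint* condition (low mean and top-decile spread),
and an independent per-model mixture cannot guarantee both — the planted
structure, not the noise process, is the contract. Coverage is an
independent Bernoulli per cell. Real predictor ensembles are correlated
across models and calibrated differently per method; passing recovery tests
on this generator shows the categorizer implements its rules correctly, not
that the thresholds are optimal on real CAFA-style submissions.

Null calibration: with no planted effect the two-tailed Welch rejection
rate on NB(12-replicate) counts sits at 5 % ± 1.5 %; the directional call
(reject **and** decrease) fires at roughly half that, bounded by α. Both
properties are asserted in the acceptance suite.

## Network stage

Queries drop edges below `min_conf`, keep query nodes plus one-hop
neighbors (the query-plus-partners layout of typical network reports), and
label retained edges with a stringency tier (≥ 0.85 strong, ≥ 0.4 weak;
0.85 is the default stringent cutoff — 0.8 appears as an alternative in
some reports and is configurable). Enrichment is the one-sided
hypergeometric upper tail, the standard over-representation test; the
background defaults to all annotated genes in the annotation map and
percentages are over the retained (annotated) network genes. The packaged
toy networks are synthetic, hand-built to realize the documented
connectivity facts (TkR86C with a single stringent partner l(1)G0020; Nrk
isolated at 0.85 but connected at 0.4); they stand in for no external
database and their enrichment outputs are illustrative only.

## Problem sizes and reproducibility

Every stochastic step takes a seed; the pipeline derives per-stage seeds
from the global seed via `numpy.random.SeedSequence` with a fixed stage
index, so stage outputs are byte-identical across reruns of an identical
config + seed. The packaged analyses run at desk scale: the screen
simulation uses the design's own n = 12 replicates over 34 lines; the
consensus classification in `scripts/acceptance.py` uses 51 replicate
screens because a single 29-gene screen draw carries irreducible ±1
counting noise at per-test power ≈ 0.98 (the mode over replicates is the
design's consensus outcome); calibration checks use 5,000 simulated null
lines; recovery checks pool 100 seeds of a 200 × 10 score matrix.

## Known limitations

* The triage thresholds assume roughly 10 models; with very few models the
  five-level quantization is coarse and the coverage floor of 7 must be
  lowered to be satisfiable.
* The negative class requires a mean of exactly 0; predictors that emit
  tiny positive scores instead of hard zeros will empty it — scores should
  be floored upstream if "no prediction" is encoded as an epsilon.
* Welch's test on n = 12 counts relies on approximate normality of vial
  means; for heavily skewed counts (dispersion ≪ 10) a rank test would be
  more robust but is not what this screen's decision rule uses.
* The enrichment stage treats annotations as flat sets; no term hierarchy
  propagation is performed.
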