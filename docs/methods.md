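# Methods

## Problem setting

Muscle-invasive bladder cancer patients on neoadjuvant chemotherapy (NAC)
are sampled serially: plasma (PLS), urine cell pellet (UCP) and urine
supernatant (USN) at each chemotherapy visit, plus the diagnostic tumour
resection (TUR) and a buffy-coat germline control (BUF). Two orthogonal
signals are read from each fluid: single-nucleotide variants in a
bladder-cancer gene panel by deep amplicon re-sequencing, and genome-wide
copy-number aberrations (CNAs) by shallow whole-genome sequencing (sWGS).
The package turns per-bin and per-variant read counts into detection
calls, per-patient presence, and recurrence statistics.

## Copy-number stage

**Bin frame.** Equal, non-overlapping bins per chromosome (1 Mb default,
50 kb supported), 0-based half-open coordinates, annotated with GC,
mappability and a blacklist flag. Only autosomal, non-blacklisted bins
with mappability ≥ 0.5 are analysed.

**Correction.** Counts receive a pseudocount of 0.5 (so zero-count bins
survive the log), are divided by a fitted GC-bias curve and by
mappability, and become log2 ratios to the sample median, re-centred so
the median over valid bins is exactly 0.

The GC curve is estimated from local medians in 20 equal-frequency GC
strata. The knots are then smoothed by a stratum-size-weighted quadratic
rather than interpolated directly: equal-frequency strata place almost all
knots in the dense GC centre, and on profiles whose GC field is spatially
autocorrelated the sparse tails — where the bias curve is steepest — are
otherwise fitted by noise-dominated extrapolation. On noiseless data the
quadratic smoother leaves residual bias below 0.01 log2 units across the
full GC range while the median knots keep the fit robust to copy-number
structure (a focal event cannot bend the curve).

**Segmentation (CBS).** Per chromosome, the circular arc `(i, j]`
maximising `|mean(arc) − mean(rest)| · sqrt(k(n−k)/n)` is found
exhaustively over all pairs with both sides ≥ `min_width` (default 2); the
split is accepted when a permutation test on the region (default 1000
permutations, fixed seed) gives p < α (default 0.01), and the procedure
recurses on the resulting pieces. The permutation loop stops early once
the exceedance count makes significance impossible; the accept/reject
decision is identical to the full test. No pruning/undo step is applied —
profiles here are short. The statistic omits a within-group variance
denominator deliberately: the permutation reference makes it scale-free,
and it remains defined on noiseless regions where a pooled variance would
vanish.

**Calling.** Segment means are thresholded at
`±max(min_abs, k_mad · noise)` with `min_abs = 0.10` log2 and
`k_mad = 3`, where `noise` is 1.4826 × median absolute residual of bins
about their segment means. This replaces a six-state mixture-model caller:
downstream analysis uses calls only as binary presence evidence, and a
mixture model is unidentifiable on a single sample. A profile is
*CNA-detectable* when any non-neutral segment spans ≥ 3 bins; with the
default noise conditions this places the detection limit between 1 % and
20 % tumour fraction for a 30-bin single-copy gain, consistent with the
~5 % allele-fraction floor usually quoted for sWGS.

**Imbalance score.** The control is the sum of the raw bin counts of the
germline (buffy-coat) samples, corrected as one sample — summation makes
pooling order-free. The test profile is regressed on the control by OLS
(control as predictor; an affine relation is absorbed by construction) and
the score is the sum of the `ceil(0.05·n)` largest squared residuals, ties
broken by bin order. "Most extreme residuals" is read as largest squared
residuals, which reconciles the two natural readings (squared-sum vs
extreme-value selection); ranking by absolute value would select the same
bins. No absolute positivity threshold is inherent to the score;
`loo_control_threshold` offers a conservative, control-derived default
(maximum leave-one-out score among the germline members) and is labelled
an artifact choice.

**Concordance.** Adjusted R² (`1 − (1−R²)(n−1)/(n−2)`) of the OLS fit of
one corrected profile on another over shared valid bins; slightly negative
values are expected for null comparisons.

## SNV detection stage

Detection in a reaction requires the allele fraction to strictly exceed
`max(0.005, 1/GE)` where GE is the amplifiable genomic equivalents input
(dPCR-quantified in practice; supplied as a column here — the assay itself
is out of scope). The 0.5 % floor is the technical threshold at which
germline controls are uniformly negative at ~7600× depth; `1/GE` is the
molecular sampling floor. The rule is applied per variant per sample (the
simplest reading; replicate pooling is not modelled). Sub-threshold AFs
are retained for kinetics. Patient-level *presence* at a timepoint means
detection of ≥ 1 panel variant in ≥ 1 available fluid; a timepoint with no
available samples is *unevaluable*, never negative. Patients with no panel
variant anywhere form an explicit unevaluable stratum in the outcome
analysis.

A deliberately crude tumour-fraction estimate `2 × max AF` (heterozygous,
copy-neutral assumption) is provided for parameter-recovery checks.

## Outcome stage

The 2×2 detection-vs-recurrence table yields sensitivity, specificity,
PPV and NPV with exact Clopper–Pearson intervals (Beta quantiles; closed
forms at k = 0 and k = n). Zero-denominator metrics are flagged undefined,
never reported as 0. Percentages are reported to one decimal; CI bounds as
integer percent (half-up). Survival uses the Kaplan–Meier product-limit
estimator and the two-group log-rank test (hypergeometric variance),
via lifelines. Group contrasts: two-sample KS on AF distributions;
per-timepoint 2×2 chi-squared without continuity correction (configurable)
with Bonferroni over timepoints; Kruskal–Wallis across the three fluids
with Dunn's rank z post-hoc (tie-corrected), Bonferroni over the three
pairs. Median time-to-event is the sample median rounded half-up, with
range.

## Synthetic cohort: what it emulates, and what it does not

Defaults mirror the motivating study design: 17 patients, 6 visits
(days 45–150 after TUR at 21-day intervals), 3 fluids per visit, 8
recurrers (recurrence 264–507 days), censoring 463–1008 days; sWGS at a
mean 13.6 M reads/sample on TUR, BUF and the first/last visits; amplicon
depth 7600×; GE per reaction log-uniform over [10², 10⁵].

* **Trajectories.** persistent (slowly declining tumour fraction),
  responder-decay (~50-fold drop by cycle 2), clonal-switch (two clones
  with anti-correlated fractions crossing once, distinct CNA/SNV
  profiles), mutDNA-absent. Default composition: recurrers = 5 persistent
  + 1 clonal-switch + 1 responder (the designed false negative) + 1
  absent; non-recurrers = 5 responders + 4 absent.
* **Compartments.** Urinary reference tumour fraction scaled by 1.0
  (USN), 0.8 (UCP) and 0.15 (PLS) — urine ≫ plasma by construction; the
  ratio is a free scenario parameter, not an estimate of shedding.
* **Counts.** Expected bin count ∝ mappability × GC-bias × mixture factor
  `1 + Σ w_c (cn_c/2 − 1)`; negative-binomial noise with dispersion
  φ = 5×10⁻⁴ (Poisson as φ→0). At the default depth this gives per-bin
  log2 noise ≈ 0.035, the regime of well-behaved sWGS libraries on 1-Mb
  bins, and is what makes a 30-bin single-copy gain reliably callable at
  20 % tumour fraction under the fixed caller defaults.
* **Variants.** AF = tf × clone fraction / 2 — a heterozygous,
  copy-neutral simplification; copy-number-aware AF adjustment is
  deliberately omitted. Molecules ~ Binomial(GE, AF), reads resampled at
  depth with symmetric substitution error 10⁻⁴ (a flat error floor stands
  in for a caller's background model, which is out of scope).

Not modelled, hence not demonstrated by passing tests: fragment-size and
FFPE artefacts, locus-specific error spectra, primer performance, sample
dropout/missingness (supported by the data model, absent from the default
scenario), urine-vs-plasma shedding biology, and absolute copy
number/ploidy. Results on synthetic cohorts show internal consistency of
the pipeline under its own generative assumptions — not clinical
performance.

## Numerical choices and degenerate inputs

Fixed seeds make every stage reproducible (cohort hash-stable; pipeline
bundles byte-identical on rerun). Ties at the imbalance 5 % cutoff break
by bin order; CBS argmax breaks ties by pair enumeration order. Constant
control profiles, all-zero counts, empty groups, zero denominators and
all-tied rank tests raise or flag rather than returning silent zeros.
Problem sizes in the test and acceptance suites (22 × 50-bin genomes,
10–20 replicate seeds, 10⁴ simulated germline loci) were chosen as the
smallest cohorts that leave the assessed frequencies comfortably away
from their acceptance boundaries.

## Known limitations

* CBS here has no undo/prune step and an O(n²) split search per region —
  appropriate for ≤ a few hundred bins per chromosome, not for 50-kb bins
  genome-wide.
* The detection rule's sample threshold `1/GE` is only marginally
  protective at exactly one template molecule (AF ≈ 1/GE); occasional
  single-molecule false positives at very low input are inherent to the
  published rule and visible in synthetic cohorts.
* The imbalance score is not calibrated to tumour fraction; only its
  ordering is meaningful.
* The specificity such a small cohort can support is weak: exact CIs on
  6-patient groups span ~40 percentage points.
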