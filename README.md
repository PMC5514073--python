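# mutdna

Liquid-biopsy analysis of **mutant DNA (mutDNA)** in muscle-invasive bladder
cancer (MIBC) under neoadjuvant chemotherapy (NAC). Patients shed
tumour-derived DNA into blood plasma (PLS) and — because the tumour sits in
the bladder wall — at much higher levels into urine, both the spun cell
pellet (UCP) and the supernatant (USN). This package implements the
computational side of monitoring that signal longitudinally and asking the
clinically important question: *does persistence of mutDNA early in
chemotherapy predict recurrence?*

The package is aimed at computational biologists working with shallow
whole-genome sequencing (sWGS) bin counts and targeted amplicon
re-sequencing read counts from serial body-fluid samples.

## What it computes

**Copy-number profiling from binned read counts.** Reads are counted into
equal 1-Mb (or 50-kb) autosomal bins; counts are corrected for GC content
(local-median fit smoothed by a weighted quadratic) and mappability,
blacklisted bins are excluded, and each bin becomes a median-centred log2
ratio. Profiles are segmented by **circular binary segmentation** (CBS):
recursively find the circular arc `(i, j]` maximising

```
T(i,j) = |mean(arc) − mean(rest)| · sqrt(k(n−k)/n)
```

and accept the split when a permutation test gives p < α. Segments are
called gain/loss by robust thresholding at `max(0.10, 3·MAD)` log2 units; a
sample is *CNA-detectable* if any non-neutral segment spans ≥ 3 bins.

**Genome-wide imbalance score.** Each sample's binned values are regressed
(OLS) on a pooled germline control (summed buffy-coat counts, corrected as
one sample); the score is the sum of the 5 % largest squared residuals —
zero exactly when the profile is an affine function of the control, and
increasing with tumour fraction. Pairwise profile concordance is the
adjusted R² of one profile's OLS fit on another.

**Dual-threshold SNV detection.** A variant in a sample is detected when
its allele fraction strictly exceeds

```
max( 0.005 ,  1 / genomic equivalents )
```

— the 0.5 % technical floor that keeps germline controls uniformly
negative, and the molecular sampling floor set by the amplifiable template
copies (GE) that entered the reaction. Sub-threshold AFs are retained for
kinetics. A patient is mutDNA-*present* at a visit if any panel variant is
detected in any available fluid; missing samples never count as negative.

**Outcome statistics.** Presence at the cycle-2 visit is treated as a
predictor of recurrence: 2×2 sensitivity/specificity/PPV/NPV with exact
Clopper–Pearson intervals, Kaplan–Meier curves and the log-rank test,
two-sample Kolmogorov–Smirnov on AF distributions, per-timepoint
chi-squared with Bonferroni correction, and Kruskal–Wallis with Dunn
post-hoc across the three fluid types.

**Synthetic cohort generator.** Because per-patient sequencing data of this
kind is not publicly deposited, the package ships a first-class simulator:
tumour clones with segmental/focal copy-number events and panel SNVs,
compartment-specific tumour fractions (urine ≫ plasma), responder-decay /
persistent / clonal-switch / mutDNA-absent trajectories, a
binomial molecular bottleneck per reaction, and negative-binomial sWGS
counts with a smooth GC bias. Its ground-truth ledger makes every pipeline
stage testable end to end.

## Worked example

Run the whole pipeline on the default synthetic cohort (17 patients, 6
visits, 3 fluids, 8 recurrers):

```bash
mutdna run --seed 1 --out run1
cat run1/report.txt
```

```
mutDNA cohort report
====================
patients: 17, samples: 340 (sWGS on 136)

cycle-2 presence vs recurrence:
  groups: {'absent': 5, 'present': 7, 'unevaluable': 5}
  2x2 table: tp=6 fp=1 fn=1 tn=4
  sensitivity: 85.7% (6/7; CI 42-100%)
  specificity: 80.0% (4/5; CI 28-99%)
  PPV:         85.7% (6/7; CI 42-100%)
  NPV:         80.0% (4/5; CI 28-99%)
  log-rank: chi2=6.137, p=0.01324

recurrence: 8 events, median 336 days (range 264-507)
CNA-detectable fraction of sWGS samples: 0.21
tumour-fraction recovery slope (est vs truth): 1.026
Kruskal-Wallis across PLS/UCP/USN: H=50.17, p=1.27e-11
```

Reading this: 5 of 17 patients have no panel SNV anywhere and are
unevaluable by an SNV assay. Among the 12 evaluable patients, mutDNA
presence just before the second chemotherapy cycle separates recurrers
from non-recurrers (log-rank p = 0.013); the one false positive is a
responder in whom a single template molecule at low input (GE ≈ 100)
crossed the 1/GE sampling floor — exactly the boundary case the dual
threshold is designed to guard. The recovery slope near 1 says the
simulator's true tumour fractions are recovered from observed allele
fractions (AF ≈ tf/2), and the Kruskal–Wallis test confirms the built-in
compartment ordering (urine ≫ plasma).

The same stages are available as a library (`mutdna.correct_counts`,
`segment_profile`, `imbalance_score`, `call_variants`,
`contingency_metrics`, ...) and as individual subcommands
(`simulate`, `cna`, `score`, `concordance`, `detect`, `outcome`).

`mutdna demo` recomputes the reference MIBC cohort's published contingency
arithmetic from its raw counts and checks every line:

```
sensitivity_percent           computed=  83.3  expected=  83.3  PASS
npv_percent                   computed=  85.7  expected=  85.7  PASS
sensitivity_ci_lower_percent  computed=    36  expected=    36  PASS
recurrence_median_days        computed=   336  expected=   336  PASS
...
all checks passed
```

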