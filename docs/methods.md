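# Methods

## The problem being modelled

A rescue experiment for DNA methylation compares four kinds of sample over a
fixed universe of genomic regions: a wild-type reference, a null mutant
carrying an empty vector (the baseline), and one or more rescue lines
re-expressing the factor (efficient or impaired). MeDIP-seq read density per
region is the methylation proxy. The analysis asks, region by region, what
fraction of the methylation the null lost has been regained by each rescue.

## Normalization

MeDIP libraries differ in depth and pulldown efficiency; both act
multiplicatively on counts, hence additively in log space. The pipeline:

1. **RPK scaling.** Each count is divided by region length in kb
   (`count / (length/1000)`). Library size is deliberately *not* divided out
   here — between-sample scale is handled by the next step — so RPK is
   per-kilobase only.
2. **log2 with pseudocount.** `log2(RPK + 0.5)` by default. The half-count
   pseudocount keeps zeros finite; it is configurable because the choice
   matters at very low coverage (see *Limitations*).
3. **Invariant-region affine anchoring.** A set of regions whose methylation
   is believed not to differ between samples is supplied with the annotation.
   For each non-reference sample, ordinary least squares of the sample's
   invariant-region log2 values on the reference's is fitted, and the whole
   sample is transformed by the inverse line, `v' = (v − b)/m`, so that
   refitting yields intercept 0 and gradient 1 (exact up to floating point, a
   consequence of OLS linearity; the test suite asserts 1e-9).

The regression direction (sample on reference) is configurable; the reference
profile is never transformed. A fitted slope ≤ 0 is treated as corrupt input
rather than silently applied. A real limitation worth knowing: with noise on
both axes, OLS is attenuated (errors-in-variables), so fitted slopes sit a
few percent below 1 even on perfectly matched samples unless the invariant
set spans a wide dynamic range. The attenuation largely cancels in the
recovery ratio below, but it is visible in the reported slopes and has a
noise floor set by the biological overdispersion, not by sequencing depth.

## The methylation-recovery statistic

With normalized log2 values `w` (reference), `m0` (baseline), `s` (rescue):

    D = w − m0,   S = w − s,   MR = 100 (D − S) / D = 100 (s − m0) / D

Anchors: `s = w` gives MR = 100; `s = m0` gives MR = 0. MR depends only on
differences, so it is invariant under any constant shift applied jointly to
the three values — which is why a per-region enrichment factor (CpG density,
copy number, mappability) that is constant across samples cancels exactly.

Conventions, all configurable and recorded in output metadata:

- `d_min = 1.0` log2 (a 2-fold deficit) defines "the null lost methylation
  here". Regions below it are excluded with a named reason, never dropped
  silently.
- MR is unclamped by default; clamping to [0, 100] is opt-in.
- "Substantially recovered" for the recovered-fraction summary defaults to
  MR ≥ 50%.
- Quantiles use linear interpolation of order statistics; whiskers are the
  most extreme observations within 1.5×IQR of the quartiles. Other quantile
  conventions would shift whiskers slightly.
- Spearman correlations are Pearson correlations of average ranks; a
  constant profile makes its pairs undefined (reported as NaN and flagged,
  not forced to 0).

Estimator behaviour to be aware of: MR is a ratio whose numerator and
denominator share the baseline's measurement noise, so at low true recovery
the per-region distribution is slightly asymmetric and class medians carry a
small positive bias (about +3 points at the default simulation conditions,
well inside the ±8-point calibration band the tests enforce). Filtering on
the *measured* deficit additionally selects noise when true deficits sit
near `d_min`; with the default generator the true deficit is ≈3 log2, far
from the 1.0 threshold, so this selection is negligible.

## The synthetic-data generator

The generator emulates the study design, not any particular genome:

- **Annotation.** Non-overlapping regions in seven classes (promoters, gene
  bodies, intergenic blocks, IAP / LINE / minor- and major-satellite
  repeats), lengths uniform per class with a 200 bp floor. A per-class
  fraction of regions is "LSH-dependent"; the invariant set is drawn from
  the non-dependent remainder, so invariance holds by construction.
- **Methylomes.** Wild-type methylation uniform per region (0.55–0.95 at
  dependent regions; invariant regions span 0.05–0.95 so the anchor set
  covers the signal range). The baseline loses 95% of wild-type methylation
  at dependent regions — rescues of near-complete loss, as at satellites and
  IAPs — and none elsewhere.
- **Recovery.** The MeDIP signal of a region with methylation m is
  `background + (1 − background)·m` (background 0.05, the pulldown rate of
  unmethylated DNA). A rescue with recovery fraction ρ interpolates
  *geometrically on the signal scale*: `s = s_base^(1−ρ) · s_wt^ρ`. Because
  MR is a ratio of log2 signal differences, this makes ρ the exact
  noise-free truth for MR/100, so parameter-recovery tests compare like with
  like. Linear interpolation of methylation levels would make the noise-free
  MR depend on each region's deficit (the log is concave), leaving the truth
  parameter ill-defined. Per-class multipliers on ρ reproduce
  class-structured recovery (the LSH-rescue preset gives the efficient
  rescue a gene-body bias and the weak rescue an intergenic bias).
- **Counts.** Negative-binomial with mean
  `library_factor · kb · depth · signal · enrichment` and variance
  `μ + dispersion·μ²` (dispersion 0.2 by default; Poisson at 0). The
  per-region enrichment propensity is log2-uniform on (0, 6), constant
  across samples: it emulates the wide per-region dynamic range of real
  MeDIP counts, gives the invariant regression the leverage it needs, and
  cancels exactly in MR. Per-sample library factors uniform on (0.5, 2)
  force the normalization to do real work.
- **Bisulfite clones.** Each CpG cytosine is retained with its per-CpG
  probability, otherwise read as T; non-CpG cytosines convert to T except
  with the conversion-failure probability (default 0.02); uniform base
  errors at the sequencing-error rate. Clones are compared against the
  unconverted reference, which is how Sanger clone reads are interpreted.
- **Assays.** qPCR ΔCt values derived from chosen fold changes with Gaussian
  cycle noise (sd 0.1); HPLC areas are molar amounts times the extinction
  coefficients with lognormal noise.

All generators are pure functions of (parameters, seed).

What the generator does **not** model — and hence what passing tests do not
show about real data: CpG-density coupling of MeDIP enrichment (a constant
per-region factor is simulated instead of a methylation-dependent one),
fragment-size and sonication effects, mappability structure, duplicate
reads, copy-number differences *between* samples, and real repeat sequence.
Results on real data additionally depend on the quality of the invariant
set, which here is known by construction.

## Problem sizes and test design

Tests run on desk-scale problems chosen so the suite completes in minutes:
the calibration grid uses 500 regions per class over four classes, depth 200
expected reads per kb, dispersion 0.2, and twenty seeds; the LSH-rescue
preset uses 1,260 regions and four samples. Depth-convergence checks run at
dispersion 0 because only counting noise vanishes with depth (the
overdispersion term sets a depth-independent floor on the invariant-fit
error). Oracle checks (per-base overlap counting, explicit average-rank
Spearman, enumeration of all global alignments, sort-based quantiles) run
exhaustively where the combinatorics allow (all sequence pairs up to length
3) and on seeded random instances beyond that.

## Alignment and bisulfite conventions

Needleman–Wunsch with match +1, mismatch −1, linear gap −2. Traceback ties
break deterministically: diagonal, then up (gap in reference), then left
(gap in query), so clone calls are bit-reproducible. Clone QC defaults
follow common practice for clone bisulfite analysis: conversion rate ≥ 0.95
(fraction of non-CpG reference cytosines read as T) and identity ≥ 0.80 over
non-cytosine reference positions; bisulfite-expected C→T changes never count
as mismatches. Only the top strand is analyzed. Per-CpG and overall
percentages are computed over non-missing calls; the overall percentage is
the call-count-weighted mean of the per-CpG percentages (asserted as an
identity in the tests).

## Assay conventions

Pfaffl efficiencies are amplification factors per cycle in [1, 2.2]
(percent-style inputs are rejected, not rescaled); ΔCt is control − sample;
technical-replicate Cts are averaged before ratios are formed. Percent 5mC
is reported relative to the cytosine pool, n₅mC/(n_C + n₅mC), with molar
amounts `area / ε` (ε_dCMP = 8.86×10³ at 276 nm, ε_5mdCMP = 9.0×10³ at
282 nm).

## Known limitations

- OLS anchoring is attenuation-biased when the invariant set is narrow or
  noisy; an errors-in-variables (major-axis) variant would remove this but
  is deliberately out of scope to keep the published procedure.
- MR at low coverage inherits the pseudocount's nonlinearity; regions whose
  baseline RPK is near the pseudocount have compressed deficits.
- The bootstrap interval for pattern differences resamples clones, not CpGs;
  it reflects clone-to-clone variance only.
- The CLI's `run-all` chains the region-level generator straight into
  normalization; read-interval counting is exercised by the `count`
  subcommand on emitted read BEDs instead.
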