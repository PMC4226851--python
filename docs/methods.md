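# Methods

## The measurement model

Two-color aCGH reports, per probe, the log2 ratio of test-sample signal to
reference-sample signal. Under diploid dosage a locus with `c` copies in the
test sample against `r` copies in the reference has expected log2 ratio
`log2(c/r)`: 0 for balanced dosage, +0.585 for a single-copy gain (3 vs 2),
−1.0 for a single-copy loss (1 vs 2). The simulator emits exactly this mean
per probe plus i.i.d. Gaussian noise; a homozygous deletion (`c = 0`) would
be −∞, so a configurable floor of −4.0 is emitted instead — real arrays
saturate, and downstream arithmetic must stay finite.

What the generator does **not** emulate: spatial/dye wave artifacts, GC
bias, probe-sequence effects, failed-probe clustering, or two-channel
intensity data. A green recovery test therefore establishes that the
segmentation/calling/aggregation logic is correct under the stated noise
model, not that the pipeline is robust to raw-array artifacts; on real data
the normalization stage (here: median centering only) would carry far more
weight.

### Synthetic-data defaults

| parameter | default | why |
|---|---|---|
| probe spacing | genome length / n_probes (~2.5 kb at 10,000 probes / 25 Mb) | matches the 385K tiling array's ~2.6 kb median spacing at desk scale |
| probe placement | uniform grid, per-probe Gaussian jitter (sd = step/8), drawn without replacement | reproduces a target median spacing without modelling probe design |
| noise sd | 0.15 log2 units | package default; the platform's array noise is not published. At 0.15, a 5-probe segment mean has se ≈ 0.067, so the ±0.3 calling bound sits ≈ 4.5 se from a null segment |
| event size | 6–12 probes | comfortably above the 5-probe calling floor, small enough that tens of events fit per chromosome |
| gain/loss mix | alternating 3-copy gains and 1-copy losses | both calling signs exercised with equal weight |
| qPCR dilution series | 2.5, 5, 10, 20, 40, 80 ng, triplicate | the standard serial-dilution design for curve fitting |
| qPCR Ct noise | 0 (simulator default; tests use 0.1 cycles) | noise-free round trips must be exact to machine precision |

All randomness flows from one explicit integer seed; per-sample noise
streams are derived from (seed, sample id) so samples are independent but
each is individually reproducible.

## Segmentation

The original pipeline's segmentation (vendor "segMNT") is proprietary and
undocumented, so the package substitutes a documented, deterministic
equivalent: exact penalized least-squares changepoint partitioning
(Jackson/Killick-style optimal partitioning). Per chromosome, the dynamic
program minimizes

    Σ_segments Σ_i (x_i − segment mean)²  +  λ · (number of segments)

over **all** partitions of the probe sequence, in O(n²) via prefix sums.
Optimality is testable: tests compare the DP's penalized cost against full
enumeration of every partition on small instances and bounded enumeration on
larger ones, and property tests check partition validity, penalty
monotonicity, and probe-count-weighted mean conservation.

Choices:

- **Default penalty** λ = 2·σ̂²·log n per chromosome — BIC-like, with σ̂
  estimated as median(|successive differences|)/(√2·Φ⁻¹(0.75)); the median
  makes the estimate insensitive to the handful of differences that straddle
  true changepoints, so the penalty adapts to the noise level without tuning.
- **Chromosome boundaries are forced breakpoints**; segmentation never spans
  them (biological contiguity), so no call can either.
- **Missing probe values** (NaN) are dropped before segmentation; segment
  probe indices refer to the retained ordering while bp bounds are genomic
  positions of real probes.
- **Normalization** is median centering only — one global shift so the
  profile median is 0. The original normalization method is unpublished;
  this is the declared substitute, not an inference about the vendor tool,
  and "baseline" in the calling rule means 0 on this centered scale.

## CNV calling

A segment becomes a call iff it has ≥ 5 probes **and** |mean log2| > 0.3,
both bounds configurable. The ±0.3 bound is strict ("greater than" read
literally; a mean of exactly 0.30 is not called), the probe bound inclusive
("five or more"). Call boundaries are the positions of the segment's first
and last probe — not extended to midpoints between flanking probes — a
conservative choice that makes overlap statistics interpretable. Adjacent
same-state calls separated by a sub-threshold segment are not merged within
a sample (no within-sample merging is part of the published rule). Probes on
uncertain chromosomal loci (`chr*_random`, `chrUn*`, `chrE22C19W28_E50C23`,
`chrE64`, `chrW`; fnmatch patterns, case-insensitive) are removed before
analysis.

## CNVR aggregation

CNVRs are connected components of the call-overlap graph with overlap
defined as ≥ 1 shared base on the 1-based inclusive scale: transitive
chaining (A–B and B–C overlapping puts A, B, C in one region even if A and C
are disjoint), which on intervals reduces to a sorted sweep. Bookended
calls (end + 1 = start) share no base and do not merge. Region state is
gain / loss / both by member enumeration; sample frequency counts distinct
samples, not calls. Summary lengths are end − start + 1; an empty region
set yields a zero summary with NaN mean/median as the explicit "undefined"
flag. Percentages of regions overlapped by an annotation track are always
reported together with their denominator (the number of query regions),
because survey literature is not consistent about that denominator.

## Annotation

- **Liftover** is table-driven (probe_id → new chrom/position), not sequence
  alignment: the original conversion realigned probe sequences against the
  new assembly, which needs external genome data; a mapping file isolates
  that dependency. Unmapped probes are dropped and counted; position
  collisions keep the first probe and warn.
- **Gene overlap** flags each gene *complete* (gene ⊆ region) or *partial*
  (≥ 1 bp but not contained); a gene spanning two regions appears in both
  lists but counts once globally.
- **QTL filter**: confidence-interval width strictly < 10 Mb; a QTL with no
  CI width cannot pass a localization filter and is excluded with a warning.
- **Enrichment** replaces a web-service lookup with the standard one-sided
  hypergeometric upper tail per term plus Benjamini–Hochberg adjustment,
  computed locally from a user-supplied gene→term map. The EASE-score
  convention (tail at k−1) is available as a flag but is not the default —
  the published analysis names the web tool, not its internal variant.
  Terms with zero hits are omitted.

## qPCR quantification

Standard-curve method (not ΔΔCt): ordinary least squares of mean Ct on
log10(quantity) over the dilution series; amplification efficiency
`E = 10^(−1/slope) − 1` (slope −3.3219 ⇔ E = 1). A sample Ct inverts to a
quantity through the curve, and relative copy number is that quantity over
the quantity of the reference unit. The reference unit is an explicit
parameter: the convention "copies in 1 ng of reference DNA = one unit" is
read off the fitted curve (Ct at 1 ng = intercept), while samples are
commonly run at 10 ng — the caller chooses the anchor rather than the
package resolving that ambiguity. Replicates are aggregated as mean Ct with
the CV of replicate-wise quantities reported; no outlier rejection.
Genotype classes for a segregating duplication use the 1× / 1.5× / 2× fold
anchors (wild type, heterozygous, homozygous duplication) with decision
bounds at the midpoints 1.25 and 1.75 — the fold levels are given by the
biology, the thresholds are this package's choice.

## Numerical and degenerate-input choices

- Coordinates are 1-based inclusive internally; BED files are 0-based
  half-open on disk, converted at the boundary (internal [100, 200] ⇔ BED
  (99, 200)); round-tripping is the identity.
- Segment means equal the arithmetic mean of member probe values to machine
  precision (prefix-sum arithmetic).
- DP ties (equal penalized cost) resolve to the earliest split index via
  argmin — deterministic across runs.
- A constant noiseless profile yields σ̂ = 0; the default penalty then falls
  back to a tiny positive value so the optimum stays a single segment.
- Empty inputs: an empty call set merges to an empty region list; an
  all-NaN profile, zero samples, an empty enrichment background, and fewer
  than 3 standard quantities are errors.

## Known limitations

- The segmenter is behaviorally close to, but not a replica of, the
  proprietary least-squares segmentation; real callsets produced by the
  vendor tools will not be reproduced region-for-region.
- O(n²) dynamic programming is exact but quadratic: fine for ~10⁴-probe
  chromosome profiles (sub-second per chromosome), not for million-probe
  arrays; a pruned (PELT-style) search would be the upgrade path.
- Enrichment assumes the user-supplied background and term map are complete;
  no ortholog mapping or live annotation retrieval is performed.
- The qPCR model treats efficiency as constant across the dilution range and
  fits one curve per locus/plate; no inter-plate calibration is modelled.
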