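# Methods

This note documents the models, estimators and numerical conventions behind
`recland`, and the design choices made where several reasonable options
existed.

## Coordinates and the rho map

All internal coordinates are 0-based, half-open; rho-map text files and VCF
are 1-based on disk and converted at the I/O boundary.  A `RhoMap` is a
piecewise-constant function of the population-scaled recombination rate
rho = 4·Ne·r per bp, tiling `[0, chrom_length)` without gaps.  LD-based
estimators emit rates between adjacent SNPs; the regions outside the SNP
span carry no information and are padded with the nearest segment's rate,
and internal gaps between rows extend the preceding segment.  Range queries
use a cumulative integral, so window means and flank means are exact
length-weighted averages, independent of how a constant region happens to
be segmented (re-segmenting a uniform stretch provably cannot change any
downstream call).  The writer emits 6 significant digits, matching the
scale of composite-likelihood estimator output.

## Hotspot caller

Windows of 2000 bp step forward every 1000 bp.  The flank mean covers up to
40 kb on each side, excludes the focal window, and is truncated at the
chromosome ends; windows with less than 10 kb of flank on either side are
skipped.  This prevents end artifacts while retaining terminal regions.
A window is a candidate when window-mean / flank-mean ≥ 5.  Candidates are
merged greedily in descending rate order — a candidate is suppressed when
its midpoint lies within 5 kb of an already-accepted one — and candidates
whose interval strictly contains a contig boundary are removed and counted.

Numerical conventions: rates and intensities are quantized to 12
significant digits before ordering and threshold comparisons, so windows
whose rates are mathematically equal (or plantings sitting exactly on the
fold threshold) behave deterministically regardless of floating-point
summation order; ties in the merge ordering break leftmost.  A zero flank
with a positive window rate yields an accepted candidate with infinite
intensity (flagged by the caller); a window that is zero everywhere is
skipped.  The caller is scale-free: multiplying the whole map by any
positive constant changes nothing.

Placement classes: a hotspot is *terminal* when its midpoint falls in the
outer quarter at either chromosome end, *internal* in the middle half;
midpoints exactly on the 25%/75% boundary classify as internal (a
zero-measure rule fixed for determinism).  Broad-scale regional contrasts
use the outer quarters against the central quarter; hotspot placement uses
outer quarters against the middle half so the two classes partition the
chromosome.

## Sharing, permutation nulls and coldspots

Two hotspots are shared when their midpoints are within 3 kb.  Matching is
one-to-one and nearest-first (candidate pairs sorted by distance, ties by
coordinate), which prevents double counting when hotspots cluster; the
shared count is symmetric in the pair order.  Permutation nulls draw random
2-kb windows uniformly over the genome, chromosome chosen with probability
proportional to length, and score them with the same matching rule.  All
empirical p-values use the +1 pseudo-count, p = (#{null ≥ observed}+1)/(n+1),
are one-sided in the enrichment direction (depletion available via flag)
and are bit-reproducible under a fixed seed.  Permutation windows may
overlap each other within a permutation.

Coldspot matching samples candidate 2-kb windows uniformly (default cap
10,000 tries per hotspot, unmatched hotspots reported, not fatal) subject
to: edge-to-edge distance ≥ 25 kb from every hotspot interval; GC content
within 2 absolute percentage points of the paired hotspot after masking
ancestral CpG positions; and mean rho below half the map-wide mean rate
(the cutoff is configurable, since published per-population cutoffs are
stated as absolute rates).

Transcript-start-site enrichment treats a TSS as a 6-kb region centered on
the transcript start; a hotspot overlaps when its midpoint lies in the
closed interval ±3 kb.  Term enrichment draws null gene sets of matched
size uniformly from all annotated genes excluding the observed set, and
Bonferroni-adjusts by the number of distinct terms observed in the set.

## Ancestral polarization and GC-bias statistics

A site receives an outgroup-consensus ancestral prior (0.91 for the
consensus base, 0.03 for each alternative) only when both outgroup species
are homozygous for the same nucleotide; anything else — disagreement,
heterozygosity, missing data — falls back to the chromosome-wide nucleotide
frequencies measured over outgroup-covered sites.  Mutation matrices count
mutations away from the ancestral allele at consensus-polarized sites only;
rows with zero counts normalize to uniform and are flagged rather than
erroring.

Variant filters run in a fixed order (multi-allelic → missing → GQ < 30 →
site mean depth outside 0.5–2× the population mean → singletons → fixed
alternate), with per-rule removal counts reported.  The depth reference is
the mean per-site depth of the *input* table, matching the convention of
filtering against the population average; the filter is idempotent given
the same reference.  A Hardy–Weinberg chi-square filter exists as an
optional rule, off by default.

Substitutions between an ancestral sequence and a population are counted
after masking both positions of every ancestral CpG dinucleotide (`CG`
only; `GC` is not a CpG, N is never masked).  The default `fixed_derived`
mode requires every haplotype to carry the same non-ancestral allele — the
conservative reading of a "substitution" — with `any_derived` available for
sensitivity analyses.  Counts classify as AT→GC (weak→strong), GC→AT
(strong→weak) or other, and GC* = AT→GC / (AT→GC + GC→AT).  GC* is
undefined (NaN, excluded from contrasts) when no strong/weak substitutions
are observed.

## Diversity, differentiation and demography summaries

π is the per-site sum of 2p(1−p)·n/(n−1); Watterson's θ is S/(a_n·L);
Tajima's D uses the standard 1989 constants.  Windows with fewer than three
segregating sites report D = NaN because the variance estimate is unstable
(and the constants vanish identically at n ≤ 3; with two haplotypes, where
π ≡ θ_W, a zero numerator reports D = 0).  Weir–Cockerham FST computes the
1984 per-site variance components a, b, c for two populations and windows
them as Σa / Σ(a+b+c) — the ratio-of-sums convention of standard windowed
FST tools; monomorphic windows report NaN.

Median-permutation contrasts draw subsets of the genome-wide window pool
equal in size to the target set (without replacement within a draw),
compute each draw's median and take a one-sided p in the direction of the
observed deviation from the null median.

A demographic trajectory is a step function of Ne over time.  The
bottleneck summary takes the pre-bottleneck size as the maximum Ne at or
before the global minimum ("earliest step" is available as an option) and
reports the percent reduction 100·(start−min)/start.

## Synthetic data and the power study

The truth landscape is a 250-kb chromosome with 0.03 rho/kb background and
four 2-kb hotspots at midpoints 75, 125, 175 and 225 kb with rates 0.06,
0.15, 0.3 and 0.6 rho/kb — fold ratios 2, 5, 10 and 20 over background.
Panels have 40 haplotypes with target pairwise diversity θ = 0.00355 per
site; bottlenecks are parameterized as (t, s) with t the scaled event time
and s the probability that a lineage coalesces during the event, with
s = 0.1 and s = 0.9 as the weak/strong scenarios at t ≈ 0.025.

**Mosaic backend (default).**  F founder haplotypes carry independent
infinite-sites mutations; every sampled haplotype copies from the founders,
switching templates at the points of an inhomogeneous Poisson process whose
intensity equals the local rho per bp, so LD between two sites decays with
the integral of rho between them.  A bottleneck of strength s collapses the
founder count to F = max(2, round(n·(1−s))); the event time t has no
further effect in this backend (a mosaic has no explicit time axis) — the
coalescent backend honors it natively.  Founder copying weights are drawn
from a flat Dirichlet: ancestral lineages leave unequal numbers of
descendants, and equal weights would concentrate the site-frequency
spectrum at 1/F, leaving almost no intermediate-frequency variants for any
LD-based analysis.  The per-founder mutation rate is
θ / (2·(1 − Σw²)) with w the realized weights, which makes the expected
pairwise diversity of the panel equal θ exactly (two haplotypes copy
different founders with probability 1 − Σw² and then differ at the union of
the two founders' private mutations).  All generators run on seeded
integer-state PCG64 streams and are deterministic across runs and
platforms.

**Coalescent backend.**  `simulate_haplotypes(..., backend="coalescent")`
runs msprime with a haploid population of size 1/2, which makes the
per-generation recombination rate numerically equal to rho per bp and the
mutation rate equal to θ per site; the bottleneck becomes a simple
bottleneck event at scaled time t·N in which each lineage coalesces with
probability s.

**Rate estimator.**  The estimator that converts a panel back into a rate
map is deliberately lightweight — a stand-in for composite-likelihood
machinery, used only in the power study.  Two classical drift-approximation
designs (inverting E[r²] ≈ 1/(1+ρ), and a window-level σ_d² ratio-of-sums
inverted through the Ohta–Kimura formula) were implemented first and
rejected: conditioning on minor allele frequency ≥ 0.1 inflates observed
r²/σ_d² far above the unconditional drift expectation at low ρ, so
background windows invert to wildly miscalibrated rates and the
hotspot/background contrast never exceeds ~2× — the 5-fold caller then
finds nothing at any intensity.  The shipped estimator instead uses the
four-gamete test: every informative SNP pair (both MAFs ≥ 0.05, distance
≤ 10 kb) exhibiting all four gametes must be separated by at least one
historical crossover, and votes one unit of recombination mass somewhere in
its interval.  Three rounds of expectation sharing redistribute each pair's
mass proportionally to the current window rates, concentrating it where
many incompatible intervals intersect.  The result is proportional to local
recombination intensity rather than calibrated in rho units — sufficient
for the scale-free fold-threshold caller and for rank comparisons with the
truth.  The estimator is deterministic; a panel in perfect LD yields an
all-zero map and mutually independent sites yield a high, flat map.

**Power study.**  Per replicate and scenario: simulate a panel on the truth
landscape, estimate the rate map, call hotspots with the standard
configuration, and score the calls against the planted midpoints with 3-kb
one-to-one matching (false positives have no truth partner; false
negatives are unmatched plantings).  Scenario streams are spawned
independently from the master seed, so cross-scenario sharing compares
genuinely independent populations; running the driver twice with the same
seed is bit-identical.  The default is 50 replicates per scenario (the full
published design of 500 sequences is available by configuration; 50 keeps a
three-scenario study around ten seconds while the binomial error on an FN
rate is ~0.03 at the pooled count).

What the simulation does and does not emulate: panels have realistic LD
decay across the planted landscape, exact diversity calibration and a
bottleneck-compressed ancestry, but no gene conversion, no mutation-rate
heterogeneity, no phasing or genotyping error, and the mosaic site
frequency spectrum is Dirichlet-founder rather than exactly coalescent.
Passing tests therefore demonstrate the pipeline's logic and its
qualitative response to demography, not the error rates of any particular
empirical dataset.  One known divergence: with the coalescent backend a
*weak* recent bottleneck (s = 0.1) slightly *improves* four-gamete
detection power (it shifts the SFS toward intermediate frequencies,
increasing informative pairs by ~8%), whereas equilibrium-likelihood
estimators are reported to lose accuracy under the same history — a
model-misspecification channel an event-counting estimator does not have.
The mosaic backend, whose bottleneck directly removes founder lineages,
reproduces the expected monotone degradation of the pooled FN rate in s and
is therefore the power-study default.

The noise model for map-level perturbation experiments is block-wise
multiplicative lognormal noise with mean one (factors exp(N(−σ²/2, σ)) per
block, default 5 kb), so the expected perturbed map equals the truth and
caller false positives grow with σ.

## Known limitations

* The rate estimator is uncalibrated in rho units and resolves hotspots
  only down to roughly its 1-kb window grid; it is not a substitute for
  composite-likelihood estimation on real data.
* FST windows assume biallelic sites shared between the two cohorts;
  sites private to one table are dropped from the comparison.
* Coldspot sampling is rejection-based; under very restrictive constraints
  it reports unmatched hotspots rather than searching exhaustively.
* The caller's flank-skipping rule (≥ 10 kb covered flank) means the first
  and last ~10 kb of a chromosome can never host a call; published analyses
  are silent on their end-handling, so this is a declared convention rather
  than a reproduction.
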