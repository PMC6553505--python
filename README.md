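# recland

Fine-scale recombination-landscape analysis for population genomic data:
hotspot detection from LD-based per-bp recombination maps, between-population
hotspot sharing, GC-biased gene-conversion statistics and a demography-aware
power study of hotspot detection.

## Who this is for

Population geneticists working with population-scaled recombination maps
(rho = 4·Ne·r per bp, as produced by composite-likelihood estimators such as
LDhat/LDHelmet) who want a tested, reusable implementation of the standard
downstream analyses:

* **Hotspot calling.** A 2-kb window slides in 1-kb steps; a window is a
  hotspot when its mean rho is ≥ 5× the mean of the 40-kb flanks on each
  side.  Overlapping candidates within 5 kb are merged (highest rate wins)
  and windows spanning assembly contig boundaries are removed.
* **Between-population sharing.** Hotspots in two populations are shared
  when their midpoints lie within 3 kb (one-to-one matching); expected
  overlap comes from permutations of random 2-kb windows over the genome.
* **Matched coldspots.** Each hotspot is paired with a 2-kb control ≥ 25 kb
  from every hotspot, GC-matched within 2 percentage points (after masking
  ancestral CpG sites) and with mean rho below half the population
  background.
* **Ancestral polarization and GC\*.** Outgroup-consensus ancestral priors
  (0.91 / 3 × 0.03), per-chromosome 4×4 mutation matrices, and equilibrium
  GC content GC\* = n(AT→GC) / (n(AT→GC) + n(GC→AT)), the stationary GC
  fraction implied by the substitution flux.
* **Diversity and differentiation.** Windowed π, Watterson's θ = S/(a_n·L),
  Tajima's D, Weir–Cockerham FST (ratio of sums), and median-permutation
  contrasts of hotspot/coldspot windows against the genome-wide background.
* **Power study.** Haplotype panels are simulated on a truth landscape
  (250 kb, 0.03 rho/kb background, four 2-kb hotspots at 2–20× background),
  with or without a single bottleneck in which each lineage coalesces with
  probability *s*; a lightweight four-gamete-test rate estimator and the
  hotspot caller then measure false-positive/false-negative rates and
  cross-population sharing.

All inputs the pipeline consumes (rho-map text, VCF, FASTA, BED, TSV) can be
generated synthetically by `recland.synthetic_data`, so every stage is
testable without external downloads.

## Worked example

```python
from recland.synthetic_data import (make_rho_landscape, SimulationDesign,
                                    simulate_haplotypes, estimate_rho_landscape)
from recland.hotspot_detection import call_hotspots
from recland.hotspot_comparison import confusion_vs_truth

rmap, truth = make_rho_landscape()          # 250-kb map, 4 planted hotspots
hotspots = call_hotspots(rmap)              # caller on the noise-free map
for h in hotspots:
    print(f"[{h.start}, {h.end})  rate={h.rate*1000:.3f} rho/kb  "
          f"intensity={h.intensity:.1f}")

gt = simulate_haplotypes(SimulationDesign(), rmap, seed=7)
est = estimate_rho_landscape(gt, rmap.chrom_length)
score = confusion_vs_truth(call_hotspots(est), truth["midpoint"].to_numpy())
print(f"panel: {gt.n_haplotypes} haplotypes, {gt.n_sites} SNPs")
print(f"re-detected from LD: TP={score.true_positive} "
      f"FP={score.false_positive} FN={score.false_negative}")
```

prints

```
[124000, 126000)  rate=0.150 rho/kb  intensity=5.0
[174000, 176000)  rate=0.300 rho/kb  intensity=10.0
[224000, 226000)  rate=0.600 rho/kb  intensity=20.0
panel: 40 haplotypes, 9375 SNPs
re-detected from LD: TP=1 FP=0 FN=3
```

On the noise-free map the caller recovers exactly the plantings at or above
the 5-fold threshold (the 2× planting at 75 kb is, correctly, not a
hotspot).  Re-estimating the landscape from a single 40-haplotype panel is
much harder: here only the strongest hotspot is recovered — the motivation
for studying detection error rates by simulation.

A command-line interface mirrors the library (`recland windows`,
`call-hotspots`, `compare`, `coldspots`, `enrich-tss`, `filter-vcf`,
`polarize`, `gcstar`, `stats`, `fst`, `demog-summary`, `simulate`); run
`recland --help`.

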