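"""Synthetic inputs for every pipeline stage, plus the hotspot power study.

The truth landscape follows the classical simulation design for hotspot
detection power: a 250-kb chromosome with a background rate of 0.03 rho/kb
and four 2-kb hotspots planted 50 kb apart (midpoints 75, 125, 175 and
225 kb) at 0.06, 0.15, 0.3 and 0.6 rho/kb — intensity ratios of 2, 5, 10 and
20 over background.

Haplotypes are generated by a mosaic-copying model: ``F`` founder haplotypes
carry independent infinite-sites mutations, and each sample haplotype copies
from the founders, switching templates at the points of an inhomogeneous
Poisson process whose intensity is the local rho per bp.  A bottleneck of
strength ``s`` (the probability that a lineage coalesces during the event)
reduces the founder count to ``F = max(2, round(n * (1 - s)))``, compressing
the effective number of ancestral lineages exactly as a strong bottleneck
collapses genealogies.  The per-founder mutation rate is calibrated so the
expected pairwise diversity equals the design theta.

A deliberately lightweight LD-based rate estimator (pairwise r^2 inversion
under the drift approximation E[r^2] ~ 1/(1+rho)) converts simulated
haplotypes back into a noisy rho map so the hotspot caller's error rates can
be measured end to end.  It is a stand-in for full composite-likelihood
estimation and is used only inside the power study.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape_io import RhoMap
from .hotspot_detection import CallerConfig, call_hotspots
from .hotspot_comparison import confusion_vs_truth, match_midpoints
from .ancestry_polarization import (GenotypeTable, SubstitutionCounts,
                                    mask_ancestral_cpg, seq_to_array,
                                    array_to_seq)

__all__ = [
    "LandscapeSpec",
    "SimulationDesign",
    "NoiseModel",
    "make_rho_landscape",
    "add_estimation_noise",
    "simulate_haplotypes",
    "estimate_rho_landscape",
    "run_power_study",
    "simulate_substitutions",
    "make_annotation",
    "random_sequence",
]

DEFAULT_HOTSPOT_MIDPOINTS = (75000, 125000, 175000, 225000)
DEFAULT_HOTSPOT_RATES = (0.06, 0.15, 0.3, 0.6)   # rho/kb


@dataclass(frozen=True)
class LandscapeSpec:
    """Planted truth landscape (rates in rho/kb, as conventionally quoted)."""

    length: int = 250000
    background: float = 0.03     # rho/kb
    hotspots: tuple = tuple(
        (m, 2000, r) for m, r in zip(DEFAULT_HOTSPOT_MIDPOINTS,
                                     DEFAULT_HOTSPOT_RATES))

    def __post_init__(self):
        for mid, width, rate in self.hotspots:
            if not (0 <= mid - width / 2 and mid + width / 2 <= self.length):
                raise ValueError("hotspot interval outside landscape")
            if rate <= self.background:
                raise ValueError("hotspot rate must exceed background")


@dataclass(frozen=True)
class SimulationDesign:
    """Haplotype-panel simulation parameters.

    ``theta`` is the per-site pairwise diversity target; ``bottleneck`` is a
    ``(t, s)`` pair with t in coalescent time units and s the probability that
    a lineage coalesces during the event (0 <= s < 1), or None for constant
    size.
    """

    n_haplotypes: int = 40
    n_replicates: int = 500
    theta: float = 0.00355
    bottleneck: tuple | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.bottleneck is not None:
            t, s = self.bottleneck
            if not (0 <= s < 1):
                raise ValueError("bottleneck strength s must be in [0, 1)")

    @property
    def n_founders(self) -> int:
        if self.bottleneck is None:
            return self.n_haplotypes
        _, s = self.bottleneck
        return max(2, round(self.n_haplotypes * (1 - s)))


@dataclass(frozen=True)
class NoiseModel:
    """Block-wise multiplicative lognormal noise with mean one."""

    sigma: float
    block: int = 5000
    seed: int | None = None

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.block <= 0:
            raise ValueError("block must be positive")


def make_rho_landscape(spec: LandscapeSpec = LandscapeSpec(),
                       chrom_id: str = "sim"):
    """Piecewise-constant truth map from a landscape spec.

    Returns ``(RhoMap, truth)`` where ``truth`` is a DataFrame with one row
    per planted hotspot (midpoint, width, rate and intensity ratio).
    """
    intervals = sorted((mid - width // 2, mid + width - width // 2, rate)
                       for mid, width, rate in spec.hotspots)
    for (s1, e1, _), (s2, _, _) in zip(intervals, intervals[1:]):
        if s2 < e1:
            raise ValueError("overlapping hotspots")
    bg = spec.background / 1000.0   # rho/kb -> rho/bp
    starts, ends, rho = [], [], []
    cursor = 0
    for s, e, rate in intervals:
        if s > cursor:
            starts.append(cursor), ends.append(s), rho.append(bg)
        starts.append(s), ends.append(e), rho.append(rate / 1000.0)
        cursor = e
    if cursor < spec.length:
        starts.append(cursor), ends.append(spec.length), rho.append(bg)
    rmap = RhoMap(chrom_id, np.array(starts), np.array(ends), np.array(rho),
                  spec.length)
    truth = pd.DataFrame([{
        "midpoint": mid, "width": width, "rate": rate,
        "intensity": rate / spec.background,
    } for mid, width, rate in spec.hotspots])
    return rmap, truth


def add_estimation_noise(truth: RhoMap, nm: NoiseModel) -> RhoMap:
    """Multiply the map by block-wise lognormal noise with mean one.

    ``sigma = 0`` returns the input unchanged.  Noise factors are
    ``exp(N(-sigma^2/2, sigma))`` per ``block`` bp, so E[noisy rho] = rho.
    """
    if nm.sigma == 0:
        return truth
    rng = np.random.default_rng(nm.seed)
    L = truth.chrom_length
    block_edges = np.arange(0, L + nm.block, nm.block, dtype=np.int64)
    block_edges[-1] = L
    block_edges = np.unique(block_edges)
    factors = np.exp(rng.normal(-nm.sigma ** 2 / 2, nm.sigma,
                                size=len(block_edges) - 1))
    # split intervals at block edges
    edges = np.unique(np.concatenate([truth.starts, truth.ends, block_edges]))
    starts, ends = edges[:-1], edges[1:]
    base = truth.rate_at(starts)
    block_idx = np.clip(np.searchsorted(block_edges, starts, side="right") - 1,
                        0, len(factors) - 1)
    return RhoMap(truth.chrom_id, starts, ends, base * factors[block_idx],
                  L, truth.contig_boundaries)


def _switch_points(rng, rmap: RhoMap, n: int):
    """Inhomogeneous-Poisson template-switch positions for n haplotypes.

    Switch intensity is the local rho per bp; points are drawn by inverting
    the cumulative map integral.
    """
    total = rmap.total_map_length()
    counts = rng.poisson(total, size=n)
    cum = np.concatenate([[0.0], np.cumsum(rmap.rho * (rmap.ends - rmap.starts))])
    out = []
    for k in counts:
        if k == 0:
            out.append(np.empty(0))
            continue
        u = np.sort(rng.uniform(0, total, size=k))
        idx = np.clip(np.searchsorted(cum, u, side="right") - 1, 0,
                      rmap.n_intervals - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(rmap.rho[idx] > 0,
                            (u - cum[idx]) / rmap.rho[idx], 0.0)
        out.append(rmap.starts[idx] + frac)
    return out


def simulate_haplotypes(design: SimulationDesign, rmap: RhoMap,
                        seed: int | None = None,
                        backend: str = "mosaic") -> GenotypeTable:
    """Simulate a haplotype panel whose LD decays with cumulative rho.

    Two backends honor the same contract (expected pairwise diversity equals
    ``design.theta``; LD between two sites decays with the integral of rho
    between them; a bottleneck of strength ``s`` compresses ancestral lineage
    diversity):

    ``mosaic``
        The lightweight reference backend described below.
    ``coalescent``
        msprime ancestry + binary mutations on the rho map, with the
        bottleneck applied as a single event in which each lineage coalesces
        with probability ``s`` at scaled time ``t``.

    Mosaic-copying backend: ``F`` founder haplotypes carry independent
    infinite-sites mutations at a per-site rate of ``theta / (2 (1 - 1/F))``,
    which makes the expected pairwise diversity of the panel equal ``theta``
    (two sampled haplotypes copy different founders with probability
    ``1 - 1/F`` and then differ at the union of the two founders' private
    mutations).  Samples switch templates at inhomogeneous-Poisson points
    with intensity rho(x) per bp, so LD between two sites decays with the
    integral of rho between them.  Monomorphic columns are dropped.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    if backend == "coalescent":
        return _simulate_coalescent(design, rmap, rng)
    if backend != "mosaic":
        raise ValueError(f"unknown backend: {backend}")
    L = rmap.chrom_length
    n = design.n_haplotypes
    F = design.n_founders
    # founder copying weights: ancestral lineages leave unequal numbers of
    # descendants; a flat Dirichlet emulates that spread and gives the panel
    # intermediate-frequency variants
    weights = rng.dirichlet(np.ones(F))
    identity = float(np.sum(weights ** 2))   # P(two samples share a template)
    mu = design.theta / (2.0 * (1.0 - identity))

    n_mut = rng.poisson(mu * L, size=F)
    total = int(n_mut.sum())
    if total > L:
        raise ValueError("mutation count exceeds sequence length; lower theta")
    # infinite sites: all mutations land on distinct positions
    positions = rng.choice(L, size=total, replace=False)
    founder_of = np.repeat(np.arange(F), n_mut)
    order = np.argsort(positions, kind="stable")
    positions, founder_of = positions[order], founder_of[order]
    S = positions.size

    switch = _switch_points(rng, rmap, n)
    haplotypes = np.zeros((n, S), dtype=np.int8)
    for i in range(n):
        pts = switch[i]
        n_seg = pts.size + 1
        templates = rng.choice(F, size=n_seg, p=weights)
        seg = np.searchsorted(pts, positions, side="right")
        haplotypes[i] = (templates[seg] == founder_of).astype(np.int8)

    derived = haplotypes.sum(axis=0)
    poly = (derived > 0) & (derived < n)
    positions, haplotypes = positions[poly], haplotypes[:, poly]
    S = positions.size

    sites = pd.DataFrame({
        "chrom": rmap.chrom_id, "pos": positions + 1,  # 1-based
        "ref": "A", "alt": "T",
    })
    genotypes = haplotypes.T[:, :, None]
    filler = np.full((S, n), 99, dtype=np.int32)
    return GenotypeTable([f"hap{i}" for i in range(n)], sites, genotypes,
                         filler, filler, ploidy=1)


def _simulate_coalescent(design: SimulationDesign, rmap: RhoMap,
                         rng: np.random.Generator) -> GenotypeTable:
    """msprime backend: haploid samples on the rho map.

    With haploid population size N the population-scaled rate between two
    lineages is 2*N*r, so setting N = 1/2 makes the per-generation
    recombination rate equal rho/bp and the mutation rate equal theta/site.
    The bottleneck (t, s) becomes a simple bottleneck at time t*N in which
    each lineage coalesces with probability s.
    """
    import msprime

    N = 0.5
    demography = msprime.Demography()
    demography.add_population(name="pop", initial_size=N)
    if design.bottleneck is not None:
        t, s = design.bottleneck
        if s > 0:
            demography.add_simple_bottleneck(time=t * N, population="pop",
                                             proportion=s)
    edges = np.append(rmap.starts, rmap.chrom_length).astype(float)
    rate_map = msprime.RateMap(position=edges, rate=rmap.rho)
    seed1, seed2 = (int(x) for x in rng.integers(1, 2 ** 31 - 1, size=2))
    ts = msprime.sim_ancestry(
        samples=design.n_haplotypes, ploidy=1, demography=demography,
        recombination_rate=rate_map, random_seed=seed1)
    mts = msprime.sim_mutations(
        ts, rate=design.theta, model=msprime.BinaryMutationModel(),
        random_seed=seed2, discrete_genome=True)
    geno = mts.genotype_matrix()          # (S, n)
    positions = np.array([int(v.site.position) for v in mts.variants()],
                         dtype=np.int64)
    derived = geno.sum(axis=1)
    poly = (derived > 0) & (derived < design.n_haplotypes)
    geno, positions = geno[poly], positions[poly]
    S = geno.shape[0]
    sites = pd.DataFrame({
        "chrom": rmap.chrom_id, "pos": positions + 1,
        "ref": "A", "alt": "T",
    })
    filler = np.full((S, design.n_haplotypes), 99, dtype=np.int32)
    return GenotypeTable([f"hap{i}" for i in range(design.n_haplotypes)],
                         sites, np.clip(geno, 0, 1).astype(np.int8)[:, :, None],
                         filler, filler, ploidy=1)


def estimate_rho_landscape(gt: GenotypeTable, chrom_length: int,
                           window: int = 1000, min_maf: float = 0.05,
                           max_pair_dist: int = 10000,
                           n_iter: int = 3) -> RhoMap:
    """Relative recombination-intensity map from four-gamete incompatibilities.

    Every pair of informative SNPs (both minor allele frequencies >=
    ``min_maf``) closer than ``max_pair_dist`` that exhibits all four gametes
    must be separated by at least one historical crossover (the four-gamete
    test).  Each incompatible pair votes one unit of recombination mass
    somewhere in its interval; ``n_iter`` rounds of expectation sharing
    redistribute every pair's mass proportionally to the current window
    rates, concentrating it where many incompatible intervals intersect.
    The returned map is the per-bp mass density: it is proportional to local
    recombination intensity rather than calibrated in rho units, which is
    sufficient for the (scale-free) fold-threshold hotspot caller and for
    rank comparisons against the truth landscape.

    A panel in perfect LD yields an all-zero map; mutually independent sites
    yield violations everywhere and a high flat map.  The estimator is
    deterministic.  It is a deliberately lightweight stand-in for
    composite-likelihood rho estimation, fit for power studies only.
    """
    hap = gt.haplotype_matrix().astype(np.int8)
    n, S = hap.shape
    positions = gt.positions().astype(np.int64) - 1   # back to 0-based
    freq = hap.mean(axis=0)
    maf = np.minimum(freq, 1 - freq)
    use = maf >= min_maf
    H = hap[:, use].astype(np.float64)
    positions = positions[use]
    S = positions.size
    n_windows = int(math.ceil(chrom_length / window))
    chrom = gt.sites["chrom"].iloc[0] if len(gt.sites) else "sim"
    starts = np.arange(n_windows, dtype=np.int64) * window
    ends = np.minimum(starts + window, chrom_length)
    if S < 2:
        return RhoMap(chrom, starts, ends, np.zeros(n_windows), chrom_length)

    # four-gamete screening, band-limited to pairs within max_pair_dist
    Hc = 1 - H
    wa_list, wb_list = [], []
    hi_idx = np.searchsorted(positions, positions + max_pair_dist, side="right")
    for i in range(S - 1):
        j1 = hi_idx[i]
        if j1 <= i + 1:
            continue
        block = H[:, i + 1:j1]
        blockc = Hc[:, i + 1:j1]
        n11 = H[:, i] @ block
        n10 = H[:, i] @ blockc
        n01 = Hc[:, i] @ block
        n00 = Hc[:, i] @ blockc
        hit = (n11 > 0) & (n10 > 0) & (n01 > 0) & (n00 > 0)
        if hit.any():
            js = np.flatnonzero(hit) + i + 1
            wa_list.append(np.full(js.size, positions[i] // window))
            wb_list.append(positions[js] // window)
    if not wa_list:
        return RhoMap(chrom, starts, ends, np.zeros(n_windows), chrom_length)
    wa = np.concatenate(wa_list).astype(np.int64)
    wb = np.concatenate(wb_list).astype(np.int64)

    rate = np.ones(n_windows)
    win_len = (ends - starts).astype(float)
    for _ in range(n_iter):
        cum = np.concatenate([[0.0], np.cumsum(rate)])
        tot = cum[wb + 1] - cum[wa]
        inv = np.where(tot > 0, 1.0 / np.maximum(tot, 1e-300), 0.0)
        diff = np.zeros(n_windows + 1)
        np.add.at(diff, wa, inv)
        np.add.at(diff, wb + 1, -inv)
        coverage = np.cumsum(diff[:-1])
        rate = rate * coverage / win_len
        if rate.sum() == 0:
            break
    return RhoMap(chrom, starts, ends, np.maximum(rate, 0.0), chrom_length)


def run_power_study(designs: dict, landscape_spec: LandscapeSpec = LandscapeSpec(),
                    caller_config: CallerConfig | None = None,
                    n_replicates: int = 50, seed: int = 0,
                    radius: float = 3000,
                    estimator_kwargs: dict | None = None):
    """Hotspot-detection error rates under different demographic scenarios.

    Per replicate and scenario: simulate haplotypes on the truth landscape,
    re-estimate a rho map from LD, call hotspots and score them against the
    planted truth.  Cross-scenario hotspot sharing is also tallied for every
    scenario pair within a replicate.

    Returns ``(per_intensity, per_scenario, sharing)`` DataFrames:
    per-intensity FN rates, per-scenario FP/FN totals, and mean pairwise
    sharing percentages between scenarios.
    """
    if caller_config is None:
        caller_config = CallerConfig()
    estimator_kwargs = estimator_kwargs or {}
    rmap_truth, truth = make_rho_landscape(landscape_spec)
    truth_mids = truth["midpoint"].to_numpy(dtype=float)
    labels = list(designs)

    fn_by_intensity = {lab: np.zeros(len(truth_mids)) for lab in labels}
    fp_counts = {lab: 0 for lab in labels}
    called_counts = {lab: 0 for lab in labels}
    sharing_acc = {(a, b): [] for i, a in enumerate(labels)
                   for b in labels[i + 1:]}

    for rep in range(n_replicates):
        called_sets = {}
        for li, lab in enumerate(labels):
            rng_seed = np.random.SeedSequence(entropy=seed,
                                              spawn_key=(rep, li))
            gt = simulate_haplotypes(designs[lab], rmap_truth,
                                     seed=rng_seed)
            est = estimate_rho_landscape(gt, rmap_truth.chrom_length,
                                         **estimator_kwargs)
            hs = call_hotspots(est, caller_config, population_label=lab)
            res = confusion_vs_truth(hs, truth_mids, radius=radius)
            missed = set(range(len(truth_mids))) - set(res.matched_truth_indices)
            for t in missed:
                fn_by_intensity[lab][t] += 1
            fp_counts[lab] += res.false_positive
            called_counts[lab] += len(hs)
            called_sets[lab] = hs.midpoints()
        for (a, b) in sharing_acc:
            ma, mb = called_sets[a], called_sets[b]
            shared = len(match_midpoints(ma, mb, radius))
            pct_a = 100.0 * shared / len(ma) if len(ma) else math.nan
            pct_b = 100.0 * shared / len(mb) if len(mb) else math.nan
            sharing_acc[(a, b)].append((pct_a, pct_b))

    per_intensity = pd.DataFrame([
        {"scenario": lab, "intensity": truth["intensity"].iloc[t],
         "rate_rho_per_kb": truth["rate"].iloc[t],
         "fn_rate": fn_by_intensity[lab][t] / n_replicates}
        for lab in labels for t in range(len(truth_mids))
    ])
    per_scenario = pd.DataFrame([
        {"scenario": lab,
         "fp_per_replicate": fp_counts[lab] / n_replicates,
         "fp_rate": (fp_counts[lab] / called_counts[lab]
                     if called_counts[lab] else math.nan),
         "fn_rate": fn_by_intensity[lab].sum()
                    / (n_replicates * len(truth_mids)),
         "called_per_replicate": called_counts[lab] / n_replicates}
        for lab in labels
    ])
    sharing = pd.DataFrame([
        {"scenario_a": a, "scenario_b": b,
         "pct_shared_a": float(np.nanmean([x for x, _ in v])) if v else math.nan,
         "pct_shared_b": float(np.nanmean([y for _, y in v])) if v else math.nan}
        for (a, b), v in sharing_acc.items()
    ])
    return per_intensity, per_scenario, sharing


def simulate_substitutions(ancestral_seq, alpha_at_to_gc: float,
                           beta_gc_to_at: float, seed: int | None = None):
    """Flip unmasked A/T sites to G/C with probability alpha and unmasked G/C
    sites to A/T with probability beta.

    Returns ``(derived_seq, SubstitutionCounts)`` with the true flip tallies.
    Ancestral CpG positions are masked and never mutated.
    """
    if not (0 <= alpha_at_to_gc <= 1 and 0 <= beta_gc_to_at <= 1):
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    anc = ancestral_seq if isinstance(ancestral_seq, np.ndarray) else seq_to_array(ancestral_seq)
    derived = anc.copy()
    mask = mask_ancestral_cpg(anc)
    is_at = np.isin(anc, np.frombuffer(b"AT", dtype=np.uint8)) & ~mask
    is_gc = np.isin(anc, np.frombuffer(b"GC", dtype=np.uint8)) & ~mask
    flip_at = is_at & (rng.random(anc.size) < alpha_at_to_gc)
    flip_gc = is_gc & (rng.random(anc.size) < beta_gc_to_at)
    derived[flip_at] = rng.choice(np.frombuffer(b"GC", dtype=np.uint8),
                                  size=int(flip_at.sum()))
    derived[flip_gc] = rng.choice(np.frombuffer(b"AT", dtype=np.uint8),
                                  size=int(flip_gc.sum()))
    counts = SubstitutionCounts(
        region_id="simulated",
        at_to_gc=int(flip_at.sum()), gc_to_at=int(flip_gc.sum()), other=0,
        masked_cpg_bp=int(mask.sum()),
        n_ancestral_sites=int((~mask).sum()),
    )
    return (array_to_seq(derived) if isinstance(ancestral_seq, str) else derived,
            counts)


def random_sequence(length: int, gc: float = 0.42,
                    seed: int | None = None) -> str:
    """Random nucleotide sequence with the given expected GC fraction."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return array_to_seq(rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8),
                                   size=length, p=p))


def make_annotation(genome: dict, n_transcripts: int, clustering: str | None = None,
                    seed: int | None = None, vocab_size: int = 50,
                    zipf_a: float = 1.5):
    """Random transcript start sites and a gene->term annotation table.

    TSS positions are uniform per chromosome (probability proportional to
    length) or clustered (``clustering='clustered'`` concentrates them in the
    first fifth of each chromosome).  Each gene receives 1-5 terms from a
    Zipf-distributed vocabulary.  Returns ``(tss, gene_terms, gene_table)``:
    ``tss`` maps chromosome -> sorted positions, ``gene_terms`` is a DataFrame
    with columns gene_id/term_id and ``gene_table`` records each gene's TSS.
    """
    if n_transcripts < 1:
        raise ValueError("need at least one transcript")
    rng = np.random.default_rng(seed)
    chroms = list(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    ci = rng.choice(len(chroms), size=n_transcripts, p=lengths / lengths.sum())
    tss = {c: [] for c in chroms}
    genes = []
    for k in range(n_transcripts):
        c = chroms[ci[k]]
        hi = genome[c] / 5 if clustering == "clustered" else genome[c]
        pos = int(rng.uniform(0, hi))
        tss[c].append(pos)
        genes.append((f"gene{k:05d}", c, pos))
    tss = {c: np.sort(np.array(v, dtype=float)) for c, v in tss.items()}
    rows = []
    for gene_id, _, _ in genes:
        n_terms = int(rng.integers(1, 6))
        ranks = np.minimum(rng.zipf(zipf_a, size=n_terms), vocab_size)
        for r in sorted(set(int(x) for x in ranks)):
            rows.append((gene_id, f"TERM:{r:04d}"))
    gene_terms = pd.DataFrame(rows, columns=["gene_id", "term_id"])
    gene_table = pd.DataFrame(genes, columns=["gene_id", "chrom", "tss"])
    return tss, gene_terms, gene_table
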