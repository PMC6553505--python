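"""Between-population hotspot sharing, permutation nulls and matched coldspots.

Two hotspots are considered shared when their midpoints lie within 3 kb of
each other; matching is one-to-one, nearest-first, so a hotspot can back at
most one partner and tallies are never double counted.  Permutation nulls
draw random 2-kb windows uniformly over the genome (per-chromosome
probability proportional to length) and score them with the same rule;
empirical p-values carry the +1 pseudo-count, so they live in
``[1/(n_perm+1), 1]`` and are bit-reproducible under a fixed seed.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hotspot_detection import HotspotSet
from .landscape_io import RhoMap
from .ancestry_polarization import mask_ancestral_cpg, seq_to_array

__all__ = [
    "SharingResult",
    "PermutationNull",
    "ColdspotConstraints",
    "Coldspot",
    "ColdspotSet",
    "ConfusionResult",
    "match_midpoints",
    "shared_hotspots",
    "sharing_percentages",
    "expected_overlap_null",
    "match_coldspots",
    "tss_enrichment",
    "term_enrichment",
    "confusion_vs_truth",
]


def match_midpoints(a_mids, b_mids, radius: float):
    """Greedy one-to-one nearest-first matching of two midpoint lists.

    Candidate pairs within ``radius`` are processed by increasing distance
    (ties by a- then b-coordinate); each midpoint participates in at most one
    pair.  Returns a list of ``(i, j, distance)`` index pairs.
    """
    a = np.asarray(a_mids, dtype=float)
    b = np.asarray(b_mids, dtype=float)
    if a.size == 0 or b.size == 0:
        return []
    b_order = np.argsort(b, kind="stable")
    b_sorted = b[b_order]
    cands = []
    lo = np.searchsorted(b_sorted, a - radius, side="left")
    hi = np.searchsorted(b_sorted, a + radius, side="right")
    for i in range(a.size):
        for jj in range(lo[i], hi[i]):
            j = int(b_order[jj])
            d = abs(a[i] - b[j])
            if d <= radius:
                cands.append((d, a[i], b[j], i, j))
    cands.sort()
    used_a, used_b, pairs = set(), set(), []
    for d, _, _, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j, d))
    return pairs


@dataclass(frozen=True)
class SharingResult:
    shared_pairs: list           # (hotspot_a, hotspot_b) tuples
    shared_count: int
    pct_shared_a: float
    pct_shared_b: float
    population_specific_a: list
    population_specific_b: list
    mean_rate_shared_a: float = math.nan
    mean_rate_specific_a: float = math.nan
    mean_rate_shared_b: float = math.nan
    mean_rate_specific_b: float = math.nan


def sharing_percentages(shared_count: int, n_a: int, n_b: int):
    """Shared-hotspot percentages per population and the combined total count."""
    pct_a = 100.0 * shared_count / n_a if n_a else 0.0
    pct_b = 100.0 * shared_count / n_b if n_b else 0.0
    return pct_a, pct_b, n_a + n_b


def shared_hotspots(a: HotspotSet, b: HotspotSet, radius: float = 3000) -> SharingResult:
    """One-to-one sharing of hotspots between two populations (same genome).

    Matching is per chromosome with the midpoint rule.  Percentages are
    ``100 * shared / |set|`` per population; unmatched hotspots are labelled
    population-specific.
    """
    a_list, b_list = list(a), list(b)
    chroms = sorted({h.chrom_id for h in a_list} | {h.chrom_id for h in b_list})
    pairs = []
    matched_a, matched_b = set(), set()
    for chrom in chroms:
        ia = [k for k, h in enumerate(a_list) if h.chrom_id == chrom]
        ib = [k for k, h in enumerate(b_list) if h.chrom_id == chrom]
        for pi, pj, _ in match_midpoints([a_list[k].midpoint for k in ia],
                                         [b_list[k].midpoint for k in ib], radius):
            ka, kb = ia[pi], ib[pj]
            pairs.append((a_list[ka], b_list[kb]))
            matched_a.add(ka)
            matched_b.add(kb)
    spec_a = [h for k, h in enumerate(a_list) if k not in matched_a]
    spec_b = [h for k, h in enumerate(b_list) if k not in matched_b]
    shared = len(pairs)
    pct_a, pct_b, _ = sharing_percentages(shared, len(a_list), len(b_list))

    def _mean(hs):
        return float(np.mean([h.rate for h in hs])) if hs else math.nan

    return SharingResult(
        shared_pairs=pairs, shared_count=shared,
        pct_shared_a=pct_a, pct_shared_b=pct_b,
        population_specific_a=spec_a, population_specific_b=spec_b,
        mean_rate_shared_a=_mean([p[0] for p in pairs]),
        mean_rate_specific_a=_mean(spec_a),
        mean_rate_shared_b=_mean([p[1] for p in pairs]),
        mean_rate_specific_b=_mean(spec_b),
    )


@dataclass(frozen=True)
class PermutationNull:
    n_perm: int
    seed: int | None
    null_counts: np.ndarray
    observed: float
    p_value: float


def _empirical_p(null: np.ndarray, observed: float, direction: str = "ge") -> float:
    n = len(null)
    if direction == "ge":
        extreme = int(np.sum(null >= observed))
    else:
        extreme = int(np.sum(null <= observed))
    return (extreme + 1) / (n + 1)


def _draw_midpoints(rng, size, genome, window=2000):
    """Random window midpoints: chromosome with prob proportional to length,
    midpoint uniform so the whole window fits.  Returns (chrom_idx, midpoint).
    """
    chroms = list(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    ci = rng.choice(len(chroms), size=size, p=probs)
    half = window / 2
    mids = rng.uniform(half, lengths[ci] - half)
    return ci, mids


def expected_overlap_null(a_size: int, b: HotspotSet, genome: dict,
                          observed: int, n_perm: int = 10000,
                          seed: int | None = None, radius: float = 3000,
                          window: int = 2000) -> PermutationNull:
    """Permutation null for between-population hotspot overlap.

    Each permutation draws ``a_size`` random 2-kb windows over the genome and
    scores one-to-one sharing against ``b`` with the midpoint-radius rule; the
    empirical p-value is for enrichment (observed >= null).
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100: permutation p-values will be very coarse")
    rng = np.random.default_rng(seed)
    chroms = list(genome)
    b_mids = {c: np.sort(np.array([h.midpoint for h in b if h.chrom_id == c]))
              for c in chroms}
    null = np.empty(n_perm, dtype=np.int64)
    for t in range(n_perm):
        ci, mids = _draw_midpoints(rng, a_size, genome, window)
        count = 0
        for k, c in enumerate(chroms):
            sub = mids[ci == k]
            if sub.size and b_mids[c].size:
                count += len(match_midpoints(sub, b_mids[c], radius))
        null[t] = count
    return PermutationNull(n_perm, seed, null, observed,
                           _empirical_p(null, observed, "ge"))


@dataclass(frozen=True)
class ColdspotConstraints:
    """Constraints for matched coldspot selection.

    ``max_rate=None`` means half the population background (map-wide mean)
    rate, mirroring the "less than half the background" rule.
    """

    min_distance_to_hotspot: int = 25000
    gc_tolerance: float = 2.0     # absolute percentage points
    max_rate: float | None = None
    max_tries: int = 10000

    def __post_init__(self):
        if self.min_distance_to_hotspot <= 0 or self.gc_tolerance <= 0:
            raise ValueError("constraints must be positive")
        if self.max_rate is not None and self.max_rate <= 0:
            raise ValueError("max_rate must be positive")


@dataclass(frozen=True)
class Coldspot:
    chrom_id: str
    start: int
    end: int
    rate: float
    gc_pct: float
    hotspot_index: int


@dataclass
class ColdspotSet:
    coldspots: list
    unmatched_hotspots: list
    constraints: ColdspotConstraints
    max_rate_used: float

    def __len__(self):
        return len(self.coldspots)

    def __iter__(self):
        return iter(self.coldspots)


def gc_content_masked(seq_arr: np.ndarray, mask: np.ndarray, start: int, end: int) -> float:
    """GC percentage of ``[start, end)`` over unmasked A/C/G/T positions."""
    window = seq_arr[start:end]
    m = mask[start:end]
    valid = ~m & np.isin(window, np.frombuffer(b"ACGT", dtype=np.uint8))
    n_valid = int(valid.sum())
    if n_valid == 0:
        return math.nan
    gc = np.isin(window, np.frombuffer(b"GC", dtype=np.uint8)) & valid
    return 100.0 * int(gc.sum()) / n_valid


def match_coldspots(hs: HotspotSet, rmap: RhoMap, ancestral_seq,
                    constraints: ColdspotConstraints = ColdspotConstraints(),
                    seed: int | None = None, window: int = 2000) -> ColdspotSet:
    """Select a GC-matched low-recombination 2-kb control window per hotspot.

    A candidate window must lie at least ``min_distance_to_hotspot`` bp
    (edge-to-edge) from every hotspot interval, have GC content within
    ``gc_tolerance`` percentage points of the hotspot's (after masking
    ancestral CpG positions) and mean rho below ``max_rate``.  Candidates are
    sampled uniformly; a hotspot is reported unmatched after ``max_tries``.
    """
    rng = np.random.default_rng(seed)
    seq_arr = ancestral_seq if isinstance(ancestral_seq, np.ndarray) else seq_to_array(ancestral_seq)
    mask = mask_ancestral_cpg(seq_arr)
    max_rate = constraints.max_rate
    if max_rate is None:
        max_rate = 0.5 * rmap.mean_rate()
    hot_starts = np.array([h.start for h in hs], dtype=np.int64)
    hot_ends = np.array([h.end for h in hs], dtype=np.int64)
    L = rmap.chrom_length
    coldspots, unmatched = [], []
    for hi, h in enumerate(hs):
        target_gc = gc_content_masked(seq_arr, mask, h.start, h.end)
        found = None
        for _ in range(constraints.max_tries):
            s = int(rng.integers(0, L - window + 1))
            e = s + window
            if hot_starts.size:
                gaps = np.maximum(hot_starts - e, s - hot_ends)
                if gaps.min() < constraints.min_distance_to_hotspot:
                    continue
            rate = rmap.integral(s, e) / window
            if rate >= max_rate:
                continue
            gc = gc_content_masked(seq_arr, mask, s, e)
            if math.isnan(target_gc) or math.isnan(gc):
                continue
            if abs(gc - target_gc) > constraints.gc_tolerance:
                continue
            found = Coldspot(rmap.chrom_id, s, e, float(rate), gc, hi)
            break
        if found is None:
            unmatched.append(h)
        else:
            coldspots.append(found)
    return ColdspotSet(coldspots, unmatched, constraints, float(max_rate))


def tss_enrichment(hs: HotspotSet, tss_positions: dict, genome: dict,
                   n_perm: int = 10000, seed: int | None = None,
                   halo: int = 3000):
    """Fraction of hotspots whose midpoint lies within ``halo`` bp of a
    transcript start site, against a permutation null of random midpoints.

    A hotspot overlaps a TSS if its midpoint is in the closed interval
    ``[tss - halo, tss + halo]``.  Returns ``(observed_frac, PermutationNull)``.
    """
    rng = np.random.default_rng(seed)
    chroms = list(genome)
    tss_sorted = {c: np.sort(np.asarray(tss_positions.get(c, []), dtype=float))
                  for c in chroms}

    def count_overlaps(chrom, mids):
        t = tss_sorted.get(chrom)
        if t is None or t.size == 0 or len(mids) == 0:
            return 0
        mids = np.asarray(mids, dtype=float)
        lo = np.searchsorted(t, mids - halo, side="left")
        hi = np.searchsorted(t, mids + halo, side="right")
        return int(np.sum(hi > lo))

    n = len(hs)
    observed = sum(count_overlaps(c, [h.midpoint for h in hs if h.chrom_id == c])
                   for c in chroms)
    observed_frac = observed / n if n else math.nan
    null = np.empty(n_perm, dtype=np.int64)
    for t in range(n_perm):
        ci, mids = _draw_midpoints(rng, n, genome)
        null[t] = sum(count_overlaps(c, mids[ci == k])
                      for k, c in enumerate(chroms))
    p = _empirical_p(null, observed, "ge")
    return observed_frac, PermutationNull(n_perm, seed, null, observed, p)


def term_enrichment(genes_near_hotspots, gene_terms: pd.DataFrame,
                    n_perm: int = 10000, seed: int | None = None,
                    depletion: bool = False) -> pd.DataFrame:
    """Annotation-term enrichment for genes near hotspots by permutation.

    ``gene_terms`` is a two-column table (``gene_id``, ``term_id``).  Null
    sets of the same size are drawn uniformly (without replacement) from all
    annotated genes excluding the observed set.  Per-term one-sided p-values
    carry the +1 pseudo-count; Bonferroni multiplies by the number of distinct
    terms in the observed set.
    """
    rng = np.random.default_rng(seed)
    gene_terms = gene_terms.rename(columns=dict(zip(gene_terms.columns[:2],
                                                    ["gene_id", "term_id"])))
    annotated = pd.Index(gene_terms["gene_id"].unique())
    observed_genes = [g for g in dict.fromkeys(genes_near_hotspots) if g in annotated]
    counts = gene_terms[gene_terms["gene_id"].isin(observed_genes)]["term_id"].value_counts()
    terms = counts.index.to_list()
    if not terms:
        return pd.DataFrame(columns=["term", "observed_count", "null_mean",
                                     "p_raw", "p_bonferroni"])
    pool = annotated.difference(pd.Index(observed_genes)).to_numpy()
    k = len(observed_genes)
    if len(pool) < k:
        raise ValueError("annotation pool smaller than the observed gene set")
    # per-gene indicator over the observed terms only
    term_index = {t: i for i, t in enumerate(terms)}
    gene_index = {g: i for i, g in enumerate(pool)}
    mat = np.zeros((len(pool), len(terms)), dtype=np.int32)
    sub = gene_terms[gene_terms["gene_id"].isin(gene_index) &
                     gene_terms["term_id"].isin(term_index)]
    for g, t in zip(sub["gene_id"], sub["term_id"]):
        mat[gene_index[g], term_index[t]] += 1
    null = np.empty((n_perm, len(terms)), dtype=np.int64)
    for it in range(n_perm):
        pick = rng.choice(len(pool), size=k, replace=False)
        null[it] = mat[pick].sum(axis=0)
    obs = counts.to_numpy()
    if depletion:
        extreme = (null <= obs).sum(axis=0)
    else:
        extreme = (null >= obs).sum(axis=0)
    p_raw = (extreme + 1) / (n_perm + 1)
    p_bonf = np.minimum(1.0, p_raw * len(terms))
    return pd.DataFrame({
        "term": terms, "observed_count": obs, "null_mean": null.mean(axis=0),
        "p_raw": p_raw, "p_bonferroni": p_bonf,
    }).sort_values("p_raw", kind="stable").reset_index(drop=True)


@dataclass(frozen=True)
class ConfusionResult:
    true_positive: int
    false_positive: int
    false_negative: int
    fp_rate: float
    fn_rate: float
    matched_truth_indices: tuple = ()


def confusion_vs_truth(called: HotspotSet, truth_midpoints,
                       radius: float = 3000) -> ConfusionResult:
    """Score called hotspots against planted truth midpoints.

    TP = called hotspots with a one-to-one truth partner within ``radius``;
    FP = called without partner; FN = truth without partner.
    ``fp_rate`` is FP / n_called and ``fn_rate`` is FN / n_truth.
    """
    truth = np.asarray(truth_midpoints, dtype=float)
    called_mids = called.midpoints()
    pairs = match_midpoints(called_mids, truth, radius)
    tp = len(pairs)
    fp = len(called_mids) - tp
    fn = len(truth) - tp
    fp_rate = fp / len(called_mids) if len(called_mids) else 0.0
    fn_rate = fn / len(truth) if len(truth) else 0.0
    return ConfusionResult(tp, fp, fn, fp_rate, fn_rate,
                           matched_truth_indices=tuple(sorted(j for _, j, _ in pairs)))
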