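"""Windowed diversity and differentiation statistics and demography summaries.

Implements the classical estimators directly from allele counts:

* pi (nucleotide diversity): per site ``2 p (1-p) n/(n-1)``, summed over sites
  and divided by the callable window length.
* Watterson's theta: ``S / (a_n * L)`` with ``a_n = sum_{i=1}^{n-1} 1/i``.
* Tajima's D with the standard 1989 normalizing constants; windows with fewer
  than 3 segregating sites report NaN (the variance estimate is unstable).
* Weir & Cockerham (1984) FST with the windowed ratio-of-sums convention
  ``sum(a) / sum(a+b+c)``.

Median-permutation contrasts compare the median of a target window set (e.g.
hotspots) against medians of equally sized random draws from the genome-wide
window pool.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ancestry_polarization import GenotypeTable

__all__ = [
    "DiversityWindow",
    "FstWindow",
    "DemographicTrajectory",
    "MedianPermResult",
    "diversity_windows",
    "wc_fst_windows",
    "wc_site_components",
    "median_permutation_test",
    "summarize_bottleneck",
    "pooled_theta",
    "read_trajectory",
    "tajima_constants",
]


@dataclass(frozen=True)
class DiversityWindow:
    chrom: str
    start: int
    end: int
    pi: float          # per site
    theta_w: float     # per site
    tajimas_d: float   # NaN when undefined
    s: int             # segregating sites
    n: int             # haplotypes
    length: int        # callable bp


@dataclass(frozen=True)
class FstWindow:
    chrom: str
    start: int
    end: int
    fst: float
    n_sites: int


def tajima_constants(n: int):
    """Normalizing constants for Tajima's D at sample size n (haplotypes)."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return a1, e1, e2


def diversity_windows(gt: GenotypeTable, window: int = 2000,
                      step: int | None = None, min_s_for_d: int = 3,
                      chrom_length: int | None = None):
    """Per-window pi, Watterson's theta and Tajima's D.

    Callable length is taken as the window span.  Sites with missing calls
    use their per-site called-haplotype count for pi; theta and D use the
    window's modal sample size.
    """
    step = window if step is None else step
    positions = gt.positions()
    n_called, alt = gt.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, alt / np.maximum(n_called, 1), 0.0)
        pi_site = np.where(n_called > 1,
                           2.0 * p * (1 - p) * n_called / np.maximum(n_called - 1, 1),
                           0.0)
    seg = (alt > 0) & (alt < n_called)
    if chrom_length is None:
        chrom_length = int(positions.max()) if len(positions) else window
    out = []
    chrom = str(gt.sites["chrom"].iloc[0]) if gt.n_sites else "chr"
    for start in range(0, chrom_length, step):
        end = min(start + window, chrom_length)
        length = end - start
        if length == 0:
            continue
        in_win = (positions > start) & (positions <= end)  # 1-based positions
        s = int(np.sum(seg & in_win))
        pi_sum = float(np.sum(pi_site[in_win & seg]))
        n_win = int(np.max(n_called[in_win])) if np.any(in_win) else gt.n_haplotypes
        if n_win < 2:
            continue
        a1, e1, e2 = tajima_constants(n_win)
        theta_w = s / (a1 * length)
        pi = pi_sum / length
        if s >= min_s_for_d:
            var = e1 * s + e2 * s * (s - 1)
            num = pi_sum - s / a1
            if var > 0:
                d = num / math.sqrt(var)
            else:
                # n = 2: pi and theta_W coincide, so D is identically 0
                d = 0.0 if abs(num) < 1e-12 else math.nan
        else:
            d = math.nan
        out.append(DiversityWindow(chrom, start, end, pi, theta_w, d, s,
                                   n_win, length))
    return out


def wc_site_components(n1, p1, h1, n2, p2, h2):
    """Weir & Cockerham (1984) variance components a, b, c for one biallelic
    site and two populations.

    ``n`` are sample sizes in diploid individuals, ``p`` alternate-allele
    frequencies and ``h`` observed heterozygote frequencies.
    """
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    if nbar <= 1 or nc == 0:
        return 0.0, 0.0, 0.0
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                               - hbar * (2 * nbar - 1) / (4 * nbar))
    c = hbar / 2
    return a, b, c


def wc_fst_windows(gt_a: GenotypeTable, gt_b: GenotypeTable,
                   window: int = 1000, chrom_length: int | None = None):
    """Windowed Weir-Cockerham FST over the sites shared by two populations.

    Per window, FST = sum(a) / sum(a+b+c) over per-site variance components
    (the ratio-of-sums convention).  Monomorphic windows report NaN.
    """
    key_a = {(c, p): i for i, (c, p) in
             enumerate(zip(gt_a.sites["chrom"], gt_a.sites["pos"]))}
    idx_a, idx_b = [], []
    for i, (c, p) in enumerate(zip(gt_b.sites["chrom"], gt_b.sites["pos"])):
        j = key_a.get((c, p))
        if j is not None:
            idx_a.append(j)
            idx_b.append(i)
    if not idx_a:
        return []
    sub_a, sub_b = gt_a.take_sites(idx_a), gt_b.take_sites(idx_b)
    positions = sub_a.positions()
    chrom = str(sub_a.sites["chrom"].iloc[0])

    def pop_stats(gt):
        g = gt.genotypes
        called = (g >= 0).all(axis=2)
        n = called.sum(axis=1).astype(float)
        alt = np.where(called[:, :, None], g, 0).sum(axis=(1, 2)).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / (gt.ploidy * np.maximum(n, 1))
        if gt.ploidy == 2:
            het = ((g[:, :, 0] != g[:, :, 1]) & called).sum(axis=1)
            h = het / np.maximum(n, 1)
        else:
            h = np.zeros_like(p)
        return n, p, h

    n1, p1, h1 = pop_stats(sub_a)
    n2, p2, h2 = pop_stats(sub_b)
    comp = np.array([wc_site_components(n1[i], p1[i], h1[i], n2[i], p2[i], h2[i])
                     for i in range(len(positions))])
    variable = (np.maximum(p1, p2) > 0) & (np.minimum(p1, p2) < 1)
    if chrom_length is None:
        chrom_length = int(positions.max())
    out = []
    for start in range(0, chrom_length, window):
        end = min(start + window, chrom_length)
        in_win = (positions > start) & (positions <= end) & variable
        n_sites = int(in_win.sum())
        if n_sites == 0:
            out.append(FstWindow(chrom, start, end, math.nan, 0))
            continue
        a_sum = comp[in_win, 0].sum()
        denom = comp[in_win].sum()
        fst = a_sum / denom if denom != 0 else math.nan
        out.append(FstWindow(chrom, start, end, float(fst), n_sites))
    return out


@dataclass(frozen=True)
class MedianPermResult:
    observed_median: float
    null_medians: np.ndarray
    p_value: float
    n_draws: int
    seed: int | None
    direction: str


def median_permutation_test(target_values, genome_values, n_draws: int = 10000,
                            seed: int | None = None) -> MedianPermResult:
    """Test whether the median of a target window set could arise from random
    equally sized draws of genome-wide windows.

    Each draw samples ``len(target_values)`` genome windows without
    replacement; the one-sided p-value (with +1 pseudo-count) is taken in the
    direction of the observed deviation from the null median.
    """
    target = np.asarray(target_values, dtype=float)
    pool = np.asarray(genome_values, dtype=float)
    k = len(target)
    if k < 1 or len(pool) < k:
        raise ValueError("need 1 <= |target| <= |genome pool|")
    rng = np.random.default_rng(seed)
    observed = float(np.median(target))
    null = np.empty(n_draws)
    for i in range(n_draws):
        null[i] = np.median(rng.choice(pool, size=k, replace=False))
    if observed >= np.median(null):
        direction = "ge"
        extreme = int(np.sum(null >= observed))
    else:
        direction = "le"
        extreme = int(np.sum(null <= observed))
    p = (extreme + 1) / (n_draws + 1)
    return MedianPermResult(observed, null, p, n_draws, seed, direction)


@dataclass(frozen=True)
class DemographicTrajectory:
    """Step function of effective population size over time (earliest first)."""

    times: np.ndarray   # step start times (generations or years), increasing
    ne: np.ndarray      # effective sizes, > 0
    label: str = ""

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        ne = np.asarray(self.ne, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "ne", ne)
        if len(times) != len(ne) or len(times) == 0:
            raise ValueError("times and Ne must be equal-length and non-empty")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be increasing")
        if np.any(ne <= 0):
            raise ValueError("Ne must be positive")


def read_trajectory(path, label: str = "") -> DemographicTrajectory:
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                     names=["time", "ne"])
    return DemographicTrajectory(df["time"].to_numpy(), df["ne"].to_numpy(),
                                 label)


def summarize_bottleneck(tr: DemographicTrajectory,
                         start_mode: str = "max_before_min"):
    """Bottleneck summary: pre-bottleneck Ne, minimum Ne and percent reduction.

    ``start_mode='max_before_min'`` takes the largest Ne at or before the
    global minimum (the pre-bottleneck plateau); ``'earliest'`` uses the first
    step.  Returns ``(start_ne, min_ne, pct_reduction)``; a constant
    trajectory reduces by 0%.
    """
    i_min = int(np.argmin(tr.ne))
    min_ne = float(tr.ne[i_min])
    if start_mode == "max_before_min":
        start_ne = float(np.max(tr.ne[: i_min + 1]))
    elif start_mode == "earliest":
        start_ne = float(tr.ne[0])
    else:
        raise ValueError(f"unknown start_mode: {start_mode}")
    pct = 100.0 * (start_ne - min_ne) / start_ne
    return start_ne, min_ne, pct


def pooled_theta(thetas) -> float:
    """Arithmetic mean of per-population Watterson's theta values."""
    arr = np.asarray(list(thetas), dtype=float)
    if arr.size == 0:
        raise ValueError("no theta values")
    return float(arr.mean())
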