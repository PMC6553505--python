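"""Sliding-window recombination hotspot caller and hotspot summary statistics.

A hotspot is a narrow (default 2 kb) window whose mean rho is at least
``fold_threshold`` (default 5) times the mean rate of the flanking background
(default 40 kb on each side, excluding the focal window).  Candidate windows
are greedily merged so that no two retained hotspots have midpoints within
``merge_radius``, and candidates spanning an assembly contig boundary are
removed as likely reference artifacts.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .landscape_io import RhoMap

__all__ = [
    "CallerConfig",
    "Hotspot",
    "HotspotSet",
    "PlacementResult",
    "call_hotspots",
    "classify_placement",
    "nearest_neighbor_spacing",
    "intensity_by_region",
    "two_proportion_ztest",
    "write_hotspots_bed",
    "write_hotspots_tsv",
    "read_hotspots_tsv",
]

TERMINAL = "terminal"
INTERNAL = "internal"


@dataclass(frozen=True)
class CallerConfig:
    """Sliding-window hotspot caller parameters (all in bp except the ratio)."""

    window: int = 2000
    step: int = 1000
    flank: int = 40000
    fold_threshold: float = 5.0
    merge_radius: int = 5000
    min_flank_covered: int = 10000

    def __post_init__(self):
        for name in ("window", "step", "flank", "merge_radius", "min_flank_covered"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must be > 1")


@dataclass(frozen=True)
class Hotspot:
    chrom_id: str
    start: int
    end: int
    rate: float
    flank_rate: float
    intensity: float
    placement: str | None = None

    @property
    def midpoint(self) -> float:
        return self.start + (self.end - self.start) / 2


@dataclass
class HotspotSet:
    """Hotspots on one chromosome (sorted by start) plus the config that made them."""

    population_label: str
    hotspots: list
    config: CallerConfig
    chrom_length: int = 0
    n_contig_removed: int = 0

    def __len__(self):
        return len(self.hotspots)

    def __iter__(self):
        return iter(self.hotspots)

    def midpoints(self) -> np.ndarray:
        return np.array([h.midpoint for h in self.hotspots], dtype=float)

    def rates(self) -> np.ndarray:
        return np.array([h.rate for h in self.hotspots], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "chrom": h.chrom_id, "start": h.start, "end": h.end,
            "midpoint": h.midpoint, "rate": h.rate, "flank_rate": h.flank_rate,
            "intensity": h.intensity, "placement": h.placement,
        } for h in self.hotspots])


def _placement_label(midpoint: float, chrom_length: int) -> str:
    q = chrom_length / 4.0
    # boundary points (exactly at 25%/75%) classify as internal
    return TERMINAL if (midpoint < q or midpoint > 3 * q) else INTERNAL


def call_hotspots(rmap: RhoMap, config: CallerConfig = CallerConfig(),
                  population_label: str = "") -> HotspotSet:
    """Call recombination hotspots on a rho map.

    Windows of ``config.window`` bp are placed every ``config.step`` bp.  Each
    window's length-weighted mean rho is compared with the mean over up to
    ``config.flank`` bp on each side (excluding the focal window, truncated at
    chromosome ends); windows with less than ``config.min_flank_covered`` bp of
    flank on either side are skipped.  Candidates at or above the fold
    threshold are merged greedily in descending rate order (ties broken
    leftmost): a candidate is suppressed if its midpoint lies within
    ``config.merge_radius`` of an already-accepted one.  Finally, candidates
    spanning a contig boundary are removed and counted.

    A zero flank rate with a positive window rate yields an accepted candidate
    with infinite intensity.
    """
    L = rmap.chrom_length
    w = config.window
    if L < w:
        raise ValueError("chromosome shorter than the hotspot window")
    starts = np.arange(0, L - w + 1, config.step, dtype=np.int64)
    ends = starts + w
    rate = rmap.integral(starts, ends) / w

    lf_lo = np.maximum(starts - config.flank, 0)
    rf_hi = np.minimum(ends + config.flank, L)
    l_cov = starts - lf_lo
    r_cov = rf_hi - ends
    ok = (l_cov >= config.min_flank_covered) & (r_cov >= config.min_flank_covered)

    flank_int = rmap.integral(lf_lo, starts) + rmap.integral(ends, rf_hi)
    flank_cov = (l_cov + r_cov).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        flank_rate = np.where(flank_cov > 0, flank_int / flank_cov, 0.0)
        intensity = np.where(flank_rate > 0, rate / flank_rate,
                             np.where(rate > 0, np.inf, np.nan))
    # flank_rate == 0 and rate == 0 -> skipped
    ok &= ~((flank_rate == 0) & (rate == 0))
    # intensities quantized to 12 significant digits so plantings sitting
    # mathematically on the fold threshold compare deterministically
    q_int = np.array([float(f"{x:.12g}") if np.isfinite(x) else x
                      for x in intensity])
    cand = ok & (q_int >= config.fold_threshold)
    idx = np.flatnonzero(cand)

    # greedy merge: descending rate, ties leftmost; rates are quantized to 12
    # significant digits so mathematically equal windows tie deterministically
    q_rate = np.array([float(f"{r:.12g}") for r in rate[idx]])
    order = idx[np.lexsort((starts[idx], -q_rate))]
    accepted = []
    accepted_mids: list[float] = []
    for i in order:
        mid = starts[i] + w / 2
        if any(abs(mid - m) <= config.merge_radius for m in accepted_mids):
            continue
        accepted.append(i)
        accepted_mids.append(mid)

    boundaries = np.array(sorted(rmap.contig_boundaries), dtype=float)
    hotspots = []
    n_removed = 0
    for i in sorted(accepted, key=lambda j: starts[j]):
        s, e = int(starts[i]), int(ends[i])
        if boundaries.size:
            j = np.searchsorted(boundaries, s, side="right")  # first boundary > s
            if j < boundaries.size and boundaries[j] < e:  # strictly inside (s, e)
                n_removed += 1
                continue
        hotspots.append(Hotspot(
            chrom_id=rmap.chrom_id, start=s, end=e,
            rate=float(rate[i]), flank_rate=float(flank_rate[i]),
            intensity=float(intensity[i]),
            placement=_placement_label(s + w / 2, L),
        ))
    return HotspotSet(population_label, hotspots, config, chrom_length=L,
                      n_contig_removed=n_removed)


@dataclass(frozen=True)
class PlacementResult:
    labels: list
    terminal_count: int
    internal_count: int
    terminal_frac: float
    internal_frac: float
    z: float
    p_value: float
    empty: bool = False


def two_proportion_ztest(x1: int, n1: int, x2: int, n2: int):
    """Two-proportion Z-test with pooled variance; two-sided p-value."""
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    return z, 2 * stats.norm.sf(abs(z))


def classify_placement(hs: HotspotSet, chrom_length: int | None = None) -> PlacementResult:
    """Classify hotspots as terminal (outer chromosome quarters) or internal
    (middle half) by midpoint, and test the two proportions against each other.
    """
    L = chrom_length if chrom_length is not None else hs.chrom_length
    if L <= 0:
        raise ValueError("chrom_length must be positive")
    n = len(hs)
    if n == 0:
        return PlacementResult([], 0, 0, math.nan, math.nan, math.nan, math.nan,
                               empty=True)
    labels = [_placement_label(h.midpoint, L) for h in hs]
    t = labels.count(TERMINAL)
    i = n - t
    z, p = two_proportion_ztest(t, n, i, n)
    return PlacementResult(labels, t, i, t / n, i / n, z, p)


def nearest_neighbor_spacing(hs: HotspotSet):
    """Distance from each hotspot midpoint to its nearest neighbor on the same
    chromosome.  Returns ``(distances, mean, median)``; empty with <2 hotspots.
    """
    by_chrom: dict[str, list[float]] = {}
    for h in hs:
        by_chrom.setdefault(h.chrom_id, []).append(h.midpoint)
    distances = []
    for mids in by_chrom.values():
        if len(mids) < 2:
            continue
        m = np.sort(np.asarray(mids, dtype=float))
        gaps = np.diff(m)
        left = np.concatenate([[np.inf], gaps])
        right = np.concatenate([gaps, [np.inf]])
        distances.extend(np.minimum(left, right).tolist())
    if not distances:
        return [], math.nan, math.nan
    arr = np.asarray(distances)
    return distances, float(arr.mean()), float(np.median(arr))


def intensity_by_region(hs: HotspotSet, chrom_length: int | None = None):
    """Mean hotspot rate in terminal vs internal placements and a two-sample
    Wilcoxon rank-sum p-value.  Returns ``(terminal_mean, internal_mean, p)``;
    p is NaN if either class is empty.
    """
    L = chrom_length if chrom_length is not None else hs.chrom_length
    term = [h.rate for h in hs if _placement_label(h.midpoint, L) == TERMINAL]
    internal = [h.rate for h in hs if _placement_label(h.midpoint, L) == INTERNAL]
    t_mean = float(np.mean(term)) if term else math.nan
    i_mean = float(np.mean(internal)) if internal else math.nan
    if not term or not internal:
        return t_mean, i_mean, math.nan
    res = stats.mannwhitneyu(term, internal, alternative="two-sided",
                             method="exact" if max(len(term), len(internal)) <= 20 else "asymptotic")
    return t_mean, i_mean, float(res.pvalue)


def write_hotspots_bed(hs: HotspotSet, path) -> None:
    """BED6 export; score = min(1000, round(100 * intensity))."""
    rows = []
    for k, h in enumerate(hs):
        score = 1000 if math.isinf(h.intensity) else min(1000, round(100 * h.intensity))
        rows.append(f"{h.chrom_id}\t{h.start}\t{h.end}\thotspot_{k}\t{score}\t.")
    text = "\n".join(rows) + ("\n" if rows else "")
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


def write_hotspots_tsv(hs: HotspotSet, path) -> None:
    hs.to_frame().to_csv(path, sep="\t", index=False)


def read_hotspots_tsv(path, population_label: str = "",
                      config: CallerConfig = CallerConfig()) -> HotspotSet:
    df = pd.read_csv(path, sep="\t")
    hotspots = [Hotspot(
        chrom_id=str(r.chrom), start=int(r.start), end=int(r.end),
        rate=float(r.rate), flank_rate=float(r.flank_rate),
        intensity=float(r.intensity),
        placement=None if pd.isna(r.placement) else str(r.placement),
    ) for r in df.itertuples()]
    return HotspotSet(population_label, hotspots, config)
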