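"""Shared fixtures: random map generators and independent oracles."""
from __future__ import annotations

import math
import numpy as np
import pytest

from recland.landscape_io import RhoMap


def random_rho_map(rng, length=None, max_intervals=40, chrom_id="chr",
                   with_contigs=False, sig_digits=None):
    """Random piecewise-constant rho map for round-trip and oracle tests."""
    if length is None:
        length = int(rng.integers(20000, 200001))
    k = int(rng.integers(1, max_intervals + 1))
    cuts = np.sort(rng.choice(np.arange(1, length), size=min(k - 1, length - 1),
                              replace=False)) if k > 1 else np.array([], dtype=int)
    starts = np.concatenate([[0], cuts])
    ends = np.concatenate([cuts, [length]])
    rho = rng.lognormal(mean=np.log(3e-5), sigma=1.5, size=len(starts))
    # occasional zero-rate and spike intervals
    rho[rng.random(len(rho)) < 0.1] = 0.0
    spikes = rng.random(len(rho)) < 0.1
    rho[spikes] *= 50
    if sig_digits is not None:
        rho = np.array([float(f"%.{sig_digits}g" % r) for r in rho])
    boundaries = frozenset()
    if with_contigs and rng.random() < 0.7:
        nb = int(rng.integers(1, 4))
        boundaries = frozenset(int(x) for x in
                               rng.integers(1, length, size=nb))
    return RhoMap(chrom_id, starts, ends, rho, length, boundaries)


def brute_force_hotspots(rmap, config):
    """Literal re-implementation of the hotspot calling rules.

    Enumerates every window, computes flank means by direct interval-overlap
    scans, applies the fold threshold, merges greedily in descending rate
    order (ties leftmost) and drops windows spanning a contig boundary.
    Returns a list of (start, end, rate, flank_rate, intensity) tuples sorted
    by start.
    """
    L = rmap.chrom_length
    cfg = config

    def mean_rho(a, b):
        if b <= a:
            return 0.0
        tot = 0.0
        for s, e, r in zip(rmap.starts, rmap.ends, rmap.rho):
            o = min(int(e), b) - max(int(s), a)
            if o > 0:
                tot += r * o
        return tot / (b - a)

    cands = []
    start = 0
    while start + cfg.window <= L:
        w0, w1 = start, start + cfg.window
        lf0 = max(0, w0 - cfg.flank)
        rf1 = min(L, w1 + cfg.flank)
        lcov, rcov = w0 - lf0, rf1 - w1
        if lcov >= cfg.min_flank_covered and rcov >= cfg.min_flank_covered:
            rate = mean_rho(w0, w1)
            flank = ((mean_rho(lf0, w0) * lcov + mean_rho(w1, rf1) * rcov)
                     / (lcov + rcov))
            if not (flank == 0 and rate == 0):
                inten = rate / flank if flank > 0 else float("inf")
                # quantized to 12 significant digits, as in the caller
                q = float(f"{inten:.12g}") if math.isfinite(inten) else inten
                if q >= cfg.fold_threshold:
                    cands.append((w0, w1, rate, flank, inten))
        start += cfg.step
    kept = []
    # rates quantized to 12 significant digits for deterministic tie-breaking
    for c in sorted(cands, key=lambda c: (-float(f"{c[2]:.12g}"), c[0])):
        mid = c[0] + cfg.window / 2
        if all(abs(mid - (k[0] + cfg.window / 2)) > cfg.merge_radius
               for k in kept):
            kept.append(c)
    out = []
    for c in sorted(kept):
        if any(c[0] < b < c[1] for b in rmap.contig_boundaries):
            continue
        out.append(c)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
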