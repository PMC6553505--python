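"""Data model and I/O for per-bp recombination maps and genetic linkage maps.

The central container is :class:`RhoMap`, a piecewise-constant map of the
population-scaled recombination rate rho = 4*Ne*r per base pair along a single
chromosome.  LD-based estimators report rho between adjacent SNPs; here those
inter-SNP segments become gap-free intervals tiling ``[0, chrom_length)``, with
the regions outside the SNP span padded with the nearest interval's rate.

Coordinates are 0-based half-open internally; files on disk are 1-based and
converted at the I/O boundary.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RhoMap",
    "GeneticMap",
    "WindowedRates",
    "RegionalSummary",
    "RhoMapFormatError",
    "read_rho_map",
    "write_rho_map",
    "read_genetic_map",
    "window_mean_rate",
    "broad_scale_correlation",
    "map_conversion_factor",
    "regional_rate_summary",
    "x_autosome_ratio",
]


class RhoMapFormatError(ValueError):
    """Raised when a rho-map file violates the expected column/ordering contract."""


@dataclass(frozen=True)
class RhoMap:
    """Piecewise-constant per-bp population recombination rate on one chromosome.

    Parameters
    ----------
    chrom_id:
        Chromosome label.
    starts, ends:
        Interval boundaries (0-based half-open).  Intervals must be sorted,
        non-overlapping and tile ``[0, chrom_length)`` with no gaps.
    rho:
        Rate (rho/bp) per interval; finite and >= 0.
    chrom_length:
        Total chromosome length in bp.
    contig_boundaries:
        Positions of assembly contig joins, in ``[0, chrom_length]``.
    """

    chrom_id: str
    starts: np.ndarray
    ends: np.ndarray
    rho: np.ndarray
    chrom_length: int
    contig_boundaries: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        starts = np.asarray(self.starts, dtype=np.int64)
        ends = np.asarray(self.ends, dtype=np.int64)
        rho = np.asarray(self.rho, dtype=np.float64)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        object.__setattr__(self, "rho", rho)
        if not (len(starts) == len(ends) == len(rho)):
            raise ValueError("starts, ends and rho must have equal length")
        if len(starts) == 0:
            raise ValueError("RhoMap needs at least one interval")
        if starts[0] != 0 or ends[-1] != self.chrom_length:
            raise ValueError("intervals must tile [0, chrom_length)")
        if np.any(starts[1:] != ends[:-1]):
            raise ValueError("intervals must be contiguous and sorted")
        if np.any(ends <= starts):
            raise ValueError("empty or inverted interval")
        if np.any(~np.isfinite(rho)) or np.any(rho < 0):
            raise ValueError("rho must be finite and >= 0")
        for b in self.contig_boundaries:
            if not (0 <= b <= self.chrom_length):
                raise ValueError("contig boundary outside chromosome")
        # cumulative integral of rho for O(log n) range queries
        cum = np.concatenate([[0.0], np.cumsum(rho * (ends - starts))])
        object.__setattr__(self, "_cum", cum)

    @property
    def n_intervals(self) -> int:
        return len(self.starts)

    def total_map_length(self) -> float:
        """Integral of rho over the whole chromosome (units: rho)."""
        return float(self._cum[-1])

    def mean_rate(self, start=None, end=None):
        """Length-weighted mean rho over ``[start, end)`` (whole map by default)."""
        if start is None and end is None:
            return self.total_map_length() / self.chrom_length
        integral = self.integral(start, end)
        span = np.asarray(end, dtype=float) - np.asarray(start, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = integral / span
        return out

    def integral(self, start, end):
        """Integral of rho over ``[start, end)``.  Accepts scalars or arrays."""
        a = np.clip(np.asarray(start, dtype=float), 0, self.chrom_length)
        b = np.clip(np.asarray(end, dtype=float), 0, self.chrom_length)
        scalar = a.ndim == 0
        a, b = np.atleast_1d(a), np.atleast_1d(b)
        # index of interval containing each endpoint
        ia = np.searchsorted(self.ends, a, side="right")
        ib = np.searchsorted(self.ends, b, side="right")
        ia = np.minimum(ia, self.n_intervals - 1)
        ib = np.minimum(ib, self.n_intervals - 1)
        full = (
            self._cum[ib] - self._cum[ia]
            - self.rho[ia] * (a - self.starts[ia])
            + self.rho[ib] * (b - self.starts[ib])
        )
        out = np.where(b > a, full, 0.0)
        return float(out[0]) if scalar else out

    def rate_at(self, pos):
        """rho at position(s) ``pos``."""
        idx = np.searchsorted(self.ends, np.asarray(pos), side="right")
        idx = np.minimum(idx, self.n_intervals - 1)
        return self.rho[idx]

    def scaled(self, factor: float) -> "RhoMap":
        """New map with every rate multiplied by ``factor``."""
        return RhoMap(self.chrom_id, self.starts, self.ends, self.rho * factor,
                      self.chrom_length, self.contig_boundaries)


@dataclass(frozen=True)
class GeneticMap:
    """Linkage-map markers on one chromosome: physical bp vs map position in cM."""

    chrom_id: str
    positions: np.ndarray  # bp, strictly increasing
    cm: np.ndarray         # centimorgans, non-decreasing

    def __post_init__(self):
        positions = np.asarray(self.positions, dtype=np.int64)
        cm = np.asarray(self.cm, dtype=np.float64)
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "cm", cm)
        if len(positions) != len(cm):
            raise ValueError("positions and cM must have equal length")
        if np.any(np.diff(positions) <= 0):
            raise ValueError("marker positions must be strictly increasing")
        if np.any(np.diff(cm) < 0):
            raise ValueError("cM positions must be non-decreasing")

    @property
    def n_markers(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class WindowedRates:
    """Windowed length-weighted mean rates along one chromosome."""

    chrom_id: str
    window_size: int
    step: int
    starts: np.ndarray
    ends: np.ndarray
    mean_rho: np.ndarray
    covered_bp: np.ndarray

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    def to_bedgraph(self, path) -> None:
        df = pd.DataFrame({
            "chrom": self.chrom_id,
            "start": self.starts,
            "end": self.ends,
            "mean_rho": self.mean_rho,
        })
        df.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


@dataclass(frozen=True)
class RegionalSummary:
    """Length-weighted mean rho in terminal vs central chromosome regions."""

    terminal_mean: float
    central_mean: float
    scheme: str
    terminal_bp: int
    central_bp: int


def read_rho_map(path, chrom_length: int, position_base: int = 1,
                 chrom_id: str = "chr", contig_boundaries=()) -> RhoMap:
    """Read a whitespace-delimited rho map (``left_pos right_pos mean_rho ...``).

    The file style follows LDHelmet's ``post_to_text`` output: one row per
    inter-SNP segment, optional ``#`` comment lines, extra columns ignored.
    1-based positions (``position_base=1``) are converted to the internal
    0-based half-open convention.  The chromosome ends outside the SNP span
    are padded with the nearest segment's rate; internal gaps between rows
    extend the preceding segment.
    """
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    rows = []
    for lineno, line in enumerate(lines, start=1):
        text = line.strip()
        if not text or text.startswith("#"):
            continue
        parts = text.split()
        if len(parts) < 3:
            raise RhoMapFormatError(f"line {lineno}: expected >=3 columns, got {len(parts)}")
        try:
            left, right, rho = float(parts[0]), float(parts[1]), float(parts[2])
        except ValueError as exc:
            raise RhoMapFormatError(f"line {lineno}: non-numeric field") from exc
        if rows and left < rows[-1][0]:
            raise RhoMapFormatError(f"line {lineno}: left_pos decreases")
        if right <= left:
            raise RhoMapFormatError(f"line {lineno}: right_pos <= left_pos")
        if rho < 0:
            raise ValueError(f"line {lineno}: negative rho")
        rows.append((left, right, rho, lineno))
    if not rows:
        raise RhoMapFormatError("no data rows in rho map file")

    starts, ends, rhos = [], [], []
    for left, right, rho, lineno in rows:
        s = int(left) - (1 if position_base == 1 else 0)
        e = int(right) - (1 if position_base == 1 else 0)
        if starts and s < ends[-1]:
            raise RhoMapFormatError(f"line {lineno}: interval overlaps previous row")
        if starts and s > ends[-1]:
            # internal gap: extend the previous segment's rate
            starts.append(ends[-1])
            ends.append(s)
            rhos.append(rhos[-1])
        starts.append(s)
        ends.append(e)
        rhos.append(rho)
    # pad chromosome ends with the nearest rate
    if starts[0] > 0:
        starts.insert(0, 0)
        ends.insert(0, starts[1])
        rhos.insert(0, rhos[0])
    if ends[-1] > chrom_length:
        raise RhoMapFormatError("rho map extends past chrom_length")
    if ends[-1] < chrom_length:
        starts.append(ends[-1])
        ends.append(chrom_length)
        rhos.append(rhos[-1])
    return RhoMap(chrom_id, np.array(starts), np.array(ends), np.array(rhos),
                  chrom_length, frozenset(contig_boundaries))


def write_rho_map(rmap: RhoMap, path, position_base: int = 1) -> None:
    """Write a rho map in the 3-column text dialect read by :func:`read_rho_map`.

    Rates are emitted with 6 significant digits.
    """
    off = 1 if position_base == 1 else 0
    buf = io.StringIO()
    buf.write("# left_pos right_pos mean_rho\n")
    for s, e, r in zip(rmap.starts, rmap.ends, rmap.rho):
        buf.write(f"{s + off} {e + off} {r:.6g}\n")
    if hasattr(path, "write"):
        path.write(buf.getvalue())
    else:
        with open(path, "w") as fh:
            fh.write(buf.getvalue())


def read_genetic_map(path) -> dict:
    """Read a ``chrom pos_bp cM`` TSV into per-chromosome :class:`GeneticMap`."""
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                     names=["chrom", "pos", "cm"])
    out = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("pos")
        out[str(chrom)] = GeneticMap(str(chrom), grp["pos"].to_numpy(),
                                     grp["cm"].to_numpy())
    return out


def window_mean_rate(rmap: RhoMap, window_size: int, step: int | None = None) -> WindowedRates:
    """Length-weighted mean rho in sliding windows.

    The final partial window is retained with its actual covered span; a
    window size exceeding the chromosome yields a single truncated window.
    """
    if window_size <= 0:
        raise ValueError("window_size must be > 0")
    step = window_size if step is None else step
    if step <= 0:
        raise ValueError("step must be > 0")
    starts = np.arange(0, rmap.chrom_length, step, dtype=np.int64)
    ends = np.minimum(starts + window_size, rmap.chrom_length)
    covered = ends - starts
    means = rmap.integral(starts, ends) / covered
    return WindowedRates(rmap.chrom_id, window_size, step, starts, ends,
                         means, covered)


def broad_scale_correlation(a: WindowedRates, b: WindowedRates):
    """Spearman rank correlation between two windowed maps, paired on coordinates.

    Returns ``(spearman_rho, p_value, n_windows)``.  Ties are mid-ranked.
    """
    key_a = {(s, e): m for s, e, m in zip(a.starts, a.ends, a.mean_rho)}
    xs, ys = [], []
    for s, e, m in zip(b.starts, b.ends, b.mean_rho):
        if (s, e) in key_a:
            xs.append(key_a[(s, e)])
            ys.append(m)
    if len(xs) < 3:
        raise ValueError("fewer than 3 paired windows: correlation undefined")
    res = stats.spearmanr(xs, ys)
    return float(res.statistic), float(res.pvalue), len(xs)


def map_conversion_factor(gmap: GeneticMap, rmap: RhoMap, weighted: bool = False):
    """Chromosome-level cM-per-rho conversion factor from a linkage map.

    For every adjacent marker pair the linkage rate (cM/Mb) and LD rate
    (rho/Mb, the length-weighted mean rho scaled by 1e6) are computed; the
    chromosome averages are unweighted means across marker intervals (a
    length-weighted average is available via ``weighted=True``) and the factor
    is ``avg(cM/Mb) / avg(rho/Mb)``.  Multiplying a rho/Mb rate by the factor
    converts it to cM/Mb.

    Returns ``(factor, per_interval)`` where ``per_interval`` is a DataFrame
    with columns start, end, cm_per_mb, rho_per_mb.
    """
    if gmap.n_markers < 2:
        raise ValueError("need at least 2 markers")
    if gmap.positions[0] < 0 or gmap.positions[-1] > rmap.chrom_length:
        raise ValueError("markers outside chromosome")
    p0, p1 = gmap.positions[:-1], gmap.positions[1:]
    span_mb = (p1 - p0) / 1e6
    cm_per_mb = np.diff(gmap.cm) / span_mb
    rho_per_mb = rmap.integral(p0, p1) / (p1 - p0) * 1e6
    if weighted:
        w = (p1 - p0).astype(float)
        avg_cm = float(np.average(cm_per_mb, weights=w))
        avg_rho = float(np.average(rho_per_mb, weights=w))
    else:
        avg_cm = float(np.mean(cm_per_mb))
        avg_rho = float(np.mean(rho_per_mb))
    if avg_rho == 0:
        raise ZeroDivisionError(
            "average LD-based rate is zero; cannot form cM/rho conversion factor")
    per_interval = pd.DataFrame({
        "start": p0, "end": p1,
        "cm_per_mb": cm_per_mb, "rho_per_mb": rho_per_mb,
    })
    return avg_cm / avg_rho, per_interval


def regional_rate_summary(rmap: RhoMap, scheme: str = "quarter_ends_vs_center_quarter") -> RegionalSummary:
    """Mean rho in the terminal chromosome quarters vs a central region.

    ``quarter_ends_vs_center_quarter`` contrasts the combined outer quarters
    against the middle quarter (a broad-scale rate contrast);
    ``quarter_ends_vs_middle_half`` contrasts them against the middle half so
    the two classes partition the chromosome (the convention used for hotspot
    placement).
    """
    L = rmap.chrom_length
    q = L // 4
    term_integral = rmap.integral(0, q) + rmap.integral(L - q, L)
    term_bp = 2 * q
    if scheme == "quarter_ends_vs_center_quarter":
        c_lo = L // 2 - L // 8
        c_hi = c_lo + q
    elif scheme == "quarter_ends_vs_middle_half":
        c_lo, c_hi = q, L - q
    else:
        raise ValueError(f"unknown scheme: {scheme}")
    cent_integral = rmap.integral(c_lo, c_hi)
    cent_bp = c_hi - c_lo
    return RegionalSummary(
        terminal_mean=term_integral / term_bp,
        central_mean=cent_integral / cent_bp,
        scheme=scheme,
        terminal_bp=term_bp,
        central_bp=cent_bp,
    )


def x_autosome_ratio(x_mean: float, autosome_mean: float) -> float:
    """Ratio of the X-chromosome mean rate to the autosome mean rate.

    With an equal sex ratio the X recombines in two-thirds of meioses, so this
    ratio is expected near 2/3.
    """
    if autosome_mean == 0:
        raise ZeroDivisionError("autosome mean rate is zero")
    return x_mean / autosome_mean
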