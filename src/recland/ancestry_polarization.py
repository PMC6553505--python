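"""Variant filtering, outgroup-based ancestral polarization and GC-bias statistics.

Ancestral states are assigned from two outgroup species: when both are
homozygous for the same nucleotide, that base receives a prior probability of
0.91 and the three alternatives 0.03 each; otherwise the prior falls back to
the chromosome-wide nucleotide frequencies.  Per-chromosome 4x4 mutation
matrices count mutations away from the ancestral allele at confidently
polarized sites.  Substitutions between an ancestral sequence and a
population are classified strong/weak (AT->GC vs GC->AT) after masking
ancestral CpG dinucleotides, and the equilibrium GC content is

    GC* = n(AT->GC) / (n(AT->GC) + n(GC->AT)),

the stationary GC fraction implied by the observed substitution flux and a
standard proxy for GC-biased gene conversion intensity.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"
_NT_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}
_ACGT_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_AT_BYTES = np.frombuffer(b"AT", dtype=np.uint8)
_GC_BYTES = np.frombuffer(b"GC", dtype=np.uint8)

__all__ = [
    "GenotypeTable",
    "FilterRules",
    "FilterReport",
    "AncestralPrior",
    "MutationMatrix",
    "SubstitutionCounts",
    "seq_to_array",
    "array_to_seq",
    "read_vcf",
    "write_vcf",
    "filter_variants",
    "assign_ancestral",
    "chromosome_nucleotide_frequencies",
    "build_mutation_matrix",
    "mask_ancestral_cpg",
    "count_substitutions",
    "equilibrium_gc",
]


def seq_to_array(seq: str) -> np.ndarray:
    """Sequence string -> uint8 byte array (upper-cased)."""
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


@dataclass
class GenotypeTable:
    """Genotype matrix with per-call quality annotations.

    ``genotypes`` has shape (n_sites, n_samples, ploidy) with allele indices
    (0 = ref, 1.. = alt) and -1 for missing.  ``gq`` and ``dp`` are
    (n_sites, n_samples) arrays of genotype quality (phred) and read depth.
    """

    sample_ids: list
    sites: pd.DataFrame          # columns: chrom, pos (1-based), ref, alt
    genotypes: np.ndarray
    gq: np.ndarray
    dp: np.ndarray
    ploidy: int = 2

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.gq = np.asarray(self.gq, dtype=np.int32)
        self.dp = np.asarray(self.dp, dtype=np.int32)
        n_sites = len(self.sites)
        if self.genotypes.shape != (n_sites, len(self.sample_ids), self.ploidy):
            raise ValueError("genotype array shape mismatch")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.n_samples * self.ploidy

    def positions(self) -> np.ndarray:
        return self.sites["pos"].to_numpy()

    def allele_counts(self):
        """Per-site (n_called_haplotypes, alt_allele_count) over non-missing calls."""
        g = self.genotypes
        called = g >= 0
        n_called = called.sum(axis=(1, 2))
        alt = np.where(called, g, 0).sum(axis=(1, 2))
        return n_called, alt

    def haplotype_matrix(self) -> np.ndarray:
        """(n_haplotypes, n_sites) allele matrix (phased interpretation)."""
        return self.genotypes.transpose(1, 2, 0).reshape(self.n_haplotypes,
                                                         self.n_sites)

    def take_sites(self, idx) -> "GenotypeTable":
        return GenotypeTable(self.sample_ids,
                             self.sites.iloc[idx].reset_index(drop=True),
                             self.genotypes[idx], self.gq[idx], self.dp[idx],
                             self.ploidy)


def read_vcf(path) -> GenotypeTable:
    """Read a VCF (4.2, FORMAT GT:GQ:DP) into a :class:`GenotypeTable`."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, gts, gqs, dps = [], [], [], []
    for v in vcf:
        alt = ",".join(v.ALT) if v.ALT else "."
        rows.append((v.CHROM, v.POS, v.REF, alt))
        g = np.array([gt[:2] for gt in v.genotypes], dtype=np.int8)
        gts.append(g)
        gq = v.format("GQ")
        gqs.append(np.full(len(samples), -1, dtype=np.int32) if gq is None
                   else gq.reshape(-1).astype(np.int32))
        dp = v.format("DP")
        dps.append(np.full(len(samples), -1, dtype=np.int32) if dp is None
                   else dp.reshape(-1).astype(np.int32))
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    n = len(rows)
    genotypes = (np.stack(gts) if n else
                 np.zeros((0, len(samples), 2), dtype=np.int8))
    gq = np.stack(gqs) if n else np.zeros((0, len(samples)), dtype=np.int32)
    dp = np.stack(dps) if n else np.zeros((0, len(samples)), dtype=np.int32)
    return GenotypeTable(samples, sites, genotypes, gq, dp, ploidy=2)


def write_vcf(gt: GenotypeTable, path) -> None:
    """Write a minimal VCF 4.2 with FORMAT GT:GQ:DP."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">',
    ]
    for chrom in gt.sites["chrom"].unique():
        lines.append(f"##contig=<ID={chrom}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gt.sample_ids))
    sep = "/" if gt.ploidy == 2 else ""
    for i, row in enumerate(gt.sites.itertuples()):
        calls = []
        for s in range(gt.n_samples):
            alleles = gt.genotypes[i, s]
            g = sep.join("." if a < 0 else str(int(a)) for a in alleles)
            calls.append(f"{g}:{gt.gq[i, s]}:{gt.dp[i, s]}")
        lines.append(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\t"
                     "GT:GQ:DP\t" + "\t".join(calls))
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


@dataclass(frozen=True)
class FilterRules:
    """Site-level filters, applied in the declared order."""

    max_alleles: int = 2
    no_missing: bool = True
    min_gq: int = 30
    depth_band: tuple = (0.5, 2.0)   # multiples of the population mean depth
    drop_singletons: bool = True
    drop_fixed_alt: bool = True
    hwe_alpha: float | None = None   # optional Hardy-Weinberg chi-square filter

    def __post_init__(self):
        if self.depth_band[0] >= self.depth_band[1]:
            raise ValueError("depth band low must be < high")


@dataclass
class FilterReport:
    n_input: int
    n_output: int
    removed: dict = field(default_factory=dict)
    mean_depth: float = math.nan


def _hwe_chi2_p(n_hom_ref, n_het, n_hom_alt):
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    p = (2 * n_hom_ref + n_het) / (2 * n)
    q = 1 - p
    exp = np.array([p * p * n, 2 * p * q * n, q * q * n])
    obs = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    keep = exp > 0
    chi2 = float(np.sum((obs[keep] - exp[keep]) ** 2 / exp[keep]))
    from scipy import stats
    return float(stats.chi2.sf(chi2, df=1))


def filter_variants(gt: GenotypeTable, rules: FilterRules = FilterRules()):
    """Apply site filters in order and report per-rule removal counts.

    Order: multi-allelic -> missing genotypes -> genotype quality -> depth
    band (relative to the mean per-site depth over the *input* table) ->
    singletons -> fixed alternate (-> optional Hardy-Weinberg).  The filter is
    idempotent given the same mean-depth reference.
    """
    site_depth = np.where(gt.dp >= 0, gt.dp, np.nan)
    with np.errstate(invalid="ignore"):
        mean_site_depth = np.nanmean(site_depth, axis=1)
    pop_mean_depth = float(np.nanmean(mean_site_depth)) if gt.n_sites else math.nan

    keep = np.ones(gt.n_sites, dtype=bool)
    removed = {}

    def apply(name, bad):
        nonlocal keep
        bad = bad & keep
        removed[name] = int(bad.sum())
        keep &= ~bad

    n_alt = gt.sites["alt"].astype(str).str.count(",") + 1
    apply("max_alleles", (n_alt + 1 > rules.max_alleles).to_numpy())

    if rules.no_missing:
        missing = (gt.genotypes < 0).any(axis=(1, 2))
        apply("missing", missing)

    low_gq = (gt.gq < rules.min_gq).any(axis=1)
    apply("min_gq", low_gq)

    if not math.isnan(pop_mean_depth):
        lo = rules.depth_band[0] * pop_mean_depth
        hi = rules.depth_band[1] * pop_mean_depth
        bad_depth = (mean_site_depth < lo) | (mean_site_depth > hi)
        apply("depth", np.nan_to_num(bad_depth, nan=True).astype(bool))

    n_called, alt = gt.allele_counts()
    minor = np.minimum(alt, n_called - alt)
    if rules.drop_singletons:
        apply("singleton", minor == 1)
    if rules.drop_fixed_alt:
        apply("fixed_alt", (n_called > 0) & (alt == n_called))
    if rules.hwe_alpha is not None:
        bad = np.zeros(gt.n_sites, dtype=bool)
        for i in np.flatnonzero(keep):
            g = gt.genotypes[i]
            ok = (g >= 0).all(axis=1)
            s = g[ok].sum(axis=1)
            p = _hwe_chi2_p(int((s == 0).sum()), int((s == 1).sum()),
                            int((s == 2).sum()))
            bad[i] = p < rules.hwe_alpha
        apply("hwe", bad)

    out = gt.take_sites(np.flatnonzero(keep))
    report = FilterReport(gt.n_sites, out.n_sites, removed, pop_mean_depth)
    return out, report


@dataclass(frozen=True)
class AncestralPrior:
    """Per-site prior over the ancestral nucleotide (order A, C, G, T)."""

    pos: int
    probs: np.ndarray
    source: str   # "outgroup_consensus" | "frequency_fallback"

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.shape != (4,) or np.any(probs < 0) or abs(probs.sum() - 1) > 1e-9:
            raise ValueError("prior must be a 4-vector summing to 1")


CONSENSUS_PRIOR = 0.91
OTHER_PRIOR = 0.03


def assign_ancestral(pos: int, outgroup1_call, outgroup2_call,
                     chrom_freqs) -> AncestralPrior:
    """Ancestral-state prior from two outgroup genotype calls.

    When both outgroups are homozygous for the same A/C/G/T nucleotide that
    base takes prior 0.91 and the other three 0.03 each; any disagreement,
    heterozygosity or missing call falls back to the chromosome-wide
    nucleotide frequencies.
    """
    freqs = np.asarray(chrom_freqs, dtype=float)
    if abs(freqs.sum() - 1) > 1e-6:
        raise ValueError("chrom_freqs must sum to 1")

    def hom_base(call):
        if call is None:
            return None
        a = [x.upper() for x in call]
        if len(a) >= 1 and all(x == a[0] for x in a) and a[0] in _NT_INDEX:
            return a[0]
        return None

    b1, b2 = hom_base(outgroup1_call), hom_base(outgroup2_call)
    if b1 is not None and b1 == b2:
        probs = np.full(4, OTHER_PRIOR)
        probs[_NT_INDEX[b1]] = CONSENSUS_PRIOR
        return AncestralPrior(pos, probs, "outgroup_consensus")
    return AncestralPrior(pos, freqs, "frequency_fallback")


def chromosome_nucleotide_frequencies(seq, coverage_mask=None) -> np.ndarray:
    """Relative A/C/G/T frequencies over covered positions of a sequence."""
    arr = seq if isinstance(seq, np.ndarray) else seq_to_array(seq)
    if coverage_mask is not None:
        arr = arr[np.asarray(coverage_mask, dtype=bool)]
    counts = np.array([(arr == ord(b)).sum() for b in NUCLEOTIDES], dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("no covered A/C/G/T sites")
    return counts / total


@dataclass(frozen=True)
class MutationMatrix:
    """4x4 mutation counts away from the ancestral allele, plus row-normalized form."""

    counts: np.ndarray
    normalized: np.ndarray
    uniform_rows: tuple   # rows with zero counts, normalized to uniform

    @property
    def n_sites(self) -> int:
        return int(self.counts.sum())


def build_mutation_matrix(polarized_sites) -> MutationMatrix:
    """Count mutations (ancestral -> derived) at confidently polarized sites.

    ``polarized_sites`` yields ``(ancestral, derived, source)`` triples; sites
    whose ancestral call came from the frequency fallback are excluded, as are
    degenerate anc == der entries.  Rows with zero counts normalize to uniform
    and are flagged.
    """
    counts = np.zeros((4, 4), dtype=np.int64)
    for anc, der, source in polarized_sites:
        if source != "outgroup_consensus":
            continue
        a, d = anc.upper(), der.upper()
        if a not in _NT_INDEX or d not in _NT_INDEX or a == d:
            continue
        counts[_NT_INDEX[a], _NT_INDEX[d]] += 1
    normalized = np.empty((4, 4), dtype=float)
    uniform_rows = []
    for i in range(4):
        row_sum = counts[i].sum()
        if row_sum == 0:
            normalized[i] = 0.25
            uniform_rows.append(i)
        else:
            normalized[i] = counts[i] / row_sum
    return MutationMatrix(counts, normalized, tuple(uniform_rows))


def mask_ancestral_cpg(seq) -> np.ndarray:
    """Boolean mask of positions inside a CpG ("CG") dinucleotide.

    Both positions of every C-followed-by-G pair are masked; the reverse "GC"
    is not a CpG and N is never masked.
    """
    arr = seq if isinstance(seq, np.ndarray) else seq_to_array(seq)
    mask = np.zeros(arr.size, dtype=bool)
    if arr.size < 2:
        return mask
    cg = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    mask[:-1] |= cg
    mask[1:] |= cg
    return mask


@dataclass
class SubstitutionCounts:
    """Strong/weak substitution tallies within one region."""

    region_id: str
    at_to_gc: int = 0
    gc_to_at: int = 0
    other: int = 0
    masked_cpg_bp: int = 0
    n_ancestral_sites: int = 0

    @property
    def total_strong_weak(self) -> int:
        return self.at_to_gc + self.gc_to_at

    def __add__(self, other: "SubstitutionCounts") -> "SubstitutionCounts":
        return SubstitutionCounts(
            region_id=f"{self.region_id}+{other.region_id}",
            at_to_gc=self.at_to_gc + other.at_to_gc,
            gc_to_at=self.gc_to_at + other.gc_to_at,
            other=self.other + other.other,
            masked_cpg_bp=self.masked_cpg_bp + other.masked_cpg_bp,
            n_ancestral_sites=self.n_ancestral_sites + other.n_ancestral_sites,
        )


def count_substitutions(ancestral_seq, population_alleles, regions=None,
                        mode: str = "fixed_derived"):
    """Classify substitutions away from the ancestral sequence per region.

    ``population_alleles`` is a (n_haplotypes, L) or (L,) byte/str array of
    the population's alleles aligned to the ancestral sequence.  Ancestral CpG
    positions are masked before counting.  In ``fixed_derived`` mode a
    substitution requires every haplotype to carry the same non-ancestral
    allele; in ``any_derived`` mode the most common non-ancestral allele
    counts as derived whenever at least one haplotype carries it.  Counts are
    classified AT->GC (weak to strong), GC->AT (strong to weak), or other.

    Returns a list of :class:`SubstitutionCounts`, one per region (the whole
    sequence when ``regions`` is None).
    """
    if mode not in ("fixed_derived", "any_derived"):
        raise ValueError("mode must be fixed_derived or any_derived")
    anc = ancestral_seq if isinstance(ancestral_seq, np.ndarray) else seq_to_array(ancestral_seq)
    pop = population_alleles
    if isinstance(pop, str):
        pop = seq_to_array(pop)
    pop = np.asarray(pop)
    if pop.ndim == 1:
        pop = pop[None, :]
    if pop.shape[1] != anc.size:
        raise ValueError("population alleles not aligned to ancestral sequence")
    mask = mask_ancestral_cpg(anc)
    anc_ok = np.isin(anc, _ACGT_BYTES) & ~mask
    pop_ok = np.isin(pop, _ACGT_BYTES).all(axis=0)
    usable = anc_ok & pop_ok

    diff = pop != anc[None, :]
    if mode == "fixed_derived":
        is_sub = usable & diff.all(axis=0) & (pop == pop[0]).all(axis=0)
        derived = pop[0]
    else:
        is_sub = usable & diff.any(axis=0)
        # most common non-ancestral allele per site
        derived = np.empty(anc.size, dtype=np.uint8)
        for i in np.flatnonzero(is_sub):
            col = pop[:, i]
            alts, cnt = np.unique(col[col != anc[i]], return_counts=True)
            derived[i] = alts[np.argmax(cnt)]

    anc_weak = np.isin(anc, _AT_BYTES)
    anc_strong = np.isin(anc, _GC_BYTES)
    der_weak = np.isin(derived, _AT_BYTES)
    der_strong = np.isin(derived, _GC_BYTES)
    at_to_gc = is_sub & anc_weak & der_strong
    gc_to_at = is_sub & anc_strong & der_weak
    other = is_sub & ~at_to_gc & ~gc_to_at

    if regions is None:
        regions = [("all", 0, anc.size)]
    out = []
    for region_id, start, end in ((r[0], r[1], r[2]) if len(r) == 3 else r
                                  for r in regions):
        sl = slice(int(start), int(end))
        sc = SubstitutionCounts(
            region_id=str(region_id),
            at_to_gc=int(at_to_gc[sl].sum()),
            gc_to_at=int(gc_to_at[sl].sum()),
            other=int(other[sl].sum()),
            masked_cpg_bp=int(mask[sl].sum()),
            n_ancestral_sites=int(usable[sl].sum()),
        )
        if sc.n_ancestral_sites == 0:
            logger.warning("region %s has no usable ancestral sites", region_id)
        out.append(sc)
    return out


def equilibrium_gc(sc: SubstitutionCounts) -> float:
    """Equilibrium GC content GC* = AT->GC / (AT->GC + GC->AT); NaN if no
    strong/weak substitutions were observed."""
    denom = sc.at_to_gc + sc.gc_to_at
    if denom == 0:
        return math.nan
    return sc.at_to_gc / denom
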