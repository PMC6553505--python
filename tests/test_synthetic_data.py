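"""Truth landscapes, haplotype simulation contracts, the stand-in rate
estimator and the power-study driver."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from recland.ancestry_polarization import count_substitutions, equilibrium_gc, seq_to_array
from recland.hotspot_comparison import tss_enrichment, term_enrichment
from recland.hotspot_detection import CallerConfig, call_hotspots
from recland.landscape_io import RhoMap
from recland.synthetic_data import (
    LandscapeSpec, NoiseModel, SimulationDesign, add_estimation_noise,
    estimate_rho_landscape, make_annotation, make_rho_landscape,
    random_sequence, run_power_study, simulate_haplotypes,
    simulate_substitutions,
)
from recland.hotspot_detection import HotspotSet, Hotspot


class TestLandscape:
    def test_default_design(self):
        m, truth = make_rho_landscape()
        assert m.chrom_length == 250000
        assert list(truth["midpoint"]) == [75000, 125000, 175000, 225000]
        np.testing.assert_allclose(truth["intensity"],
                                   [2.0, 5.0, 10.0, 20.0])
        # strongest hotspot: 0.6 rho/kb over 0.03 rho/kb background
        assert m.rate_at(225000) == pytest.approx(0.0006)
        assert m.rate_at(10000) == pytest.approx(3e-5)

    def test_empty_hotspot_list_is_uniform(self):
        m, truth = make_rho_landscape(LandscapeSpec(hotspots=()))
        assert m.n_intervals == 1
        assert truth.empty

    def test_map_integral_arithmetic(self):
        spec = LandscapeSpec()
        m, _ = make_rho_landscape(spec)
        widths = sum(w for _, w, _ in spec.hotspots)
        expected = (spec.background / 1000 * (spec.length - widths)
                    + sum(w * r / 1000 for _, w, r in spec.hotspots))
        assert m.total_map_length() == pytest.approx(expected, rel=1e-12)

    def test_overlapping_hotspots_rejected(self):
        spec = LandscapeSpec(hotspots=((75000, 2000, 0.3), (76000, 2000, 0.3)))
        with pytest.raises(ValueError, match="overlap"):
            make_rho_landscape(spec)


class TestEstimationNoise:
    def test_sigma_zero_is_identity(self):
        m, _ = make_rho_landscape()
        out = add_estimation_noise(m, NoiseModel(sigma=0.0, seed=1))
        assert out is m

    def test_noise_is_mean_one(self):
        m = RhoMap("sim", [0], [100000], [1.0], 100000)
        means = [add_estimation_noise(m, NoiseModel(sigma=0.5, block=5000,
                                                    seed=s)).mean_rate()
                 for s in range(500)]
        se = np.std(means) / math.sqrt(len(means))
        assert abs(np.mean(means) - 1.0) < 3 * se

    def test_noise_increases_false_positives(self):
        """Caller FP counts rise monotonically with noise amplitude."""
        m, truth = make_rho_landscape()
        tm = truth["midpoint"].to_numpy()
        fp = {}
        for sigma in (0.0, 0.3, 0.6):
            count = 0
            for seed in range(40):
                noisy = add_estimation_noise(m, NoiseModel(sigma=sigma,
                                                           block=2000,
                                                           seed=seed))
                hs = call_hotspots(noisy)
                for h in hs:
                    if np.min(np.abs(tm - h.midpoint)) > 3000:
                        count += 1
            fp[sigma] = count
        assert fp[0.0] <= fp[0.3] <= fp[0.6]


class TestMosaicSimulator:
    def test_theta_calibration(self):
        """Mean pairwise diversity hits the design theta within 3 s.e."""
        m, _ = make_rho_landscape()
        design = SimulationDesign()
        pis = []
        for rep in range(100):
            gt = simulate_haplotypes(design, m, seed=rep)
            hap = gt.haplotype_matrix()
            n = hap.shape[0]
            p = hap.mean(axis=0)
            pis.append(np.sum(2 * p * (1 - p) * n / (n - 1)) / m.chrom_length)
        se = np.std(pis) / math.sqrt(len(pis))
        assert abs(np.mean(pis) - design.theta) < 3 * se

    def test_bottleneck_founder_count(self):
        assert SimulationDesign().n_founders == 40
        assert SimulationDesign(bottleneck=(0.025, 0.1)).n_founders == 36
        assert SimulationDesign(bottleneck=(0.025, 0.9)).n_founders == 4
        assert SimulationDesign(bottleneck=(0.025, 0.99)).n_founders == 2

    def test_strong_bottleneck_maximizes_adjacent_ld(self):
        """The two-founder limit yields higher adjacent-site r^2 than the
        constant-size panel."""
        m, _ = make_rho_landscape()

        def mean_adjacent_r2(design, seeds):
            vals = []
            for s in seeds:
                gt = simulate_haplotypes(design, m, seed=s)
                hap = gt.haplotype_matrix().astype(float)
                pos = gt.positions()
                maf = np.minimum(hap.mean(0), 1 - hap.mean(0))
                keep = maf >= 0.1
                hap, pos = hap[:, keep], pos[keep]
                for i in range(hap.shape[1] - 1):
                    if pos[i + 1] - pos[i] < 500:
                        r = np.corrcoef(hap[:, i], hap[:, i + 1])[0, 1]
                        if not math.isnan(r):
                            vals.append(r ** 2)
            return np.mean(vals)
        strong = mean_adjacent_r2(SimulationDesign(bottleneck=(0.025, 0.95)),
                                  range(10))
        constant = mean_adjacent_r2(SimulationDesign(), range(10))
        assert strong > constant

    def test_ld_decays_across_hotspots(self):
        """Mean r^2 across a planted hotspot is below an equally long
        background interval."""
        m, _ = make_rho_landscape()
        design = SimulationDesign()
        hot, cold = [], []
        for rep in range(50):
            gt = simulate_haplotypes(design, m, seed=rep)
            hap = gt.haplotype_matrix().astype(float)
            pos = gt.positions() - 1
            maf = np.minimum(hap.mean(0), 1 - hap.mean(0))
            keep = maf >= 0.1
            hap, pos = hap[:, keep], pos[keep]

            def r2_between(lo1, hi1, lo2, hi2):
                i = np.flatnonzero((pos >= lo1) & (pos < hi1))
                j = np.flatnonzero((pos >= lo2) & (pos < hi2))
                out = []
                for a in i[:5]:
                    for b in j[:5]:
                        r = np.corrcoef(hap[:, a], hap[:, b])[0, 1]
                        if not math.isnan(r):
                            out.append(r ** 2)
                return out
            # across the strongest hotspot [224k, 226k) vs background span
            hot.extend(r2_between(221000, 224000, 226000, 229000))
            cold.extend(r2_between(51000, 54000, 56000, 59000))
        assert np.mean(hot) < np.mean(cold)

    def test_determinism(self):
        m, _ = make_rho_landscape()
        g1 = simulate_haplotypes(SimulationDesign(), m, seed=11)
        g2 = simulate_haplotypes(SimulationDesign(), m, seed=11)
        np.testing.assert_array_equal(g1.genotypes, g2.genotypes)
        pd.testing.assert_frame_equal(g1.sites, g2.sites)


class TestCoalescentBackend:
    def test_theta_calibration(self):
        m, _ = make_rho_landscape()
        design = SimulationDesign()
        pis = []
        for rep in range(30):
            gt = simulate_haplotypes(design, m, seed=rep,
                                     backend="coalescent")
            hap = gt.haplotype_matrix()
            n = hap.shape[0]
            p = hap.mean(axis=0)
            pis.append(np.sum(2 * p * (1 - p) * n / (n - 1)) / m.chrom_length)
        se = np.std(pis) / math.sqrt(len(pis))
        assert abs(np.mean(pis) - design.theta) < 3 * se

    def test_unknown_backend_rejected(self):
        m, _ = make_rho_landscape()
        with pytest.raises(ValueError):
            simulate_haplotypes(SimulationDesign(), m, seed=1, backend="exact")


class TestRateEstimator:
    def test_duplicated_haplotypes_give_zero_map(self):
        """A panel in perfect LD shows no four-gamete violations."""
        rng = np.random.default_rng(3)
        base = (rng.random(400) < 0.4).astype(np.int8)
        hap = np.tile(base, (20, 1))
        hap[10:] = 1 - hap[10:]   # two complementary haplotypes, still r^2 = 1
        from test_popgen_stats import haploid_table
        gt = haploid_table(hap, positions=np.sort(
            rng.choice(np.arange(1, 100001), size=400, replace=False)))
        est = estimate_rho_landscape(gt, 100000)
        assert est.total_map_length() == 0.0

    def test_independent_sites_give_high_flat_map(self):
        rng = np.random.default_rng(4)
        hap = (rng.random((40, 500)) < 0.5).astype(np.int8)
        from test_popgen_stats import haploid_table
        gt = haploid_table(hap, positions=np.sort(
            rng.choice(np.arange(1, 100001), size=500, replace=False)))
        est = estimate_rho_landscape(gt, 100000)
        assert np.median(est.rho) > 0

    def test_recovers_planted_landscape(self):
        """Pooled estimates rank-correlate positively with the truth and are
        elevated in the planted hotspot windows."""
        m, truth = make_rho_landscape()
        design = SimulationDesign()
        pooled_est = np.zeros(250)
        for rep in range(30):
            gt = simulate_haplotypes(design, m, seed=rep)
            est = estimate_rho_landscape(gt, m.chrom_length)
            pooled_est += est.rho
        truth_win = m.integral(np.arange(250) * 1000,
                               np.arange(250) * 1000 + 1000) / 1000
        rho, _ = stats.spearmanr(pooled_est, truth_win)
        assert rho > 0
        hot_windows = (truth["midpoint"].to_numpy() // 1000).astype(int)
        hot_mean = np.mean([pooled_est[w - 1:w + 1].mean()
                            for w in hot_windows])
        background = np.median(np.delete(pooled_est, hot_windows))
        assert hot_mean > 2 * background

    def test_deterministic(self):
        m, _ = make_rho_landscape()
        gt = simulate_haplotypes(SimulationDesign(), m, seed=5)
        e1 = estimate_rho_landscape(gt, m.chrom_length)
        e2 = estimate_rho_landscape(gt, m.chrom_length)
        np.testing.assert_array_equal(e1.rho, e2.rho)


class TestPowerStudy:
    def test_noise_free_threshold_logic(self):
        """On noise-free truth maps the caller recovers exactly the plantings
        at or above the 5-fold ratio and never the 2-fold one."""
        for rates in [(0.06, 0.15, 0.3, 0.6), (0.06, 0.6, 0.15, 0.3)]:
            spec = LandscapeSpec(hotspots=tuple(
                (m, 2000, r) for m, r in zip((75000, 125000, 175000, 225000),
                                             rates)))
            m, truth = make_rho_landscape(spec)
            hs = call_hotspots(m)
            called_mids = hs.midpoints()
            for mid, rate in zip(truth["midpoint"], truth["rate"]):
                ratio = rate / spec.background
                hit = np.any(np.abs(called_mids - mid) <= 1000)
                assert hit == (ratio >= 5)

    def test_fn_rates_and_determinism(self):
        designs = {"constant": SimulationDesign(),
                   "strong": SimulationDesign(bottleneck=(0.025, 0.9))}
        out1 = run_power_study(designs, n_replicates=8, seed=123)
        out2 = run_power_study(designs, n_replicates=8, seed=123)
        for a, b in zip(out1, out2):
            pd.testing.assert_frame_equal(a, b)
        per_intensity, per_scenario, sharing = out1
        assert set(per_intensity["scenario"]) == {"constant", "strong"}
        fn = per_scenario.set_index("scenario")["fn_rate"]
        assert 0 <= fn["constant"] <= fn["strong"] <= 1
        assert len(sharing) == 1


class TestSubstitutionSimulator:
    def test_zero_rates_identity(self):
        seq = random_sequence(2000, seed=1)
        derived, counts = simulate_substitutions(seq, 0.0, 0.0, seed=2)
        assert derived == seq
        assert counts.at_to_gc == 0 and counts.gc_to_at == 0

    def test_round_trip_with_counter(self):
        """count_substitutions recovers the simulator's true counts exactly."""
        seq = random_sequence(5000, seed=3)
        derived, truth = simulate_substitutions(seq, 0.05, 0.08, seed=4)
        (sc,) = count_substitutions(seq, derived, mode="fixed_derived")
        assert sc.at_to_gc == truth.at_to_gc
        assert sc.gc_to_at == truth.gc_to_at

    def test_equilibrium_gc_recovery(self):
        """Pooled GC* matches alpha*nAT / (alpha*nAT + beta*nGC) within 3 s.e."""
        seq = random_sequence(100000, gc=0.42, seed=5)
        alpha, beta = 0.02, 0.03
        arr = seq_to_array(seq)
        from recland.ancestry_polarization import mask_ancestral_cpg
        mask = mask_ancestral_cpg(arr)
        n_at = int((np.isin(arr, np.frombuffer(b"AT", dtype=np.uint8)) & ~mask).sum())
        n_gc = int((np.isin(arr, np.frombuffer(b"GC", dtype=np.uint8)) & ~mask).sum())
        derived, truth = simulate_substitutions(seq, alpha, beta, seed=6)
        gc_star = equilibrium_gc(truth)
        expect = alpha * n_at / (alpha * n_at + beta * n_gc)
        n_subs = truth.at_to_gc + truth.gc_to_at
        se = math.sqrt(expect * (1 - expect) / n_subs)
        assert abs(gc_star - expect) < 3 * se


class TestAnnotationGenerator:
    def test_uniform_tss_halo_coverage(self):
        genome = {"chr1": 1_000_000}
        tss, terms, genes = make_annotation(genome, 40, seed=8)
        hs = HotspotSet("pop", [Hotspot("chr1", 499000, 501000, 1.0, 0.1, 10.0)],
                        CallerConfig(), chrom_length=10**6)
        frac, null = tss_enrichment(hs, tss, genome, n_perm=3000, seed=9)
        # analytic expectation from the realized (possibly overlapping) halos
        merged = []
        for t in np.sort(tss["chr1"]):
            lo, hi = t - 3000, t + 3000
            if merged and lo <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(hi, merged[-1][1]))
            else:
                merged.append((lo, hi))
        coverage = sum(hi - lo for lo, hi in merged) / (10**6 - 2000)
        mean_frac = null.null_counts.mean()
        se = math.sqrt(coverage * (1 - coverage) / 3000)
        assert abs(mean_frac - coverage) < 3 * se

    def test_hotspots_planted_on_tss_maximally_enriched(self):
        genome = {"chr1": 500_000}
        tss, _, _ = make_annotation(genome, 10, seed=10)
        spots = [Hotspot("chr1", int(t) - 1000, int(t) + 1000, 1.0, 0.1, 10.0)
                 for t in tss["chr1"][:5]]
        hs = HotspotSet("pop", spots, CallerConfig(), chrom_length=500_000)
        frac, null = tss_enrichment(hs, tss, genome, n_perm=500, seed=11)
        assert frac == pytest.approx(1.0)
        assert null.p_value == pytest.approx(1 / 501)

    def test_empty_term_table_passthrough(self):
        res = term_enrichment(["g1"], pd.DataFrame(columns=["gene_id",
                                                            "term_id"]),
                              n_perm=10, seed=1)
        assert res.empty

    def test_gene_terms_structure(self):
        genome = {"chr1": 200000, "chr2": 100000}
        tss, terms, genes = make_annotation(genome, 25, seed=12)
        assert sum(len(v) for v in tss.values()) == 25
        assert set(terms.columns) == {"gene_id", "term_id"}
        per_gene = terms.groupby("gene_id").size()
        assert per_gene.between(1, 5).all()
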