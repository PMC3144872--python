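"""Generator tests: construction guarantees, calibration, reproducibility."""

import numpy as np
import pytest
from scipy import stats

from clustrep.association import pool_ttest
from clustrep.simulate import (
    SimConfig,
    generate_dataset,
    plant_risk_regions,
    simulate_gene_models,
    simulate_genotype_counts,
    simulate_pools,
    simulate_pvalues,
    simulate_snp_maps,
)

SMALL = SimConfig(
    n_chromosomes=4,
    chrom_length=2_000_000,
    n_snps_a=10_000,
    n_snps_b=10_000,
    n_risk_regions=5,
    seed=123,
)


class TestSnpMaps:
    def test_shared_marker_count_exact_by_construction(self, rng):
        map_a, map_b, shared = simulate_snp_maps(SMALL, rng)
        assert len(shared) == round(0.25 * 10_000)
        assert map_a.n_total == 10_000 and map_b.n_total == 10_000
        # shared ids sit at identical positions on both maps
        for chrom in map_a.positions:
            ids_a = {i: p for i, p in zip(map_a.ids[chrom], map_a.positions[chrom])}
            ids_b = {i: p for i, p in zip(map_b.ids[chrom], map_b.positions[chrom])}
            common = set(ids_a) & set(ids_b)
            assert all(ids_a[i] == ids_b[i] for i in common)

    def test_zero_sharing_gives_disjoint_id_sets(self, rng):
        cfg = SimConfig(**{**SMALL.__dict__, "shared_fraction": 0.0})
        map_a, map_b, shared = simulate_snp_maps(cfg, rng)
        assert shared == frozenset()
        ids_a = {i for c in map_a.ids for i in map_a.ids[c]}
        ids_b = {i for c in map_b.ids for i in map_b.ids[c]}
        assert ids_a.isdisjoint(ids_b)

    def test_same_seed_reproduces_maps(self):
        m1, _, s1 = simulate_snp_maps(SMALL, np.random.default_rng(9))
        m2, _, s2 = simulate_snp_maps(SMALL, np.random.default_rng(9))
        assert s1 == s2
        for chrom in m1.positions:
            assert np.array_equal(m1.positions[chrom], m2.positions[chrom])

    def test_excess_density_rejected(self, rng):
        cfg = SimConfig(n_chromosomes=1, chrom_length=100, n_snps_a=200, n_snps_b=200)
        with pytest.raises(ValueError, match="density too high"):
            simulate_snp_maps(cfg, rng)


class TestPlantRiskRegions:
    def test_regions_disjoint_with_enough_members_per_platform(self, rng):
        map_a, map_b, _ = simulate_snp_maps(SMALL, rng)
        truth = plant_risk_regions(map_a, map_b, SMALL, rng)
        assert len(truth) == 5
        by_chrom = {}
        for r in truth.regions:
            assert len(r.members_a) >= SMALL.snps_per_risk_region
            assert len(r.members_b) >= SMALL.snps_per_risk_region
            by_chrom.setdefault(r.chromosome, []).append((r.start, r.end))
        for intervals in by_chrom.values():
            intervals.sort()
            for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
                assert s2 > e1 + SMALL.max_gap  # separated by more than max_gap

    def test_zero_regions_gives_pure_null(self):
        ds = generate_dataset(SimConfig(**{**SMALL.__dict__, "n_risk_regions": 0}))
        assert len(ds.truth) == 0

    def test_impossible_density_raises(self, rng):
        cfg = SimConfig(
            n_chromosomes=1, chrom_length=20_000_000, n_snps_a=300, n_snps_b=300,
            shared_fraction=0.05, n_risk_regions=50, snps_per_risk_region=6,
        )
        map_a, map_b, _ = simulate_snp_maps(cfg, rng)
        with pytest.raises(ValueError, match="cannot place regions"):
            plant_risk_regions(map_a, map_b, cfg, rng)


class TestPvalues:
    def test_null_pvalues_uniform_by_ks(self, rng):
        map_a, _, _ = simulate_snp_maps(SMALL, rng)
        pv = simulate_pvalues(map_a, None, SMALL, rng)
        allp = np.concatenate(list(pv.values()))
        assert stats.kstest(allp, "uniform").pvalue > 0.001

    def test_risk_snp_small_p_fraction_matches_beta_cdf(self, rng):
        map_a, map_b, _ = simulate_snp_maps(SMALL, rng)
        truth = plant_risk_regions(map_a, map_b, SMALL, rng)
        pv = simulate_pvalues(map_a, truth, SMALL, rng)
        risk_p = []
        for r in truth.regions:
            pos = map_a.positions[r.chromosome]
            mask = (pos >= r.start) & (pos <= r.end)
            risk_p.extend(pv[r.chromosome][mask])
        risk_p = np.array(risk_p)
        expected = 0.05**0.1  # Beta(0.1, 1) CDF at 0.05
        half = 2.576 * np.sqrt(expected * (1 - expected) / len(risk_p))
        assert abs((risk_p < 0.05).mean() - expected) < 3 * half + 0.02

    def test_beta_1_1_indistinguishable_from_null(self, rng):
        cfg = SimConfig(**{**SMALL.__dict__, "risk_p_beta": (1.0, 1.0)})
        map_a, map_b, _ = simulate_snp_maps(cfg, rng)
        truth = plant_risk_regions(map_a, map_b, cfg, rng)
        pv = simulate_pvalues(map_a, truth, cfg, rng)
        allp = np.concatenate(list(pv.values()))
        assert stats.kstest(allp, "uniform").pvalue > 0.001


class TestPools:
    def test_zero_noise_reproduces_true_frequency(self, rng):
        cfg = SimConfig(**{**SMALL.__dict__, "pool_noise_sd": 0.0})
        case, ctrl = simulate_pools(0.3, 0.4, cfg, rng)
        assert all(x == 0.3 for x in case.estimates)
        assert all(x == 0.4 for x in ctrl.estimates)

    def test_pool_sd_near_configured_002(self):
        ests = []
        for i in range(3_000):
            case, _ = simulate_pools(0.3, 0.3, SimConfig(), np.random.default_rng(i))
            ests.append(case.estimates)
        sd = np.asarray(ests).std(ddof=1)
        assert sd == pytest.approx(0.02, abs=0.002)

    def test_ttest_type_i_rate_calibrated_on_equal_frequencies(self, rng):
        n = 4_000
        hits = 0
        for _ in range(n):
            case, ctrl = simulate_pools(0.3, 0.3, SimConfig(), rng)
            if pool_ttest(case, ctrl).p_value < 0.05:
                hits += 1
        # Welch at 4v4 is slightly conservative; rate must not exceed nominal band
        assert hits / n < 0.05 + 2.576 * np.sqrt(0.05 * 0.95 / n)


class TestGenotypeCounts:
    def test_mean_minor_count_matches_binomial_expectation(self, rng):
        (cm, _), _ = simulate_genotype_counts(np.full(5_000, 0.3), np.full(5_000, 0.3), 500, 500, rng)
        assert cm.mean() == pytest.approx(2 * 500 * 0.3, rel=0.01)

    def test_fully_separated_frequencies(self, rng):
        (cm, cM), (tm, tM) = simulate_genotype_counts(1.0, 0.0, 100, 100, rng)
        assert (cm, cM) == (200, 0) and (tm, tM) == (0, 200)


class TestGeneModels:
    def test_gene_placed_over_each_planted_region(self, rng):
        from clustrep.annotate import annotate_region, build_annotation_index
        from clustrep.scan import Region

        map_a, map_b, _ = simulate_snp_maps(SMALL, rng)
        truth = plant_risk_regions(map_a, map_b, SMALL, rng)
        genes = simulate_gene_models(SMALL, truth, rng=rng)
        index = build_annotation_index(genes, flank=10_000)
        for r in truth.regions:
            reg = Region(r.chromosome, r.start, r.end, ("a", "b", "c", "d"), 4, 0.01, "a")
            assert any(g.startswith("RISKG") for g in annotate_region(reg, index))

    def test_same_seed_identical_models(self):
        g1 = simulate_gene_models(SMALL, None, rng=np.random.default_rng(4))
        g2 = simulate_gene_models(SMALL, None, rng=np.random.default_rng(4))
        assert g1 == g2

    def test_genes_disjoint_within_chromosome(self, rng):
        genes = simulate_gene_models(SMALL, None, n_background_genes=40, rng=rng)
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chromosome, []).append((g.tx_start, g.tx_end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert s2 > e1


def test_generate_dataset_deterministic_under_seed():
    d1 = generate_dataset(SMALL)
    d2 = generate_dataset(SMALL)
    assert d1.truth == d2.truth
    assert d1.records_a[:50] == d2.records_a[:50]
    assert d1.records_b[-1] == d2.records_b[-1]
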