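"""Unit and property tests for the per-SNP association statistics and QC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from clustrep.association import (
    AssocResult,
    DegenerateTableError,
    InsufficientPoolsError,
    PoolFreqSet,
    SnpRecord,
    chi2_allelic,
    chi2_allelic_arrays,
    filter_snps,
    pool_ttest,
)


class TestChi2Allelic:
    def test_worked_2x2_closed_form(self):
        # n(ad-bc)^2/(r1 r2 c1 c2) = 200*(3600-1600)^2/(100*100*100*100) = 8
        res = chi2_allelic((60, 40), (40, 60))
        assert res.statistic == pytest.approx(8.0, abs=1e-12)
        assert res.df == 1
        assert res.p_value == pytest.approx(stats.chi2.sf(8.0, 1), abs=1e-12)
        assert res.p_value == pytest.approx(4.6777e-3, rel=1e-4)

    def test_identical_proportions_give_zero(self):
        res = chi2_allelic((50, 50), (50, 50))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_reference_implementation_on_random_tables(self, rng):
        counts = rng.integers(1, 500, size=(200, 4))
        _, p = chi2_allelic_arrays(counts[:, 0], counts[:, 1], counts[:, 2], counts[:, 3])
        for row, pv in zip(counts, p):
            ref = stats.chi2_contingency(row.reshape(2, 2), correction=False)
            assert pv == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_marginal_raises_degenerate(self):
        with pytest.raises(DegenerateTableError):
            chi2_allelic((0, 100), (0, 80))  # monomorphic minor allele

    @given(
        a=st.integers(1, 300), b=st.integers(1, 300),
        c=st.integers(1, 300), d=st.integers(1, 300),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_invariant_under_row_and_column_swaps(self, a, b, c, d):
        base = chi2_allelic((a, b), (c, d)).statistic
        assert chi2_allelic((c, d), (a, b)).statistic == pytest.approx(base, rel=1e-12)
        assert chi2_allelic((b, a), (d, c)).statistic == pytest.approx(base, rel=1e-12)

    def test_type_i_rate_within_band_under_hwe_null(self, rng):
        from clustrep.simulate import simulate_genotype_counts

        n = 100_000
        (cm, cM), (tm, tM) = simulate_genotype_counts(
            np.full(n, 0.3), np.full(n, 0.3), 1000, 1000, rng
        )
        _, p = chi2_allelic_arrays(cm, cM, tm, tM)
        frac = float(np.mean(p < 0.05))
        half = 2.576 * np.sqrt(0.05 * 0.95 / n)
        assert 0.05 - half < frac < 0.05 + half


class TestPoolTtest:
    def test_identical_groups_give_p_one(self):
        case = PoolFreqSet("case", (0.50, 0.52, 0.48))
        ctrl = PoolFreqSet("control", (0.50, 0.52, 0.48))
        res = pool_ttest(case, ctrl)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_matches_hand_computed_welch(self):
        x = np.array([0.60, 0.62, 0.58, 0.61])
        y = np.array([0.50, 0.49, 0.52, 0.51])
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        se2 = vx / 4 + vy / 4
        t_hand = (x.mean() - y.mean()) / np.sqrt(se2)
        df_hand = se2**2 / ((vx / 4) ** 2 / 3 + (vy / 4) ** 2 / 3)
        p_hand = 2 * stats.t.sf(abs(t_hand), df_hand)
        res = pool_ttest(PoolFreqSet("case", tuple(x)), PoolFreqSet("control", tuple(y)))
        assert res.statistic == pytest.approx(t_hand, abs=1e-10)
        assert res.df == pytest.approx(df_hand, abs=1e-10)
        assert res.p_value == pytest.approx(p_hand, abs=1e-10)

    def test_matches_scipy_welch(self, rng):
        for _ in range(50):
            x = rng.uniform(0.2, 0.8, size=rng.integers(2, 7))
            y = rng.uniform(0.2, 0.8, size=rng.integers(2, 7))
            res = pool_ttest(PoolFreqSet("case", tuple(x)), PoolFreqSet("control", tuple(y)))
            ref = stats.ttest_ind(x, y, equal_var=False)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_single_pool_raises(self):
        with pytest.raises(InsufficientPoolsError):
            pool_ttest(PoolFreqSet("case", (0.5, 0.5)), PoolFreqSet("control", (0.5,)))

    def test_zero_variance_both_groups_raises(self):
        with pytest.raises(ValueError, match="degenerate variance"):
            pool_ttest(PoolFreqSet("case", (0.5, 0.5)), PoolFreqSet("control", (0.4, 0.4)))

    def test_two_sided_symmetry_under_group_exchange(self, rng):
        x = tuple(rng.uniform(0.3, 0.7, size=4))
        y = tuple(rng.uniform(0.3, 0.7, size=5))
        p_xy = pool_ttest(PoolFreqSet("case", x), PoolFreqSet("control", y)).p_value
        p_yx = pool_ttest(PoolFreqSet("case", y), PoolFreqSet("control", x)).p_value
        assert p_xy == pytest.approx(p_yx, rel=1e-12)

    def test_pooled_variance_variant_matches_scipy(self, rng):
        x = rng.uniform(0.2, 0.8, size=4)
        y = rng.uniform(0.2, 0.8, size=4)
        res = pool_ttest(
            PoolFreqSet("case", tuple(x)), PoolFreqSet("control", tuple(y)), equal_var=True
        )
        ref = stats.ttest_ind(x, y, equal_var=True)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)
        assert res.df == 6


def _rec(i, maf=None, miss=None):
    return SnpRecord("1", 100 + i, f"rs{i}", 0.5, maf=maf, missing_rate=miss)


class TestFilterSnps:
    def test_low_maf_excluded_with_reason(self):
        retained, log = filter_snps([_rec(0, maf=0.005)], maf_min=0.01)
        assert retained == []
        assert log[0].reason == "maf"

    def test_all_pass_is_identity(self):
        recs = [_rec(i, maf=0.2, miss=0.01) for i in range(5)]
        retained, log = filter_snps(recs)
        assert retained == recs and log == []

    def test_toy_table_enumeration(self):
        recs = [
            _rec(0, maf=0.005, miss=0.01),  # maf fail
            _rec(1, maf=0.008, miss=0.01),  # maf fail
            _rec(2, maf=0.3, miss=0.10),    # missing fail
            _rec(3, maf=0.001, miss=0.50),  # double fail
            _rec(4, maf=0.3, miss=0.01),
            _rec(5, maf=0.4, miss=0.0),
        ]
        retained, log = filter_snps(recs, maf_min=0.01, missing_max=0.05)
        assert len(retained) == 2 and len(log) == 4
        assert dict(log)["rs3"] == "maf+missing_rate"

    def test_records_without_qc_fields_pass(self):
        recs = [SnpRecord("1", 1, "rs0", 0.2)]
        retained, log = filter_snps(recs)
        assert retained == recs and log == []

    @given(
        st.lists(
            st.tuples(st.floats(0, 0.5), st.floats(0, 1)), min_size=0, max_size=30
        )
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_partition_and_idempotence(self, qc):
        recs = [_rec(i, maf=m, miss=f) for i, (m, f) in enumerate(qc)]
        retained, log = filter_snps(recs)
        assert len(retained) + len(log) == len(recs)
        again, log2 = filter_snps(retained)
        assert again == retained and log2 == []


def test_snp_record_validates_fields():
    with pytest.raises(ValueError):
        SnpRecord("1", 0, "rs1", 0.5)
    with pytest.raises(ValueError):
        SnpRecord("1", 10, "rs1", 1.5)
    with pytest.raises(ValueError):
        SnpRecord("1", 10, "rs1", 0.5, maf=0.6)
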