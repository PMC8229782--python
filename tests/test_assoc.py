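"""Verification-stage statistics: HWE, allelic/genotypic tests, BH, ORs.

External oracle values frozen from R 4.3.3: stats::prop.trend.test for the
Cochran-Armitage trend and stats::fisher.test for the exact 2x3 tests.
"""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from poolgwas.assoc import (
    GenotypeCountTable,
    VerificationStudy,
    allelic_test,
    bh_adjust,
    choose_genotype_test,
    fisher_test_2x3,
    genotypic_ors,
    hwe_test,
    tables_from_genotypes,
    trend_test,
    verify_snps,
)

# frozen R oracles (R 4.3.3, stats package)
R_TREND_CHI2_RS10935945 = 22.7533923577
R_TREND_P_RS10935945 = 1.84178725197e-06
R_FISHER_P_RS17575184 = 0.00045226556488
R_FISHER_P_RS12424924 = 0.357257421245


def _table(case, ctrl, snp_id="s"):
    return GenotypeCountTable(
        snp_id,
        case_mm=case[0], case_mM=case[1], case_MM=case[2],
        ctrl_mm=ctrl[0], ctrl_mM=ctrl[1], ctrl_MM=ctrl[2],
    )


class TestCountTable:
    def test_allele_counts_derived_consistently(self, crc_tables):
        t = crc_tables["rs10935945"]
        assert t.allele_counts == (906, 1242, 478, 450)
        assert t.maf_controls == pytest.approx(0.422, abs=5e-4)
        assert t.maf_cases == pytest.approx(0.515, abs=5e-4)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            _table((-1, 2, 3), (1, 2, 3))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            _table((0, 0, 0), (1, 2, 3))


class TestHwe:
    def test_perfect_equilibrium(self):
        assert hwe_test(25, 50, 25) == pytest.approx(1.0)

    def test_maximal_disequilibrium(self):
        assert hwe_test(50, 0, 50) < 1e-10

    def test_verified_controls_in_equilibrium(self, crc_tables):
        for t in crc_tables.values():
            assert hwe_test(t.ctrl_mm, t.ctrl_mM, t.ctrl_MM) > 0.05

    def test_exact_variant_close_to_chi2_when_dense(self):
        p_chi2 = hwe_test(40, 160, 300)
        p_exact = hwe_test(40, 160, 300, method="exact")
        assert p_exact == pytest.approx(p_chi2, abs=0.05)

    def test_monomorphic_warns(self):
        with pytest.warns(RuntimeWarning):
            assert hwe_test(0, 0, 100) == 1.0


class TestAllelic:
    def test_closed_form_chi2(self, crc_tables):
        # oracle: chi2 = N (ad - bc)^2 / (r1 r2 c1 c2) on the allele table
        t = crc_tables["rs10935945"]
        a, b, c, d = t.allele_counts
        n = a + b + c + d
        chi2_exp = n * (c * b - d * a) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        res = allelic_test(t)
        assert res.chi2 == pytest.approx(chi2_exp, abs=1e-9)
        assert res.p == pytest.approx(stats.chi2.sf(chi2_exp, 1), rel=1e-9)
        assert res.chi2 == pytest.approx(22.79, abs=0.01)

    def test_or_against_statsmodels(self, crc_tables):
        import statsmodels.api as sm

        t = crc_tables["rs17575184"]
        a, b, c, d = t.allele_counts
        t22 = sm.stats.Table2x2(np.array([[c, d], [a, b]]))
        res = allelic_test(t)
        assert res.odds_ratio == pytest.approx(t22.oddsratio, rel=1e-12)
        lo, hi = t22.oddsratio_confint()
        assert res.ci_low == pytest.approx(lo, rel=1e-9)
        assert res.ci_high == pytest.approx(hi, rel=1e-9)

    def test_balanced_table_is_null(self):
        res = allelic_test(_table((0, 10, 10), (0, 10, 10)))
        assert (res.chi2, res.p, res.odds_ratio) == (0.0, 1.0, 1.0)

    def test_zero_cell_haldane_flagged(self):
        with pytest.warns(RuntimeWarning):
            res = allelic_test(_table((0, 0, 50), (5, 20, 25)))
        assert res.corrected and np.isfinite(res.odds_ratio)

    def test_cell_scaling_invariance(self, crc_tables):
        t = crc_tables["rs12935896"]
        scaled = _table(
            tuple(3 * x for x in t.case_genotypes()),
            tuple(3 * x for x in t.control_genotypes()),
        )
        r1, r2 = allelic_test(t), allelic_test(scaled)
        assert r2.odds_ratio == pytest.approx(r1.odds_ratio, rel=1e-12)
        assert r2.chi2 == pytest.approx(3 * r1.chi2, rel=1e-9)

    def test_label_swap_gives_reciprocal_or_same_p(self, crc_tables):
        t = crc_tables["rs9927668"]
        r1, r2 = allelic_test(t), allelic_test(t.swapped())
        assert r2.odds_ratio == pytest.approx(1 / r1.odds_ratio, rel=1e-12)
        assert r2.p == pytest.approx(r1.p, rel=1e-12)


class TestTrend:
    def test_frozen_r_oracle(self, crc_tables):
        z, p = trend_test(crc_tables["rs10935945"])
        assert z**2 == pytest.approx(R_TREND_CHI2_RS10935945, abs=1e-8)
        assert p == pytest.approx(R_TREND_P_RS10935945, rel=1e-8)

    def test_identical_distributions_null(self):
        z, p = trend_test(_table((10, 10, 10), (10, 10, 10)))
        assert (z, p) == (0.0, 1.0)

    def test_extreme_trend(self):
        _, p = trend_test(_table((30, 10, 0), (0, 10, 30)))
        assert p < 1e-6

    def test_sign_follows_risk_direction(self, crc_tables):
        assert trend_test(crc_tables["rs10935945"]).z > 0  # risk allele
        assert trend_test(crc_tables["rs9927668"]).z < 0  # protective allele

    def test_degenerate_margins_warn(self):
        with pytest.warns(RuntimeWarning):
            z, p = trend_test(_table((0, 20, 0), (0, 30, 0)))
        assert p == 1.0


class TestFisher2x3:
    def test_uniform_table(self):
        assert fisher_test_2x3(_table((1, 1, 1), (1, 1, 1))) == pytest.approx(1.0)

    def test_frozen_r_oracles(self, crc_tables):
        assert fisher_test_2x3(crc_tables["rs17575184"]) == pytest.approx(
            R_FISHER_P_RS17575184, rel=1e-8
        )
        assert fisher_test_2x3(crc_tables["rs12424924"]) == pytest.approx(
            R_FISHER_P_RS12424924, rel=1e-8
        )

    def test_empty_column_matches_2x2_fisher(self):
        p3 = fisher_test_2x3(_table((0, 3, 9), (0, 8, 4)))
        _, p2 = stats.fisher_exact([[3, 9], [8, 4]])
        assert p3 == pytest.approx(p2, rel=1e-9)

    def test_enumeration_limit(self):
        big = _table((40_000, 40_000, 40_000), (40_000, 40_000, 40_000))
        with pytest.raises(ValueError, match="enumeration"):
            fisher_test_2x3(big, max_tables=1000)


class TestChooseTest:
    def test_sparse_cells_trigger_fisher(self, crc_tables):
        chosen = {s: choose_genotype_test(t) for s, t in crc_tables.items()}
        assert chosen["rs17575184"] == "fisher"
        assert [s for s, c in chosen.items() if c == "fisher"] == ["rs17575184"]

    def test_boundary_cell_of_five_uses_trend(self):
        assert choose_genotype_test(_table((5, 30, 30), (5, 30, 30))) == "trend"
        assert choose_genotype_test(_table((4, 30, 30), (5, 30, 30))) == "fisher"


class TestBh:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04], atol=1e-12
        )

    def test_all_ones(self):
        assert (bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=25))
    def test_dominates_raw_and_permutation_equivariant(self, p):
        adj = bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-15).all() and (adj <= 1 + 1e-12).all()
        perm = np.random.default_rng(1).permutation(len(p))
        np.testing.assert_allclose(bh_adjust(np.asarray(p)[perm]), adj[perm], atol=1e-12)


class TestGenotypicOrs:
    def test_symmetric_table_all_unit(self):
        ors = genotypic_ors(_table((5, 10, 20), (5, 10, 20)))
        assert all(o.odds_ratio == pytest.approx(1.0) for o in ors)

    def test_reference_is_major_homozygote(self, crc_tables):
        t = crc_tables["rs10935945"]
        mm, mM = genotypic_ors(t)
        assert mm.label == "TT" and mM.label == "TC"
        # (case TT / case CC) / (ctrl TT / ctrl CC)
        assert mm.odds_ratio == pytest.approx((117 / 103) / (195 / 363), rel=1e-12)

    def test_midp_close_to_wald_when_dense(self, crc_tables):
        t = crc_tables["rs10935945"]
        wald = genotypic_ors(t, method="wald")
        midp = genotypic_ors(t, method="midp")
        assert midp[0].odds_ratio == pytest.approx(wald[0].odds_ratio, rel=0.05)
        assert midp[0].ci_low < midp[0].odds_ratio < midp[0].ci_high


class TestVerifyStudy:
    def test_label_swap_symmetry(self, crc_tables):
        tables = list(crc_tables.values())
        res = verify_snps(tables)
        res_swapped = verify_snps([t.swapped() for t in tables])
        np.testing.assert_allclose(
            res.frame["allelic_p"], res_swapped.frame["allelic_p"], rtol=1e-10
        )
        np.testing.assert_allclose(
            res.frame["allelic_or"], 1 / res_swapped.frame["allelic_or"], rtol=1e-10
        )

    def test_null_tables_reject_at_nominal_rate(self, rng):
        n_rep, n = 1000, 500
        rej_allelic = rej_trend = 0
        for _ in range(n_rep):
            g_case = rng.binomial(2, 0.3, n)
            g_ctrl = rng.binomial(2, 0.3, n)
            t = _table(
                tuple(int((g_case == k).sum()) for k in (2, 1, 0)),
                tuple(int((g_ctrl == k).sum()) for k in (2, 1, 0)),
            )
            rej_allelic += allelic_test(t).p < 0.05
            rej_trend += trend_test(t).p < 0.05
        band = 3 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rej_allelic / n_rep - 0.05) < band
        assert abs(rej_trend / n_rep - 0.05) < band

    def test_from_genotypes_counts_and_minor_flip(self):
        g = np.array(
            [[2, 0], [1, 0], [0, 1], [-1, 2], [2, 2], [1, 2]], dtype=float
        )
        is_case = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        tables = tables_from_genotypes(g, is_case, ["a", "b"])
        ta = tables[0]  # coded allele at 3/4 in controls (NA dropped) -> flipped
        assert ta.minor_allele == "M"
        assert (ta.case_mm, ta.case_mM, ta.case_MM) == (1, 1, 1)
        assert (ta.ctrl_mm, ta.ctrl_mM, ta.ctrl_MM) == (0, 1, 1)
        tb = tables[1]  # coded allele frequency > 0.5 in controls -> flipped
        assert (tb.ctrl_mm, tb.ctrl_mM, tb.ctrl_MM) == (0, 0, 3)

    def test_summary_mentions_significant_count(self, crc_results):
        assert "significant" in crc_results.summary()


class TestOrientationInvariant:
    def test_minor_major_exposure_product_is_one(self, crc_tables):
        t = crc_tables["rs11060839"]
        a, b, c, d = t.allele_counts
        or_minor = (c / d) / (a / b)
        or_major = (d / c) / (b / a)
        assert or_minor * or_major == pytest.approx(1.0, rel=1e-12)
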