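"""Pooled scan: RAS, Welch test, Holm, genomic lambda, pool QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from poolgwas.scan import (
    PooledAlleleScan,
    PoolIntensityMatrix,
    ScanError,
    compute_ras,
    genomic_lambda,
    holm_adjust,
    pca_pool_qc,
    welch_test,
)
from poolgwas.simulate import SimConfig, simulate_study


class TestRas:
    @pytest.mark.parametrize(
        "a, b, expected", [(50, 50, 0.5), (702, 298, 0.702), (1, 0, 1.0), (0, 3, 0.0)]
    )
    def test_values(self, a, b, expected):
        assert compute_ras(np.array([a]), np.array([b]))[0] == pytest.approx(expected)

    def test_zero_total_is_missing(self):
        assert np.isnan(compute_ras(np.array([0.0]), np.array([0.0]))[0])

    def test_negative_signal_rejected(self):
        with pytest.raises(ScanError):
            compute_ras(np.array([-1.0]), np.array([1.0]))

    @given(
        a=st.floats(min_value=0, max_value=1e6),
        b=st.floats(min_value=0, max_value=1e6),
    )
    def test_channel_swap_complementarity(self, a, b):
        r1 = compute_ras(np.array([a]), np.array([b]))[0]
        r2 = compute_ras(np.array([b]), np.array([a]))[0]
        if a + b > 0:
            assert r1 + r2 == pytest.approx(1.0)
        else:
            assert np.isnan(r1) and np.isnan(r2)


class TestWelch:
    CASE = [0.52, 0.58, 0.55, 0.60]
    CTRL = [0.40, 0.45, 0.42]

    def test_against_textbook_formula(self):
        # independent oracle: direct Welch/Satterthwaite formulas
        x, y = np.array(self.CASE), np.array(self.CTRL)
        m1, m2 = x.mean(), y.mean()
        v1, v2 = x.var(ddof=1), y.var(ddof=1)
        n1, n2 = len(x), len(y)
        t_exp = (m1 - m2) / np.sqrt(v1 / n1 + v2 / n2)
        df_exp = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
        p_exp = 2 * stats.t.sf(abs(t_exp), df_exp)
        t, df, p = welch_test(self.CASE, self.CTRL)
        assert t == pytest.approx(t_exp, abs=1e-10)
        assert df == pytest.approx(df_exp, abs=1e-10)
        assert p == pytest.approx(p_exp, abs=1e-10)

    def test_against_scipy(self, rng):
        x = rng.normal(0.5, 0.05, (10, 200))
        y = rng.normal(0.48, 0.07, (14, 200))
        t, df, p = welch_test(x, y)
        ref = stats.ttest_ind(x, y, equal_var=False, axis=0)
        np.testing.assert_allclose(t, ref.statistic, atol=1e-12)
        np.testing.assert_allclose(p, ref.pvalue, atol=1e-12)

    def test_identical_groups(self):
        t, df, p = welch_test([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert (t, p) == (0.0, 1.0)

    def test_flat_unequal_groups(self):
        t, df, p = welch_test([0.6, 0.6], [0.4, 0.4])
        assert np.isinf(t) and t > 0 and p == 0.0

    def test_group_swap_antisymmetry(self):
        t1, _, p1 = welch_test(self.CASE, self.CTRL)
        t2, _, p2 = welch_test(self.CTRL, self.CASE)
        assert t2 == pytest.approx(-t1) and p2 == pytest.approx(p1)

    def test_insufficient_pools_missing(self):
        t, df, p = welch_test([0.5], [0.4, 0.5, 0.6])
        assert np.isnan(t) and np.isnan(p)

    def test_nan_cells_ignored_per_probe(self):
        x = np.array([[0.5, 0.5], [0.6, np.nan], [0.4, 0.45], [0.5, 0.55]])
        y = np.array([[0.3, 0.4], [0.35, 0.42], [0.32, 0.41]])
        t, df, p = welch_test(x, y)
        t1, _, p1 = welch_test([0.5, 0.45, 0.55], [0.4, 0.42, 0.41])
        assert t[1] == pytest.approx(t1) and p[1] == pytest.approx(p1)


class TestHolm:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.02, 0.03]), [0.03, 0.04, 0.04], atol=1e-12
        )

    def test_single_test(self):
        assert holm_adjust([1.0])[0] == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ScanError):
            holm_adjust([0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30)
    )
    def test_dominates_raw_and_permutation_equivariant(self, p):
        adj = holm_adjust(p)
        assert (adj >= np.asarray(p) - 1e-15).all() and (adj <= 1 + 1e-15).all()
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(holm_adjust(np.asarray(p)[perm]), adj[perm], atol=1e-12)


class TestGenomicLambda:
    def test_ideal_uniform_order_statistics(self):
        n = 10_001
        p = (np.arange(n) + 1) / (n + 1)
        assert genomic_lambda(p) == pytest.approx(1.0, abs=1e-3)

    def test_uniform_draws(self):
        p = np.random.default_rng(0).uniform(size=100_000)
        assert 0.99 <= genomic_lambda(p) <= 1.01

    def test_inflation_direction(self, rng):
        p = rng.uniform(size=20_000)
        assert genomic_lambda(p**2) > 1.0

    def test_empty_rejected(self):
        with pytest.raises(ScanError):
            genomic_lambda([])

    def test_degenerate_all_one(self):
        with pytest.warns(RuntimeWarning):
            assert np.isnan(genomic_lambda(np.ones(10)))


class TestPoolQc:
    def _pools(self, n):
        return pd.DataFrame(
            {"pool_id": [f"P{i}" for i in range(n)], "group": ["case"] * n, "sex": "F"}
        )

    def test_identical_pools_unflagged(self):
        ras = np.tile(np.linspace(0.2, 0.8, 50), (10, 1))
        report = pca_pool_qc(ras, self._pools(10))
        assert report.flagged == []

    def test_single_shifted_pool_flagged(self, rng):
        ras = np.clip(rng.normal(0.5, 0.02, (21, 300)), 0, 1)
        ras[7] = np.clip(ras[7] + 0.4, 0, 1)
        report = pca_pool_qc(ras, self._pools(21))
        assert report.flagged == ["P7"]

    def test_infinite_threshold_disables_flagging(self, rng):
        ras = rng.uniform(0.2, 0.8, (12, 100))
        report = pca_pool_qc(ras, self._pools(12), mad_threshold=np.inf)
        assert report.flagged == []

    def test_too_few_pools_rejected(self):
        with pytest.raises(ScanError):
            pca_pool_qc(np.ones((2, 10)), self._pools(2))


def _study(seed=21, **kw):
    cfg = SimConfig(n_null_snps=kw.pop("n_null_snps", 10_000), seed=seed, **kw)
    return simulate_study(cfg)


class TestRunScan:
    def test_null_scan_type_one_error_and_uniformity(self):
        _, _, intens, _ = _study(seed=31)
        res = PooledAlleleScan(intens).fit()
        p = res.table["p"].to_numpy()
        rate = (p < 0.05).mean()
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / p.size)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_planted_strong_locus_attains_minimum_p(self):
        from poolgwas.simulate import PlantedLocus

        hits = 0
        n_rep = 20
        for s in range(n_rep):
            _, _, intens, _ = _study(
                seed=600 + s,
                n_null_snps=2_000,
                planted_loci=[
                    PlantedLocus("chr9", 700_000, 0.3, 2.0, block_n_snps=1, name="hit")
                ],
            )
            res = PooledAlleleScan(intens).fit()
            best = res.table.loc[res.table["p"].idxmin(), "probe_id"]
            hits += best == "hit"
        assert hits >= int(0.9 * n_rep)

    def test_scale_invariance_per_pool(self):
        _, _, intens, _ = _study(seed=32, n_null_snps=300)
        res1 = PooledAlleleScan(intens).fit()
        gains = np.linspace(0.5, 2.0, intens.A.shape[0])[:, None]
        scaled = PoolIntensityMatrix(
            pools=intens.pools, probes=intens.probes,
            A=intens.A * gains, B=intens.B * gains,
        )
        res2 = PooledAlleleScan(scaled).fit()
        np.testing.assert_allclose(res1.table["t"], res2.table["t"], atol=1e-9)
        np.testing.assert_allclose(res1.table["p"], res2.table["p"], atol=1e-9)

    def test_all_identical_intensities(self):
        pools = pd.DataFrame(
            {
                "pool_id": [f"P{i}" for i in range(8)],
                "group": ["case"] * 4 + ["control"] * 4,
                "sex": "F",
            }
        )
        probes = pd.DataFrame(
            {"probe_id": [f"pr{j}" for j in range(5)], "chrom": "chr1",
             "pos": np.arange(1, 6) * 1000}
        )
        m = PoolIntensityMatrix(
            pools=pools, probes=probes,
            A=np.full((8, 5), 100.0), B=np.full((8, 5), 100.0),
        )
        with pytest.warns(RuntimeWarning):
            res = PooledAlleleScan(m).fit()
        assert (res.table["p"] == 1.0).all()
        assert np.isnan(res.lambda_gc)

    def test_holm_never_below_raw(self):
        _, _, intens, _ = _study(seed=33, n_null_snps=500)
        res = PooledAlleleScan(intens).fit()
        ok = res.table.dropna(subset=["p"])
        assert (ok["p_holm"] >= ok["p"] - 1e-15).all()

    def test_summary_and_plots_run(self, tmp_path):
        import matplotlib

        matplotlib.use("Agg")
        _, _, intens, _ = _study(seed=34, n_null_snps=400)
        res = PooledAlleleScan(intens).fit()
        assert "lambda" in res.summary()
        res.plot_qq()
        res.plot_manhattan()
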