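"""Correlated Fisher set test: limiting cases, invariances, df behaviour."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from conftest import make_panel, make_stats
from pleiogene.errors import ValidationError
from pleiogene.genes import assign_snps_to_genes
from pleiogene.io import GeneModel
from pleiogene.ld import LdMatrix, compute_ld
from pleiogene.setscreen import (
    SetScreenConfig,
    pairwise_rho,
    setscreen_gene_p,
    setscreen_scan,
)


class TestPairwiseRho:
    def test_absolute_value_and_r2(self):
        r = np.array([[1.0, -0.6], [-0.6, 1.0]])
        ld = LdMatrix(("a", "b"), r)
        assert pairwise_rho(ld, "abs")[0, 1] == pytest.approx(0.6)
        assert pairwise_rho(ld, "r2")[0, 1] == pytest.approx(0.36)
        for kind in ("abs", "r2"):
            rho = pairwise_rho(ld, kind)
            np.testing.assert_array_equal(rho, rho.T)
            np.testing.assert_array_equal(np.diag(rho), 1.0)

    def test_identity_stays_identity(self):
        assert (pairwise_rho(LdMatrix(("a", "b"), np.eye(2)), "abs") == np.eye(2)).all()


class TestSetscreenGeneP:
    def test_single_snp_returns_input_p(self):
        res = setscreen_gene_p([0.01], np.eye(1))
        assert res.p == pytest.approx(0.01, abs=1e-12)
        assert res.sigma2 == 4.0 and res.df == 2.0

    def test_two_independent_snps_classical_fisher(self):
        res = setscreen_gene_p([0.05, 0.05], np.eye(2))
        assert res.statistic == pytest.approx(11.9830, abs=1e-4)
        assert res.df == 4.0
        # closed form for 4 df: p = e^{-x/2} (1 + x/2)
        x = res.statistic
        assert res.p == pytest.approx(np.exp(-x / 2) * (1 + x / 2), rel=1e-10)
        assert res.p == pytest.approx(0.017479, abs=1e-5)

    @pytest.mark.parametrize("n", [2, 5, 10])
    def test_zero_rho_equals_chi2_2n_oracle(self, n, rng):
        p = rng.uniform(1e-6, 1.0, size=n)
        res = setscreen_gene_p(p, np.eye(n))
        oracle = sps.chi2.sf(-2 * np.log(p).sum(), df=2 * n)
        assert abs(res.p - oracle) < 1e-12

    @pytest.mark.parametrize("n_copies", [2, 3, 5])
    def test_perfectly_duplicated_snp_adds_no_evidence(self, n_copies):
        # n identical copies of one marker collapse to the single-marker p
        p0 = 0.05
        rho = np.ones((n_copies, n_copies))
        res = setscreen_gene_p([p0] * n_copies, rho)
        assert res.p == pytest.approx(p0, abs=1e-12)
        assert res.df == pytest.approx(2.0, abs=1e-12)

    def test_strict_printed_sigma_breaks_duplication_invariance(self):
        rho = np.ones((2, 2))
        res = setscreen_gene_p([0.05, 0.05], rho, strict_printed_sigma=True)
        assert res.df == pytest.approx(8 / 3)
        assert res.p != pytest.approx(0.05, abs=1e-6)

    def test_monotone_in_each_p(self):
        rho = np.array([[1.0, 0.4], [0.4, 1.0]])
        base = setscreen_gene_p([0.1, 0.2], rho).p
        assert setscreen_gene_p([0.05, 0.2], rho).p <= base
        assert setscreen_gene_p([0.1, 0.1], rho).p <= base

    @given(
        st.integers(min_value=2, max_value=8),
        st.integers(min_value=0, max_value=10_000),
    )
    def test_df_bounds_and_identity_condition(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(30, n)).cumsum(axis=1)  # correlated columns
        rho = np.abs(np.corrcoef(x, rowvar=False))
        np.fill_diagonal(rho, 1.0)
        res = setscreen_gene_p(rng.uniform(0.01, 1.0, n), rho)
        assert 0 < res.df <= 2 * n + 1e-12
        ident = setscreen_gene_p(rng.uniform(0.01, 1.0, n), np.eye(n))
        assert ident.df == pytest.approx(2 * n)

    def test_validation_errors(self):
        with pytest.raises(ValidationError):
            setscreen_gene_p([], np.eye(0))
        with pytest.raises(ValidationError):
            setscreen_gene_p([0.5, 0.5], np.eye(3))
        with pytest.raises(ValidationError):
            setscreen_gene_p([0.0], np.eye(1))


class TestSetscreenScan:
    def _inputs(self, rng):
        dos = rng.integers(0, 3, size=(60, 5)).astype(float)
        panel = make_panel(dos, pos=[100, 200, 300, 1100, 1200], chrom=["1"] * 5)
        stats = make_stats(
            [f"rs{i}" for i in range(5)],
            [100, 200, 300, 1100, 1200],
            [0.01, 0.3, 0.6, 0.2, 0.4],
        )
        genes = [GeneModel("GA", "1", 50, 350), GeneModel("GB", "1", 1000, 1300)]
        return stats, genes, panel

    def test_rerun_bit_identical_and_n_conserved(self, rng):
        stats, genes, panel = self._inputs(rng)
        aset = assign_snps_to_genes(stats, genes, panel, mode="plain")
        r1 = setscreen_scan(stats, aset, panel)
        r2 = setscreen_scan(stats, aset, panel)
        assert [(r.gene_id, r.statistic, r.p) for r in r1] == [
            (r.gene_id, r.statistic, r.p) for r in r2
        ]
        assert [r.n_snps for r in r1] == [a.n_snps for a in aset.testable]

    def test_rho_r2_config_changes_result(self, rng):
        stats, genes, panel = self._inputs(rng)
        aset = assign_snps_to_genes(stats, genes, panel, mode="plain")
        p_abs = [r.p for r in setscreen_scan(stats, aset, panel, SetScreenConfig(rho="abs"))]
        p_r2 = [r.p for r in setscreen_scan(stats, aset, panel, SetScreenConfig(rho="r2"))]
        # r² ≤ |r| shrinks the covariance correction, so the p-values differ
        assert p_abs != p_r2


def test_null_scan_p_values_roughly_uniform():
    """All-null synthetic scan: the deterministic test's p-values are close
    to uniform (KS at α=0.01 over 400 independent null genes)."""
    from scipy import stats as sps

    from pleiogene.simulate import SimulationConfig, simulate_dataset

    cfg = SimulationConfig(seed=1001, n_genes=400, snps_per_gene=(5, 10),
                           n_samples_panel=300)
    ds = simulate_dataset(cfg)
    aset = assign_snps_to_genes(ds.stats1, ds.genes, ds.panel, mode="plain")
    pvals = [r.p for r in setscreen_scan(ds.stats1, aset, ds.panel)]
    assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_rho_consistent_with_panel_ld(self, rng):
        stats, genes, panel = self._inputs(rng)
        aset = assign_snps_to_genes(stats, genes, panel, mode="plain")
        ld = compute_ld(panel, list(aset.testable[0].snp_ids))
        rho = pairwise_rho(ld, "r2")
        expected = setscreen_gene_p(
            stats.p_for(list(aset.testable[0].snp_ids)), rho, gene_id="GA"
        )
        got = setscreen_scan(stats, aset, panel)[0]
        assert got.p == pytest.approx(expected.p, rel=1e-9)
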