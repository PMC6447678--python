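"""Simulation gene test: χ² conversion, empirical p, staging, determinism."""
import numpy as np
import pytest
from scipy import stats as sps

from conftest import make_panel, make_stats
from pleiogene.errors import NotPositiveSemidefiniteError, ValidationError
from pleiogene.genes import assign_snps_to_genes
from pleiogene.io import GeneModel
from pleiogene.ld import LdMatrix
from pleiogene.vegas import (
    VegasConfig,
    chi2_convert,
    derive_seed,
    vegas_gene_p,
    vegas_scan,
)


def mc_se(p, m):
    return np.sqrt(p * (1 - p) / m)


class TestChi2Convert:
    @pytest.mark.parametrize(
        "p, expected",
        [
            (1.0, 0.0),  # upper tail of zero
            (0.05, 3.8415),  # classical table value
            (0.3173, 1.0000),  # 2(1 - Φ(1)) ≈ 0.3173 maps back to 1
        ],
    )
    def test_table_values(self, p, expected):
        assert chi2_convert([p])[0] == pytest.approx(expected, abs=5e-4)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.0001])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValidationError):
            chi2_convert([bad])

    def test_inverse_of_survival_function(self, rng):
        p = rng.uniform(1e-10, 1.0, size=50)
        np.testing.assert_allclose(sps.chi2.sf(chi2_convert(p), df=1), p, rtol=1e-9)


class TestVegasGeneP:
    def test_single_snp_recovers_input_p(self):
        ld = LdMatrix(("a",), np.eye(1))
        res = vegas_gene_p([0.04], ld, stages=(19_999,), seed=11)
        assert abs(res.p - 0.04) < 3 * mc_se(0.04, 19_999)
        assert res.p == (res.exceedances + 1) / (res.n_sims_used + 1)

    def test_independent_two_snp_closed_form(self):
        # T_obs = 2 * isf(0.05); under independence p = sf_chi2(T_obs, 2) = 0.02146
        ld = LdMatrix(("a", "b"), np.eye(2))
        res = vegas_gene_p([0.05, 0.05], ld, stages=(60_000,), seed=5)
        assert abs(res.p - 0.021448) < 3 * mc_se(0.021448, 60_000)

    def test_zero_exceedances_escalate_and_floor(self):
        ld = LdMatrix(("a",), np.eye(1))
        res = vegas_gene_p([1e-12], ld, stages=(1_000, 10_000), seed=2)
        assert res.n_sims_used == 10_000  # escalated past the first stage
        assert res.p >= 1 / (res.n_sims_used + 1)
        assert res.p == (res.exceedances + 1) / (res.n_sims_used + 1)

    def test_monotone_in_observed_statistic(self):
        ld = LdMatrix(("a", "b"), np.array([[1.0, 0.6], [0.6, 1.0]]))
        weaker = vegas_gene_p([0.3, 0.4], ld, stages=(5_000,), seed=9)
        stronger = vegas_gene_p([0.01, 0.02], ld, stages=(5_000,), seed=9)
        assert stronger.p <= weaker.p

    def test_dimension_mismatch_and_non_psd_errors(self):
        ld = LdMatrix(("a", "b"), np.eye(2))
        with pytest.raises(ValidationError):
            vegas_gene_p([0.5], ld)
        bad = LdMatrix(
            ("a", "b", "c"),
            np.array([[1, 0.9, 0.9], [0.9, 1, -0.9], [0.9, -0.9, 1.0]]),
        )
        with pytest.raises(NotPositiveSemidefiniteError):
            vegas_gene_p([0.5, 0.5, 0.5], bad)

    @pytest.mark.parametrize("n", [2, 5])
    def test_identity_sigma_matches_analytic_chi2(self, n, rng):
        p_in = rng.uniform(0.01, 0.5, size=n)
        truth = sps.chi2.sf(chi2_convert(p_in).sum(), df=n)
        ld = LdMatrix(tuple(f"s{i}" for i in range(n)), np.eye(n))
        res = vegas_gene_p(p_in, ld, stages=(40_000,), seed=n)
        assert abs(res.p - truth) < 3 * mc_se(truth, 40_000)


class TestVegasScan:
    def _inputs(self, rng):
        dos = rng.integers(0, 3, size=(80, 4)).astype(float)
        dos[:, 1] = np.clip(dos[:, 0] + rng.integers(-1, 2, 80), 0, 2)
        panel = make_panel(dos, pos=[100, 200, 1100, 1200], chrom=["1"] * 4)
        stats = make_stats([f"rs{i}" for i in range(4)], [100, 200, 1100, 1200],
                           [0.02, 0.3, 0.5, 0.7])
        genes = [GeneModel("GA", "1", 50, 250), GeneModel("GB", "1", 1000, 1300)]
        return stats, genes, panel

    def test_scan_preserves_gene_order_and_is_reproducible(self, rng):
        stats, genes, panel = self._inputs(rng)
        aset = assign_snps_to_genes(stats, genes, panel, mode="plain")
        cfg = VegasConfig(seed=42, stages=(2_000,))
        res1 = vegas_scan(stats, aset, panel, cfg)
        res2 = vegas_scan(stats, aset, panel, cfg)
        assert [r.gene_id for r in res1] == ["GA", "GB"]
        assert [(r.p, r.exceedances) for r in res1] == [(r.p, r.exceedances) for r in res2]

    def test_scan_seed_independent_of_gene_order(self, rng):
        stats, genes, panel = self._inputs(rng)
        aset_fwd = assign_snps_to_genes(stats, genes, panel, mode="plain")
        aset_rev = assign_snps_to_genes(stats, list(reversed(genes)), panel, mode="plain")
        cfg = VegasConfig(seed=42, stages=(2_000,))
        fwd = {r.gene_id: r.p for r in vegas_scan(stats, aset_fwd, panel, cfg)}
        rev = {r.gene_id: r.p for r in vegas_scan(stats, aset_rev, panel, cfg)}
        assert fwd == rev

    def test_different_seed_moves_p_within_mc_error(self, rng):
        stats, genes, panel = self._inputs(rng)
        aset = assign_snps_to_genes(stats, genes, panel, mode="plain")
        a = vegas_scan(stats, aset, panel, VegasConfig(seed=1, stages=(20_000,)))
        b = vegas_scan(stats, aset, panel, VegasConfig(seed=2, stages=(20_000,)))
        for ra, rb in zip(a, b):
            assert abs(ra.p - rb.p) < 6 * mc_se(max(ra.p, 1e-3), 20_000)

    def test_missing_snp_error_names_gene(self, rng):
        stats, genes, panel = self._inputs(rng)
        aset = assign_snps_to_genes(stats, genes, panel, mode="plain")
        trimmed = make_stats(["rs0", "rs1", "rs2"], [100, 200, 1100], [0.02, 0.3, 0.5])
        with pytest.raises(ValidationError, match="GB"):
            vegas_scan(trimmed, aset, panel, VegasConfig(stages=(100,)))

    def test_derived_seeds_stable_and_bounded(self):
        s1 = derive_seed(17, "GENE1")
        assert s1 == derive_seed(17, "GENE1")
        assert s1 != derive_seed(18, "GENE1") and s1 != derive_seed(17, "GENE2")
        assert 0 <= s1 < 2**31
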