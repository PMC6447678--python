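"""SNP-to-gene assignment: boundary containment, LD buddies, drop rules."""
import numpy as np
import pytest

from conftest import make_panel, make_stats
from pleiogene.errors import ConfigError
from pleiogene.genes import (
    assign_snps_to_genes,
    assignment_report,
    assignment_table,
)
from pleiogene.io import GeneModel


@pytest.fixture
def three_snp_layout(rng):
    """Gene [100, 200] with SNPs at 150, 180 inside and 500 outside."""
    gene = GeneModel(gene_id="G", chrom="1", start=100, end=200)
    # rs_out is a noisy copy of rs_a; rs_b is independent
    a = rng.integers(0, 3, size=200).astype(float)
    b = rng.integers(0, 3, size=200).astype(float)
    out = a.copy()
    flip = rng.choice(200, size=20, replace=False)
    out[flip] = rng.integers(0, 3, size=20)
    panel = make_panel(
        np.column_stack([a, b, out]), snp_ids=["rs_a", "rs_b", "rs_out"]
    )
    stats = make_stats(["rs_a", "rs_b", "rs_out"], [150, 180, 500], [0.1, 0.2, 0.3])
    r = np.corrcoef(a, out)[0, 1]
    return gene, panel, stats, r**2


class TestPlainMode:
    def test_boundary_containment(self, three_snp_layout):
        gene, panel, stats, _ = three_snp_layout
        aset = assign_snps_to_genes(stats, [gene], mode="plain", pad_kb=0)
        (a,) = aset.assignments
        assert a.snp_ids == ("rs_a", "rs_b")
        assert all(a.within_gene)

    def test_padding_extends_the_window(self, three_snp_layout):
        gene, panel, stats, _ = three_snp_layout
        aset = assign_snps_to_genes(stats, [gene], mode="plain", pad_kb=1)
        assert aset.assignments[0].snp_ids == ("rs_a", "rs_b", "rs_out")

    def test_other_chromosome_excluded(self, three_snp_layout):
        gene, panel, stats, _ = three_snp_layout
        far_gene = GeneModel(gene_id="G2", chrom="2", start=100, end=200)
        aset = assign_snps_to_genes(stats, [far_gene], mode="plain")
        assert aset.assignments == [] and aset.dropped_gene_ids == ["G2"]


class TestLdbinMode:
    def test_high_ld_buddy_included_with_strict_threshold(self, three_snp_layout):
        gene, panel, stats, r2 = three_snp_layout
        assert 0.5 < r2 < 1.0  # the crafted noisy copy sits strictly inside (0.5, 1)
        below = assign_snps_to_genes(
            stats, [gene], panel, mode="ldbin", r2_threshold=r2 - 1e-9
        )
        at = assign_snps_to_genes(
            stats, [gene], panel, mode="ldbin", r2_threshold=r2
        )
        assert below.assignments[0].snp_ids == ("rs_a", "rs_b", "rs_out")
        assert at.assignments[0].snp_ids == ("rs_a", "rs_b")  # strict >
        assert below.assignments[0].within_gene == (True, True, False)

    def test_buddy_beyond_window_never_assigned(self, three_snp_layout):
        gene, panel, stats, _ = three_snp_layout
        far = make_stats(["rs_a", "rs_b", "rs_out"], [150, 180, 2_000_000], [0.1, 0.2, 0.3])
        aset = assign_snps_to_genes(
            far, [gene], panel, mode="ldbin", ld_window_kb=100, r2_threshold=0.0
        )
        assert aset.assignments[0].snp_ids == ("rs_a", "rs_b")

    def test_ldbin_superset_of_plain(self, three_snp_layout):
        gene, panel, stats, _ = three_snp_layout
        plain = assign_snps_to_genes(stats, [gene], panel, mode="plain", pad_kb=0)
        ldbin = assign_snps_to_genes(stats, [gene], panel, mode="ldbin", r2_threshold=0.3)
        assert set(plain.assignments[0].snp_ids) <= set(ldbin.assignments[0].snp_ids)

    def test_ldbin_without_panel_is_config_error(self, three_snp_layout):
        gene, _, stats, _ = three_snp_layout
        with pytest.raises(ConfigError):
            assign_snps_to_genes(stats, [gene], panel=None, mode="ldbin")


class TestDropAndReport:
    def _genes_and_stats(self):
        genes = [
            GeneModel("A", "1", 100, 300),  # 2 SNPs
            GeneModel("B", "1", 1000, 2000),  # 5 SNPs
            GeneModel("C", "1", 5000, 5100),  # 1 SNP -> dropped
        ]
        pos = [100, 300, 1000, 1200, 1400, 1600, 2000, 5050]
        snps = [f"rs{i}" for i in range(8)]
        stats = make_stats(snps, pos, [0.5] * 8)
        return genes, stats

    def test_single_snp_gene_dropped_and_counted(self):
        genes, stats = self._genes_and_stats()
        aset = assign_snps_to_genes(stats, genes, mode="plain")
        assert [a.gene_id for a in aset.testable] == ["A", "B"]
        assert aset.dropped_gene_ids == ["C"]
        report = assignment_report(aset)
        assert report["testable"] == 2 and report["dropped"] == 1
        assert report["testable"] + report["dropped"] == report["n_genes"] == 3
        assert report["mean_snps_per_gene"] == pytest.approx((2 + 5) / 2)

    def test_empty_input_gives_zero_report(self):
        _, stats = self._genes_and_stats()
        report = assignment_report(assign_snps_to_genes(stats, [], mode="plain"))
        assert report["n_genes"] == report["testable"] == report["dropped"] == 0

    def test_assignment_deterministic_and_dumpable(self):
        genes, stats = self._genes_and_stats()
        a = assign_snps_to_genes(stats, genes, mode="plain")
        b = assign_snps_to_genes(stats, genes, mode="plain")
        assert [x.snp_ids for x in a.assignments] == [x.snp_ids for x in b.assignments]
        dump = assignment_table(a.testable)
        assert set(dump.columns) == {"gene_id", "snp_id", "within_gene"}
        assert len(dump) == 7

    def test_snp_may_belong_to_overlapping_genes(self):
        genes = [GeneModel("A", "1", 100, 300), GeneModel("B", "1", 200, 400)]
        stats = make_stats(["rs1", "rs2", "rs3"], [150, 250, 350], [0.5] * 3)
        aset = assign_snps_to_genes(stats, genes, mode="plain")
        assert aset.assignments[0].snp_ids == ("rs1", "rs2")
        assert aset.assignments[1].snp_ids == ("rs2", "rs3")
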