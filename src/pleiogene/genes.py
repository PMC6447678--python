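"""SNP-to-gene assignment under boundary rules.

Two modes:

* ``plain`` — SNPs whose position lies within [start − pad, end + pad] on the
  gene's chromosome.
* ``ldbin`` — the "0 kb + LD bin" boundary: SNPs inside the gene itself, plus
  any SNP within ``ld_window_kb`` of the gene boundary whose squared dosage
  correlation with at least one within-gene SNP exceeds ``r2_threshold``
  (strict >).  Distant markers tagging the gene through LD then contribute to
  the gene statistic instead of being silently ignored.

Genes with fewer than two assigned SNPs carry no aggregable signal and are
dropped from testing (counted in the assignment report).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import GeneModel, ReferencePanel, SummaryStats

MIN_SNPS_PER_GENE = 2


@dataclass
class GeneAssignment:
    """Ordered SNP membership of one gene under a stated boundary rule."""

    gene_id: str
    snp_ids: Tuple[str, ...]
    within_gene: Tuple[bool, ...]
    boundary_mode: str
    pad_kb: int

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass
class AssignmentSet:
    """All per-gene assignments from one run, plus drop bookkeeping."""

    assignments: List[GeneAssignment]
    n_genes_input: int
    mode: str
    dropped_gene_ids: List[str] = field(default_factory=list)

    @property
    def testable(self) -> List[GeneAssignment]:
        return [a for a in self.assignments if a.n_snps >= MIN_SNPS_PER_GENE]


def assign_snps_to_genes(
    stats: SummaryStats,
    genes: Sequence[GeneModel],
    panel: Optional[ReferencePanel] = None,
    mode: str = "plain",
    pad_kb: int = 0,
    ld_window_kb: int = 1000,
    r2_threshold: float = 0.8,
) -> AssignmentSet:
    """Assign SNPs from ``stats`` to each gene; see the module docstring.

    A SNP may belong to several overlapping genes.  In ``ldbin`` mode a panel
    is mandatory; SNPs monomorphic in the panel are removed up front (their LD
    is undefined and they carry no association information).
    """
    if mode not in ("plain", "ldbin"):
        raise ConfigError(f"unknown boundary mode: {mode!r}")
    if mode == "ldbin" and panel is None:
        raise ConfigError("ldbin assignment requires a reference panel")

    table = stats.table
    if panel is not None:
        panel_idx = {s: i for i, s in enumerate(panel.snp_ids)}
        keep = table["snp"].map(
            lambda s: s in panel_idx and not panel.monomorphic[panel_idx[s]]
        )
        table = table[keep]

    pad = pad_kb * 1000
    window = ld_window_kb * 1000
    by_chrom: Dict[str, pd.DataFrame] = {c: g for c, g in table.groupby("chrom")}

    assignments: List[GeneAssignment] = []
    dropped: List[str] = []
    for gene in genes:
        chrom_snps = by_chrom.get(gene.chrom)
        if chrom_snps is None:
            dropped.append(gene.gene_id)
            continue
        pos = chrom_snps["pos"].to_numpy()
        ids = chrom_snps["snp"].to_numpy()

        if mode == "plain":
            mask = (pos >= gene.start - pad) & (pos <= gene.end + pad)
            sel_ids = ids[mask]
            sel_pos = pos[mask]
            within = np.ones(mask.sum(), dtype=bool)
        else:  # ldbin: within-gene core plus high-LD buddies inside the window
            inside = (pos >= gene.start) & (pos <= gene.end)
            near = (pos >= gene.start - window) & (pos <= gene.end + window) & ~inside
            core_ids = ids[inside]
            buddy_mask = np.zeros(near.sum(), dtype=bool)
            if len(core_ids) and near.any():
                cand_ids = ids[near]
                sub = panel.columns(list(core_ids) + list(cand_ids))
                r = np.corrcoef(sub, rowvar=False)
                r2 = r[: len(core_ids), len(core_ids):] ** 2
                buddy_mask = (r2 > r2_threshold).any(axis=0)
            sel_ids = np.concatenate([core_ids, ids[near][buddy_mask]])
            sel_pos = np.concatenate([pos[inside], pos[near][buddy_mask]])
            within = np.concatenate(
                [np.ones(len(core_ids), dtype=bool), np.zeros(int(buddy_mask.sum()), dtype=bool)]
            )

        order = np.argsort(sel_pos, kind="mergesort")
        assignment = GeneAssignment(
            gene_id=gene.gene_id,
            snp_ids=tuple(sel_ids[order]),
            within_gene=tuple(bool(w) for w in within[order]),
            boundary_mode=mode,
            pad_kb=pad_kb,
        )
        if assignment.n_snps == 0:
            dropped.append(gene.gene_id)
        else:
            assignments.append(assignment)
            if assignment.n_snps < MIN_SNPS_PER_GENE:
                dropped.append(gene.gene_id)

    return AssignmentSet(
        assignments=assignments,
        n_genes_input=len(genes),
        mode=mode,
        dropped_gene_ids=dropped,
    )


def assignment_report(
    assignments: Union[AssignmentSet, Sequence[GeneAssignment]],
) -> Dict[str, float]:
    """Per-mode counts of testable vs dropped genes and mean SNPs per gene."""
    if isinstance(assignments, AssignmentSet):
        testable = assignments.testable
        n_total = assignments.n_genes_input
        mode = assignments.mode
    else:
        testable = [a for a in assignments if a.n_snps >= MIN_SNPS_PER_GENE]
        n_total = len(assignments)
        mode = assignments[0].boundary_mode if assignments else ""
    n_testable = len(testable)
    return {
        "mode": mode,
        "n_genes": n_total,
        "testable": n_testable,
        "dropped": n_total - n_testable,
        "mean_snps_per_gene": (
            float(np.mean([a.n_snps for a in testable])) if testable else 0.0
        ),
    }


def assignment_table(assignments: Sequence[GeneAssignment]) -> pd.DataFrame:
    """Long-format dump: one row per (gene, SNP) with a within-gene flag."""
    rows = [
        {"gene_id": a.gene_id, "snp_id": s, "within_gene": int(w)}
        for a in assignments
        for s, w in zip(a.snp_ids, a.within_gene)
    ]
    return pd.DataFrame(rows, columns=["gene_id", "snp_id", "within_gene"])
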