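"""Simulation-based gene test: sum of per-SNP χ²₁ statistics vs an LD-aware null.

Each SNP's p-value is converted to the upper-tail χ² statistic with 1 df and
summed over the gene, T = Σ qᵢ.  If the SNPs were independent T would be
χ²_n, but LD correlates them; the null is therefore obtained by sampling
z ~ MVN(0, Σ) with Σ the gene's LD matrix and recording how often
T_sim = Σ zᵢ² reaches T_obs.  The empirical p is (r + 1)/(m + 1) with r
exceedances in m simulations — never zero, never below 1/(m + 1).

Simulation counts escalate in stages: a gene whose exceedance count at the
current stage is too small for a stable estimate (fewer than ``min_exceed``)
is rerun at the next stage size, so cheap genes stay cheap and significant
genes get resolution.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .errors import NotPositiveSemidefiniteError, ValidationError
from .genes import AssignmentSet, GeneAssignment
from .io import ReferencePanel, SummaryStats
from .ld import LdMatrix, compute_ld, condition_psd
from .results import GeneTestResult

DEFAULT_STAGES: Tuple[int, ...] = (1_000, 10_000, 1_000_000)


def chi2_convert(p_values: Sequence[float]) -> np.ndarray:
    """Upper-tail χ²₁ statistics for the given p-values; p = 1 maps to 0."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p <= 0).any() or (p > 1).any()):
        raise ValidationError("p-values must lie in (0, 1]")
    return sps.chi2.isf(p, df=1)


def derive_seed(global_seed: int, label: str) -> int:
    """Stable per-gene seed from (global seed, label); independent of scan order."""
    digest = hashlib.sha256(f"{global_seed}|{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _mvn_factor(ld: LdMatrix) -> np.ndarray:
    """Deterministic factor L with L Lᵀ = Σ (eigendecomposition)."""
    w, v = np.linalg.eigh(ld.r)
    if w[0] < -1e-8:
        raise NotPositiveSemidefiniteError(
            f"LD matrix has eigenvalue {w[0]:.3e} < 0; run condition_psd first"
        )
    return v * np.sqrt(np.clip(w, 0.0, None))


@dataclass
class VegasConfig:
    """Knobs for the simulation test.

    ``stages`` are the escalating simulation counts; escalation triggers when
    fewer than ``min_exceed`` simulated statistics reach the observed one.
    ``top_k`` optionally restricts each gene to its k smallest-p SNPs
    (default: off — all assigned SNPs contribute).
    """

    seed: int = 0
    stages: Tuple[int, ...] = DEFAULT_STAGES
    min_exceed: int = 100
    top_k: Optional[int] = None
    chunk: int = 200_000


def vegas_gene_p(
    p_values: Sequence[float],
    ld: LdMatrix,
    stages: Sequence[int] = DEFAULT_STAGES,
    seed: int = 0,
    min_exceed: int = 100,
    gene_id: str = "",
    chunk: int = 200_000,
) -> GeneTestResult:
    """Empirical gene p-value for one gene.

    ``p_values`` must align with the rows of ``ld``, which must already be
    PSD-conditioned.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size != ld.n:
        raise ValidationError(
            f"gene {gene_id or '?'}: {p.size} p-values vs {ld.n}-dim LD matrix"
        )
    q = chi2_convert(p)
    t_obs = float(q.sum())
    L = _mvn_factor(ld)
    n = ld.n
    rng = np.random.default_rng(seed)

    exceed = 0
    m_used = 0
    p_emp = 1.0
    for stage_i, m in enumerate(stages):
        exceed = 0
        done = 0
        while done < m:
            k = min(chunk, m - done)
            z = L @ rng.standard_normal((n, k))
            t_sim = np.einsum("ij,ij->j", z, z)
            exceed += int(np.count_nonzero(t_sim >= t_obs))
            done += k
        m_used = m
        p_emp = (exceed + 1) / (m + 1)
        if exceed >= min_exceed or stage_i == len(stages) - 1:
            break
    return GeneTestResult(
        gene_id=gene_id,
        n_snps=n,
        statistic=t_obs,
        p=p_emp,
        method="vegas",
        n_sims_used=m_used,
        exceedances=exceed,
    )


def vegas_scan(
    stats: SummaryStats,
    assignments: AssignmentSet | Sequence[GeneAssignment],
    panel: ReferencePanel,
    config: Optional[VegasConfig] = None,
) -> list[GeneTestResult]:
    """Run the simulation test on every testable gene.

    Per-gene seeds derive deterministically from (config.seed, gene_id), so
    reruns are bit-identical and independent of gene order.
    """
    cfg = config or VegasConfig()
    genes = assignments.testable if isinstance(assignments, AssignmentSet) else list(assignments)
    out: list[GeneTestResult] = []
    for a in genes:
        snp_ids = list(a.snp_ids)
        try:
            p = stats.p_for(snp_ids)
        except ValidationError as exc:
            raise ValidationError(f"gene {a.gene_id}: {exc}") from exc
        if cfg.top_k is not None and cfg.top_k < len(snp_ids):
            keep = np.argsort(p, kind="mergesort")[: cfg.top_k]
            keep.sort()
            snp_ids = [snp_ids[i] for i in keep]
            p = p[keep]
        ld = condition_psd(compute_ld(panel, snp_ids))
        out.append(
            vegas_gene_p(
                p,
                ld,
                stages=cfg.stages,
                seed=derive_seed(cfg.seed, a.gene_id),
                min_exceed=cfg.min_exceed,
                gene_id=a.gene_id,
                chunk=cfg.chunk,
            )
        )
    return out
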