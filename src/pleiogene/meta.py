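"""Cross-phenotype shared-gene logic.

A gene is a *candidate* when it is nominally associated (p < α, strict) with
both phenotypes under the same gene-based method.  Candidates' two p-values
are combined by Fisher's meta-analysis, x² = −2(ln P₁ + ln P₂) ~ χ²₄, and
declared significant under a Bonferroni threshold 0.05/(candidates × 2).
Running the funnel once per method and intersecting the two significant sets
yields the final shared genes.
"""
from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .errors import ValidationError
from .results import CrossPhenotypeResult, GeneTestResult

DEFAULT_ALPHA_NOMINAL = 0.05


def _p_map(results: Sequence[GeneTestResult], which: str) -> Dict[str, float]:
    seen: Dict[str, float] = {}
    for r in results:
        if r.gene_id in seen:
            raise ValidationError(f"duplicate gene id in {which} results: {r.gene_id}")
        seen[r.gene_id] = r.p
    return seen


def shared_candidates(
    results1: Sequence[GeneTestResult],
    results2: Sequence[GeneTestResult],
    alpha_nominal: float = DEFAULT_ALPHA_NOMINAL,
) -> List[str]:
    """Genes with p strictly below ``alpha_nominal`` in both phenotypes.

    Order follows ``results1``; both inputs must come from the same method.
    """
    p1 = _p_map(results1, "phenotype-1")
    p2 = _p_map(results2, "phenotype-2")
    return [
        g
        for g, p in p1.items()
        if p < alpha_nominal and g in p2 and p2[g] < alpha_nominal
    ]


def fisher_meta(p1: float, p2: float) -> Tuple[float, float]:
    """Fisher combination of two independent study p-values (χ² with 4 df)."""
    for p in (p1, p2):
        if not (0.0 < p <= 1.0):
            raise ValidationError(f"p-value {p} outside (0, 1]")
    chi2 = float(-2.0 * (np.log(p1) + np.log(p2)))
    return chi2, float(sps.chi2.sf(chi2, df=4))


def bonferroni_threshold(n_candidates: int, n_phenotypes: int = 2) -> float:
    """0.05 divided by (candidate count × phenotype count)."""
    if n_candidates < 1 or n_phenotypes < 1:
        raise ValidationError("counts must be positive")
    return 0.05 / (n_candidates * n_phenotypes)


def cross_phenotype_meta(
    results1: Sequence[GeneTestResult],
    results2: Sequence[GeneTestResult],
    alpha_nominal: float = DEFAULT_ALPHA_NOMINAL,
    n_phenotypes: int = 2,
) -> List[CrossPhenotypeResult]:
    """Full candidate → meta → Bonferroni funnel for one method.

    Output is sorted by ascending meta p (most significant first).
    """
    candidates = shared_candidates(results1, results2, alpha_nominal)
    if not candidates:
        return []
    p1 = _p_map(results1, "phenotype-1")
    p2 = _p_map(results2, "phenotype-2")
    method = results1[0].method if results1 else ""
    threshold = bonferroni_threshold(len(candidates), n_phenotypes)
    out = []
    for g in candidates:
        chi2, meta_p = fisher_meta(p1[g], p2[g])
        out.append(
            CrossPhenotypeResult(
                gene_id=g,
                p_pheno1=p1[g],
                p_pheno2=p2[g],
                meta_chi2=chi2,
                meta_p=meta_p,
                n_candidates=len(candidates),
                passes_bonferroni=meta_p < threshold,
                method=method,
            )
        )
    out.sort(key=lambda r: (r.meta_p, r.gene_id))
    return out


def significant_genes(results: Sequence[CrossPhenotypeResult]) -> List[str]:
    return [r.gene_id for r in results if r.passes_bonferroni]


def _normalize_gene(g: str) -> str:
    return g.strip().upper()


def intersect_methods(
    sig_method1: Sequence[str], sig_method2: Sequence[str]
) -> List[str]:
    """Genes significant under both methods (exact match after normalization)."""
    norm1 = {_normalize_gene(g): g for g in sig_method1}
    norm2 = {_normalize_gene(g) for g in sig_method2}
    return sorted(norm1[k] for k in norm1.keys() & norm2)
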