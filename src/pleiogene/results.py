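"""Result records produced by the gene tests and downstream stages.

All records are plain dataclasses; ``to_frame`` turns a homogeneous list into a
:class:`pandas.DataFrame` with a deterministic column order for writing.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from typing import Optional, Sequence

import pandas as pd


@dataclass
class GeneTestResult:
    """Per-gene statistic and p-value from one method on one phenotype.

    ``method`` is ``"vegas"`` (simulation test; ``n_sims_used`` and
    ``exceedances`` are set, and ``p == (exceedances + 1) / (n_sims_used + 1)``)
    or ``"setscreen"`` (correlated Fisher test; ``sigma2`` and fractional ``df``
    of the scaled-χ² null are set).
    """

    gene_id: str
    n_snps: int
    statistic: float
    p: float
    method: str
    n_sims_used: Optional[int] = None
    exceedances: Optional[int] = None
    sigma2: Optional[float] = None
    df: Optional[float] = None


@dataclass
class CrossPhenotypeResult:
    """Fisher meta-analysis of one gene's p-values across two phenotypes."""

    gene_id: str
    p_pheno1: float
    p_pheno2: float
    meta_chi2: float
    meta_p: float
    n_candidates: int
    passes_bonferroni: bool
    method: str


@dataclass
class DiffExprResult:
    """Two-group differential-expression call for one gene.

    ``tested`` is False when the gene was requested but absent from the
    expression matrix; all numeric fields are then NaN.
    """

    gene_id: str
    logFC: float
    t_statistic: float
    p: float
    significant: bool
    tested: bool = True


def to_frame(records: Sequence) -> pd.DataFrame:
    """Convert a list of identical dataclass records to a DataFrame.

    An empty list yields an empty frame with no columns; callers that need a
    typed header pass the record class to :func:`empty_frame`.
    """
    if not records:
        return pd.DataFrame()
    return pd.DataFrame([asdict(r) for r in records])


def empty_frame(record_cls) -> pd.DataFrame:
    return pd.DataFrame({f.name: [] for f in fields(record_cls)})
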