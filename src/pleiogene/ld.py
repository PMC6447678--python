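"""LD (linkage disequilibrium) matrices from a reference panel.

The SNP × SNP Pearson correlation of dosages ("composite" LD, valid for
unphased panels) is both the covariance Σ of the simulation null and the
source of the ρ_ij correction in the correlated Fisher test.  Empirical
correlation matrices of more SNPs than samples (or with duplicated variants)
can be numerically indefinite, so a PSD repair step is provided; multivariate
normal sampling requires it.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .errors import ValidationError
from .io import ReferencePanel

#: eigenvalues are raised at least to this before factorization.
PSD_FLOOR = 1e-8


@dataclass(frozen=True)
class LdMatrix:
    """Symmetric SNP × SNP correlation matrix with unit diagonal."""

    snp_ids: Tuple[str, ...]
    r: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1] or r.shape[0] != len(self.snp_ids):
            raise ValidationError("LD matrix shape does not match snp_ids")
        if not np.allclose(r, r.T, atol=1e-10):
            raise ValidationError("LD matrix is not symmetric")
        object.__setattr__(self, "r", r)

    @property
    def n(self) -> int:
        return len(self.snp_ids)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.r)[0])


def compute_ld(panel: ReferencePanel, snp_ids: Sequence[str]) -> LdMatrix:
    """Pearson correlation of panel dosage columns for the given SNPs.

    Monomorphic variants have undefined correlation and must be excluded by
    the caller; requesting one is an error naming the id.
    """
    snp_ids = list(snp_ids)
    if len(snp_ids) == 0:
        raise ValidationError("compute_ld: empty SNP list")
    idx = panel.index_of(snp_ids)
    mono = [s for s, i in zip(snp_ids, idx) if panel.monomorphic[i]]
    if mono:
        raise ValidationError(f"monomorphic variants requested for LD: {mono[:5]}")
    X = panel.dosages[:, idx]
    if len(snp_ids) == 1:
        r = np.ones((1, 1))
    else:
        r = np.corrcoef(X, rowvar=False)
        r = np.clip(r, -1.0, 1.0)
        r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return LdMatrix(snp_ids=tuple(snp_ids), r=r)


def condition_psd(ld: LdMatrix, psd_floor: float = PSD_FLOOR, max_iter: int = 60) -> LdMatrix:
    """Repair an indefinite correlation matrix to PSD with unit diagonal.

    Eigenvalues below the floor are raised, the matrix is rescaled back to a
    correlation matrix, and the two steps repeat until the smallest eigenvalue
    is at least ``psd_floor``.  A matrix already satisfying that is returned
    unchanged, which makes the operation exactly idempotent.
    """
    a = ld.r
    if float(np.linalg.eigvalsh(a)[0]) >= psd_floor:
        return ld
    for _ in range(max_iter):
        w, v = np.linalg.eigh(a)
        # clip above the target so the diagonal rescale cannot drop back below it
        w = np.maximum(w, 2.0 * psd_floor)
        a = (v * w) @ v.T
        d = np.sqrt(np.diag(a))
        a = a / np.outer(d, d)
        a = (a + a.T) / 2.0
        np.fill_diagonal(a, 1.0)
        if float(np.linalg.eigvalsh(a)[0]) >= psd_floor:
            break
    return LdMatrix(snp_ids=ld.snp_ids, r=a)
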