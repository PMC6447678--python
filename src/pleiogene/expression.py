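"""Two-group differential-expression validation on log2 expression.

For each gene of interest: logFC = mean(case) − mean(control) on the log2
scale, an unequal-variance (Welch) two-sample test for the p-value, and a
Bonferroni threshold of 0.05 divided by the number of genes actually tested.
Genes requested but absent from the matrix become explicit "untested" records
rather than errors, so a validation panel can report blanks.
"""
from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .io import ExpressionMatrix
from .results import DiffExprResult


def diff_expression(
    expr: ExpressionMatrix,
    genes_of_interest: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> List[DiffExprResult]:
    """Welch-test every requested gene (default: all genes in the matrix).

    The significance cut is ``alpha / n_tested`` (strict <), with n_tested the
    number of requested genes present in the matrix.
    """
    case_cols = expr.group_samples("case")
    ctrl_cols = expr.group_samples("control")
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValidationError("each group needs at least 2 samples")
    requested = (
        list(genes_of_interest)
        if genes_of_interest is not None
        else list(expr.values.index)
    )
    present = [g for g in requested if g in expr.values.index]
    n_tested = len(present)
    threshold = alpha / n_tested if n_tested else math.nan

    out: List[DiffExprResult] = []
    for g in requested:
        if g not in expr.values.index:
            out.append(
                DiffExprResult(
                    gene_id=g,
                    logFC=math.nan,
                    t_statistic=math.nan,
                    p=math.nan,
                    significant=False,
                    tested=False,
                )
            )
            continue
        case = expr.values.loc[g, case_cols].to_numpy(dtype=float)
        ctrl = expr.values.loc[g, ctrl_cols].to_numpy(dtype=float)
        logfc = float(case.mean() - ctrl.mean())
        t, p = sps.ttest_ind(case, ctrl, equal_var=False)
        if not np.isfinite(p):  # both groups constant
            t, p = 0.0, 1.0
        out.append(
            DiffExprResult(
                gene_id=g,
                logFC=logfc,
                t_statistic=float(t),
                p=float(p),
                significant=bool(p < threshold),
            )
        )
    return out


def direction_consistency(
    results_by_dataset: Dict[str, Sequence[DiffExprResult]],
) -> pd.DataFrame:
    """Cross-dataset sign agreement of significant log fold changes.

    Per gene: ``consistent-decrease`` / ``consistent-increase`` when it is
    significant in at least two datasets and every significant logFC shares
    the sign; ``inconsistent`` when significant calls disagree in sign;
    ``not-evaluable`` with fewer than two significant calls.
    """
    genes: List[str] = []
    for results in results_by_dataset.values():
        for r in results:
            if r.gene_id not in genes:
                genes.append(r.gene_id)
    rows = []
    for g in genes:
        sig_fc = [
            r.logFC
            for results in results_by_dataset.values()
            for r in results
            if r.gene_id == g and r.tested and r.significant
        ]
        if len(sig_fc) < 2:
            status = "not-evaluable"
        elif all(fc < 0 for fc in sig_fc):
            status = "consistent-decrease"
        elif all(fc > 0 for fc in sig_fc):
            status = "consistent-increase"
        else:
            status = "inconsistent"
        rows.append(
            {"gene_id": g, "n_significant": len(sig_fc), "status": status}
        )
    return pd.DataFrame(rows, columns=["gene_id", "n_significant", "status"])
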