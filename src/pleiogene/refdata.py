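"""Bundled reference table of published cross-phenotype candidate genes.

Eighteen gene-level records from a published ischemic-stroke / Parkinson's
disease cross-phenotype analysis: nine genes per gene-based method (the
simulation test and the correlated Fisher set test), each with the two
per-disease gene p-values and the published Fisher meta-analysis columns.
Used as a regression fixture: recomputing the meta χ² and meta p from the
per-disease p-values must reproduce the published columns at their printed
precision, and intersecting the two significant sets must recover the five
jointly significant genes.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd


def load_reference_candidates() -> pd.DataFrame:
    """Columns: method, chrom, gene, p_is, p_pd, chi2, meta_p.

    ``method`` is ``vegas`` or ``setscreen``; ``chi2``/``meta_p`` are the
    published meta-analysis values; n_candidates per method were 75 (vegas)
    and 33 (setscreen).
    """
    with resources.files("pleiogene").joinpath("data/is_pd_candidates.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str})


#: candidate-set sizes the published Bonferroni thresholds were based on
N_CANDIDATES = {"vegas": 75, "setscreen": 33}

#: genome-wide testable gene counts per phenotype under the simulation test
N_TESTABLE_GENES = {"is": 20946, "pd": 19858}
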