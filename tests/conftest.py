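import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pleiogene.io import ReferencePanel, SummaryStats

settings.register_profile(
    "pleiogene",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("pleiogene")


def make_panel(dosages, snp_ids=None, chrom=None, pos=None) -> ReferencePanel:
    """Reference panel from a raw samples × variants dosage array."""
    dosages = np.asarray(dosages, dtype=float)
    n, k = dosages.shape
    snp_ids = snp_ids or [f"rs{i}" for i in range(k)]
    return ReferencePanel(
        sample_ids=[f"S{i}" for i in range(n)],
        snp_ids=list(snp_ids),
        dosages=dosages,
        chrom=np.array(chrom) if chrom is not None else None,
        pos=np.array(pos, dtype=np.int64) if pos is not None else None,
    )


def make_stats(snps, positions, pvals, chrom="1", phenotype="pheno") -> SummaryStats:
    return SummaryStats.from_frame(
        pd.DataFrame(
            {"snp": snps, "chrom": [chrom] * len(snps), "pos": positions, "p": pvals}
        ),
        phenotype=phenotype,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
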