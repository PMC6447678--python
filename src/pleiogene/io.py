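"""Readers, writers and validated containers for every table the pipeline touches.

Formats are deliberately plain: tab-separated summary statistics with a
configurable column map, BED4 or a 1-based gene table for annotation, VCF (via
cyvcf2) or a dosage TSV for the LD reference panel, and a genes × samples
expression TSV with a sidecar group table.  Coordinates are 1-based inclusive
internally; BED input is converted from 0-based half-open on read.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger("pleiogene")

#: p-values at or below zero are raised to this floor so that -2 ln p is finite.
P_FLOOR = 1e-300

#: columns formatted in scientific notation (full precision, round-trip exact).
_P_COLUMNS = {"p", "p_value", "meta_p", "p_pheno1", "p_pheno2"}

DEFAULT_SUMMARY_COLUMNS = {"snp": "snp", "chr": "chr", "bp": "bp", "p": "p"}


def normalize_chrom(label: object) -> str:
    """Normalize a chromosome label: 'chr1', 'Chr1' and '1' all map to '1'."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s


def _chrom_sort_key(label: str):
    # numeric chromosomes before named ones (X, Y, MT ...), both in order
    try:
        return (0, int(label), "")
    except ValueError:
        return (1, 0, label)


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class SummaryStats:
    """One phenotype's per-SNP GWAS association results.

    ``table`` holds columns ``snp, chrom, pos, p`` (plus optional ``a1``,
    ``beta``), sorted by (chromosome, position), with unique SNP ids and every
    p in (0, 1].
    """

    phenotype: str
    table: pd.DataFrame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, phenotype: str = "") -> "SummaryStats":
        df = frame.copy()
        required = ["snp", "chrom", "pos", "p"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"summary stats missing columns: {missing}")
        dup = df["snp"][df["snp"].duplicated()]
        if len(dup):
            raise ValidationError(
                f"duplicate SNP ids in phenotype {phenotype!r}: {sorted(set(dup))[:5]}"
            )
        df["chrom"] = df["chrom"].map(normalize_chrom)
        df["pos"] = df["pos"].astype(np.int64)
        df["p"] = df["p"].astype(float)
        bad = df[(df["p"] <= 0) | (df["p"] > 1)]
        if len(bad):
            raise ValidationError(f"{len(bad)} p-values outside (0,1]")
        key = df["chrom"].map(_chrom_sort_key)
        df = (
            df.assign(_key=key)
            .sort_values(["_key", "pos"], kind="mergesort")
            .drop(columns="_key")
            .reset_index(drop=True)
        )
        return cls(phenotype=phenotype, table=df)

    def p_for(self, snp_ids: Sequence[str]) -> np.ndarray:
        """p-values for the given SNP ids, in the given order."""
        lookup = pd.Series(self.table["p"].values, index=self.table["snp"].values)
        missing = [s for s in snp_ids if s not in lookup.index]
        if missing:
            raise ValidationError(f"SNPs absent from summary stats: {missing[:5]}")
        return lookup.loc[list(snp_ids)].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class GeneModel:
    """A gene interval, 1-based inclusive on both ends."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )


@dataclass
class ReferencePanel:
    """Genotype dosages (samples × variants, each value in [0, 2]) used for LD.

    ``chrom``/``pos`` may be None for dosage-TSV input, where positions come
    from the summary statistics instead.  ``monomorphic`` flags zero-variance
    columns, which carry no LD information and are excluded from testing.
    """

    sample_ids: List[str]
    snp_ids: List[str]
    dosages: np.ndarray
    chrom: Optional[np.ndarray] = None
    pos: Optional[np.ndarray] = None
    monomorphic: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2 or self.dosages.shape != (
            len(self.sample_ids),
            len(self.snp_ids),
        ):
            raise ValidationError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} variants"
            )
        if np.isnan(self.dosages).any():
            raise ValidationError("dosage matrix contains missing values after load")
        if (self.dosages < 0).any() or (self.dosages > 2).any():
            raise ValidationError("dosages outside [0, 2]")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValidationError("duplicate variant ids in reference panel")
        if self.monomorphic is None:
            self.monomorphic = self.dosages.std(axis=0) == 0.0

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def index_of(self, snp_ids: Sequence[str]) -> np.ndarray:
        order = {s: i for i, s in enumerate(self.snp_ids)}
        missing = [s for s in snp_ids if s not in order]
        if missing:
            raise ValidationError(f"variants absent from panel: {missing[:5]}")
        return np.array([order[s] for s in snp_ids], dtype=int)

    def columns(self, snp_ids: Sequence[str]) -> np.ndarray:
        return self.dosages[:, self.index_of(snp_ids)]


@dataclass
class ExpressionMatrix:
    """Gene × sample log2-scale expression with case/control labels."""

    values: pd.DataFrame  # index gene_id, columns sample ids
    groups: pd.Series  # index sample ids, values "case" / "control"

    def __post_init__(self):
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()]
            raise ValidationError(f"duplicate gene ids in expression: {list(dups[:5])}")
        if set(self.groups.index) != set(self.values.columns):
            raise ValidationError("group labels do not cover the sample columns")
        counts = self.groups.value_counts()
        for g in ("case", "control"):
            if counts.get(g, 0) < 2:
                raise ValidationError(f"group {g!r} has fewer than 2 samples")

    def group_samples(self, group: str) -> List[str]:
        return list(self.groups.index[self.groups == group])


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_summary_stats(
    path: Union[str, Path],
    columns: Optional[Dict[str, str]] = None,
    phenotype: str = "",
    p_floor: float = P_FLOOR,
) -> SummaryStats:
    """Read a per-SNP summary-statistics TSV.

    ``columns`` maps logical names {snp, chr, bp, p[, a1, beta]} to the file's
    header names.  p ≤ 0 is clipped to ``p_floor``; rows with p > 1 or a
    non-numeric p are dropped and counted in the load report.
    """
    colmap = dict(DEFAULT_SUMMARY_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [v for k, v in colmap.items() if k in ("snp", "chr", "bp", "p") and v not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    p_probe = pd.to_numeric(df[colmap["p"]], errors="coerce")
    pos_probe = pd.to_numeric(df[colmap["bp"]], errors="coerce")
    out = pd.DataFrame(
        {
            "snp": df[colmap["snp"]].astype(str),
            "chrom": df[colmap["chr"]],
            "pos": pos_probe,
            "p": p_probe,
        }
    )
    for opt in ("a1", "beta"):
        if opt in colmap and colmap[opt] in df.columns:
            out[opt] = df[colmap[opt]]
    n_in = len(out)
    bad_rows = out["p"].isna() | out["pos"].isna() | (out["p"] > 1)
    if bad_rows.any():
        out = out[~bad_rows]
    # to_numeric is not correctly rounded; reparse kept values exactly
    out["p"] = df[colmap["p"]].loc[out.index].astype(float)
    out.loc[out["p"] <= 0, "p"] = p_floor
    n_dropped = n_in - len(out)
    logger.info(
        "read_summary_stats(%s): kept %d rows, dropped %d", path, len(out), n_dropped
    )
    return SummaryStats.from_frame(out, phenotype=phenotype or str(path))


def read_gene_annotation(path: Union[str, Path], format: str = "bed") -> List[GeneModel]:
    """Read gene intervals from BED4 (0-based half-open) or a 1-based gene table.

    Gene-table columns: gene, chr, start, end (tab-separated, with header).
    """
    genes: List[GeneModel] = []
    if format == "bed":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "gene_id"], usecols=[0, 1, 2, 3],
        )
        for row in df.itertuples(index=False):
            genes.append(
                GeneModel(
                    gene_id=str(row.gene_id),
                    chrom=normalize_chrom(row.chrom),
                    start=int(row.start) + 1,
                    end=int(row.end),
                )
            )
    elif format == "gene-table":
        df = pd.read_csv(path, sep="\t")
        required = ["gene", "chr", "start", "end"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: gene table missing columns {missing}")
        for row in df.itertuples(index=False):
            genes.append(
                GeneModel(
                    gene_id=str(row.gene),
                    chrom=normalize_chrom(row.chr),
                    start=int(row.start),
                    end=int(row.end),
                )
            )
    else:
        raise FormatError(f"unknown gene annotation format: {format!r}")
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate gene ids: {dups[:5]}")
    return genes


def _read_vcf_panel(path: Union[str, Path]) -> ReferencePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, cols = [], [], [], []
    for v in vcf:
        dos = np.full(len(samples), np.nan)
        for i, gt in enumerate(v.genotypes):
            a = [x for x in gt[:2] if x >= 0]
            if len(a) == 2:
                dos[i] = float(a[0] > 0) + float(a[1] > 0)
        if np.isnan(dos).all():
            raise ValidationError(f"variant {v.ID or v.POS}: all genotypes missing")
        mean = np.nanmean(dos)
        dos[np.isnan(dos)] = mean
        ids.append(v.ID if v.ID else f"{v.CHROM}:{v.POS}")
        chroms.append(normalize_chrom(v.CHROM))
        poss.append(v.POS)
        cols.append(dos)
    if not cols:
        raise FormatError(f"{path}: no variants")
    return ReferencePanel(
        sample_ids=samples,
        snp_ids=ids,
        dosages=np.column_stack(cols),
        chrom=np.array(chroms),
        pos=np.array(poss, dtype=np.int64),
    )


def _read_dosage_panel(path: Union[str, Path]) -> ReferencePanel:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "sample":
        raise FormatError(f"{path}: first dosage column must be 'sample'")
    samples = df["sample"].astype(str).tolist()
    snp_ids = list(df.columns[1:])
    mat = df.iloc[:, 1:].to_numpy(dtype=float)
    all_missing = np.isnan(mat).all(axis=0)
    if all_missing.any():
        raise ValidationError(
            f"variants with all dosages missing: {list(np.array(snp_ids)[all_missing][:5])}"
        )
    if np.isnan(mat).any():
        means = np.nanmean(mat, axis=0)
        idx = np.where(np.isnan(mat))
        mat[idx] = means[idx[1]]
    if (mat < 0).any() or (mat > 2).any():
        raise ValidationError(f"{path}: dosages outside [0, 2]")
    return ReferencePanel(sample_ids=samples, snp_ids=snp_ids, dosages=mat)


def read_reference_panel(path: Union[str, Path], format: str = "vcf") -> ReferencePanel:
    """Read a reference genotype panel from VCF (GT field) or a dosage TSV.

    Missing genotypes are mean-imputed per variant; an all-missing variant is
    an error.  The dosage TSV is samples × variants with a leading ``sample``
    column and SNP ids as the remaining header.
    """
    if format == "vcf":
        return _read_vcf_panel(path)
    if format == "dosage":
        return _read_dosage_panel(path)
    raise FormatError(f"unknown panel format: {format!r}")


def read_expression(
    values_path: Union[str, Path], groups_path: Union[str, Path]
) -> ExpressionMatrix:
    """Read a genes × samples log2 expression TSV plus a {sample, group} sidecar."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    groups_df = pd.read_csv(groups_path, sep="\t")
    if not {"sample", "group"} <= set(groups_df.columns):
        raise FormatError(f"{groups_path}: needs columns sample, group")
    groups = pd.Series(
        groups_df["group"].astype(str).values, index=groups_df["sample"].astype(str)
    )
    values.columns = values.columns.astype(str)
    return ExpressionMatrix(values=values, groups=groups)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_results(table, path: Union[str, Path]) -> None:
    """Write a result table as TSV with deterministic columns.

    Accepts a DataFrame or a list of result dataclasses.  p-value columns are
    written in full-precision scientific notation so a round-trip read returns
    identical floats.
    """
    from .results import to_frame

    df = table if isinstance(table, pd.DataFrame) else to_frame(table)
    df = df.copy()
    for col in df.columns:
        if col in _P_COLUMNS and len(df):
            df[col] = [f"{float(v):.17e}" for v in df[col]]
    df.to_csv(path, sep="\t", index=False)


def read_results(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_summary_stats(stats: SummaryStats, path: Union[str, Path]) -> None:
    df = stats.table.rename(columns={"snp": "snp", "chrom": "chr", "pos": "bp"})
    df = df.copy()
    df["p"] = [f"{float(v):.17e}" for v in df["p"]]
    df.to_csv(path, sep="\t", index=False)


def write_gene_table(genes: Sequence[GeneModel], path: Union[str, Path]) -> None:
    pd.DataFrame(
        {
            "gene": [g.gene_id for g in genes],
            "chr": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


def write_dosage_panel(panel: ReferencePanel, path: Union[str, Path]) -> None:
    df = pd.DataFrame(panel.dosages, columns=panel.snp_ids)
    df.insert(0, "sample", panel.sample_ids)
    df.to_csv(path, sep="\t", index=False)


def write_expression(
    expr: ExpressionMatrix,
    values_path: Union[str, Path],
    groups_path: Union[str, Path],
) -> None:
    expr.values.to_csv(values_path, sep="\t", index_label="gene")
    pd.DataFrame({"sample": expr.groups.index, "group": expr.groups.values}).to_csv(
        groups_path, sep="\t", index=False
    )
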