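"""End-to-end orchestration: simulate/load → assign → both gene tests on both
phenotypes → cross-phenotype meta per method → intersect → differential
expression, from one structured configuration, with a run manifest.

Every stage's output lands in the run directory as TSV; the manifest (written
last) snapshots the config, library versions, per-file SHA-256 digests and
the gene-count funnel, and reruns with the same config and seed are
bit-identical.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .expression import diff_expression, direction_consistency
from .genes import assign_snps_to_genes, assignment_report, assignment_table
from .io import (
    read_expression,
    read_gene_annotation,
    read_reference_panel,
    read_summary_stats,
    write_dosage_panel,
    write_expression,
    write_gene_table,
    write_results,
    write_summary_stats,
)
from .meta import cross_phenotype_meta, intersect_methods, significant_genes
from .results import DiffExprResult, empty_frame, to_frame
from .setscreen import SetScreenConfig, setscreen_scan
from .simulate import (
    CausalGene,
    ExpressionSpec,
    SimulationConfig,
    demo_simulation_config,
    simulate_dataset,
)
from .vegas import VegasConfig, vegas_scan

logger = logging.getLogger("pleiogene")


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    config: dict
    seed: int
    versions: Dict[str, str]
    file_digests: Dict[str, str] = field(default_factory=dict)
    counts: Dict[str, dict] = field(default_factory=dict)
    shared_genes: List[str] = field(default_factory=list)

    def validate(self) -> None:
        """Funnel counts must shrink monotonically along the pipeline."""
        for method, c in self.counts.items():
            if not isinstance(c, dict) or "candidates" not in c:
                continue
            testable = min(c["testable_pheno1"], c["testable_pheno2"])
            if not (
                c["candidates"] <= testable
                and c["significant"] <= c["candidates"]
                and self.counts.get("intersected", 0) <= c["significant"]
            ):
                raise ConfigError(f"inconsistent count funnel for {method}: {c}")

    def write(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _simulation_config_from_dict(spec: dict, seed: int) -> SimulationConfig:
    if spec.get("demo"):
        return demo_simulation_config(seed=seed)
    causal = [
        CausalGene(
            gene_id=c["gene_id"],
            phenotypes=tuple(int(x) for x in c["phenotypes"]),
            delta=float(c["delta"]),
        )
        for c in spec.get("causal", [])
    ]
    expression = [
        ExpressionSpec(
            name=e.get("name", f"dataset{i + 1}"),
            n_case=int(e.get("n_case", 39)),
            n_control=int(e.get("n_control", 24)),
            baseline=float(e.get("baseline", 8.0)),
            noise_sd=float(e.get("noise_sd", 0.5)),
            planted_logfc={str(k): float(v) for k, v in e.get("planted_logfc", {}).items()},
        )
        for i, e in enumerate(spec.get("expression", []))
    ]
    kwargs = {
        k: spec[k]
        for k in (
            "n_samples_panel",
            "n_genes",
            "within_block_rho",
            "snp_spacing_bp",
            "gene_gap_bp",
        )
        if k in spec
    }
    if "snps_per_gene" in spec:
        kwargs["snps_per_gene"] = tuple(spec["snps_per_gene"])
    if "maf_range" in spec:
        kwargs["maf_range"] = tuple(spec["maf_range"])
    return SimulationConfig(seed=seed, causal=causal, expression=expression, **kwargs)


def demo_config(seed: int = 17, outdir: Union[str, Path] = "runs/demo") -> dict:
    """The bundled demo: simulated pleiotropy dataset through the full funnel."""
    return {
        "seed": seed,
        "outdir": str(outdir),
        "simulate": {"demo": True},
        "assign": {"mode": "plain", "pad_kb": 0},
        "vegas": {"stages": [1_000, 10_000, 100_000]},
        "setscreen": {"rho": "abs"},
        "crossmeta": {"alpha_nominal": 0.05, "n_phenotypes": 2},
        "diffexpr": {"enabled": True},
    }


def _validate_config(cfg: dict) -> None:
    if "seed" not in cfg or "outdir" not in cfg:
        raise ConfigError("config requires 'seed' and 'outdir'")
    if ("simulate" in cfg) == ("inputs" in cfg):
        raise ConfigError("config needs exactly one of 'simulate' or 'inputs'")
    mode = cfg.get("assign", {}).get("mode", "plain")
    if mode not in ("plain", "ldbin"):
        raise ConfigError(f"unknown assignment mode {mode!r}")
    if mode == "ldbin" and "inputs" in cfg and not cfg["inputs"].get("panel"):
        raise ConfigError("ldbin assignment requires a reference panel")
    if "inputs" in cfg:
        inputs = cfg["inputs"]
        for key in ("summary1", "summary2", "genes", "panel"):
            if key in inputs and not Path(inputs[key]).exists():
                raise ConfigError(f"input file for {key!r} not found: {inputs[key]}")


def run_pipeline(config: Union[dict, str, Path]) -> RunManifest:
    """Run the whole analysis; returns the manifest (also written to outdir)."""
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    _validate_config(config)
    seed = int(config["seed"])
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}

    # ---- stage 1: data -----------------------------------------------------
    truth = None
    if "simulate" in config:
        sim_cfg = _simulation_config_from_dict(config["simulate"], seed)
        ds = simulate_dataset(sim_cfg)
        panel, genes, stats1, stats2, truth = (
            ds.panel,
            ds.genes,
            ds.stats1,
            ds.stats2,
            ds.truth,
        )
        expression = ds.expression
        write_summary_stats(stats1, outdir / "summary_pheno1.tsv")
        write_summary_stats(stats2, outdir / "summary_pheno2.tsv")
        write_gene_table(genes, outdir / "genes.tsv")
        write_dosage_panel(panel, outdir / "panel.tsv")
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        for name, expr in expression.items():
            write_expression(
                expr, outdir / f"expr_{name}.tsv", outdir / f"expr_{name}_groups.tsv"
            )
        for f in outdir.glob("*.tsv"):
            written[f.name] = f
    else:
        inputs = config["inputs"]
        stats1 = read_summary_stats(
            inputs["summary1"], inputs.get("summary1_columns"), phenotype="phenotype1"
        )
        stats2 = read_summary_stats(
            inputs["summary2"], inputs.get("summary2_columns"), phenotype="phenotype2"
        )
        genes = read_gene_annotation(
            inputs["genes"], inputs.get("genes_format", "gene-table")
        )
        panel = read_reference_panel(
            inputs["panel"], inputs.get("panel_format", "dosage")
        )
        expression = {
            e["name"]: read_expression(e["values"], e["groups"])
            for e in inputs.get("expression", [])
        }

    # ---- stage 2: assignment ----------------------------------------------
    acfg = config.get("assign", {})
    assign_kwargs = dict(
        mode=acfg.get("mode", "plain"),
        pad_kb=int(acfg.get("pad_kb", 0)),
        ld_window_kb=int(acfg.get("ld_window_kb", 1000)),
        r2_threshold=float(acfg.get("r2_threshold", 0.8)),
    )
    assign1 = assign_snps_to_genes(stats1, genes, panel, **assign_kwargs)
    assign2 = assign_snps_to_genes(stats2, genes, panel, **assign_kwargs)
    assignment_table(assign1.testable).to_csv(
        outdir / "assignment_pheno1.tsv", sep="\t", index=False
    )
    written["assignment_pheno1.tsv"] = outdir / "assignment_pheno1.tsv"
    logger.info("assignment: %s / %s", assignment_report(assign1), assignment_report(assign2))

    # ---- stage 3: gene tests ----------------------------------------------
    vcfg_d = config.get("vegas", {})
    vcfg = VegasConfig(
        seed=seed,
        stages=tuple(vcfg_d.get("stages", VegasConfig.stages)),
        min_exceed=int(vcfg_d.get("min_exceed", 100)),
        top_k=vcfg_d.get("top_k"),
    )
    scfg_d = config.get("setscreen", {})
    scfg = SetScreenConfig(
        rho=scfg_d.get("rho", "abs"),
        strict_printed_sigma=bool(scfg_d.get("strict_printed_sigma", False)),
    )
    scans = {
        "vegas": (vegas_scan(stats1, assign1, panel, vcfg), vegas_scan(stats2, assign2, panel, vcfg)),
        "setscreen": (
            setscreen_scan(stats1, assign1, panel, scfg),
            setscreen_scan(stats2, assign2, panel, scfg),
        ),
    }
    for method, (r1, r2) in scans.items():
        for pheno, res in (("pheno1", r1), ("pheno2", r2)):
            path = outdir / f"{method}_{pheno}.tsv"
            write_results(res, path)
            written[path.name] = path

    # ---- stage 4: cross-phenotype meta and intersection --------------------
    mcfg = config.get("crossmeta", {})
    alpha = float(mcfg.get("alpha_nominal", 0.05))
    n_phenos = int(mcfg.get("n_phenotypes", 2))
    counts: Dict[str, dict] = {}
    sig_sets: Dict[str, List[str]] = {}
    for method, (r1, r2) in scans.items():
        meta = cross_phenotype_meta(r1, r2, alpha_nominal=alpha, n_phenotypes=n_phenos)
        path = outdir / f"meta_{method}.tsv"
        write_results(to_frame(meta), path)
        written[path.name] = path
        sig_sets[method] = significant_genes(meta)
        counts[method] = {
            "testable_pheno1": len(r1),
            "testable_pheno2": len(r2),
            "candidates": len(meta),
            "significant": len(sig_sets[method]),
        }
        logger.info(
            "%s funnel: %d candidates -> %d significant", method,
            len(meta), len(sig_sets[method]),
        )
    shared = intersect_methods(sig_sets["vegas"], sig_sets["setscreen"])
    counts["intersected"] = len(shared)
    pd.DataFrame({"gene_id": shared}).to_csv(
        outdir / "shared_genes.tsv", sep="\t", index=False
    )
    written["shared_genes.tsv"] = outdir / "shared_genes.tsv"

    # ---- stage 5: expression validation ------------------------------------
    if config.get("diffexpr", {}).get("enabled", True) and expression:
        de_by_dataset = {}
        for name, expr in expression.items():
            de = diff_expression(expr, genes_of_interest=shared) if shared else []
            de_by_dataset[name] = de
            path = outdir / f"diffexpr_{name}.tsv"
            write_results(to_frame(de) if de else empty_frame(DiffExprResult), path)
            written[path.name] = path
        if de_by_dataset:
            consistency = direction_consistency(de_by_dataset)
            consistency.to_csv(outdir / "direction_consistency.tsv", sep="\t", index=False)
            written["direction_consistency.tsv"] = outdir / "direction_consistency.tsv"

    # ---- manifest -----------------------------------------------------------
    import numpy as np
    import scipy

    manifest = RunManifest(
        config=config,
        seed=seed,
        versions={
            "pleiogene": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        file_digests={name: _sha256(p) for name, p in sorted(written.items())},
        counts=counts,
        shared_genes=shared,
    )
    manifest.validate()
    manifest.write(outdir / "manifest.json")
    return manifest
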