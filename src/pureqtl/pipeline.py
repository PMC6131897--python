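"""End-to-end workflow: simulate -> preprocess -> map -> evaluate.

A :class:`RunConfig` (typically loaded from YAML) names the inputs, thresholds
and stages; :func:`run_pipeline` executes them, writes every artifact as a
headered TSV and records a manifest (version, seed, config hash, outputs) so a
rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io
from .evaluate import classify_performance
from .models import run_scan
from .preprocess import (
    compute_expression_factors,
    compute_genotype_pcs,
    filter_genes_expressed,
    filter_variants_maf,
    quantile_normalize_and_int,
)
from .simulate import SimConfig, add_purity_noise, simulate_cohort

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a pipeline run.

    Either ``simulate`` holds SimConfig fields (a fresh cohort is generated)
    or the ``*_path`` entries point at existing TSV inputs.  Thresholds
    mirror the standard cis-eQTL defaults: BH FDR 0.05, MAF >= 0.05, genes
    expressed in >= 75% of samples, 500-kb cis window.
    """

    out_dir: str = "pureqtl_run"
    seed: int = 0
    models: tuple[str, ...] = ("conventional", "interaction")
    simulate: dict | None = None
    expression_path: str | None = None
    genotype_path: str | None = None
    pairs_path: str | None = None
    purity_path: str | None = None
    covariates_path: str | None = None
    truth_path: str | None = None
    preprocess: bool = False
    fdr_threshold: float = 0.05
    maf_min: float = 0.05
    expressed_fraction: float = 0.75
    cis_window: int = 500_000
    n_genotype_pcs: int = 0
    n_expression_factors: int = 0
    purity_noise_sd: float | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "models" in data:
            data["models"] = tuple(data["models"])
        return cls(**data)

    def validate(self) -> None:
        for name, value, lo, hi in [
            ("fdr_threshold", self.fdr_threshold, 0, 1),
            ("maf_min", self.maf_min, 0, 0.5),
            ("expressed_fraction", self.expressed_fraction, 0, 1),
        ]:
            if not lo <= value <= hi:
                raise ValueError(f"{name}={value} outside [{lo}, {hi}]")
        if self.cis_window <= 0:
            raise ValueError("cis_window must be positive")
        for m in self.models:
            if m not in ("conventional", "interaction"):
                raise ValueError(f"unknown model '{m}'")
        if self.simulate is None:
            if self.expression_path is None or self.genotype_path is None or self.pairs_path is None:
                raise ValueError("without a simulate block, expression/genotype/pairs paths are required")
            if "interaction" in self.models and self.purity_path is None:
                raise ValueError("interaction model requires a purity file")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def analytic_dict(self) -> dict:
        """Config fields that determine the results (excludes output paths)."""
        d = self.as_dict()
        d.pop("out_dir")
        d.pop("log_level")
        return d


def _load_inputs(config: RunConfig, out: Path, meta: dict, outputs: list[str]):
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        sim = SimConfig(**sim_kwargs)
        cohort = simulate_cohort(sim)
        for name, writer, obj in [
            ("bulk_expression.tsv", io.write_expression, cohort.bulk),
            ("cancer_expression.tsv", io.write_expression, cohort.cancer),
            ("normal_expression.tsv", io.write_expression, cohort.normal),
            ("genotypes.tsv", io.write_genotypes, cohort.genotypes),
            ("purity.tsv", io.write_purity, cohort.purity),
            ("truth.tsv", io.write_truth, cohort.truth),
            ("pairs.tsv", io.write_table, cohort.pairs),
        ]:
            writer(obj, out / name, meta)
            outputs.append(name)
        return cohort.bulk, cohort.genotypes, cohort.pairs, cohort.purity, cohort.truth
    expr = io.read_expression(config.expression_path)
    geno = io.read_genotypes(config.genotype_path)
    pairs = io.read_table(config.pairs_path)
    purity = io.read_purity(config.purity_path) if config.purity_path else None
    truth = io.read_truth(config.truth_path) if config.truth_path else None
    return expr, geno, pairs, purity, truth


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns artifact paths and summaries."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config_hash": io.config_hash(config.analytic_dict())}
    outputs: list[str] = []

    expr, geno, pairs, purity, truth = _load_inputs(config, out, meta, outputs)

    if config.preprocess:
        logger.info("preprocess: normalize + filters")
        expr = filter_genes_expressed(expr, config.expressed_fraction)
        expr = quantile_normalize_and_int(expr)
        geno = filter_variants_maf(geno, config.maf_min)
        pairs = pairs[
            pairs["gene_id"].isin(expr.columns) & pairs["variant_id"].isin(geno.columns)
        ].reset_index(drop=True)

    covars = None
    if config.covariates_path:
        covars = io.read_table(config.covariates_path).set_index("sample_id")
    blocks = [] if covars is None else [covars]
    if config.n_genotype_pcs:
        blocks.append(compute_genotype_pcs(geno, config.n_genotype_pcs))
    if config.n_expression_factors:
        known = pd.concat(blocks, axis=1) if blocks else None
        blocks.append(compute_expression_factors(expr, known, config.n_expression_factors))
    if blocks:
        covars = pd.concat(blocks, axis=1)
        io.write_table(covars.reset_index(names="sample_id"), out / "covariates.tsv", meta)
        outputs.append("covariates.tsv")

    measured_purity = purity
    if purity is not None and config.purity_noise_sd:
        measured_purity = add_purity_noise(purity, config.purity_noise_sd, config.seed)

    summaries = {}
    for model in config.models:
        logger.info("map: %s model over %d pairs", model, len(pairs))
        res = run_scan(
            expr, geno, pairs,
            purity=measured_purity if model == "interaction" else None,
            covars=covars, model=model,
        )
        name = f"results_{model}.tsv"
        io.write_results(res, out / name, meta)
        outputs.append(name)
        if truth is not None:
            perf = classify_performance(res, truth, config.fdr_threshold)
            summaries[model] = perf.as_dict()
    if summaries:
        perf_df = pd.DataFrame(summaries.values())
        io.write_table(perf_df, out / "performance.tsv", meta)
        outputs.append("performance.tsv")

    io.write_manifest(out / "manifest.json", config.as_dict(), config.seed, outputs)
    outputs.append("manifest.json")
    return {"out_dir": str(out), "outputs": outputs, "performance": summaries}
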