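"""End-to-end pipeline: adjustment -> multi-analysis -> integration.

`run_pipeline` reads a configuration (path or :class:`RunConfig`), loads
and cleans the data, runs every selected engine, picks the best
gene-action model per engine where several were scanned, and writes one
report folder per trait (``out-<name>/<trait>/``).  Results are
deterministic and independent of engine execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .association import ENGINE_PRESETS, AssociationTable, run_engine
from .exceptions import DataError
from .integration import ConsensusReport, build_consensus_report, render_report
from .io import (GenotypeMatrix, PhenotypeTable, RunConfig,
                 normalize_genotype_chromosomes, read_config, read_genotype,
                 read_phenotype)
from .model_selection import score_models, scores_frame, select_best_model
from .qc import QCReport, apply_qc

logger = logging.getLogger(__name__)

__all__ = ["TraitResult", "PipelineResult", "run_pipeline"]


@dataclass
class TraitResult:
    trait: str
    tables: dict[str, list[AssociationTable]]   # all tables per engine
    chosen: dict[str, AssociationTable]         # best model per engine
    model_scores: dict[str, pd.DataFrame]
    consensus: ConsensusReport
    qc: QCReport
    out_dir: Path | None


@dataclass
class PipelineResult:
    config: RunConfig
    traits: dict[str, TraitResult]
    out_dir: Path | None


def _analyze_trait(geno: GenotypeMatrix, pheno: PhenotypeTable, trait: str,
                   config: RunConfig, qc_report: QCReport) -> TraitResult:
    y = pheno.trait_vector(trait, geno.samples)
    if np.sum(np.isfinite(y)) < 10:
        raise DataError(f"trait '{trait}' has fewer than 10 observed values")
    all_tables: dict[str, list[AssociationTable]] = {}
    chosen: dict[str, AssociationTable] = {}
    model_scores: dict[str, pd.DataFrame] = {}
    for engine in config.engines:  # order never affects any output table
        tables = run_engine(ENGINE_PRESETS[engine], geno, y, config)
        if not tables:
            logger.warning("engine %s produced no tables for trait %s", engine, trait)
            continue
        all_tables[engine] = tables
        if len(tables) > 1:
            scores, _ = score_models(tables, config.n_best)
            model_scores[engine] = scores_frame(scores)
        chosen[engine] = select_best_model(tables, config.n_best)
    if not chosen:
        raise DataError(f"no engine produced results for trait '{trait}'")
    consensus = build_consensus_report(
        chosen, geno, y, trait, config.n_best, config.ld_r2,
        model_scores=model_scores)
    return TraitResult(trait=trait, tables=all_tables, chosen=chosen,
                       model_scores=model_scores, consensus=consensus,
                       qc=qc_report, out_dir=None)


def run_pipeline(config: RunConfig | str | Path, out_dir: str | Path | None = None,
                 write_report: bool = True) -> PipelineResult:
    """Run the full consensus GWAS pipeline for every trait in the phenotype.

    ``out_dir`` defaults to ``out-<config name>`` next to the
    configuration file (or the working directory for an in-memory
    config).  Each trait gets its own subfolder with the HTML report,
    tables and figures.
    """
    if isinstance(config, (str, Path)):
        config_path = Path(config)
        config = read_config(config_path)
        default_out = config_path.parent / f"out-{config.name}"
    else:
        default_out = Path(f"out-{config.name}")
    logger.info("adjustment stage: reading inputs")
    geno = read_genotype(config.genotype_path, config.genotype_format,
                         config.map_path, config.ploidy)
    geno = normalize_genotype_chromosomes(geno, config.n_chromosomes)
    pheno = read_phenotype(config.phenotype_path)
    geno, pheno, qc_report = apply_qc(geno, pheno, config.filters)
    logger.info("quality control kept %d markers x %d samples",
                geno.n_markers, geno.n_samples)
    out = Path(out_dir) if out_dir is not None else default_out
    traits: dict[str, TraitResult] = {}
    for trait in pheno.trait_names:
        logger.info("multi-analysis stage: trait '%s', engines %s",
                    trait, list(config.engines))
        result = _analyze_trait(geno, pheno, trait, config, qc_report)
        if write_report:
            trait_dir = out / trait
            render_report(result.consensus, qc_report, trait_dir)
            result.out_dir = trait_dir
            logger.info("integration stage: report written to %s", trait_dir)
        traits[trait] = result
    return PipelineResult(config=config, traits=traits,
                          out_dir=out if write_report else None)
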