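"""End-to-end orchestration: load -> impute -> iterate RF -> ensemble +
Boruta per iteration -> consensus + confidence -> report tables.

Defaults reproduce the reference protocol: ntree schedule
(500, 1000, 2000, 3000), k = 40, significance cutoff 0.01, Boruta
max_runs 100 at alpha 0.01, consensus 3-of-4, confidence threshold 0.5.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import boruta as boruta_mod
from . import regression as reg
from .consensus import (
    DEFAULT_CONFIDENCE_THRESHOLD,
    DEFAULT_MIN_METHODS,
    ConsensusReport,
    summarise,
)
from .datamodel import CovariateTable, GenotypeTable, PhenotypeVector, impute_missing
from .io import read_dataset, write_report_tables
from .regression import MethodCall
from .rf_stage import DEFAULT_K, DEFAULT_MTRY_FRACTION, DEFAULT_SCHEDULE, run_iterations

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    input_path: str | None = None
    out_dir: str | None = None
    phenotype_names: list[str] = field(default_factory=list)
    covariate_names: list[str] = field(default_factory=list)
    sample_id_column: str | None = None
    ntree_schedule: tuple[int, ...] = DEFAULT_SCHEDULE
    k: int = DEFAULT_K
    mtry_fraction: float = DEFAULT_MTRY_FRACTION
    significance_cutoff: float = reg.SIGNIFICANCE_CUTOFF
    stepwise_entry_alpha: float = reg.STEPWISE_ENTRY_ALPHA
    cv_folds: int = reg.DEFAULT_CV_FOLDS
    boruta_max_runs: int = boruta_mod.DEFAULT_MAX_RUNS
    boruta_alpha: float = boruta_mod.DEFAULT_ALPHA
    boruta_ntree: int = boruta_mod.DEFAULT_NTREE
    min_methods: int = DEFAULT_MIN_METHODS
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ntree_schedule"] = list(self.ntree_schedule)
        return d


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the stage name attached."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False
    return _Ctx()


def analyse_phenotype(genotypes: GenotypeTable, phenotype: PhenotypeVector,
                      covariates: CovariateTable | None = None,
                      config: PipelineConfig | None = None) -> ConsensusReport:
    """Run all stages for a single phenotype and return the report."""
    config = config or PipelineConfig()
    covariates = covariates if (covariates and covariates.n_covariates) else None
    cov_names = set(covariates.names) if covariates else set()

    root = np.random.SeedSequence(config.seed)
    ss_rf, ss_ens = root.spawn(2)

    with _stage("random_forest"):
        records = run_iterations(
            genotypes, phenotype,
            schedule=tuple(config.ntree_schedule), k=config.k,
            seed=int(ss_rf.generate_state(1)[0] >> 1),
            covariates=covariates, mtry_fraction=config.mtry_fraction,
        )

    calls: list[MethodCall] = []
    y = phenotype.values
    iter_seeds = ss_ens.spawn(len(records))
    for record, it_ss in zip(records, iter_seeds):
        x_top = genotypes.subset_snps(record.top_k).design_matrix()
        names = list(record.top_k)
        if covariates:
            x_top = np.hstack([x_top, covariates.values])
            names = names + list(covariates.names)
        s_lasso, s_boruta = [int(c.generate_state(1)[0] >> 1)
                             for c in it_ss.spawn(2)]
        it = record.iteration_index
        with _stage("stepwise"):
            _, c_step = reg.stepwise_forward(
                x_top, y, names,
                entry_alpha=config.stepwise_entry_alpha,
                cutoff=config.significance_cutoff,
                iteration_index=it, covariate_names=cov_names,
            )
        with _stage("ridge"):
            _, c_ridge = reg.ridge_fit(
                x_top, y, names, cutoff=config.significance_cutoff,
                iteration_index=it, covariate_names=cov_names,
            )
        with _stage("lasso"):
            _, c_lasso = reg.lasso_fit(
                x_top, y, names, n_folds=config.cv_folds, seed=s_lasso,
                cutoff=config.significance_cutoff,
                iteration_index=it, covariate_names=cov_names,
            )
        with _stage("boruta"):
            bres = boruta_mod.run_boruta(
                x_top, y, names,
                max_runs=config.boruta_max_runs, alpha=config.boruta_alpha,
                ntree=config.boruta_ntree, seed=s_boruta,
            )
        c_boruta = [MethodCall(
            method="boruta", snp_id=name, statistic=bres.mean_z[name],
            significant=bres.status[name] == boruta_mod.CONFIRMED,
            iteration_index=it, is_covariate=name in cov_names,
        ) for name in names]
        calls.extend(c_step + c_ridge + c_lasso + c_boruta)
        logger.info(
            "iteration %d (ntree=%d): %%var all=%.2f top-k=%.2f; votes "
            "stepwise=%d ridge=%d lasso=%d boruta=%d",
            it, record.ntree, record.pct_var_all, record.pct_var_topk,
            sum(c.significant for c in c_step),
            sum(c.significant for c in c_ridge),
            sum(c.significant for c in c_lasso),
            sum(c.significant for c in c_boruta),
        )

    with _stage("consensus"):
        report = summarise(
            calls, records, phenotype.name,
            min_methods=config.min_methods,
            threshold=config.confidence_threshold,
            config=config.to_dict(),
        )
    return report


def run_pipeline(config: PipelineConfig) -> dict[str, ConsensusReport]:
    """Load the dataset, analyse every configured phenotype, write tables.

    Phenotypes are processed as independent runs sharing the genotype
    matrix; tables land in ``out_dir/<phenotype>/``.  On failure no
    partial tables are left behind.
    """
    if not config.input_path:
        raise PipelineError("stage 'load' failed: no input path configured")
    if not config.phenotype_names:
        raise PipelineError("stage 'load' failed: no phenotype names configured")
    with _stage("load"):
        genotypes, phenotypes, covariates = read_dataset(
            config.input_path, config.phenotype_names,
            config.covariate_names, config.sample_id_column,
        )
    with _stage("impute"):
        genotypes = impute_missing(genotypes)

    reports: dict[str, ConsensusReport] = {}
    child = np.random.SeedSequence(config.seed).spawn(len(phenotypes))
    for pheno, ss in zip(phenotypes, child):
        sub = PipelineConfig(**{**config.to_dict(),
                                "seed": int(ss.generate_state(1)[0] >> 1),
                                "ntree_schedule": tuple(config.ntree_schedule)})
        start = time.perf_counter()
        reports[pheno.name] = analyse_phenotype(genotypes, pheno, covariates, sub)
        wall = time.perf_counter() - start
        if config.out_dir:
            out = Path(config.out_dir) / pheno.name
            written = {}
            try:
                with _stage("write_report"):
                    written = write_report_tables(reports[pheno.name], out,
                                                  wall_time_s=wall)
            except PipelineError:
                for p in written.values():
                    p.unlink(missing_ok=True)
                raise
    return reports


def compare_key_snps(a: ConsensusReport, b: ConsensusReport) -> pd.DataFrame:
    """Report-only diff of two key-SNP lists (e.g. with/without a covariate)."""
    snps = sorted(set(a.key_snps) | set(b.key_snps))
    return pd.DataFrame({
        "snp": snps,
        f"in_{a.phenotype}_a": [s in a.key_snps for s in snps],
        f"in_{b.phenotype}_b": [s in b.key_snps for s in snps],
    })
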