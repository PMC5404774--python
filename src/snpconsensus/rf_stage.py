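"""Iterative random-forest filtering of SNPs.

Each iteration fits a regression forest on all p SNPs (plus any
covariates), ranks predictors by OOB permutation variable importance,
keeps the top k SNPs, and refits on that subset.  The tree count rises
across iterations (default 500, 1000, 2000, 3000); model quality is
tracked as the percent variance explained by OOB predictions, which can
be negative when the forest predicts worse than the phenotype mean — the
typical outcome of fitting all p >> n mostly-irrelevant SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import CovariateTable, GenotypeTable, PhenotypeVector
from .forest import BaggedForest

DEFAULT_SCHEDULE = (500, 1000, 2000, 3000)
DEFAULT_K = 40
DEFAULT_MTRY_FRACTION = 1 / 3


@dataclass
class ImportanceRanking:
    """Predictors ordered by non-increasing importance score."""

    entries: list[tuple[str, float]]

    def __post_init__(self) -> None:
        scores = [s for _, s in self.entries]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("importance entries must be non-increasing in score")

    @property
    def ids(self) -> list[str]:
        return [name for name, _ in self.entries]


@dataclass
class RFIterationRecord:
    iteration_index: int  # 1-based
    ntree: int
    pct_var_all: float
    pct_var_topk: float
    top_k: list[str]


def pct_variance(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Percent variance explained: 100 * (1 - SS_res / SS_tot).

    May be negative when the predictor is worse than the observed mean.
    """
    obs = np.asarray(observed, dtype=np.float64).ravel()
    pred = np.asarray(predicted, dtype=np.float64).ravel()
    if obs.size != pred.size:
        raise ValueError("observed and predicted must have equal length")
    if obs.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed vector is constant; percent variance undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 100.0 * (1.0 - ss_res / ss_tot)


def fit_rf(x: np.ndarray, y: np.ndarray, ntree: int, seed: int,
           mtry_fraction: float = DEFAULT_MTRY_FRACTION
           ) -> tuple[BaggedForest, float]:
    """Fit a bagged regression forest; return it with its OOB percent variance."""
    x = np.asarray(x)
    mtry = max(1, int(x.shape[1] * mtry_fraction))
    forest = BaggedForest(n_trees=ntree, mtry=mtry, seed=seed).fit(x, y)
    oob = forest.oob_predictions()
    return forest, pct_variance(y, oob)


def rank_importance(forest: BaggedForest, names: list[str], seed: int = 0
                    ) -> ImportanceRanking:
    """Rank predictors by raw OOB permutation importance, ties by input order."""
    scores = forest.permutation_importance(seed=seed)
    if len(names) != scores.size:
        raise ValueError("one name per fitted predictor required")
    order = np.argsort(-scores, kind="stable")  # stable: ties keep input order
    return ImportanceRanking([(names[i], float(scores[i])) for i in order])


def select_top_k(ranking: ImportanceRanking, k: int) -> list[str]:
    """First min(k, p) ids of the ranking, order preserved."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return ranking.ids[:k]


def run_iterations(genotypes: GenotypeTable, phenotype: PhenotypeVector,
                   schedule: tuple[int, ...] = DEFAULT_SCHEDULE,
                   k: int = DEFAULT_K, seed: int = 0,
                   covariates: CovariateTable | None = None,
                   mtry_fraction: float = DEFAULT_MTRY_FRACTION
                   ) -> list[RFIterationRecord]:
    """Run the filtering schedule; each iteration restarts from all p SNPs.

    Covariates, when present, are appended as extra predictor columns to
    both the full fit and the top-k refit; the top-k selection itself is
    restricted to SNPs.
    """
    if not schedule:
        raise ValueError("schedule must be non-empty")
    x_snp = genotypes.design_matrix()
    names = list(genotypes.snp_ids)
    snp_set = set(names)
    if covariates:
        x_all = np.hstack([x_snp, covariates.values])
        names = names + list(covariates.names)
    else:
        x_all = x_snp
    y = phenotype.values
    seeds = np.random.SeedSequence(seed).spawn(len(schedule))
    records = []
    for it, (ntree, ss) in enumerate(zip(schedule, seeds), start=1):
        s_fit, s_rank, s_refit = [int(c.generate_state(1)[0] >> 1) for c in ss.spawn(3)]
        forest, pv_all = fit_rf(x_all, y, ntree, seed=s_fit,
                                mtry_fraction=mtry_fraction)
        ranking = rank_importance(forest, names, seed=s_rank)
        top = [sid for sid in ranking.ids if sid in snp_set][:k]
        x_top = genotypes.subset_snps(top).design_matrix()
        if covariates:
            x_top = np.hstack([x_top, covariates.values])
        _, pv_top = fit_rf(x_top, y, ntree, seed=s_refit,
                           mtry_fraction=mtry_fraction)
        records.append(RFIterationRecord(
            iteration_index=it, ntree=ntree,
            pct_var_all=pv_all, pct_var_topk=pv_top, top_k=top,
        ))
    return records
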