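"""All-relevant SNP selection with shadow features (Boruta).

Each run appends a permuted copy of every real predictor ("shadow"
features, re-permuted every run), fits a regression forest on the
extended design, and converts per-tree importances into a Z-score per
feature (mean importance across trees divided by its standard
deviation).  A real SNP scores a "hit" when its Z exceeds the best
shadow Z.  Hit counts accumulate across runs; after every run a
two-sided binomial test (two one-sided tests at ``alpha`` with Holm
step-down correction over the still-undecided features) promotes
features to *confirmed* or demotes them to *rejected*.  Features still
undecided after ``max_runs`` are *tentative*; only confirmed features
count as Boruta votes downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .forest import BaggedForest

DEFAULT_MAX_RUNS = 100
DEFAULT_ALPHA = 0.01
DEFAULT_NTREE = 500

CONFIRMED = "confirmed"
TENTATIVE = "tentative"
REJECTED = "rejected"


@dataclass
class BorutaResult:
    names: list[str]
    status: dict[str, str]           # name -> confirmed/tentative/rejected
    mean_z: dict[str, float]         # mean Z-score over the runs a feature saw
    hits: dict[str, int]
    runs_used: int

    @property
    def confirmed(self) -> list[str]:
        return [n for n in self.names if self.status[n] == CONFIRMED]

    @property
    def rejected(self) -> list[str]:
        return [n for n in self.names if self.status[n] == REJECTED]

    @property
    def tentative(self) -> list[str]:
        return [n for n in self.names if self.status[n] == TENTATIVE]


def _holm_decide(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Holm step-down: boolean reject-null decisions at family level alpha."""
    m = pvals.size
    decide = np.zeros(m, dtype=bool)
    order = np.argsort(pvals, kind="stable")
    for rank, i in enumerate(order):
        if pvals[i] <= alpha / (m - rank):
            decide[i] = True
        else:
            break
    return decide


def run_boruta(x: np.ndarray, y: np.ndarray, names: list[str] | None = None,
               max_runs: int = DEFAULT_MAX_RUNS, alpha: float = DEFAULT_ALPHA,
               ntree: int = DEFAULT_NTREE, seed: int = 0) -> BorutaResult:
    """Run the shadow-feature selection loop until all features are decided
    or ``max_runs`` is reached."""
    if max_runs < 1:
        raise ValueError("max_runs must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n, p = x.shape
    names = list(names) if names is not None else [f"x{j}" for j in range(p)]
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))

    undecided = np.ones(p, dtype=bool)
    status = np.full(p, TENTATIVE, dtype=object)
    hits = np.zeros(p, dtype=int)
    z_sums = np.zeros(p)
    z_runs = np.zeros(p, dtype=int)
    runs = 0
    for runs in range(1, max_runs + 1):
        # rejected attributes drop out of later runs (reference behaviour);
        # confirmed ones stay in as importance competitors
        active = np.nonzero(status != REJECTED)[0]
        xa = x[:, active]
        # at least 5 shadows (reference behaviour): pad by cycling columns
        n_shadow = max(active.size, 5)
        shadow = np.empty((n, n_shadow))
        for j in range(n_shadow):  # fresh permutation per shadow per run
            shadow[:, j] = xa[rng.permutation(n), j % active.size]
        model = BaggedForest(
            n_trees=ntree,
            mtry=max(1, int(np.sqrt(active.size + n_shadow))),
            seed=int(rng.integers(0, 2**31 - 1)),
        ).fit(np.hstack([xa, shadow]), y)
        z = model.feature_importances_z()
        z_real, z_shadow = z[:active.size], z[active.size:]
        z_sums[active] += z_real
        z_runs[active] += 1
        hits[active] += z_real > z_shadow.max()
        # two one-sided binomial tests on hit counts over the runs so far
        if undecided.any():
            h = hits[undecided]
            p_acc = stats.binom.sf(h - 1, runs, 0.5)
            p_rej = stats.binom.cdf(h, runs, 0.5)
            accept = _holm_decide(p_acc, alpha)
            reject = _holm_decide(p_rej, alpha) & ~accept
            idx = np.nonzero(undecided)[0]
            status[idx[accept]] = CONFIRMED
            status[idx[reject]] = REJECTED
            undecided[idx[accept | reject]] = False
        if not undecided.any():
            break
    return BorutaResult(
        names=names,
        status={names[j]: str(status[j]) for j in range(p)},
        mean_z={names[j]: float(z_sums[j] / max(z_runs[j], 1)) for j in range(p)},
        hits={names[j]: int(hits[j]) for j in range(p)},
        runs_used=runs,
    )
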