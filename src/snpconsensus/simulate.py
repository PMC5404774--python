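"""Synthetic genotype/phenotype generator.

Emulates the candidate-gene association setting the pipeline targets: a
p > n rectangular table of additively coded genotypes {1,2,3} with an
approximately standard-normal continuous phenotype.  Genotype frequencies
follow Hardy-Weinberg proportions with a per-SNP minor-allele frequency
drawn Uniform(0.05, 0.5), giving realistic class imbalance across SNPs.

Null datasets have the phenotype independent of every genotype; planted
datasets add an additive linear signal Y = sum_j beta_j * code_j + eps so
that recovery of known causal SNPs can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import GenotypeTable, PhenotypeVector

#: paper-scale simulation shape: 460 subjects x 1400 SNPs
DEFAULT_N = 460
DEFAULT_P = 1400

MAF_LOW = 0.05
MAF_HIGH = 0.5


@dataclass
class SimulationSpec:
    """Parameters of a planted-effect simulation.

    ``causal_snps`` maps SNP column index -> additive effect size beta_j
    (phenotype units per genotype-code unit).  ``noise_sd`` is the residual
    standard deviation of the phenotype.
    """

    n: int = DEFAULT_N
    p: int = DEFAULT_P
    causal_snps: dict[int, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    maf_range: tuple[float, float] = (MAF_LOW, MAF_HIGH)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.p < 1:
            raise ValueError("n and p must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for j in self.causal_snps:
            if not 0 <= j < self.p:
                raise ValueError(f"causal SNP index {j} outside [0, {self.p})")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")


def _draw_genotypes(n: int, p: int, rng: np.random.Generator,
                    maf_range: tuple[float, float]) -> np.ndarray:
    """Codes {1,2,3} under Hardy-Weinberg with per-SNP MAF ~ U(maf_range)."""
    maf = rng.uniform(maf_range[0], maf_range[1], size=p)
    # P(code) = [(1-q)^2, 2q(1-q), q^2] for minor-allele frequency q
    probs = np.stack([(1 - maf) ** 2, 2 * maf * (1 - maf), maf ** 2], axis=1)
    u = rng.random((n, p))
    cum = np.cumsum(probs, axis=1)  # (p, 3)
    codes = 1 + (u[:, :, None] > cum[None, :, :2]).sum(axis=2)
    return codes.astype(np.int16)


def _ids(n: int, p: int) -> tuple[list[str], list[str]]:
    samples = [f"S{i + 1}" for i in range(n)]
    snps = [f"X{j + 1}" for j in range(p)]
    return samples, snps


def simulate_null(n: int = DEFAULT_N, p: int = DEFAULT_P, seed: int = 0,
                  phenotype_name: str = "Y") -> tuple[GenotypeTable, PhenotypeVector]:
    """Genotypes independent of a standard-normal phenotype.

    Deterministic given ``seed``: genotype and phenotype draws come from
    separate child streams of one ``SeedSequence`` so the genotype matrix
    is identical between null and planted simulations at the same seed.
    """
    if n < 1 or p < 1:
        raise ValueError("n and p must be >= 1")
    geno_rng, pheno_rng = [
        np.random.Generator(np.random.PCG64(s))
        for s in np.random.SeedSequence(seed).spawn(2)
    ]
    codes = _draw_genotypes(n, p, geno_rng, (MAF_LOW, MAF_HIGH))
    y = pheno_rng.standard_normal(n)
    samples, snps = _ids(n, p)
    return (GenotypeTable(samples, snps, codes),
            PhenotypeVector(phenotype_name, y))


def simulate_with_effects(spec: SimulationSpec, phenotype_name: str = "Y"
                          ) -> tuple[GenotypeTable, PhenotypeVector, set[str]]:
    """Additive planted-effect dataset; returns the ground-truth causal SNP ids.

    Phenotype: Y_i = sum_j beta_j * code_ij + eps_i, eps ~ N(0, noise_sd^2).
    """
    geno_rng, pheno_rng = [
        np.random.Generator(np.random.PCG64(s))
        for s in np.random.SeedSequence(spec.seed).spawn(2)
    ]
    codes = _draw_genotypes(spec.n, spec.p, geno_rng, spec.maf_range)
    y = spec.noise_sd * pheno_rng.standard_normal(spec.n)
    for j, beta in spec.causal_snps.items():
        y = y + beta * codes[:, j]
    samples, snps = _ids(spec.n, spec.p)
    truth = {snps[j] for j in spec.causal_snps}
    return (GenotypeTable(samples, snps, codes),
            PhenotypeVector(phenotype_name, y),
            truth)


def planted_spec_for_variance_fraction(n: int, p: int, n_causal: int,
                                       frac_each: float, seed: int,
                                       maf: float = 0.3) -> SimulationSpec:
    """Spec whose causal SNPs each explain ~``frac_each`` of phenotype variance.

    Effect sizes are calibrated analytically from the Hardy-Weinberg code
    variance at minor-allele frequency ``maf`` (the simulation then draws
    per-SNP MAFs in a band around it), with residual sd fixed at 1, so the
    realised variance fraction is approximate but unbiased.
    """
    pr = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf ** 2])
    codes = np.array([1.0, 2.0, 3.0])
    var_code = float(pr @ codes ** 2 - (pr @ codes) ** 2)
    # each SNP: beta^2 var_code = frac_each * total, total = n_causal*beta^2*var_code + 1
    beta_sq = frac_each / (var_code * (1 - n_causal * frac_each))
    beta = float(np.sqrt(beta_sq))
    idx = np.linspace(0, p - 1, n_causal, dtype=int)
    return SimulationSpec(
        n=n, p=p,
        causal_snps={int(j): beta for j in idx},
        noise_sd=1.0,
        maf_range=(max(MAF_LOW, maf - 0.1), min(MAF_HIGH, maf + 0.1)),
        seed=seed,
    )
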