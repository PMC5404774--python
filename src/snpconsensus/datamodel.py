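"""Core containers for genotype/phenotype/covariate data.

Genotypes are additively coded integers: 1 = major homozygous,
2 = heterozygous, 3 = minor homozygous.  Missing genotypes are held as
``MISSING_CODE`` (-1) until :func:`impute_missing` replaces them with the
per-SNP modal code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

VALID_CODES = (1, 2, 3)
MISSING_CODE = -1


class ValidationError(ValueError):
    """A table violates a structural invariant (bad code, duplicate id, shape)."""


def _check_unique(labels: list[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValidationError(f"duplicate {what} id: {lab!r}")
        seen.add(lab)


@dataclass
class GenotypeTable:
    """n samples x p SNPs matrix of genotype codes {1,2,3} (or missing)."""

    sample_ids: list[str]
    snp_ids: list[str]
    codes: np.ndarray  # (n, p) int array; MISSING_CODE marks missing

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int16)
        if self.codes.ndim != 2:
            raise ValidationError("genotype codes must be a 2-D matrix")
        n, p = self.codes.shape
        if n != len(self.sample_ids) or p != len(self.snp_ids):
            raise ValidationError(
                f"matrix shape {self.codes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.snp_ids, "SNP")
        bad = ~(np.isin(self.codes, VALID_CODES) | (self.codes == MISSING_CODE))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"invalid genotype code {int(self.codes[i, j])} at sample "
                f"{self.sample_ids[i]!r}, SNP {self.snp_ids[j]!r} "
                "(expected 1, 2, 3 or missing)"
            )

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    @property
    def n_missing(self) -> int:
        return int((self.codes == MISSING_CODE).sum())

    def design_matrix(self) -> np.ndarray:
        """Additive design matrix (float); requires no missing entries."""
        if self.n_missing:
            raise ValidationError(
                f"{self.n_missing} missing genotypes present; impute first"
            )
        return self.codes.astype(np.float64)

    def subset_snps(self, snp_ids: list[str]) -> "GenotypeTable":
        index = {s: j for j, s in enumerate(self.snp_ids)}
        cols = [index[s] for s in snp_ids]
        return GenotypeTable(
            sample_ids=list(self.sample_ids),
            snp_ids=list(snp_ids),
            codes=self.codes[:, cols].copy(),
        )


@dataclass
class PhenotypeVector:
    """A named continuous trait, one value per sample."""

    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if np.isnan(self.values).any():
            raise ValidationError(
                f"phenotype {self.name!r} contains missing values after loading"
            )

    def __len__(self) -> int:
        return self.values.size


@dataclass
class CovariateTable:
    """Numeric covariates (e.g. age) carried through every stage as predictors."""

    names: list[str] = field(default_factory=list)
    values: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size == 0:
            self.values = self.values.reshape((self.values.shape[0] if self.values.ndim else 0, 0))
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValidationError(
                f"covariate matrix shape {self.values.shape} does not match "
                f"{len(self.names)} covariate names"
            )
        if np.isnan(self.values).any():
            raise ValidationError("covariates contain non-numeric or missing values")

    @property
    def n_covariates(self) -> int:
        return len(self.names)

    def __bool__(self) -> bool:
        return self.n_covariates > 0


def impute_missing(g: GenotypeTable) -> GenotypeTable:
    """Replace missing genotypes with the SNP's most frequent code.

    Ties between modal codes break toward the smaller code (deterministic,
    and usually the major-allele class).  Raises if any SNP column is
    entirely missing.
    """
    codes = g.codes.copy()
    missing = codes == MISSING_CODE
    if not missing.any():
        return replace(g, codes=codes)
    for j in np.unique(np.nonzero(missing)[1]):
        col = codes[:, j]
        observed = col[col != MISSING_CODE]
        if observed.size == 0:
            raise ValidationError(f"SNP {g.snp_ids[j]!r} has no observed genotypes")
        counts = np.bincount(observed, minlength=4)[1:4]
        mode = int(np.argmax(counts)) + 1  # argmax returns the first (smallest) tie
        col[col == MISSING_CODE] = mode
    return replace(g, codes=codes)
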