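"""Reading and writing of dataset and report tables.

Input is a single delimited table (CSV, or TSV for ``.tsv``/``.txt``
paths) with a header row: genotype columns coded 1/2/3, one or more
continuous phenotype columns, and optional numeric covariates.  Column
roles are assigned by name — every column not named as a phenotype,
covariate or sample-id column is treated as a SNP.  Empty cells and
``NA`` mark missing genotypes.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .consensus import ConsensusReport
from .datamodel import (
    MISSING_CODE,
    VALID_CODES,
    CovariateTable,
    GenotypeTable,
    PhenotypeVector,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_MISSING_MARKERS = ("", "NA")


class ParseError(ValueError):
    """A cell could not be parsed as the expected numeric type."""


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def read_dataset(path: str | Path, phenotype_names: list[str],
                 covariate_names: list[str] | None = None,
                 sample_id_column: str | None = None,
                 missing_markers: tuple[str, ...] = DEFAULT_MISSING_MARKERS,
                 ) -> tuple[GenotypeTable, list[PhenotypeVector], CovariateTable]:
    """Load an aligned genotype/phenotype/covariate dataset.

    Rows with a missing phenotype value are dropped (with their genotype
    rows) and logged.  Genotype codes outside {1,2,3,missing} raise
    :class:`~snpconsensus.datamodel.ValidationError`.
    """
    path = Path(path)
    covariate_names = list(covariate_names or [])
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str,
                     keep_default_na=False)
    for name in phenotype_names + covariate_names:
        if name not in df.columns:
            raise ValidationError(f"column {name!r} not found in {path.name}")
    if sample_id_column is not None:
        if sample_id_column not in df.columns:
            raise ValidationError(
                f"sample id column {sample_id_column!r} not found in {path.name}")
        sample_ids = [str(v) for v in df[sample_id_column]]
    else:
        sample_ids = [f"S{i + 1}" for i in range(len(df))]

    reserved = set(phenotype_names) | set(covariate_names) | {sample_id_column}
    snp_cols = [c for c in df.columns if c not in reserved]

    def parse_numeric(col: str) -> np.ndarray:
        try:
            return pd.to_numeric(df[col].replace(list(missing_markers), np.nan)
                                 ).to_numpy(dtype=float)
        except (ValueError, TypeError) as exc:
            raise ParseError(f"column {col!r}: {exc}") from exc

    pheno_values = {name: parse_numeric(name) for name in phenotype_names}
    cov_values = {name: parse_numeric(name) for name in covariate_names}

    # drop samples with any missing phenotype, with their genotype rows
    pheno_mask = np.ones(len(df), dtype=bool)
    for vals in pheno_values.values():
        pheno_mask &= ~np.isnan(vals)
    n_dropped = int((~pheno_mask).sum())
    if n_dropped:
        logger.info("dropped %d sample(s) with missing phenotype values",
                    n_dropped)

    markers = set(missing_markers)
    codes = np.empty((int(pheno_mask.sum()), len(snp_cols)), dtype=np.int16)
    rows = np.nonzero(pheno_mask)[0]
    for j, col in enumerate(snp_cols):
        raw = df[col].to_numpy(dtype=object)[rows]
        parsed = np.empty(rows.size, dtype=np.int16)
        for i, cell in enumerate(raw):
            text = str(cell).strip()
            if text in markers:
                parsed[i] = MISSING_CODE
                continue
            try:
                value = float(text)
            except ValueError as exc:
                raise ParseError(
                    f"non-numeric genotype {text!r} at row "
                    f"{sample_ids[rows[i]]!r}, column {col!r}") from exc
            code = int(value)
            if code != value or code not in VALID_CODES:
                raise ValidationError(
                    f"invalid genotype code {text!r} at row "
                    f"{sample_ids[rows[i]]!r}, column {col!r} "
                    "(expected 1, 2, 3 or missing)")
            parsed[i] = code
        codes[:, j] = parsed

    kept_ids = [sample_ids[i] for i in rows]
    genotypes = GenotypeTable(kept_ids, snp_cols, codes)
    if genotypes.n_missing:
        logger.info("loaded %d missing genotype call(s)", genotypes.n_missing)
    phenotypes = [PhenotypeVector(name, pheno_values[name][rows])
                  for name in phenotype_names]
    covariates = CovariateTable(
        names=covariate_names,
        values=(np.column_stack([cov_values[c][rows] for c in covariate_names])
                if covariate_names else np.empty((len(kept_ids), 0))),
    )
    for name in covariate_names:
        if np.isnan(covariates.values[:, covariate_names.index(name)]).any():
            raise ValidationError(f"covariate {name!r} has missing values")
    return genotypes, phenotypes, covariates


def write_dataset(path: str | Path, genotypes: GenotypeTable,
                  phenotypes: list[PhenotypeVector],
                  covariates: CovariateTable | None = None,
                  sample_id_column: str = "sample") -> None:
    """Write the standard dataset table (inverse of :func:`read_dataset`)."""
    path = Path(path)
    data: dict[str, object] = {sample_id_column: genotypes.sample_ids}
    for ph in phenotypes:
        data[ph.name] = ph.values
    if covariates:
        for i, name in enumerate(covariates.names):
            data[name] = covariates.values[:, i]
    frame = pd.DataFrame(data)
    geno = pd.DataFrame(genotypes.codes, columns=genotypes.snp_ids).astype(object)
    geno[genotypes.codes == MISSING_CODE] = "NA"
    frame = pd.concat([frame, geno], axis=1)
    frame.to_csv(path, sep=_sep_for(path), index=False)


def _versions() -> dict[str, str]:
    import importlib.metadata as md
    out = {}
    for pkg in ("snpconsensus", "numpy", "scipy", "pandas", "scikit-learn"):
        try:
            out[pkg] = md.version(pkg)
        except md.PackageNotFoundError:
            out[pkg] = "unknown"
    return out


def write_report_tables(report: ConsensusReport, out_dir: str | Path,
                        wall_time_s: float | None = None) -> dict[str, Path]:
    """Write all report tables as TSV plus a JSON run manifest.

    Returns a mapping of table name -> written path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def emit(name: str, frame: pd.DataFrame) -> None:
        p = out_dir / f"{name}.tsv"
        frame.to_csv(p, sep="\t", index=False)
        written[name] = p

    emit("iteration_metrics", pd.DataFrame([{
        "iteration": r.iteration_index, "ntree": r.ntree,
        "pct_var_all": r.pct_var_all, "pct_var_topk": r.pct_var_topk,
        "top_k": ";".join(r.top_k),
    } for r in report.iteration_records]))

    emit("method_calls", pd.DataFrame([{
        "iteration": c.iteration_index, "method": c.method, "snp": c.snp_id,
        "statistic": c.statistic, "significant": c.significant,
    } for c in report.calls]))

    vote_frame = report.votes.to_frame().reset_index(names="snp")
    vote_frame["n_votes"] = report.votes.votes.sum(axis=1) if len(
        report.votes.snp_ids) else []
    vote_frame["consensus"] = vote_frame["snp"].isin(report.key_snps)
    emit("vote_matrix", vote_frame)

    emit("frequency", pd.DataFrame([{
        "snp": c.snp_id, "iteration": c.iteration_index, "method": c.method,
    } for c in report.calls if c.significant]))

    emit("frequency_counts", pd.DataFrame([{
        "snp": f.snp_id, "count": f.count,
    } for f in report.frequencies]))

    conf_by_snp = {c.snp_id: c for c in report.confidences}
    emit("confidence", pd.DataFrame([{
        "snp": c.snp_id, "score": c.score,
        "true_positive_candidate": c.is_true_positive_candidate,
    } for c in report.confidences]))

    key_rows = []
    for snp in report.key_snps:
        conf = conf_by_snp.get(snp)
        key_rows.append({
            "snp": snp,
            "n_votes": report.votes.n_votes(snp),
            "confidence": conf.score if conf else 0.0,
            "true_positive_candidate": bool(
                conf and conf.is_true_positive_candidate),
        })
    emit("key_snps", pd.DataFrame(
        key_rows, columns=["snp", "n_votes", "confidence",
                           "true_positive_candidate"]))

    if report.covariate_calls:
        emit("covariate_calls", pd.DataFrame([{
            "iteration": c.iteration_index, "method": c.method,
            "covariate": c.snp_id, "statistic": c.statistic,
            "significant": c.significant,
        } for c in report.covariate_calls]))

    manifest = {
        "phenotype": report.phenotype,
        "n_methods": report.n_methods,
        "n_iterations": report.n_iterations,
        "config": report.config,
        "versions": _versions(),
        "wall_time_s": wall_time_s,
        "written_utc": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    written["manifest"] = manifest_path
    return written
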