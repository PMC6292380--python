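"""Tabular input/output for feature-level multiple-testing data.

Reads delimited (TSV/CSV) feature tables — one p-value per row plus optional
covariate columns, including the GWAS summary-statistic layout (SNP, beta,
SE, p, N, EAF) — and writes per-feature result tables with a JSON provenance
sidecar recording the configuration and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fdr import FdrResults
from .pi0 import Pi0Fit, PValueSet

logger = logging.getLogger(__name__)

__all__ = ["FeatureTableFile", "read_feature_table", "write_results", "write_provenance"]

RESULT_COLUMNS = (
    "id",
    "p",
    "pi0",
    "ci_lower",
    "ci_upper",
    "bh_adjusted",
    "fdr_covariate",
)


@dataclass(frozen=True)
class FeatureTableFile:
    """A delimited feature table plus its column mapping."""

    path: str
    p_value: str = "p"
    covariates: tuple[str, ...] = ()
    id_column: str | None = None
    delimiter: str | None = None  # None: auto-detect tab vs comma
    fold_eaf: tuple[str, ...] = ()  # EAF columns to fold to MAF = min(f, 1-f)


def _detect_delimiter(path: str) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_feature_table(file: FeatureTableFile) -> tuple[PValueSet, pd.DataFrame]:
    """Load and validate a feature table.

    Rows with missing covariates are dropped (with a logged count); a missing
    or out-of-range p-value column is fatal, naming the offending rows.
    """
    path = Path(file.path)
    if not path.exists():
        raise FileNotFoundError(f"feature table not found: {path}")
    sep = file.delimiter or _detect_delimiter(str(path))
    df = pd.read_csv(path, sep=sep)

    if file.p_value not in df.columns:
        raise ValueError(f"p-value column {file.p_value!r} not present in {path.name}")
    missing = [c for c in file.covariates if c not in df.columns]
    if missing:
        raise ValueError(f"covariate columns not present: {missing}")

    cols = [file.p_value, *file.covariates]
    n_before = len(df)
    df = df.dropna(subset=cols)
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("dropped %d rows with missing p-values or covariates", n_dropped)

    p = pd.to_numeric(df[file.p_value], errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(p) | (p < 0) | (p > 1))
    if bad.size:
        rows = (df.index[bad][:10] + 2).tolist()  # 1-based, counting the header
        raise ValueError(
            f"p-values outside [0, 1] (or non-numeric) in {path.name}, "
            f"file rows {rows}"
        )
    if p.size < 2:
        raise ValueError("fewer than 2 usable rows after filtering")

    cov = df[list(file.covariates)].reset_index(drop=True).copy()
    for col in file.fold_eaf:
        if col not in cov.columns:
            raise ValueError(f"fold_eaf column {col!r} is not among the covariates")
        f = cov[col].to_numpy(dtype=float)
        cov[col] = np.minimum(f, 1.0 - f)

    if file.id_column and file.id_column in df.columns:
        ids = df[file.id_column].to_numpy()
    else:
        ids = None
    return PValueSet(p, feature_id=ids), cov


def write_results(
    fit: Pi0Fit, results: FdrResults, pvalues: PValueSet, path: str
) -> None:
    """Write the per-feature results table (tab-delimited, full precision)."""
    m = len(pvalues)
    if m == 0:
        raise ValueError("refusing to write an empty results table")
    empty = np.full(m, np.nan)
    table = pd.DataFrame(
        {
            "id": pvalues.feature_id,
            "p": pvalues.p,
            "pi0": fit.pi0,
            "ci_lower": fit.ci_lower if fit.ci_lower is not None else empty,
            "ci_upper": fit.ci_upper if fit.ci_upper is not None else empty,
            "bh_adjusted": results.bh_adjusted,
            "fdr_covariate": results.fdr_covariate,
        },
        columns=list(RESULT_COLUMNS),
    )
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_provenance(path: str, config: dict) -> None:
    """JSON sidecar with everything needed to reproduce the run exactly."""
    import covfdr

    payload = {"covfdr_version": covfdr.__version__, **config}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
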