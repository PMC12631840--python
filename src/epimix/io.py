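"""Readers and writers for the delimited-text interchange formats.

TSV is the canonical format. Beta and reference matrices are written CpGs
as rows / samples (or cell types) as columns, matching the GEO
series-matrix orientation; fraction matrices and score tables are written
samples as rows. All writers use 12 significant digits so that a
read/write round trip preserves values to at least 10 significant digits.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BetaMatrix, FractionMatrix, ReferenceMatrix, Signature, validate_phenotypes

logger = logging.getLogger("epimix")

FLOAT_FORMAT = "%.12g"


def _read_table(path: str | Path, delimiter: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep=delimiter, index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return frame


def _coerce_numeric(frame: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.to_numpy().any():
        row = bad.any(axis=1).idxmax()
        col = bad.loc[row].idxmax()
        raise ValueError(f"non-numeric cell in {path} at row {row!r}, column {col!r}: {frame.loc[row, col]!r}")
    return numeric


def read_beta_matrix(path: str | Path, delimiter: str = "\t") -> BetaMatrix:
    """Read a CpG-by-sample beta matrix from delimited text.

    First row holds sample ids, first column CpG ids. Values must be
    numeric or missing; values outside [0, 1] by more than rounding
    tolerance raise ``ValueError``.
    """
    frame = _coerce_numeric(_read_table(path, delimiter), path)
    return BetaMatrix(frame)


def write_beta_matrix(beta: BetaMatrix, path: str | Path, delimiter: str = "\t") -> None:
    beta.data.to_csv(path, sep=delimiter, float_format=FLOAT_FORMAT, index_label="cpg_id")


def read_reference_matrix(path: str | Path, delimiter: str = "\t") -> ReferenceMatrix:
    return ReferenceMatrix(_coerce_numeric(_read_table(path, delimiter), path))


def write_reference_matrix(ref: ReferenceMatrix, path: str | Path, delimiter: str = "\t") -> None:
    ref.data.to_csv(path, sep=delimiter, float_format=FLOAT_FORMAT, index_label="cpg_id")


def read_fraction_matrix(path: str | Path, delimiter: str = "\t", normalized: bool = True) -> FractionMatrix:
    return FractionMatrix(_coerce_numeric(_read_table(path, delimiter), path), normalized=normalized)


def write_fraction_matrix(fractions: FractionMatrix, path: str | Path, delimiter: str = "\t") -> None:
    fractions.data.to_csv(path, sep=delimiter, float_format=FLOAT_FORMAT, index_label="sample_id")


def read_phenotypes(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    frame = _read_table(path, delimiter)
    return validate_phenotypes(frame)


def write_phenotypes(pheno: pd.DataFrame, path: str | Path, delimiter: str = "\t") -> None:
    pheno.to_csv(path, sep=delimiter, index_label="sample_id")


def read_signature(path: str | Path, delimiter: str = "\t") -> Signature:
    """Read a signature file: rows of ``cpg_id<TAB>weight``.

    An optional line ``intercept<TAB>value`` carries the linear intercept;
    an optional header line ``cpg_id<TAB>weight`` is skipped.
    """
    cpgs: list[str] = []
    weights: list[float] = []
    intercept = 0.0
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split(delimiter)
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected two fields, got {len(fields)}")
            key, value = fields
            if lineno == 1 and key == "cpg_id":
                continue
            if key == "intercept":
                intercept = float(value)
                continue
            cpgs.append(key)
            try:
                weights.append(float(value))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric weight {value!r}") from exc
    return Signature(tuple(cpgs), np.asarray(weights), intercept)


def write_signature(sig: Signature, path: str | Path, delimiter: str = "\t") -> None:
    with open(path, "w") as handle:
        handle.write(f"cpg_id{delimiter}weight\n")
        if sig.intercept != 0.0:
            handle.write(f"intercept{delimiter}{sig.intercept:.12g}\n")
        for cpg, weight in zip(sig.cpg_ids, sig.weights):
            handle.write(f"{cpg}{delimiter}{weight:.12g}\n")


def align_features(
    beta: BetaMatrix, ref: ReferenceMatrix, min_overlap_frac: float = 0.5
) -> tuple[BetaMatrix, ReferenceMatrix]:
    """Restrict a beta matrix and a reference panel to their shared CpGs.

    Arrays from different platforms (450k vs EPIC) cover different probe
    sets, so every deconvolution starts by intersecting features. The
    overlap fraction is measured against the reference's marker set; below
    ``min_overlap_frac`` an error is raised.
    """
    if not 0.0 < min_overlap_frac <= 1.0:
        raise ValueError("min_overlap_frac must be in (0, 1]")
    shared = beta.cpg_ids.intersection(ref.cpg_ids, sort=False)
    overlap = len(shared) / len(ref.cpg_ids)
    if overlap < min_overlap_frac:
        raise ValueError(
            f"only {overlap:.1%} of reference CpGs found in the beta matrix "
            f"(required {min_overlap_frac:.1%})"
        )
    logger.info("align_features: %d/%d reference CpGs present (%.1f%%)", len(shared), len(ref.cpg_ids), 100 * overlap)
    return BetaMatrix(beta.data.loc[shared]), ReferenceMatrix(ref.data.loc[shared])
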