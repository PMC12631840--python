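"""Core domain containers for methylation-deconvolution workflows.

All matrices are thin, validated wrappers around :class:`pandas.DataFrame`
in the field's conventional orientation: CpGs (probes) as rows, samples or
cell types as columns for methylation data; samples as rows and cell types
as columns for fraction matrices (the output orientation of deconvolution).

Beta values are methylation proportions and must lie in [0, 1]; missing
values are permitted in observed beta matrices (real array data has them)
but never in reference panels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("epimix")

#: absolute slack allowed before an out-of-range beta value is an error
BETA_RANGE_TOL = 1e-6

#: tolerance on row sums of a normalized fraction matrix
FRACTION_SUM_TOL = 1e-8


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:10]}")


def _clamp_beta(values: np.ndarray, what: str) -> np.ndarray:
    """Clamp rounding noise into [0, 1]; genuinely out-of-range values raise."""
    low = np.nanmin(values) if values.size else 0.0
    high = np.nanmax(values) if values.size else 1.0
    if low < -BETA_RANGE_TOL or high > 1.0 + BETA_RANGE_TOL:
        raise ValueError(
            f"beta out of range in {what}: values span [{low:.6g}, {high:.6g}], "
            "expected [0, 1]"
        )
    return np.clip(values, 0.0, 1.0)


@dataclass(frozen=True)
class BetaMatrix:
    """CpG-by-sample matrix of methylation beta values in [0, 1].

    Missing entries (NaN) are allowed; each consumer states its own
    missing-data policy (deconvolution drops CpGs per sample, scoring
    drops missing signature CpGs).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "CpG ids")
        _check_unique(self.data.columns, "sample ids")
        values = self.data.to_numpy(dtype=float)
        clamped = _clamp_beta(values, "BetaMatrix")
        object.__setattr__(
            self, "data", pd.DataFrame(clamped, index=self.data.index, columns=self.data.columns)
        )

    @property
    def cpg_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass(frozen=True)
class ReferenceMatrix:
    """CpG-by-cell-type matrix of mean beta values over marker CpGs."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "CpG ids")
        _check_unique(self.data.columns, "cell types")
        if self.data.shape[1] < 2:
            raise ValueError("a reference matrix needs at least 2 cell types")
        if self.data.shape[0] < 1:
            raise ValueError("a reference matrix needs at least 1 marker CpG")
        values = self.data.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValueError("reference matrix must not contain missing values")
        clamped = _clamp_beta(values, "ReferenceMatrix")
        object.__setattr__(
            self, "data", pd.DataFrame(clamped, index=self.data.index, columns=self.data.columns)
        )

    @property
    def cpg_ids(self) -> pd.Index:
        return self.data.index

    @property
    def cell_types(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


@dataclass(frozen=True)
class FractionMatrix:
    """Sample-by-cell-type matrix of (estimated or true) cell proportions.

    ``normalized=True`` (the default) asserts that each row sums to 1;
    hierarchical subtype output sums to the parent fraction instead and is
    constructed with ``normalized=False``.
    """

    data: pd.DataFrame
    normalized: bool = field(default=True)

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample ids")
        _check_unique(self.data.columns, "cell types")
        values = self.data.to_numpy(dtype=float)
        if (values < -FRACTION_SUM_TOL).any():
            raise ValueError("fractions must be non-negative")
        if self.normalized and values.shape[1] > 0:
            sums = values.sum(axis=1)
            bad = np.abs(sums - 1.0) > FRACTION_SUM_TOL
            if bad.any():
                raise ValueError(
                    f"{int(bad.sum())} fraction rows do not sum to 1 "
                    f"(max deviation {np.abs(sums - 1).max():.3g})"
                )
        object.__setattr__(
            self,
            "data",
            pd.DataFrame(np.clip(values, 0.0, None), index=self.data.index, columns=self.data.columns),
        )

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def cell_types(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


@dataclass(frozen=True)
class Signature:
    """A CpG signature: signed (+1/-1 weights, intercept 0) or weighted linear.

    Signed signatures drive correlation-based scores (the inflammaging
    CRP-style score); weighted signatures with an intercept define linear
    predictors (IL-6-style scores, generic methylation clocks).
    """

    cpg_ids: tuple[str, ...]
    weights: np.ndarray
    intercept: float = 0.0

    def __post_init__(self) -> None:
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "cpg_ids", tuple(str(c) for c in self.cpg_ids))
        object.__setattr__(self, "weights", weights)
        if len(set(self.cpg_ids)) != len(self.cpg_ids):
            raise ValueError("signature contains duplicate CpG ids")
        if weights.shape != (len(self.cpg_ids),):
            raise ValueError("weights must match cpg_ids one-to-one")
        if not np.isfinite(weights).all() or not np.isfinite(self.intercept):
            raise ValueError("signature weights and intercept must be finite")

    def __len__(self) -> int:
        return len(self.cpg_ids)

    @property
    def is_signed(self) -> bool:
        return self.intercept == 0.0 and np.isin(self.weights, (-1.0, 1.0)).all()

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=pd.Index(self.cpg_ids, name="cpg_id"), name="weight")


def validate_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-sample phenotype table (index = sample ids).

    Requires unique sample ids and, where an ``age`` column is present,
    non-negative ages.
    """
    _check_unique(pheno.index, "sample ids")
    if "age" in pheno.columns:
        ages = pd.to_numeric(pheno["age"], errors="raise")
        if (ages.dropna() < 0).any():
            raise ValueError("ages must be non-negative")
    return pheno
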