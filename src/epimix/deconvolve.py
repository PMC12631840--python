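"""Reference-based cell-type deconvolution via robust partial correlations.

Each bulk sample's marker-CpG betas are regressed on the reference panel
columns with a Huber M-estimator (iteratively reweighted least squares);
negative coefficients are truncated to zero and the remainder renormalized
to sum to one. A two-stage hierarchical estimator refines a parent cell
type into subtypes: total parent fraction from the full panel, relative
subtype split from a dedicated subtype panel, final fractions as their
product.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import BetaMatrix, FractionMatrix, ReferenceMatrix
from .io import align_features

logger = logging.getLogger("epimix")

_MAD_SCALE = 0.6744897501960817  # Phi^-1(0.75); MAD / this estimates sigma


@dataclass(frozen=True)
class DeconvolutionOptions:
    """Tuning knobs of the robust regression.

    ``huber_c = 1.345`` gives 95% efficiency under Gaussian noise; ``tol``
    is on the max absolute coefficient change between IRLS iterations.
    ``renormalize`` controls whether truncated coefficients are rescaled to
    sum to one (the conventional behavior) or reported raw.
    """

    maxit: int = 500
    huber_c: float = 1.345
    tol: float = 1e-6
    include_intercept: bool = True
    renormalize: bool = True

    def __post_init__(self) -> None:
        if self.maxit < 1 or self.tol <= 0 or self.huber_c <= 0:
            raise ValueError("need maxit >= 1, tol > 0, huber_c > 0")


def huber_irls(
    X: np.ndarray,
    y: np.ndarray,
    c: float = 1.345,
    maxit: int = 500,
    tol: float = 1e-6,
) -> np.ndarray:
    """Huber M-estimate of ``y ~ X`` by iteratively reweighted least squares.

    The residual scale is re-estimated each iteration as MAD/0.6745. A
    (near-)perfect fit short-circuits to the OLS solution.
    """
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    for _ in range(maxit):
        resid = y - X @ coef
        scale = np.median(np.abs(resid - np.median(resid))) / _MAD_SCALE
        if scale < 1e-10:
            break
        absr = np.abs(resid)
        with np.errstate(divide="ignore"):
            w = np.minimum(1.0, c * scale / np.where(absr > 0, absr, np.inf))
        sw = np.sqrt(w)
        new, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        step = np.max(np.abs(new - coef))
        coef = new
        if step < tol * max(1.0, np.max(np.abs(coef))):
            break
    return coef


def _check_collinearity(ref: ReferenceMatrix) -> None:
    values = ref.values
    rank = np.linalg.matrix_rank(values)
    if rank < values.shape[1]:
        corr = np.corrcoef(values, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(
            "reference matrix is rank-deficient; most collinear cell-type pair: "
            f"{ref.cell_types[i]!r} and {ref.cell_types[j]!r}"
        )


def rpc_deconvolve(
    beta: BetaMatrix,
    ref: ReferenceMatrix,
    opts: DeconvolutionOptions | None = None,
    min_overlap_frac: float = 0.5,
) -> FractionMatrix:
    """Estimate cell-type fractions of each sample by robust regression.

    Features are first intersected with the reference; per sample, CpGs
    missing in that sample are dropped (not listwise). Negative robust
    coefficients are truncated to zero; by default the truncated vector is
    renormalized to sum to one. An all-zero coefficient vector falls back
    to uniform fractions with a warning.
    """
    opts = opts or DeconvolutionOptions()
    beta, ref = align_features(beta, ref, min_overlap_frac=min_overlap_frac)
    n_types = len(ref.cell_types)
    needed = max(10, 2 * n_types)
    if len(ref.cpg_ids) < needed:
        raise ValueError(
            f"only {len(ref.cpg_ids)} shared marker CpGs; need at least {needed} "
            f"for a {n_types}-cell-type panel"
        )
    _check_collinearity(ref)

    R = ref.values
    Y = beta.values
    design_full = np.column_stack([R, np.ones(R.shape[0])]) if opts.include_intercept else R

    out = np.empty((Y.shape[1], n_types))
    for s in range(Y.shape[1]):
        y = Y[:, s]
        mask = ~np.isnan(y)
        if mask.sum() < needed:
            raise ValueError(
                f"sample {beta.sample_ids[s]!r} has only {int(mask.sum())} non-missing "
                f"marker CpGs; need at least {needed}"
            )
        coef = huber_irls(design_full[mask], y[mask], c=opts.huber_c, maxit=opts.maxit, tol=opts.tol)
        frac = np.maximum(coef[:n_types], 0.0)
        total = frac.sum()
        if total <= 0.0:
            warnings.warn(
                f"sample {beta.sample_ids[s]!r}: all coefficients non-positive; "
                "falling back to uniform fractions",
                stacklevel=2,
            )
            frac = np.full(n_types, 1.0 / n_types)
            total = 1.0
        out[s] = frac / total if opts.renormalize else frac
    frame = pd.DataFrame(out, index=beta.sample_ids, columns=ref.cell_types)
    return FractionMatrix(frame, normalized=opts.renormalize)


def hierarchical_subtypes(
    beta: BetaMatrix,
    parent_ref: ReferenceMatrix,
    subtype_ref: ReferenceMatrix,
    parent_type: str,
    opts: DeconvolutionOptions | None = None,
    min_overlap_frac: float = 0.5,
) -> FractionMatrix:
    """Two-stage subtype estimation (e.g., classical vs non-classical monocytes).

    Stage 1 estimates the total parent fraction with the full panel;
    stage 2 estimates the relative subtype split with the subtype panel;
    the final absolute fractions are the product of the two, so they sum
    per sample to the stage-1 parent fraction.
    """
    if parent_type not in parent_ref.cell_types:
        raise ValueError(f"parent type {parent_type!r} not in the parent panel")
    if len(subtype_ref.cell_types) < 2:
        raise ValueError("subtype panel must cover at least 2 subtypes")
    parent_frac = rpc_deconvolve(beta, parent_ref, opts, min_overlap_frac).data[parent_type]
    relative = rpc_deconvolve(beta, subtype_ref, opts, min_overlap_frac)
    absolute = relative.data.mul(parent_frac, axis=0)
    return FractionMatrix(absolute, normalized=False)
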