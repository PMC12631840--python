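"""Cohort-level association models and inverse-variance meta-analysis.

Per cohort, each cell-type fraction is standardized to unit variance and
regressed (OLS) against a phenotype with optional covariates; the effect,
standard error, t statistic and p-value of the fraction term are
extracted. Per-cohort estimates are then pooled under fixed- and
random-effects inverse-variance models with DerSimonian-Laird tau^2,
Cochran's Q and the I^2 heterogeneity index.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import FractionMatrix

logger = logging.getLogger("epimix")


@dataclass(frozen=True)
class EffectEstimate:
    """One regression effect from one cohort (per SD of the fraction)."""

    cohort: str
    term: str
    effect: float
    se: float
    t: float
    p: float
    n: int


@dataclass(frozen=True)
class MetaResult:
    """Pooled effect under fixed and random models with heterogeneity stats."""

    k: int
    fixed_effect: float
    fixed_se: float
    random_effect: float
    random_se: float
    tau2: float
    Q: float
    I2: float
    p_fixed: float
    p_random: float
    p_heterogeneity: float


def _standardize(x: pd.Series) -> pd.Series:
    return (x - x.mean()) / x.std(ddof=1)


def _design_matrix(pheno: pd.DataFrame, covariates: tuple[str, ...]) -> pd.DataFrame:
    """Numeric covariates standardized; categorical ones indicator-coded."""
    parts = []
    for cov in covariates:
        col = pheno[cov]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            parts.append(_standardize(col.astype(float)).rename(cov))
        elif pd.api.types.is_numeric_dtype(col):
            parts.append(col.astype(float).rename(cov))
        else:
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            parts.append(dummies)
    if not parts:
        return pd.DataFrame(index=pheno.index)
    return pd.concat(parts, axis=1)


def cohort_assoc(
    fractions: FractionMatrix,
    pheno: pd.DataFrame,
    outcome: str,
    covariates: tuple[str, ...] = (),
    cohort: str = "cohort",
) -> pd.DataFrame:
    """Associate each standardized cell-type fraction with a phenotype.

    Complete cases only (exclusions logged); the fraction is centered and
    scaled to unit variance so effects are per SD. A constant fraction
    yields a missing estimate with a warning; a rank-deficient design
    raises, naming the collinear terms.

    Returns one row per cell type with columns effect/se/t/p/n and a
    Bonferroni significance flag over the panel size.
    """
    shared = fractions.sample_ids.intersection(pheno.index, sort=False)
    y_raw = pd.to_numeric(pheno.loc[shared, outcome], errors="raise")
    covs = _design_matrix(pheno.loc[shared], covariates)
    keep = ~(y_raw.isna() | covs.isna().any(axis=1))
    n_excluded = int((~keep).sum()) + (len(fractions.sample_ids) - len(shared))
    if n_excluded:
        logger.info("cohort_assoc: excluded %d incomplete samples", n_excluded)
    y = y_raw[keep]
    covs = covs.loc[keep]
    if y.nunique() < 2:
        raise ValueError(f"outcome {outcome!r} is constant among complete cases")

    rows = []
    n_types = len(fractions.cell_types)
    for ct in fractions.cell_types:
        frac = fractions.data.loc[keep[keep].index, ct]
        if frac.nunique() <= 1 or frac.isna().any():
            warnings.warn(f"cell type {ct!r}: constant or missing fraction; estimate set missing", stacklevel=2)
            rows.append({"cohort": cohort, "cell_type": ct, "effect": np.nan, "se": np.nan,
                         "t": np.nan, "p": np.nan, "n": int(keep.sum())})
            continue
        X = pd.concat([_standardize(frac).rename("fraction"), covs], axis=1)
        X = sm.add_constant(X)
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            corr = np.corrcoef(X.to_numpy()[:, 1:], rowvar=False)
            np.fill_diagonal(corr, 0.0)
            i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
            names = X.columns[1:]
            raise ValueError(f"rank-deficient design: collinear terms {names[i]!r} and {names[j]!r}")
        fit = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
        idx = list(X.columns).index("fraction")
        rows.append({
            "cohort": cohort, "cell_type": ct,
            "effect": float(fit.params[idx]), "se": float(fit.bse[idx]),
            "t": float(fit.tvalues[idx]), "p": float(fit.pvalues[idx]),
            "n": int(fit.nobs),
        })
    out = pd.DataFrame(rows).set_index("cell_type")
    out["significant_bonferroni"] = out["p"] < 0.05 / n_types
    return out


def fraction_trend(
    fraction: pd.Series,
    age: pd.Series,
    covariates: pd.DataFrame | None = None,
    weights: pd.Series | None = None,
    min_count: float = 30,
) -> EffectEstimate:
    """Covariate-adjusted, count-weighted trend of a cell fraction with age.

    Donors whose count (the ``weights`` series) falls below ``min_count``
    are excluded first. Stage 1 residualizes the fraction on the
    covariates by OLS; stage 2 regresses the residuals on age by weighted
    least squares with the counts as weights, returning the age effect.
    """
    fraction = pd.Series(fraction).astype(float)
    age = pd.Series(age).astype(float).reindex(fraction.index)
    if weights is None:
        weights = pd.Series(1.0, index=fraction.index)
    weights = pd.Series(weights).astype(float).reindex(fraction.index)
    if (weights < 0).any():
        raise ValueError("weights must be non-negative")
    keep = weights >= min_count if min_count > 0 else weights.notna()
    keep &= fraction.notna() & age.notna()
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("fraction_trend: excluded %d donors (count floor %g or missingness)", n_excluded, min_count)
    fraction, age, weights = fraction[keep], age[keep], weights[keep]
    if weights.sum() <= 0:
        raise ValueError("all regression weights are zero")

    if covariates is not None and covariates.shape[1] > 0:
        C = sm.add_constant(
            _design_matrix(covariates.loc[fraction.index], tuple(covariates.columns)).to_numpy()
        )
        resid = sm.OLS(fraction.to_numpy(), C).fit().resid
    else:
        resid = fraction.to_numpy() - fraction.mean()

    X = sm.add_constant(age.to_numpy())
    fit = sm.WLS(resid, X, weights=weights.to_numpy()).fit()
    return EffectEstimate(
        cohort="", term="age",
        effect=float(fit.params[1]), se=float(fit.bse[1]),
        t=float(fit.tvalues[1]), p=float(fit.pvalues[1]), n=int(fit.nobs),
    )


def meta_fixed_random(estimates: "list[EffectEstimate] | pd.DataFrame") -> MetaResult:
    """Fixed- and random-effects inverse-variance meta-analysis.

    Fixed weights are 1/se^2; heterogeneity is Cochran's Q with k-1
    degrees of freedom; the between-study variance tau^2 is the
    DerSimonian-Laird moment estimator; random weights are
    1/(se^2 + tau^2); I^2 = max(0, (Q - (k-1))/Q) * 100. Effect p-values
    come from the normal distribution, the heterogeneity p-value from
    chi-square(k-1).
    """
    if isinstance(estimates, pd.DataFrame):
        effects = estimates["effect"].to_numpy(dtype=float)
        ses = estimates["se"].to_numpy(dtype=float)
    else:
        effects = np.array([e.effect for e in estimates], dtype=float)
        ses = np.array([e.se for e in estimates], dtype=float)
    k = len(effects)
    if k == 0:
        raise ValueError("meta-analysis requires at least one estimate")
    if (ses <= 0).any() or np.isnan(ses).any() or np.isnan(effects).any():
        raise ValueError("all estimates must have finite effects and positive standard errors")

    w = 1.0 / ses**2
    fixed = float(np.sum(w * effects) / np.sum(w))
    fixed_se = float(np.sum(w) ** -0.5)
    Q = float(np.sum(w * (effects - fixed) ** 2))
    if k > 1:
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
        I2 = max(0.0, (Q - (k - 1)) / Q) * 100.0 if Q > 0 else 0.0
        p_het = float(stats.chi2.sf(Q, k - 1))
    else:
        tau2, I2, p_het = 0.0, 0.0, np.nan
    w_star = 1.0 / (ses**2 + tau2)
    random = float(np.sum(w_star * effects) / np.sum(w_star))
    random_se = float(np.sum(w_star) ** -0.5)
    return MetaResult(
        k=k,
        fixed_effect=fixed,
        fixed_se=fixed_se,
        random_effect=random,
        random_se=random_se,
        tau2=float(tau2),
        Q=Q,
        I2=float(I2),
        p_fixed=float(2 * stats.norm.sf(abs(fixed / fixed_se))),
        p_random=float(2 * stats.norm.sf(abs(random / random_se))),
        p_heterogeneity=p_het,
    )
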