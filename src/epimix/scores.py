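"""Sample-level methylation scores.

Three families:

* the signed-signature inflammaging score (CRP-style "InflScore"): each
  CpG is z-scored across the cohort, and a sample's score is the Pearson
  correlation of its z-profile with the +/-1 direction vector of the
  signature — bounded in [-1, 1] by construction;
* weighted linear CpG predictors (IL-6-style scores, generic methylation
  clocks): intercept + sum of weight * beta over the signature CpGs;
* relative age acceleration (RAA): residuals of a DNAm-predicted age
  regressed on chronological age.

Because z-scoring is cohort-wise, correlation scores are comparable
within a cohort but not across cohorts in absolute terms.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import BetaMatrix, Signature

logger = logging.getLogger("epimix")


def zscore_rows(beta: BetaMatrix) -> pd.DataFrame:
    """Z-score each CpG across samples (mean 0, sd 1 per row).

    Rows with zero variance are dropped with a logged count. Requires at
    least two samples. Missing values are ignored in the row statistics
    and propagated.
    """
    if beta.shape[1] < 2:
        raise ValueError("z-scoring requires a cohort (>= 2 samples)")
    values = beta.data
    mean = values.mean(axis=1, skipna=True)
    sd = values.std(axis=1, ddof=1, skipna=True)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("zscore_rows: dropped %d zero-variance CpGs", n_dropped)
    z = values.loc[keep].sub(mean[keep], axis=0).div(sd[keep], axis=0)
    return z


def infl_score(zbeta: pd.DataFrame, sig: Signature) -> pd.DataFrame:
    """Signed-signature inflammaging score per sample.

    ``score_s`` is the Pearson correlation between sample ``s``'s z-scored
    values over the signature CpGs present in ``zbeta`` and the signature's
    +/-1 weights. Requires a signed signature and at least 3 overlapping
    CpGs; a sample whose profile has zero variance over the signature CpGs
    gets a missing score with a warning.

    Returns a DataFrame indexed by sample with columns ``score`` and
    ``n_cpgs_used``.
    """
    if not sig.is_signed:
        raise ValueError("infl_score requires a signed (+1/-1) signature")
    weights = sig.as_series()
    shared = zbeta.index.intersection(weights.index, sort=False)
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} signature CpGs present in the data; need >= 3"
        )
    if len(shared) < len(sig):
        warnings.warn(
            f"{len(sig) - len(shared)} of {len(sig)} signature CpGs missing from the data",
            stacklevel=2,
        )
    z = zbeta.loc[shared]
    w = weights.loc[shared].to_numpy()
    scores = np.empty(z.shape[1])
    n_used = np.empty(z.shape[1], dtype=int)
    w_centered = w - w.mean()
    for s in range(z.shape[1]):
        profile = z.iloc[:, s].to_numpy()
        mask = ~np.isnan(profile)
        n_used[s] = int(mask.sum())
        x = profile[mask]
        wv = w[mask]
        if n_used[s] < 3 or x.std() == 0 or wv.std() == 0:
            warnings.warn(
                f"sample {z.columns[s]!r}: degenerate profile over signature CpGs; score set missing",
                stacklevel=2,
            )
            scores[s] = np.nan
            continue
        if mask.all():
            wc = w_centered
        else:
            wc = wv - wv.mean()
        xc = x - x.mean()
        scores[s] = float(xc @ wc / (np.linalg.norm(xc) * np.linalg.norm(wc)))
    return pd.DataFrame({"score": scores, "n_cpgs_used": n_used}, index=z.columns)


def linear_cpg_score(beta: BetaMatrix, sig: Signature) -> pd.DataFrame:
    """Weighted linear CpG predictor: intercept + sum(weight * beta).

    Signature CpGs absent from the data contribute zero, with a warning
    and a per-sample ``n_cpgs_used`` count; at least one signature CpG
    must be present.
    """
    weights = sig.as_series()
    shared = beta.cpg_ids.intersection(weights.index, sort=False)
    if len(shared) < 1:
        raise ValueError("no signature CpGs present in the data")
    if len(shared) < len(sig):
        warnings.warn(
            f"{len(sig) - len(shared)} of {len(sig)} signature CpGs missing; they contribute 0",
            stacklevel=2,
        )
    sub = beta.data.loc[shared]
    w = weights.loc[shared]
    contrib = sub.mul(w, axis=0)
    scores = sig.intercept + contrib.sum(axis=0, skipna=True)
    n_used = sub.notna().sum(axis=0)
    return pd.DataFrame({"score": scores, "n_cpgs_used": n_used.astype(int)})


def raa(predicted_age: pd.Series, chron_age: pd.Series) -> pd.Series:
    """Relative age acceleration: residuals of predicted on chronological age.

    An ordinary least-squares line is fit through (chronological,
    predicted) pairs; the residuals sum to zero and are uncorrelated with
    chronological age, isolating age-independent deviation of the
    methylation-predicted age.
    """
    predicted_age = pd.Series(predicted_age).astype(float)
    chron_age = pd.Series(chron_age).astype(float).reindex(predicted_age.index)
    if chron_age.isna().any():
        raise ValueError("predicted and chronological ages must share sample ids")
    if len(predicted_age) < 3:
        raise ValueError("RAA requires at least 3 samples")
    if chron_age.nunique() < 2:
        raise ValueError("chronological age is constant; residualization undefined")
    X = sm.add_constant(chron_age.to_numpy())
    fit = sm.OLS(predicted_age.to_numpy(), X).fit()
    return pd.Series(fit.resid, index=predicted_age.index, name="raa")
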