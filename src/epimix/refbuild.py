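"""Construction of a cell-subtype reference panel from sorted samples.

The pipeline mirrors the standard differential-methylation route to a
deconvolution panel: an empirical-Bayes moderated t-test between the two
sorted populations, Benjamini-Hochberg FDR control, ranking of the
significant differentially methylated cytosines (DMCs) by a gap
specificity score, thresholding, and per-cell-type mean aggregation over
the surviving marker CpGs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .containers import BetaMatrix, ReferenceMatrix

logger = logging.getLogger("epimix")


def _two_groups(labels: pd.Series, sample_ids: pd.Index) -> tuple[list[str], np.ndarray]:
    raw = pd.Series(labels)
    labels = raw.reindex(sample_ids)
    if labels.isna().any():
        missing = sample_ids[labels.isna()].tolist()
        raise ValueError(f"samples without a group label: {missing[:10]}")
    groups = list(pd.unique(raw))  # caller's label order, stable under sample shuffling
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    return groups, labels.to_numpy()


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching fit of the scaled-inverse-chi-square variance prior.

    Matches the first two moments of log(s^2) against the theoretical
    log-F distribution of sample variances around the prior, returning
    (prior_df d0, prior_variance s0^2). d0 = inf when the observed spread
    of log-variances is no larger than expected from chance alone.
    """
    s2 = s2[s2 > 0]
    if s2.size < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1e-8
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))

    def gap(log_half_d0: float) -> float:
        return float(special.polygamma(1, np.exp(log_half_d0))) - e_var

    # trigamma is monotone decreasing; bracket the root on the log scale
    lo, hi = -12.0, 12.0
    if gap(lo) < 0:  # even tiny d0 cannot produce this much spread
        return 0.01, float(np.exp(e_mean))
    half_d0 = np.exp(optimize.brentq(gap, lo, hi))
    d0 = 2.0 * half_d0
    s0_2 = np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0))
    return float(d0), float(s0_2)


def moderated_ttest(
    beta: BetaMatrix,
    labels: pd.Series,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-group t-test per CpG.

    Pooled per-CpG variances are shrunk toward a prior estimated across
    CpGs by method of moments on the log variances; the t statistic uses
    the shrunk variance and gains the prior degrees of freedom. Setting
    ``prior_df=0`` disables shrinkage and recovers the ordinary
    pooled-variance t-test. CpGs with any missing value are dropped with a
    logged count.

    Returns a DataFrame indexed by CpG with columns ``t``, ``p``, ``fdr``,
    ``delta`` (group1 - group2 mean) and ``gap`` (two-group specificity).
    """
    groups, lab = _two_groups(labels, beta.sample_ids)
    values = beta.values
    complete = ~np.isnan(values).any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("moderated_ttest: dropped %d CpGs with missing values", n_dropped)
    values = values[complete]
    cpgs = beta.cpg_ids[complete]

    m1 = lab == groups[0]
    m2 = lab == groups[1]
    n1, n2 = int(m1.sum()), int(m2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs >= 2 samples (got {n1} and {n2})")

    x1, x2 = values[:, m1], values[:, m2]
    mean1, mean2 = x1.mean(axis=1), x2.mean(axis=1)
    delta = mean1 - mean2
    df = n1 + n2 - 2
    ss = ((x1 - mean1[:, None]) ** 2).sum(axis=1) + ((x2 - mean2[:, None]) ** 2).sum(axis=1)
    s2 = ss / df

    if prior_df is None:
        d0, s0_2 = _fit_variance_prior(s2, df)
    elif prior_df == 0:
        d0, s0_2 = 0.0, 0.0
    else:
        d0, s0_2 = float(prior_df), float(np.median(s2[s2 > 0])) if (s2 > 0).any() else 1e-8

    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s0_2 + df * s2) / (d0 + df)
        # information cannot exceed the pooled residual df across all CpGs
        df_total = min(df + d0, len(s2) * df)

    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / se
    t = np.where(np.isnan(t), 0.0, t)  # 0/0: no signal, no evidence
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)
    fdr = multipletests(p, method="fdr_bh")[1]
    gap = np.abs(delta)  # two-group specificity gap reduces to |delta-beta|
    return pd.DataFrame(
        {"t": t, "p": p, "fdr": fdr, "delta": delta, "gap": gap},
        index=pd.Index(cpgs, name="cpg_id"),
    )


def specificity_gap(ref_means: np.ndarray | pd.Series) -> float:
    """Gap specificity score of one CpG given its per-cell-type means.

    The most discriminative ("extreme") cell type is the one whose mean is
    furthest from its nearest other type; the score is the signed distance
    from that mean to the nearest other mean. For two cell types the
    magnitude reduces to |mean1 - mean2|.
    """
    means = np.asarray(ref_means, dtype=float)
    if means.size < 2:
        raise ValueError("need at least 2 cell types")
    diffs = np.abs(means[:, None] - means[None, :])
    np.fill_diagonal(diffs, np.inf)
    nearest = diffs.min(axis=1)
    k = int(np.argmax(nearest))
    j = int(np.argmin(diffs[k]))
    return float(means[k] - means[j])


def build_reference(
    beta: BetaMatrix,
    labels: pd.Series,
    fdr_threshold: float = 0.05,
    gap_threshold: float = 0.3,
    max_markers: int | None = None,
    balance_directions: bool = True,
    prior_df: float | None = None,
) -> tuple[ReferenceMatrix, pd.DataFrame]:
    """Select marker CpGs and build the subtype reference panel.

    Markers are CpGs with ``fdr < fdr_threshold`` and ``|gap| >=
    gap_threshold``, ranked by descending gap (ties: ascending p, then
    CpG id). With ``balance_directions`` (default), equal numbers of
    hyper- and hypomethylated markers are kept where both directions are
    available. Reference values are the per-group sample means over the
    selected markers.
    """
    if not (0.0 < fdr_threshold < 1.0 and 0.0 < gap_threshold < 1.0):
        raise ValueError("thresholds must lie in (0, 1)")
    groups, lab = _two_groups(labels, beta.sample_ids)
    dmc = moderated_ttest(beta, labels, prior_df=prior_df)
    passing = dmc[(dmc["fdr"] < fdr_threshold) & (dmc["gap"] >= gap_threshold)].copy()
    if passing.empty:
        raise ValueError("no discriminative markers at stated thresholds")

    passing = passing.reset_index().sort_values(
        by=["gap", "p", "cpg_id"], ascending=[False, True, True], kind="mergesort"
    )

    hyper = passing[passing["delta"] > 0]
    hypo = passing[passing["delta"] < 0]
    if balance_directions and not hyper.empty and not hypo.empty:
        per_dir = min(len(hyper), len(hypo))
        if max_markers is not None:
            per_dir = min(per_dir, max_markers // 2)
        selected = pd.concat([hyper.iloc[:per_dir], hypo.iloc[:per_dir]])
    else:
        selected = passing if max_markers is None else passing.iloc[:max_markers]

    marker_ids = sorted(selected["cpg_id"].tolist())
    logger.info(
        "build_reference: %d markers (%d hyper / %d hypo) at FDR<%g, gap>=%g",
        len(marker_ids),
        int((selected["delta"] > 0).sum()),
        int((selected["delta"] < 0).sum()),
        fdr_threshold,
        gap_threshold,
    )
    sub = beta.data.loc[marker_ids]
    means = {g: sub.loc[:, np.asarray(lab) == g].mean(axis=1) for g in groups}
    ref = ReferenceMatrix(pd.DataFrame(means))
    return ref, dmc
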