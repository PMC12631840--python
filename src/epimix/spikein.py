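"""In-silico rare-cell spike-in experiment.

Mixtures with known rare-cell (nucleated-red-blood-cell-like) content are
assembled across bins of the true fraction, deconvolved against a
reference panel, and recovery is summarized per bin (Pearson r of true vs
estimated, mean bias, mean estimate) and overall. The construction
follows the standard recipe: realistic base fractions for the common cell
types are rescaled by (1 - rare fraction), one sorted profile per cell
type is drawn at random, and the mixture is the fraction-weighted average
of the chosen profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BetaMatrix, FractionMatrix, ReferenceMatrix
from .deconvolve import DeconvolutionOptions, rpc_deconvolve

#: nine bins of true rare-cell fraction: 0% exactly, then 0-0.1%,
#: 0.1-0.5%, 0.5-1%, 1-2%, 2-4%, 4-6%, 6-8%, 8-10%.
DEFAULT_BINS: tuple[tuple[float, float], ...] = (
    (0.0, 0.0),
    (0.0, 0.001),
    (0.001, 0.005),
    (0.005, 0.01),
    (0.01, 0.02),
    (0.02, 0.04),
    (0.04, 0.06),
    (0.06, 0.08),
    (0.08, 0.10),
)


@dataclass(frozen=True)
class SpikeInDesign:
    """Design of the spike-in experiment.

    ``base_fractions`` holds realistic fractions for the non-rare cell
    types (rows sum to 1); ``pools`` maps every required cell type —
    including ``rare_type`` — to a BetaMatrix of sorted-sample profiles
    sharing one CpG index. Bins are half-open [low, high) except the
    degenerate zero bin; all must lie within [0, 0.10].
    """

    base_fractions: FractionMatrix
    pools: dict[str, BetaMatrix]
    rare_type: str
    bins: tuple[tuple[float, float], ...] = DEFAULT_BINS
    n_per_bin: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        prev_high = -1.0
        for low, high in self.bins:
            if not (0.0 <= low <= high <= 0.10):
                raise ValueError(f"bin ({low}, {high}) outside [0, 0.10]")
            if low < prev_high:
                raise ValueError("bins must be non-overlapping and ordered")
            prev_high = high
        required = list(self.base_fractions.cell_types) + [self.rare_type]
        for ct in required:
            pool = self.pools.get(ct)
            if pool is None or pool.shape[1] < 1:
                raise ValueError(f"no sorted pool profiles for cell type {ct!r}")
        index = self.pools[required[0]].cpg_ids
        for ct in required[1:]:
            if not index.equals(self.pools[ct].cpg_ids):
                raise ValueError("all sorted pools must share one CpG index")
        if self.rare_type in self.base_fractions.cell_types:
            raise ValueError("base fractions must cover only the non-rare cell types")


@dataclass(frozen=True)
class SpikeInResult:
    """Per-bin and pooled recovery of the rare-cell fraction."""

    per_bin: pd.DataFrame
    overall_r: float
    overall_slope: float


def build_mixtures(design: SpikeInDesign) -> tuple[BetaMatrix, pd.DataFrame]:
    """Assemble spike-in mixtures with known rare fractions.

    For each bin and draw: a rare fraction is sampled uniformly within the
    bin, a base fraction row is sampled with replacement and rescaled by
    (1 - rare fraction), one sorted profile per cell type is chosen
    uniformly, and the mixture beta is the weighted average of the chosen
    profiles. Total fractions sum to 1 exactly before any noise.

    Returns the mixture BetaMatrix and a truth table with columns ``bin``
    (index into ``design.bins``) and ``true_fraction``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 3]))
    common_types = list(design.base_fractions.cell_types)
    cpg_index = design.pools[design.rare_type].cpg_ids
    pool_arrays = {ct: design.pools[ct].values for ct in common_types + [design.rare_type]}
    base = design.base_fractions.values

    columns: list[np.ndarray] = []
    ids: list[str] = []
    records: list[tuple[int, float]] = []
    for b, (low, high) in enumerate(design.bins):
        for j in range(design.n_per_bin):
            f_rare = low if low == high else rng.uniform(low, high)
            base_row = base[rng.integers(base.shape[0])] * (1.0 - f_rare)
            profile = np.zeros(len(cpg_index))
            for ct, w in zip(common_types, base_row):
                pool = pool_arrays[ct]
                profile += w * pool[:, rng.integers(pool.shape[1])]
            rare_pool = pool_arrays[design.rare_type]
            profile += f_rare * rare_pool[:, rng.integers(rare_pool.shape[1])]
            columns.append(profile)
            ids.append(f"bin{b}_mix{j:04d}")
            records.append((b, f_rare))
    beta = BetaMatrix(
        pd.DataFrame(np.column_stack(columns), index=cpg_index, columns=pd.Index(ids, name="sample_id"))
    )
    truth = pd.DataFrame(records, columns=["bin", "true_fraction"], index=pd.Index(ids, name="sample_id"))
    return beta, truth


def evaluate_spikein(
    mixtures: BetaMatrix,
    truth: pd.DataFrame,
    ref: ReferenceMatrix,
    rare_type: str,
    opts: DeconvolutionOptions | None = None,
    bins: tuple[tuple[float, float], ...] | None = None,
) -> SpikeInResult:
    """Deconvolve spike-in mixtures and summarize rare-fraction recovery.

    Per bin: Pearson r between true and estimated rare fraction (missing
    when the truth is constant, e.g. the 0% bin), mean bias (estimated -
    true), and mean estimate. Overall: pooled Pearson r and the slope of
    estimated on true across all mixtures.
    """
    if rare_type not in ref.cell_types:
        raise ValueError(f"rare type {rare_type!r} not in the reference panel")
    fractions = rpc_deconvolve(mixtures, ref, opts)
    est = fractions.data[rare_type].reindex(truth.index)
    true = truth["true_fraction"]

    rows = []
    for b, group in truth.groupby("bin"):
        e = est.loc[group.index].to_numpy()
        t = group["true_fraction"].to_numpy()
        if np.ptp(t) > 0 and np.ptp(e) > 0:
            r = float(stats.pearsonr(t, e)[0])
        else:
            r = np.nan
        rows.append(
            {
                "bin": int(b),
                "n": len(group),
                "pearson_r": r,
                "mean_bias": float(np.mean(e - t)),
                "mean_estimate": float(np.mean(e)),
                "mean_true": float(np.mean(t)),
            }
        )
    per_bin = pd.DataFrame(rows).set_index("bin")
    if bins is not None:
        per_bin["low"] = [bins[b][0] for b in per_bin.index]
        per_bin["high"] = [bins[b][1] for b in per_bin.index]
    t_all = true.to_numpy()
    e_all = est.to_numpy()
    overall_r = float(stats.pearsonr(t_all, e_all)[0]) if np.ptp(t_all) > 0 else np.nan
    slope = float(np.polyfit(t_all, e_all, 1)[0]) if np.ptp(t_all) > 0 else np.nan
    return SpikeInResult(per_bin=per_bin, overall_r=overall_r, overall_slope=slope)
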