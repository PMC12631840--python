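"""Synthetic blood-methylation cohorts with known cell-type composition.

The generator emulates the statistical structure of reference-based
deconvolution studies of whole blood: a panel of immune cell types each
carrying a block of marker CpGs (hyper- or hypomethylated in that type
relative to all others), per-sample cell fractions drawn from a Dirichlet
whose log-concentrations drift with age and sex, bulk profiles formed as
the fraction-weighted average of the reference profiles, beta-scale
measurement noise, and a latent-inflammation CpG signature superimposed on
non-marker CpGs. Every quantity that downstream stages estimate (true
fractions, phenotypes, the signature's sign vector) is returned alongside
the observed data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import BetaMatrix, FractionMatrix, ReferenceMatrix, Signature

#: 19 immune cell types of a full blood panel, including rare populations
#: (erythroid precursors among them) alongside the major leukocyte lineages.
DEFAULT_CELL_TYPES: tuple[str, ...] = (
    "Neu", "Eos", "Baso", "Mono", "DC",
    "CD4Tnv", "CD4Tmem", "Treg", "CD8Tnv", "CD8Tmem",
    "Bnv", "Bmem", "Plasmablast", "NK", "MAIT",
    "gdT", "HSC", "nRBC", "Mega",
)

#: plausible mean blood fractions for the default panel (sum to 1); the
#: Dirichlet concentration vector is this times a total concentration.
_DEFAULT_MEAN_FRACTIONS: tuple[float, ...] = (
    0.45, 0.025, 0.010, 0.080, 0.010,
    0.070, 0.070, 0.015, 0.040, 0.040,
    0.025, 0.025, 0.005, 0.060, 0.010,
    0.020, 0.005, 0.025, 0.015,
)

_TOTAL_CONCENTRATION = 40.0

#: default per-decade drift of log-concentrations: naive lymphocyte
#: compartments shrink with age, memory compartments and erythroid
#: precursors expand.
_DEFAULT_AGE_SLOPES: dict[str, float] = {
    "CD4Tnv": -0.10, "CD8Tnv": -0.12, "Bnv": -0.10,
    "CD4Tmem": 0.06, "CD8Tmem": 0.06, "Bmem": 0.04,
    "nRBC": 0.05,
}

_DEFAULT_SEX_EFFECTS: dict[str, float] = {"NK": 0.08, "CD4Tnv": -0.05}

#: standard deviation of the noise added to standardized age to form the
#: latent inflammation variable (inflammation tracks age only partially).
LATENT_NOISE_SD = 0.5


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    ``noise_precision`` is the precision of the beta-distributed
    measurement noise (observed ~ Beta(mean*lam, (1-mean)*lam)); ``None``
    disables noise entirely. ``age_slopes`` and ``sex_effects`` act on the
    Dirichlet log-concentrations (per decade of age / per unit sex code),
    so fractions stay on the simplex at every age.
    """

    n_cpgs: int = 5000
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    markers_per_type: int = 50
    beta_high: float = 0.85
    beta_low: float = 0.10
    dirichlet_alpha: tuple[float, ...] | None = None
    age_slopes: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_AGE_SLOPES))
    sex_effects: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_SEX_EFFECTS))
    noise_precision: float | None = 200.0
    signature_size: int = 100
    signature_effect: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.beta_low < self.beta_high < 1.0):
            raise ValueError("need 0 < beta_low < beta_high < 1")
        if self.noise_precision is not None and self.noise_precision <= 2.0:
            raise ValueError("noise_precision must exceed 2 (or be None for noiseless)")
        if len(set(self.cell_types)) != len(self.cell_types):
            raise ValueError("cell_types must be unique")
        if self.alpha().shape != (len(self.cell_types),) or (self.alpha() <= 0).any():
            raise ValueError("dirichlet_alpha must be positive, one entry per cell type")

    def alpha(self) -> np.ndarray:
        if self.dirichlet_alpha is not None:
            return np.asarray(self.dirichlet_alpha, dtype=float)
        if self.cell_types == DEFAULT_CELL_TYPES:
            return _TOTAL_CONCENTRATION * np.asarray(_DEFAULT_MEAN_FRACTIONS)
        return np.full(len(self.cell_types), _TOTAL_CONCENTRATION / len(self.cell_types))

    @property
    def n_marker_cpgs(self) -> int:
        return len(self.cell_types) * self.markers_per_type


def _cpg_ids(n: int) -> pd.Index:
    return pd.Index([f"cg{i:08d}" for i in range(n)], name="cpg_id")


def make_reference(cfg: SimulationConfig) -> ReferenceMatrix:
    """Build the synthetic cell-type reference panel.

    The first ``cell_types x markers_per_type`` CpGs are marker blocks:
    within type k's block, alternating markers are at ``beta_high`` in
    type k and ``beta_low`` everywhere else, or the reverse (so each type
    carries both hyper- and hypomethylated markers). Remaining CpGs share
    a common baseline level drawn uniform(0.2, 0.8) across all types.
    """
    n_types = len(cfg.cell_types)
    if cfg.n_cpgs < cfg.n_marker_cpgs:
        raise ValueError(
            f"n_cpgs={cfg.n_cpgs} cannot host {n_types} x {cfg.markers_per_type} marker CpGs"
        )
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    values = np.empty((cfg.n_cpgs, n_types))
    for k in range(n_types):
        block = slice(k * cfg.markers_per_type, (k + 1) * cfg.markers_per_type)
        sub = np.full((cfg.markers_per_type, n_types), cfg.beta_low)
        sub[:, k] = cfg.beta_high
        # alternate marker direction so each type has hyper and hypo markers
        flip = np.arange(cfg.markers_per_type) % 2 == 1
        sub[flip, :] = cfg.beta_high
        sub[flip, k] = cfg.beta_low
        values[block] = sub
    baseline = rng.uniform(0.2, 0.8, size=cfg.n_cpgs - cfg.n_marker_cpgs)
    values[cfg.n_marker_cpgs:] = baseline[:, None]
    return ReferenceMatrix(pd.DataFrame(values, index=_cpg_ids(cfg.n_cpgs), columns=list(cfg.cell_types)))


def _beta_noise(mean: np.ndarray, lam: float | None, rng: np.random.Generator) -> np.ndarray:
    """Beta-distributed observation around ``mean`` with precision ``lam``."""
    mean = np.clip(mean, 1e-6, 1.0 - 1e-6)
    if lam is None:
        return mean
    observed = rng.beta(mean * lam, (1.0 - mean) * lam)
    return np.clip(observed, 1e-6, 1.0 - 1e-6)


@dataclass(frozen=True)
class CohortData:
    """A simulated cohort: observed betas plus all ground truth."""

    beta: BetaMatrix
    fractions: FractionMatrix
    phenotypes: pd.DataFrame
    signature: Signature


def make_cohort(cfg: SimulationConfig, n_samples: int, cohort_label: str = "sim") -> CohortData:
    """Simulate a whole-blood cohort with known composition and phenotype.

    Ages ~ uniform(18, 90); sex ~ Bernoulli(0.5); the latent inflammation
    variable is standardized age plus independent Gaussian noise. Fractions
    come from a Dirichlet whose log-concentrations shift linearly with age
    (per decade) and sex; the noiseless bulk profile is the reference times
    the fraction vector; the inflammation signature shifts the means of
    ``signature_size`` randomly chosen non-marker CpGs by
    ``sign * signature_effect * latent`` (clamped to [0.01, 0.99]) before
    beta noise is applied.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    ref = make_reference(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n_types = len(cfg.cell_types)

    age = rng.uniform(18.0, 90.0, size=n_samples)
    sex = rng.integers(0, 2, size=n_samples)
    age_std = (age - age.mean()) / age.std(ddof=0) if n_samples > 1 else np.zeros(n_samples)
    latent = age_std + LATENT_NOISE_SD * rng.standard_normal(n_samples)

    slopes = np.array([cfg.age_slopes.get(ct, 0.0) for ct in cfg.cell_types])
    sexfx = np.array([cfg.sex_effects.get(ct, 0.0) for ct in cfg.cell_types])
    log_alpha = (
        np.log(cfg.alpha())[None, :]
        + slopes[None, :] * ((age[:, None] - 54.0) / 10.0)
        + sexfx[None, :] * sex[:, None]
    )
    alpha = np.exp(log_alpha)
    fractions = np.empty((n_samples, n_types))
    for i in range(n_samples):
        fractions[i] = rng.dirichlet(alpha[i])

    expected = ref.values @ fractions.T  # CpGs x samples

    non_marker = np.arange(cfg.n_marker_cpgs, cfg.n_cpgs)
    if cfg.signature_size > len(non_marker):
        raise ValueError("signature_size exceeds the number of non-marker CpGs")
    sig_rows = rng.choice(non_marker, size=cfg.signature_size, replace=False)
    sig_rows.sort()
    signs = rng.choice([-1.0, 1.0], size=cfg.signature_size)
    expected[sig_rows, :] = np.clip(
        expected[sig_rows, :] + signs[:, None] * cfg.signature_effect * latent[None, :],
        0.01,
        0.99,
    )

    observed = _beta_noise(expected, cfg.noise_precision, rng)

    sample_ids = pd.Index([f"{cohort_label}_{i:05d}" for i in range(n_samples)], name="sample_id")
    cpg_ids = ref.cpg_ids
    beta = BetaMatrix(pd.DataFrame(observed, index=cpg_ids, columns=sample_ids))
    frac = FractionMatrix(pd.DataFrame(fractions, index=sample_ids, columns=list(cfg.cell_types)))
    pheno = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "cohort": cohort_label,
            "latent_inflammation": latent,
        },
        index=sample_ids,
    )
    signature = Signature(tuple(cpg_ids[sig_rows]), signs)
    return CohortData(beta, frac, pheno, signature)


def make_hierarchical_cohort(
    parent_fractions: np.ndarray | Sequence[Sequence[float]],
    subtype_split: np.ndarray | Sequence[Sequence[float]],
    parent_type: str = "Mono",
    parent_types: Sequence[str] = ("Gran", "CD4T", "Mono"),
    subtypes: Sequence[str] = ("Mono_classical", "Mono_nonclassical"),
    markers_per_type: int = 30,
    noise_precision: float | None = None,
    seed: int = 0,
) -> tuple[ReferenceMatrix, ReferenceMatrix, BetaMatrix]:
    """Nested two-panel cohort for the two-stage subtype estimator.

    ``parent_fractions`` (samples x parent types) and ``subtype_split``
    (samples x subtypes, rows summing to 1) define each sample's
    composition. The parent panel and the subtype panel live on disjoint
    CpG sets; at the subtype panel's CpGs every non-parent cell type sits
    at a fixed baseline of 0.5 (subtype-discriminating CpGs carry no
    signal in other lineages), so noiseless recovery is exact.

    Returns (parent_ref, subtype_ref, beta) where beta spans the union of
    both panels' CpGs.
    """
    parent_fractions = np.atleast_2d(np.asarray(parent_fractions, dtype=float))
    subtype_split = np.atleast_2d(np.asarray(subtype_split, dtype=float))
    if parent_fractions.shape[0] != subtype_split.shape[0]:
        raise ValueError("parent_fractions and subtype_split need one row per sample")
    if not np.allclose(parent_fractions.sum(axis=1), 1.0):
        raise ValueError("parent fraction rows must sum to 1")
    if not np.allclose(subtype_split.sum(axis=1), 1.0):
        raise ValueError("subtype split rows must sum to 1")
    p_idx = list(parent_types).index(parent_type)

    parent_cfg = SimulationConfig(
        n_cpgs=len(parent_types) * markers_per_type + 200,
        cell_types=tuple(parent_types),
        markers_per_type=markers_per_type,
        seed=seed,
    )
    parent_ref = make_reference(parent_cfg)
    sub_cfg = SimulationConfig(
        n_cpgs=len(subtypes) * markers_per_type + 200,
        cell_types=tuple(subtypes),
        markers_per_type=markers_per_type,
        seed=seed + 1,
    )
    sub_raw = make_reference(sub_cfg)
    sub_ids = pd.Index([f"sub_{c}" for c in sub_raw.cpg_ids], name="cpg_id")
    subtype_ref = ReferenceMatrix(pd.DataFrame(sub_raw.values, index=sub_ids, columns=list(subtypes)))

    n = parent_fractions.shape[0]
    parent_part = parent_ref.values @ parent_fractions.T
    mono_abs = parent_fractions[:, p_idx][None, :] * (subtype_ref.values @ subtype_split.T)
    sub_part = 0.5 * (1.0 - parent_fractions[:, p_idx])[None, :] + mono_abs
    values = np.vstack([parent_part, sub_part])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    values = _beta_noise(values, noise_precision, rng)
    sample_ids = pd.Index([f"hier_{i:04d}" for i in range(n)], name="sample_id")
    beta = BetaMatrix(
        pd.DataFrame(values, index=parent_ref.cpg_ids.append(sub_ids), columns=sample_ids)
    )
    return parent_ref, subtype_ref, beta


def make_sorted_samples(
    ref: ReferenceMatrix,
    cell_type: str,
    n: int,
    purity: float = 1.0,
    noise_precision: float | None = 500.0,
    seed: int = 0,
) -> BetaMatrix:
    """Simulate sorted-cell samples of one cell type at a given purity.

    Each sample is ``purity`` of the target type's reference profile plus
    ``(1 - purity)`` split uniformly over the remaining panel types, with
    beta-scale noise at the given precision. Emulates flow-sorted samples
    whose contaminating cells are other leukocytes.
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must be in (0, 1]")
    if cell_type not in ref.cell_types:
        raise ValueError(f"unknown cell type {cell_type!r}; panel has {list(ref.cell_types)}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    n_types = len(ref.cell_types)
    weights = np.full(n_types, (1.0 - purity) / max(n_types - 1, 1))
    weights[ref.cell_types.get_loc(cell_type)] = purity
    mean = ref.values @ weights
    columns = {}
    for i in range(n):
        columns[f"{cell_type}_sorted_{i:03d}"] = _beta_noise(mean, noise_precision, rng)
    return BetaMatrix(pd.DataFrame(columns, index=ref.cpg_ids))
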