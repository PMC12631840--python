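import numpy as np
import pandas as pd
import pytest

import epimix as em


@pytest.fixture(scope="session")
def small_cfg() -> em.SimulationConfig:
    """A desk-scale 5-type panel for fast unit tests."""
    return em.SimulationConfig(
        n_cpgs=400,
        cell_types=("Neu", "Mono", "CD4T", "B", "NK"),
        markers_per_type=20,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_ref(small_cfg) -> em.ReferenceMatrix:
    return em.make_reference(small_cfg)


@pytest.fixture(scope="session")
def planted_dmc_cohort():
    """Sorted samples of two subtypes with 50 planted DMCs among nulls.

    Groups of 10 and 8 samples; planted CpGs differ by 0.4 in mean beta
    (25 hyper, 25 hypo); per-sample noise sd 0.03.
    """
    rng = np.random.default_rng(2024)
    n_null, n_plant, g1, g2 = 5000, 50, 10, 8
    n = n_null + n_plant
    base = rng.uniform(0.25, 0.75, n)
    values = base[:, None] + rng.normal(0.0, 0.03, (n, g1 + g2))
    direction = np.r_[np.full(25, 1.0), np.full(25, -1.0)]
    values[:n_plant, :g1] += 0.2 * direction[:, None]
    values[:n_plant, g1:] -= 0.2 * direction[:, None]
    beta = em.BetaMatrix(
        pd.DataFrame(
            np.clip(values, 0.0, 1.0),
            index=pd.Index([f"cg{i:06d}" for i in range(n)], name="cpg_id"),
            columns=[f"s{i:02d}" for i in range(g1 + g2)],
        )
    )
    labels = pd.Series(["classical"] * g1 + ["nonclassical"] * g2, index=beta.sample_ids)
    planted = set(beta.cpg_ids[:n_plant])
    return beta, labels, planted
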