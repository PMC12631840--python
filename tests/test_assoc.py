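"""Association models and inverse-variance meta-analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import epimix as em


def _fractions(values, cell_types=None):
    values = np.atleast_2d(values)
    cell_types = cell_types or [f"ct{i}" for i in range(values.shape[1])]
    return em.FractionMatrix(
        pd.DataFrame(values, columns=cell_types,
                     index=[f"s{i:04d}" for i in range(values.shape[0])])
    )


def _simulate_cohort(n, beta_effect, seed, noise=1.0):
    rng = np.random.default_rng(seed)
    frac = rng.dirichlet(np.array([5.0, 3.0, 2.0]), size=n)
    fractions = _fractions(frac)
    x = (frac[:, 0] - frac[:, 0].mean()) / frac[:, 0].std(ddof=1)
    outcome = beta_effect * x + noise * rng.standard_normal(n)
    pheno = pd.DataFrame({"outcome": outcome,
                          "age": rng.uniform(20, 80, n),
                          "sex": rng.integers(0, 2, n)},
                         index=fractions.sample_ids)
    return fractions, pheno


class TestCohortAssoc:
    def test_outcome_equal_to_fraction_gives_unit_effect(self):
        fractions, pheno = _simulate_cohort(100, 1.0, 0, noise=0.0)
        table = em.cohort_assoc(fractions, pheno, "outcome")
        assert table.loc["ct0", "effect"] == pytest.approx(1.0, abs=1e-10)
        assert table.loc["ct0", "p"] < 1e-30

    def test_planted_effect_recovered_with_covariates(self):
        fractions, pheno = _simulate_cohort(500, 0.3, 1)
        table = em.cohort_assoc(fractions, pheno, "outcome", covariates=("age", "sex"))
        est = table.loc["ct0"]
        assert est["effect"] == pytest.approx(0.3, abs=3 * est["se"])

    def test_constant_fraction_emits_missing_with_warning(self):
        fractions = _fractions(np.column_stack([np.full(20, 0.4), np.full(20, 0.3),
                                                np.full(20, 0.3)]))
        pheno = pd.DataFrame({"outcome": np.random.default_rng(0).standard_normal(20)},
                             index=fractions.sample_ids)
        with pytest.warns(UserWarning, match="constant"):
            table = em.cohort_assoc(fractions, pheno, "outcome")
        assert table["effect"].isna().all()

    def test_collinear_covariates_error_names_terms(self):
        fractions, pheno = _simulate_cohort(50, 0.2, 3)
        pheno["age2"] = pheno["age"]
        with pytest.raises(ValueError, match="age"):
            em.cohort_assoc(fractions, pheno, "outcome", covariates=("age", "age2"))

    def test_type_one_error_calibrated(self):
        """Null simulations: rejection rate at alpha=0.05 in (0.03, 0.07)."""
        rng = np.random.default_rng(2718)
        n, reps = 150, 1000
        rejections = 0
        for _ in range(reps):
            frac = rng.dirichlet(np.array([5.0, 3.0, 2.0]), size=n)
            x = (frac[:, 0] - frac[:, 0].mean()) / frac[:, 0].std(ddof=1)
            y = rng.standard_normal(n)  # independent of the fraction
            X = np.column_stack([np.ones(n), x])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ coef
            s2 = resid @ resid / (n - 2)
            se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
            p = 2 * stats.t.sf(abs(coef[1] / se), n - 2)
            rejections += p < 0.05
        # sanity-check the fast path against cohort_assoc on one draw
        fractions, pheno = _simulate_cohort(n, 0.0, 7)
        table = em.cohort_assoc(fractions, pheno, "outcome")
        assert 0.03 < rejections / reps < 0.07
        assert 0.0 <= table.loc["ct0", "p"] <= 1.0


class TestFractionTrend:
    def test_equal_weights_match_unweighted_slope(self):
        rng = np.random.default_rng(4)
        n = 120
        age = pd.Series(rng.uniform(20, 90, n), index=[f"d{i}" for i in range(n)])
        frac = pd.Series(0.3 + 0.001 * age.to_numpy() + rng.normal(0, 0.02, n), index=age.index)
        est = em.fraction_trend(frac, age, weights=pd.Series(100.0, index=age.index),
                               min_count=0)
        slope = stats.linregress(age, frac).slope
        assert est.effect == pytest.approx(slope, rel=1e-10)

    def test_count_floor_excludes_donors(self):
        rng = np.random.default_rng(5)
        n = 40
        idx = [f"d{i}" for i in range(n)]
        age = pd.Series(rng.uniform(20, 90, n), index=idx)
        frac = pd.Series(rng.uniform(0.2, 0.4, n), index=idx)
        counts = pd.Series(100.0, index=idx)
        counts.iloc[:5] = 10.0  # below the floor of 30
        est = em.fraction_trend(frac, age, weights=counts, min_count=30)
        assert est.n == n - 5

    def test_weighting_reduces_rmse_under_count_dependent_noise(self):
        rng = np.random.default_rng(6)
        slope_true = 0.002
        err_w, err_u = [], []
        for _ in range(200):
            n = 80
            counts = rng.integers(30, 2000, n).astype(float)
            age = rng.uniform(20, 90, n)
            noise_sd = 0.5 / np.sqrt(counts)
            frac = 0.2 + slope_true * age + rng.normal(0, noise_sd)
            idx = [f"d{i}" for i in range(n)]
            fs = pd.Series(frac, index=idx)
            ag = pd.Series(age, index=idx)
            w = em.fraction_trend(fs, ag, weights=pd.Series(counts, index=idx)).effect
            u = em.fraction_trend(fs, ag, weights=pd.Series(1000.0, index=idx), min_count=0).effect
            err_w.append((w - slope_true) ** 2)
            err_u.append((u - slope_true) ** 2)
        assert np.mean(err_w) < np.mean(err_u)

    def test_all_zero_weights_error(self):
        idx = ["a", "b", "c"]
        with pytest.raises(ValueError, match="zero"):
            em.fraction_trend(pd.Series([0.1, 0.2, 0.3], index=idx),
                              pd.Series([30.0, 40.0, 50.0], index=idx),
                              weights=pd.Series(0.0, index=idx), min_count=0)


class TestMetaFixedRandom:
    def test_single_study_passthrough(self):
        result = em.meta_fixed_random(pd.DataFrame({"effect": [0.3], "se": [0.1]}))
        assert result.fixed_effect == pytest.approx(0.3)
        assert result.random_effect == pytest.approx(0.3)
        assert result.fixed_se == pytest.approx(0.1)
        assert result.tau2 == 0.0 and result.I2 == 0.0

    def test_hand_computed_three_study_example(self):
        """Effects (0.1, 0.3, 0.5), each se 0.1: closed forms give fixed 0.3,
        Q = 8, I2 = 75%, tau2 = 0.03, random se = sqrt(1/75)."""
        result = em.meta_fixed_random(pd.DataFrame({"effect": [0.1, 0.3, 0.5],
                                                    "se": [0.1, 0.1, 0.1]}))
        assert result.fixed_effect == pytest.approx(0.3, abs=1e-12)
        assert result.Q == pytest.approx(8.0, abs=1e-9)
        assert result.I2 == pytest.approx(75.0, abs=1e-9)
        assert result.tau2 == pytest.approx(0.03, abs=1e-12)
        assert result.random_effect == pytest.approx(0.3, abs=1e-12)
        assert result.random_se == pytest.approx(np.sqrt(1 / 75), abs=1e-12)

    def test_identical_studies_have_no_heterogeneity(self):
        result = em.meta_fixed_random(pd.DataFrame({"effect": [0.2] * 5, "se": [0.05] * 5}))
        assert result.Q == pytest.approx(0.0, abs=1e-12)
        assert result.tau2 == 0.0
        assert result.random_effect == pytest.approx(result.fixed_effect)

    def test_agrees_with_metafor_oracle(self):
        """Independent oracle: R's metafor with DerSimonian-Laird tau2."""
        import subprocess, tempfile, pathlib, textwrap

        effects = [0.12, -0.05, 0.31, 0.22, 0.08]
        ses = [0.08, 0.15, 0.11, 0.05, 0.2]
        script = textwrap.dedent(f"""
            suppressMessages(library(metafor))
            y <- c({','.join(map(str, effects))})
            s <- c({','.join(map(str, ses))})
            f <- rma(yi=y, sei=s, method="FE")
            r <- rma(yi=y, sei=s, method="DL")
            cat(coef(f), f$se, coef(r), r$se, r$tau2, r$QE, r$I2, sep="\\n")
        """)
        with tempfile.TemporaryDirectory() as tmp:
            path = pathlib.Path(tmp) / "meta.R"
            path.write_text(script)
            proc = subprocess.run(["Rscript", str(path)], capture_output=True, text=True)
            assert proc.returncode == 0, proc.stderr
            fe, fse, re, rse, tau2, Q, I2 = map(float, proc.stdout.split())
        mine = em.meta_fixed_random(pd.DataFrame({"effect": effects, "se": ses}))
        assert mine.fixed_effect == pytest.approx(fe, rel=1e-6)
        assert mine.fixed_se == pytest.approx(fse, rel=1e-6)
        assert mine.random_effect == pytest.approx(re, rel=1e-6)
        assert mine.random_se == pytest.approx(rse, rel=1e-6)
        assert mine.tau2 == pytest.approx(tau2, rel=1e-6)
        assert mine.Q == pytest.approx(Q, rel=1e-6)
        assert mine.I2 == pytest.approx(I2, rel=1e-4)

    def test_requires_positive_se(self):
        with pytest.raises(ValueError, match="positive"):
            em.meta_fixed_random(pd.DataFrame({"effect": [0.1], "se": [0.0]}))

    @settings(max_examples=50, deadline=None)
    @given(data=st.data())
    def test_pooled_effect_within_range_and_random_se_dominates(self, data):
        k = data.draw(st.integers(1, 8))
        effects = data.draw(st.lists(st.floats(-5, 5), min_size=k, max_size=k))
        ses = data.draw(st.lists(st.floats(0.01, 3), min_size=k, max_size=k))
        result = em.meta_fixed_random(pd.DataFrame({"effect": effects, "se": ses}))
        assert min(effects) - 1e-9 <= result.fixed_effect <= max(effects) + 1e-9
        assert result.random_se >= result.fixed_se - 1e-12
        assert result.tau2 >= 0.0
        assert 0.0 <= result.I2 <= 100.0


class TestEndToEndMeta:
    def test_fifteen_cohort_coverage_and_heterogeneity_ordering(self):
        """Pooled CI covers a common planted effect ~95% of the time; mean
        I2 rises with planted between-cohort effect variance."""
        rng = np.random.default_rng(314)
        beta_true = 0.3

        def run_reps(tau, reps):
            cover, i2s = 0, []
            for _ in range(reps):
                rows = []
                for _c in range(15):
                    n = 120
                    b_c = beta_true + tau * rng.standard_normal()
                    x = rng.standard_normal(n)
                    y = b_c * x + rng.standard_normal(n)
                    X = np.column_stack([np.ones(n), x])
                    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
                    resid = y - X @ coef
                    se = np.sqrt(resid @ resid / (n - 2) * np.linalg.inv(X.T @ X)[1, 1])
                    rows.append({"effect": coef[1], "se": se})
                result = em.meta_fixed_random(pd.DataFrame(rows))
                lo = result.fixed_effect - 1.96 * result.fixed_se
                hi = result.fixed_effect + 1.96 * result.fixed_se
                cover += lo <= beta_true <= hi
                i2s.append(result.I2)
            return cover / reps, float(np.mean(i2s))

        coverage, i2_0 = run_reps(0.0, 300)
        assert 0.92 <= coverage <= 0.98
        _, i2_mid = run_reps(0.15, 60)
        _, i2_high = run_reps(0.4, 60)
        assert i2_0 < i2_mid < i2_high
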