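"""Posterior machinery: probability of direction, convergence
diagnostics, the WBSR hierarchical model and the trajectory GAM."""

import numpy as np
import pandas as pd
import pytest

from thermosweat.heat_balance import DomainError
from thermosweat.inference import (
    ContrastResult,
    PosteriorDraws,
    TrajectoryGAM,
    WBSRHierarchicalModel,
    convergence_diagnostics,
    endpoint_contrast,
    probability_of_direction,
    summarize_contrast,
)


class TestProbabilityOfDirection:
    def test_symmetric_zero_mean(self, rng):
        x = rng.normal(0, 1, 100000)
        assert probability_of_direction(x) == pytest.approx(50.0, abs=1.0)

    def test_constant_sign_is_certain(self, rng):
        assert probability_of_direction(np.abs(rng.normal(0, 1, 500)) + 0.01) == 100.0

    def test_normal_unit_shift_matches_gaussian_orthant(self, rng):
        x = rng.normal(1.0, 1.0, 200000)
        assert probability_of_direction(x) == pytest.approx(84.13, abs=0.5)

    def test_sign_symmetry(self, rng):
        x = rng.normal(0.4, 1.0, 5000)
        assert probability_of_direction(x) == pytest.approx(probability_of_direction(-x))

    def test_all_zero_vector_is_even_split(self):
        assert probability_of_direction(np.zeros(200)) == 50.0

    def test_bounds(self, rng):
        for loc in (-2, -0.5, 0, 0.5, 2):
            pd_ = probability_of_direction(rng.normal(loc, 1, 1000))
            assert 50.0 <= pd_ <= 100.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(DomainError):
            probability_of_direction(np.ones(10))


class TestContrastResult:
    def test_ordering_invariant_enforced(self):
        with pytest.raises(DomainError):
            ContrastResult(mean=5.0, ci90=(1.0, 2.0), pd=90.0)

    def test_summary_of_known_draws(self, rng):
        x = rng.normal(0.2, 0.1, 50000)
        c = summarize_contrast(x)
        assert c.mean == pytest.approx(0.2, abs=0.005)
        assert c.ci90[0] == pytest.approx(0.2 - 1.645 * 0.1, abs=0.01)
        assert c.ci90[1] == pytest.approx(0.2 + 1.645 * 0.1, abs=0.01)
        assert c.pd == pytest.approx(97.7, abs=0.5)


class TestDiagnostics:
    def test_identical_white_noise_chains_rhat_one(self, rng):
        draws = rng.normal(0, 1, size=(2, 2000, 1))
        d = convergence_diagnostics(PosteriorDraws(draws, ["x"]))
        assert d["rhat"]["x"] == pytest.approx(1.0, abs=0.01)
        assert d["ess"]["x"] > 2000

    def test_shifted_chains_flagged(self, rng):
        a = rng.normal(0, 1, size=(2000, 1))
        b = rng.normal(5, 1, size=(2000, 1))
        d = convergence_diagnostics(PosteriorDraws(np.stack([a, b]), ["x"]))
        assert d["rhat"]["x"] > 1.5

    def test_ar1_ess_matches_analytic(self):
        rho, n = 0.5, 20000
        chains = []
        for c in range(2):
            r = np.random.default_rng((11, c))
            e = np.empty(n)
            e[0] = r.normal()
            w = r.normal(0, np.sqrt(1 - rho**2), n - 1)
            for i in range(1, n):
                e[i] = rho * e[i - 1] + w[i - 1]
            chains.append(e[:, None])
        d = convergence_diagnostics(PosteriorDraws(np.stack(chains), ["x"]))
        analytic = 2 * n * (1 - rho) / (1 + rho)
        assert d["ess"]["x"] == pytest.approx(analytic, rel=0.2)

    def test_single_chain_rejected(self, rng):
        with pytest.raises(DomainError):
            convergence_diagnostics(PosteriorDraws(rng.normal(size=(1, 500, 1)), ["x"]))

    def test_ess_grows_with_chains(self, rng):
        two = PosteriorDraws(rng.normal(size=(2, 1000, 1)), ["x"])
        four = PosteriorDraws(rng.normal(size=(4, 1000, 1)), ["x"])
        assert (
            convergence_diagnostics(four)["ess"]["x"]
            > convergence_diagnostics(two)["ess"]["x"]
        )


def wbsr_frame(rng, n=40, slope=50.0, sex_effect=0.0, sigma=80.0, repeats=1):
    rows = []
    for i in range(n):
        sex = "male" if i % 2 == 0 else "female"
        age = rng.uniform(10, 16)
        mu = 500.0 + slope * (age - 13.0) + sex_effect * (sex == "male")
        for _ in range(repeats):
            rows.append({
                "participant": i, "sex": sex, "age": age,
                "wbsr": mu + rng.normal(0, sigma),
            })
    return pd.DataFrame(rows)


class TestWBSRModel:
    def test_slope_recovery(self, rng):
        """Posterior mean age slope within ±15 g/h/yr of the truth,
        averaged over seeded replicates."""
        est = []
        for _ in range(10):
            df = wbsr_frame(rng, n=40, slope=50.0)
            m = WBSRHierarchicalModel(random_state=3).fit(df)
            est.append(m.draws_.stacked()["age_c"].mean())
        assert abs(np.mean(est) - 50.0) < 15.0

    def test_flat_data_slope_concentrates_at_zero(self):
        df = pd.DataFrame({
            "participant": np.arange(20),
            "sex": ["male", "female"] * 10,
            "age": np.linspace(10, 16, 20),
            "wbsr": np.full(20, 500.0),
        })
        m = WBSRHierarchicalModel(random_state=0).fit(df)
        s = m.draws_.stacked()
        assert abs(s["age_c"].mean()) < 2.0
        assert s["sigma"].mean() < 5.0

    def test_posterior_approaches_ols_with_wide_priors(self, rng):
        df = wbsr_frame(rng, n=60, slope=40.0)
        m = WBSRHierarchicalModel(random_state=4).fit(df)
        male = (df.sex == "male").to_numpy(float)
        age_c = df.age.to_numpy() - df.age.mean()
        X = np.column_stack([np.ones(len(df)), male, age_c, male * age_c])
        ols = np.linalg.lstsq(X, df.wbsr.to_numpy(), rcond=None)[0]
        post = m.draws_.stacked()[["intercept", "male", "age_c", "male:age_c"]].mean()
        # priors are weak relative to n=60 likelihood: posterior ~ OLS
        assert np.allclose(post.to_numpy(), ols, atol=12.0)

    def test_repeat_trials_activate_random_intercepts(self, rng):
        df = wbsr_frame(rng, n=15, repeats=2)
        m = WBSRHierarchicalModel(random_state=5).fit(df)
        assert m.uses_random_intercepts_
        assert "tau" in m.draws_.names
        single = wbsr_frame(rng, n=15, repeats=1)
        m2 = WBSRHierarchicalModel(random_state=5).fit(single)
        assert not m2.uses_random_intercepts_

    def test_age_contrast_linearity(self, rng):
        df = wbsr_frame(rng, n=30)
        m = WBSRHierarchicalModel(random_state=6).fit(df)
        c4 = m.age_contrast("female", 11.0, 15.0)
        slope = m.slope_contrast("female")
        assert c4.mean == pytest.approx(4.0 * slope.mean, rel=1e-9)

    def test_minimum_data_enforced(self):
        df = pd.DataFrame({
            "participant": range(5), "sex": ["male"] * 5,
            "age": range(10, 15), "wbsr": [500] * 5,
        })
        with pytest.raises(DomainError):
            WBSRHierarchicalModel().fit(df)

    def test_null_interval_coverage_short(self, rng):
        """90 % interval covers a zero sex effect in most of a small
        batch of null simulations (full 200-replicate check lives in the
        acceptance suite)."""
        hits = 0
        for i in range(20):
            df = wbsr_frame(rng, n=24, slope=0.0, sex_effect=0.0)
            m = WBSRHierarchicalModel(
                n_warmup=200, n_draws=400, random_state=i
            ).fit(df)
            c = m.sex_contrast()
            hits += c.ci90[0] <= 0.0 <= c.ci90[1]
        assert hits >= 14


def gam_frame(rng, n_p=20, sex_gap=0.0, plateau=0.8, noise=0.05):
    rows = []
    for p in range(n_p):
        sex = "male" if p % 2 == 0 else "female"
        age = rng.uniform(10, 16)
        u = rng.normal(0, 0.05)
        for t in np.arange(0, 50, 5.0):
            mu = plateau * (1 - np.exp(-t / 12.0)) + sex_gap * (sex == "male") * t / 45.0
            rows.append({
                "participant": p, "sex": sex, "age": age, "time_min": t,
                "value": 0.05 + mu + u + rng.normal(0, noise),
            })
    return pd.DataFrame(rows)


class TestTrajectoryGAM:
    def test_posterior_mean_curve_tracks_known_smooth(self):
        rng = np.random.default_rng(3)
        df = gam_frame(rng)
        g = TrajectoryGAM(intercept_prior=(0.2, 0.2), random_state=2).fit(df)
        t = np.arange(0, 50, 5.0)
        truth = 0.05 + 0.8 * (1 - np.exp(-t / 12.0))
        curve = g.posterior_mean_curve(t, "female", 13.0)
        assert np.max(np.abs(curve - truth)) < 0.05

    def test_null_sex_contrast_calibrated(self):
        """Zero-truth sex contrast: 90 % interval covers 0 in the bulk
        of replicates."""
        rng = np.random.default_rng(8)
        hits = 0
        for i in range(8):
            df = gam_frame(rng, sex_gap=0.0)
            g = TrajectoryGAM(intercept_prior=(0.2, 0.2), random_state=5 + i).fit(df)
            c = endpoint_contrast(g, {"sex": "male", "age": 13.0}, {"sex": "female", "age": 13.0})
            hits += c.ci90[0] <= 0.0 <= c.ci90[1]
        assert hits >= 5

    def test_real_sex_gap_detected(self):
        rng = np.random.default_rng(9)
        df = gam_frame(rng, sex_gap=0.3, n_p=24)
        g = TrajectoryGAM(intercept_prior=(0.2, 0.2), random_state=6).fit(df)
        c = endpoint_contrast(g, {"sex": "male", "age": 13.0}, {"sex": "female", "age": 13.0})
        assert c.mean == pytest.approx(0.3, abs=0.12)
        assert c.pd > 95.0

    def test_identical_groups_contrast_near_zero(self):
        rng = np.random.default_rng(10)
        df = gam_frame(rng)
        g = TrajectoryGAM(intercept_prior=(0.2, 0.2), random_state=7).fit(df)
        c = endpoint_contrast(g, {"sex": "male", "age": 13.0}, {"sex": "male", "age": 13.0})
        assert c.mean == 0.0
        assert c.pd == pytest.approx(50.0, abs=1.0)

    def test_insufficient_basis_rejected(self):
        rng = np.random.default_rng(11)
        with pytest.raises(DomainError):
            TrajectoryGAM(n_basis=2).fit(gam_frame(rng, n_p=4))

    def test_prediction_outside_support_rejected(self):
        rng = np.random.default_rng(12)
        g = TrajectoryGAM(random_state=1).fit(gam_frame(rng, n_p=6))
        with pytest.raises(DomainError):
            g.predict_draws(120.0, "male", 13.0)
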