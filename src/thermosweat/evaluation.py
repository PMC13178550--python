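"""End-to-end consistency and recovery benchmarks.

Each function here runs one self-contained study-scale check of the
package — generating its own synthetic inputs from a seed, running the
relevant analysis path, and returning the measured quantity.  They back
both the acceptance test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .heat_balance import (
    Anthropometrics,
    Environment,
    GasExchange,
    du_bois_bsa,
    heat_balance_summary,
)
from .inference import (
    PosteriorDraws,
    WBSRHierarchicalModel,
    convergence_diagnostics,
    probability_of_direction,
)
from .onset import OnsetCovariateModel, SegmentedOnsetRegressor
from .pipeline import heat_balance_table
from .synthetic import TruthParams, simulate_study

__all__ = [
    "dubois_worked_examples",
    "conservation_residual",
    "cohort_consistency",
    "onset_recovery",
    "covariate_contrast_coverage",
    "pd_normal_unit_shift",
    "null_interval_coverage",
    "whitenoise_rhat",
    "ar1_ess_ratio",
]


def dubois_worked_examples() -> dict:
    """Body surface area at the printed cohort mean mass/height pairs."""
    return {
        "girls": round(du_bois_bsa(51.0, 1.59), 2),
        "adult_males": round(du_bois_bsa(77.4, 1.81), 2),
    }


def conservation_residual(seed: int = 0, n: int = 1000) -> float:
    """Max |Hprod − (C+R+Eres+Cres) − Ereq| over randomized budgets, W·m⁻²."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n):
            anthro = Anthropometrics(
                mass=rng.uniform(30, 100), height=rng.uniform(1.3, 2.0),
                age=13.0, sex="male",
            )
            hb = heat_balance_summary(
                anthropometrics=anthro,
                gas=GasExchange(rng.uniform(0.5, 4.0), rng.uniform(0.7, 1.0)),
                env=Environment(
                    Ta=rng.uniform(20, 45), RH=rng.uniform(0.1, 0.8),
                    Pb=rng.uniform(700, 780), v=rng.uniform(0.5, 2.5),
                ),
                Tsk=rng.uniform(30, 38),
                speed=rng.uniform(0.5, 2.5), incline=rng.uniform(0, 15),
            )
            worst = max(worst, abs(hb.Hprod - (hb.C + hb.R + hb.EresCres) - hb.Ereq))
    return worst


def cohort_consistency(seed: int = 0, n_per_group: int = 20) -> dict:
    """Simulate both chamber conditions (n_per_group per child group per
    condition) and summarize the realized heat budget."""
    study = simulate_study(n_per_group, TruthParams(seed=seed), with_lsr=False)
    hb = heat_balance_table(study["trials"])
    by_cond = hb.groupby("condition")
    return {
        "hprod_mean": float(hb["hprod_w_m2"].mean()),
        "c_plus_r_warm": float(by_cond.get_group("WARM")["c_plus_r_w_m2"].mean()),
        "c_plus_r_hot": float(by_cond.get_group("HOT")["c_plus_r_w_m2"].mean()),
        "ratio_warm": float(by_cond.get_group("WARM")["ereq_emax"].mean()),
        "ratio_hot": float(by_cond.get_group("HOT")["ereq_emax"].mean()),
        "n_per_condition": int(len(hb) / 2),
    }


def _onset_series(rng, t0, noise_sd, n_min=45):
    t = np.arange(0.0, float(n_min), 1.0)
    y = 0.05 + np.where(t > t0, 1.0 * (1.0 - np.exp(-0.5 * (t - t0))), 0.0)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, len(t))
    return t, y


def onset_recovery(seed: int = 0, n_replicates: int = 200, noise_sd: float = 0.05) -> dict:
    """Median |t̂0 − 13| over noisy replicates, and the noiseless error."""
    rng = np.random.default_rng(seed)
    t, y = _onset_series(rng, 13.0, 0.0)
    est = SegmentedOnsetRegressor(ci_method="asymptotic").fit(t, y)
    noiseless_err = abs(est.t0_ - 13.0)
    errs = []
    for _ in range(n_replicates):
        t, y = _onset_series(rng, 13.0, noise_sd)
        est = SegmentedOnsetRegressor(ci_method="asymptotic").fit(t, y)
        errs.append(abs(est.t0_ - 13.0))
    return {
        "median_error": float(np.median(errs)),
        "noiseless_error": float(noiseless_err),
        "n": n_replicates,
    }


def covariate_contrast_coverage(
    seed: int = 0, n_replicates: int = 100, n_participants: int = 40,
    slope: float = 0.25, noise_sd: float = 0.05,
) -> dict:
    """Fraction of replicates whose 90 % interval for the 4-year onset
    contrast covers the true 4 × slope, through the full two-stage
    estimator (segmented fits, then the weighted covariate model)."""
    rng = np.random.default_rng(seed)
    truth_contrast = 4.0 * slope
    hits = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_replicates):
            rows = []
            for i in range(n_participants):
                sex = "male" if i % 2 == 0 else "female"
                age = rng.uniform(10.0, 16.0)
                t0 = 13.0 + slope * (age - 13.0) + rng.normal(0.0, 1.0)
                t, y = _onset_series(rng, t0, noise_sd)
                fit = SegmentedOnsetRegressor(ci_method="asymptotic").fit(t, y).fit_
                rows.append({"participant": i, "sex": sex, "age": age, **fit.to_row()})
            model = OnsetCovariateModel().fit(pd.DataFrame(rows))
            for sex in ("male", "female"):
                _, (lo, hi) = model.age_contrast(sex)
                hits += lo <= truth_contrast <= hi
    return {
        "coverage_pct": 100.0 * hits / (2 * n_replicates),
        "n": n_replicates,
    }


def pd_normal_unit_shift(seed: int = 0, n: int = 100000) -> float:
    """Pd of draws from Normal(1, 1); Φ(1) ≈ 84.1 %."""
    rng = np.random.default_rng(seed)
    return probability_of_direction(rng.normal(1.0, 1.0, n))


def null_interval_coverage(seed: int = 0, n_replicates: int = 200) -> dict:
    """Coverage of the 90 % credible interval for a zero sex effect in
    the WBSR hierarchical model across null simulations."""
    rng = np.random.default_rng(seed)
    hits = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_replicates):
            n = 24
            sex = np.where(np.arange(n) % 2 == 0, "male", "female")
            age = rng.uniform(10, 16, n)
            wbsr = 500.0 + rng.normal(0.0, 80.0, n)
            df = pd.DataFrame({
                "participant": np.arange(n), "sex": sex, "age": age, "wbsr": wbsr,
            })
            m = WBSRHierarchicalModel(
                n_warmup=200, n_draws=400, check_convergence=False,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(df)
            c = m.sex_contrast()
            hits += c.ci90[0] <= 0.0 <= c.ci90[1]
    return {"coverage_pct": 100.0 * hits / n_replicates, "n": n_replicates}


def whitenoise_rhat(seed: int = 0, n: int = 4000) -> float:
    """Split-R̂ of two independent stationary white-noise chains."""
    rng = np.random.default_rng(seed)
    draws = rng.normal(size=(2, n, 1))
    return convergence_diagnostics(PosteriorDraws(draws, ["x"]))["rhat"]["x"]


def ar1_ess_ratio(seed: int = 0, rho: float = 0.5, n: int = 20000) -> dict:
    """Bulk ESS of an AR(1) chain relative to the analytic
    n_total·(1−ρ)/(1+ρ)."""
    chains = []
    for c in range(2):
        rng = np.random.default_rng((seed, c))
        e = np.empty(n)
        e[0] = rng.normal()
        w = rng.normal(0.0, np.sqrt(1 - rho**2), n - 1)
        for i in range(1, n):
            e[i] = rho * e[i - 1] + w[i - 1]
        chains.append(e[:, None])
    ess = convergence_diagnostics(PosteriorDraws(np.stack(chains), ["x"]))["ess"]["x"]
    analytic = 2 * n * (1 - rho) / (1 + rho)
    return {"ess": float(ess), "analytic": float(analytic), "ratio": float(ess / analytic)}
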