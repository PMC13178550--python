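"""Sweating-onset detection by segmented regression.

A ventilated-capsule local sweat-rate trace is flat (or gently drifting)
during rest and early exercise, then departs into a saturating rise once
the thermoregulatory onset threshold is crossed.  The onset time t0 is
estimated by fitting

    LSR(t) = a + b·t                                      for t <= t0
    LSR(t) = a + b·t0 + A·(1 − exp(−k·(t − t0)))          for t >  t0

(continuous at t0) by least squares: a grid search over t0 at 0.1-min
resolution with the conditionally linear parameters (a, b, A) profiled
out over a small grid of rate constants k, followed by a full nonlinear
refinement.  A logistic alternative for the rising segment is available.

Estimated onsets are then related to age and sex with a weighted linear
model (``OnsetCovariateModel``), weights inverse to the squared CI width
of each onset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .heat_balance import DomainError

__all__ = ["SegmentedFit", "SegmentedOnsetRegressor", "OnsetCovariateModel", "fit_segmented_onset"]


@dataclass
class SegmentedFit:
    """Result of one segmented onset fit."""

    t0: float  # onset time, min
    a: float  # baseline intercept
    b: float  # baseline slope
    A: float  # asymptote amplitude, mg·cm⁻²·min⁻¹
    k: float  # rate constant, min⁻¹
    rss: float
    sigma: float  # residual SD
    ci90: tuple[float, float]
    converged: bool = True
    onset_detected: bool = True
    f_statistic: float = field(default=np.nan)

    def to_row(self) -> dict:
        return {
            "t0": self.t0,
            "ci_lo": self.ci90[0],
            "ci_hi": self.ci90[1],
            "a": self.a,
            "b": self.b,
            "A": self.A,
            "k": self.k,
            "rss": self.rss,
            "converged": self.converged,
            "onset_detected": self.onset_detected,
        }


def _segmented_curve(t, t0, a, b, A, k, form="exponential"):
    base = a + b * np.minimum(t, t0)
    rise = np.zeros_like(t, dtype=float)
    post = t > t0
    if form == "exponential":
        rise[post] = A * (1.0 - np.exp(-k * (t[post] - t0)))
    elif form == "logistic":
        # continuous at t0 with value 0, saturating at A
        rise[post] = A * (2.0 / (1.0 + np.exp(-k * (t[post] - t0))) - 1.0)
    else:
        raise ValueError(f"unknown rise form {form!r}")
    return base + rise


class SegmentedOnsetRegressor(RegressorMixin, BaseEstimator):
    """Estimate the sweating-onset threshold time of one LSR series.

    Parameters
    ----------
    grid_step : float
        Resolution of the t0 grid search, minutes.
    k_grid : tuple of float
        Rate constants profiled during the grid search (min⁻¹); the best
        grid point seeds a full nonlinear refinement.
    rise_form : {"exponential", "logistic"}
        Shape of the post-onset asymptotic growth segment.
    min_points_per_segment : int
        Candidate onsets must leave at least this many observations on
        each side.
    f_alpha : float
        Significance level of the F-test against the single-line null;
        failing it yields a "no onset detected" result, not an error.
    ci_method : {"bootstrap", "asymptotic"}
        90 % CI for t0: parametric bootstrap (default) or the
        delta-method interval from the linearized fit, which is much
        cheaper in large simulation studies.
    n_boot : int
        Parametric bootstrap resamples.
    random_state : int | None
        Seeds the bootstrap.

    Attributes
    ----------
    fit_ : SegmentedFit
        Full parameter set, onset CI and diagnostics.
    t0_ : float
        Estimated onset time (NaN when no onset is detected).
    """

    def __init__(
        self,
        grid_step: float = 0.1,
        k_grid: tuple = (0.05, 0.1, 0.2, 0.4, 0.8, 1.6),
        rise_form: str = "exponential",
        min_points_per_segment: int = 3,
        f_alpha: float = 0.05,
        ci_method: str = "bootstrap",
        n_boot: int = 500,
        random_state: int | None = 0,
    ):
        self.grid_step = grid_step
        self.k_grid = k_grid
        self.rise_form = rise_form
        self.min_points_per_segment = min_points_per_segment
        self.f_alpha = f_alpha
        self.ci_method = ci_method
        self.n_boot = n_boot
        self.random_state = random_state

    # ---- internals -------------------------------------------------

    def _profile_grid(self, t, y):
        """Best (rss, params) over the (t0, k) grid; linear params solved
        exactly at each grid point.  Ties break toward the smallest t0."""
        m = self.min_points_per_segment
        t0_lo, t0_hi = t[m - 1], t[-m]
        t0_grid = np.arange(t0_lo, t0_hi + 1e-9, self.grid_step)
        best = (np.inf, None)
        ones = np.ones_like(t)
        for t0 in t0_grid:
            tpre = np.minimum(t, t0)
            for k in self.k_grid:
                rise = np.where(
                    t > t0,
                    (1.0 - np.exp(-k * np.clip(t - t0, 0, None)))
                    if self.rise_form == "exponential"
                    else (2.0 / (1.0 + np.exp(-k * np.clip(t - t0, 0, None))) - 1.0),
                    0.0,
                )
                X = np.column_stack([ones, tpre, rise])
                coef, rss, rank, _ = np.linalg.lstsq(X, y, rcond=None)
                if rank < 3 or coef[2] < 0:
                    # amplitude must be non-negative: refit with A = 0
                    X2 = X[:, :2]
                    coef2, rss2, _, _ = np.linalg.lstsq(X2, y, rcond=None)
                    coef = np.array([coef2[0], coef2[1], 0.0])
                    resid = y - X2 @ coef2
                    rss_val = float(resid @ resid)
                else:
                    rss_val = float(rss[0]) if len(rss) else float(
                        np.sum((y - X @ coef) ** 2)
                    )
                if rss_val < best[0] - 1e-15:
                    best = (rss_val, (t0, coef[0], coef[1], coef[2], k))
        return best

    def _refine(self, t, y, seed_params):
        t0, a, b, A, k = seed_params
        lo = [t[self.min_points_per_segment - 1], -np.inf, -np.inf, 0.0, 1e-4]
        hi = [t[-self.min_points_per_segment], np.inf, np.inf, np.inf, 50.0]
        x0 = np.clip([t0, a, b, max(A, 1e-9), max(k, 1e-3)], lo, hi)

        def resid(p):
            return _segmented_curve(t, *p, form=self.rise_form) - y

        try:
            sol = optimize.least_squares(resid, x0, bounds=(lo, hi), method="trf")
            if sol.cost * 2 <= np.sum(resid(x0) ** 2) + 1e-12:
                return sol.x, float(2 * sol.cost), True
        except Exception:  # pragma: no cover - optimizer pathology
            pass
        return x0, float(np.sum(resid(x0) ** 2)), False

    def _t0_ci(self, t, y, params, rss, rng):
        n = len(t)
        dof = max(n - 5, 1)
        sigma = np.sqrt(rss / dof)
        if self.ci_method == "asymptotic":
            # delta method on the refined least-squares fit
            def resid(p):
                return _segmented_curve(t, *p, form=self.rise_form) - y

            eps = np.maximum(1e-6, 1e-6 * np.abs(params))
            J = np.empty((n, 5))
            for j in range(5):
                pp = params.copy()
                pm = params.copy()
                pp[j] += eps[j]
                pm[j] -= eps[j]
                J[:, j] = (resid(pp) - resid(pm)) / (2 * eps[j])
            try:
                cov = sigma**2 * np.linalg.pinv(J.T @ J)
                se = np.sqrt(max(cov[0, 0], 0.0))
            except np.linalg.LinAlgError:  # pragma: no cover
                se = self.grid_step
            z = stats.norm.ppf(0.95)
            return (params[0] - z * se, params[0] + z * se), sigma
        # parametric bootstrap: resample noise on the fitted curve, refit on
        # a reduced grid around the estimate
        yhat = _segmented_curve(t, *params, form=self.rise_form)
        t0s = np.empty(self.n_boot)
        saved = (self.grid_step, self.k_grid)
        for i in range(self.n_boot):
            yb = yhat + rng.normal(0.0, sigma, size=n)
            rssb, pb = self._profile_grid_window(t, yb, params[0])
            t0s[i] = pb[0]
        lo, hi = np.quantile(t0s, [0.05, 0.95])
        return (float(lo), float(hi)), sigma

    def _profile_grid_window(self, t, y, t0_center, half_width=4.0):
        """Grid search restricted to a window around a known estimate —
        the bootstrap fast path."""
        m = self.min_points_per_segment
        t0_lo = max(t[m - 1], t0_center - half_width)
        t0_hi = min(t[-m], t0_center + half_width)
        t0_grid = np.arange(t0_lo, t0_hi + 1e-9, self.grid_step)
        ones = np.ones_like(t)
        best = (np.inf, None)
        for t0 in t0_grid:
            tpre = np.minimum(t, t0)
            for k in self.k_grid:
                dt = np.clip(t - t0, 0, None)
                rise = np.where(
                    t > t0,
                    (1.0 - np.exp(-k * dt))
                    if self.rise_form == "exponential"
                    else (2.0 / (1.0 + np.exp(-k * dt)) - 1.0),
                    0.0,
                )
                X = np.column_stack([ones, tpre, rise])
                coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
                if coef[2] < 0:
                    continue
                r = y - X @ coef
                rss = float(r @ r)
                if rss < best[0] - 1e-15:
                    best = (rss, (t0, coef[0], coef[1], coef[2], k))
        if best[1] is None:  # pragma: no cover - all-negative amplitudes
            best = self._profile_grid(t, y)
        return best

    # ---- API -------------------------------------------------------

    def fit(self, X, y=None):
        """Fit the segmented model.

        ``X`` is the time vector in minutes (1-D or a single column) and
        ``y`` the minute-mean LSR values.
        """
        t = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if t.shape != y.shape:
            raise DomainError("time and LSR vectors must have equal length")
        if len(t) < 2 * self.min_points_per_segment + 1 or len(t) < 15:
            raise DomainError(
                f"need at least 15 points with {self.min_points_per_segment} "
                "per segment around every candidate onset"
            )
        if np.any(np.diff(t) <= 0):
            raise DomainError("time must be strictly increasing")

        rng = np.random.default_rng(self.random_state)

        # single-line null
        X0 = np.column_stack([np.ones_like(t), t])
        beta0, _, _, _ = np.linalg.lstsq(X0, y, rcond=None)
        rss0 = float(np.sum((y - X0 @ beta0) ** 2))

        rss_grid, seed = self._profile_grid(t, y)
        params, rss, converged = self._refine(t, y, seed)
        if rss > rss_grid:
            params = np.asarray(seed, dtype=float)
            rss = rss_grid

        n = len(t)
        df_extra = 3  # t0, A, k beyond the two-parameter line
        df_resid = n - 5
        with np.errstate(divide="ignore", invalid="ignore"):
            f_stat = ((rss0 - rss) / df_extra) / (rss / df_resid) if rss > 0 else np.inf
        f_crit = stats.f.ppf(1 - self.f_alpha, df_extra, df_resid)
        detected = bool(f_stat > f_crit) and params[3] > 0

        if not detected:
            sigma0 = np.sqrt(rss0 / max(n - 2, 1))
            self.fit_ = SegmentedFit(
                t0=np.nan, a=float(beta0[0]), b=float(beta0[1]), A=0.0,
                k=np.nan, rss=rss0, sigma=float(sigma0),
                ci90=(np.nan, np.nan), converged=True,
                onset_detected=False, f_statistic=float(f_stat),
            )
            self.t0_ = np.nan
            return self

        ci, sigma = self._t0_ci(t, y, np.asarray(params, float), rss, rng)
        self.fit_ = SegmentedFit(
            t0=float(params[0]), a=float(params[1]), b=float(params[2]),
            A=float(params[3]), k=float(params[4]), rss=float(rss),
            sigma=float(sigma), ci90=ci, converged=converged,
            onset_detected=True, f_statistic=float(f_stat),
        )
        self.t0_ = float(params[0])
        return self

    def predict(self, X):
        """Fitted LSR at times ``X`` (minutes)."""
        f = self.fit_
        t = np.asarray(X, dtype=float).ravel()
        if not f.onset_detected:
            return f.a + f.b * t
        return _segmented_curve(t, f.t0, f.a, f.b, f.A, f.k, form=self.rise_form)


def fit_segmented_onset(time_min, lsr, **kwargs) -> SegmentedFit:
    """Functional wrapper: fit one series, return the SegmentedFit."""
    est = SegmentedOnsetRegressor(**kwargs)
    est.fit(time_min, lsr)
    return est.fit_


class OnsetCovariateModel(RegressorMixin, BaseEstimator):
    """Relate estimated onset times to age and sex.

    Weighted least squares of onset ~ sex + age + sex:age.  Each onset
    estimate carries a standard error derived from its 90 % CI width;
    because between-participant onset scatter usually dominates the
    within-series estimation error, weights are random-effects style,
    1/(se_i² + τ²), with τ² the between-participant variance estimated
    by the method of moments from an initial unweighted fit (equal
    weights when CIs are unavailable).  Age is centred at the cohort
    grand mean so the intercept is the mean-age onset.

    Attributes
    ----------
    params_ : pd.Series
        Coefficients (intercept, male, age_c, male:age_c).
    cov_ : pd.DataFrame
        Coefficient covariance.
    age_center_ : float
    """

    def __init__(self, age_center: float | None = None, ci_level: float = 0.90):
        self.age_center = age_center
        self.ci_level = ci_level

    def _design(self, age_c, male):
        return np.column_stack(
            [np.ones_like(age_c), male, age_c, male * age_c]
        )

    def fit(self, X, y=None):
        """``X``: DataFrame with columns t0, age, sex and optionally
        ci_lo/ci_hi (used for weighting).  ``y`` is ignored."""
        df = pd.DataFrame(X).copy()
        df = df[np.isfinite(df["t0"])]
        male = (df["sex"].astype(str) == "male").to_numpy(dtype=float)
        n_m, n_f = int(male.sum()), int((1 - male).sum())
        self.single_sex_ = n_m == 0 or n_f == 0
        if min(n_m, n_f) and min(n_m, n_f) < 8:
            warnings.warn(
                f"fewer than 8 onset fits per sex (male={n_m}, female={n_f})",
                stacklevel=2,
            )
        if self.single_sex_:
            warnings.warn(
                "single-sex input: model degrades to age-only", stacklevel=2
            )
        self.age_center_ = (
            float(df["age"].mean()) if self.age_center is None else self.age_center
        )
        age_c = df["age"].to_numpy(dtype=float) - self.age_center_

        y_ = df["t0"].to_numpy(dtype=float)

        if self.single_sex_:
            Xd = np.column_stack([np.ones_like(age_c), age_c])
            names = ["intercept", "age_c"]
        else:
            Xd = self._design(age_c, male)
            names = ["intercept", "male", "age_c", "male:age_c"]

        z90 = stats.norm.ppf(0.95)
        if {"ci_lo", "ci_hi"}.issubset(df.columns) and df["ci_hi"].notna().all():
            se = ((df["ci_hi"] - df["ci_lo"]).to_numpy(dtype=float)) / (2.0 * z90)
            # between-participant variance by the method of moments from an
            # unweighted pilot fit: total scatter minus mean estimation error
            b_ols, _, _, _ = np.linalg.lstsq(Xd, y_, rcond=None)
            r = y_ - Xd @ b_ols
            dof0 = max(len(y_) - Xd.shape[1], 1)
            tau2 = max(float(r @ r) / dof0 - float(np.mean(se**2)), 0.0)
            w = 1.0 / (se**2 + tau2 + 1e-12)
        else:
            w = np.ones(len(df))

        sw = np.sqrt(w)
        Xw, yw = Xd * sw[:, None], y_ * sw
        beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        resid = yw - Xw @ beta
        dof = max(len(y_) - Xd.shape[1], 1)
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.pinv(Xw.T @ Xw)

        self.params_ = pd.Series(beta, index=names)
        self.cov_ = pd.DataFrame(cov, index=names, columns=names)
        self.dof_ = dof
        self.age_range_ = (float(df["age"].min()), float(df["age"].max()))
        self.weighted_mean_onset_ = float(np.sum(w * y_) / np.sum(w))
        return self

    def _lincomb(self, c):
        est = float(c @ self.params_.to_numpy())
        se = float(np.sqrt(c @ self.cov_.to_numpy() @ c))
        tcrit = stats.t.ppf(0.5 + self.ci_level / 2, self.dof_)
        return est, (est - tcrit * se, est + tcrit * se)

    def _contrast_vector(self, age, sex):
        age_c = age - self.age_center_
        if self.single_sex_:
            return np.array([1.0, age_c])
        male = 1.0 if sex == "male" else 0.0
        return np.array([1.0, male, age_c, male * age_c])

    def predict_onset(self, age: float, sex: str):
        """Predicted onset (min) with CI at the requested covariates."""
        lo, hi = self.age_range_
        if not (lo <= age <= hi):
            warnings.warn(
                f"age {age} outside observed range [{lo}, {hi}]: extrapolating",
                stacklevel=2,
            )
        return self._lincomb(self._contrast_vector(age, sex))

    def slope(self, sex: str):
        """Per-year onset slope for one sex, with CI."""
        if self.single_sex_:
            c = np.array([0.0, 1.0])
        else:
            c = np.array([0.0, 0.0, 1.0, 1.0 if sex == "male" else 0.0])
        return self._lincomb(c)

    def age_contrast(self, sex: str, age_lo: float = 11.0, age_hi: float = 15.0):
        """Onset difference over an age span (default 11 → 15 years)."""
        c = self._contrast_vector(age_hi, sex) - self._contrast_vector(age_lo, sex)
        return self._lincomb(c)

    def effect_table(self) -> pd.DataFrame:
        """Per-sex slopes and the 4-year (11→15) contrasts with CIs."""
        rows = []
        sexes = ["male", "female"] if not self.single_sex_ else [None]
        for sex in sexes:
            s, s_ci = self.slope(sex) if sex else self._lincomb(np.array([0.0, 1.0]))
            d, d_ci = self.age_contrast(sex) if sex else (4 * s, (4 * s_ci[0], 4 * s_ci[1]))
            rows.append(
                {
                    "sex": sex or "all",
                    "slope_min_per_yr": s,
                    "slope_lo": s_ci[0],
                    "slope_hi": s_ci[1],
                    "contrast_4yr_min": d,
                    "contrast_lo": d_ci[0],
                    "contrast_hi": d_ci[1],
                }
            )
        return pd.DataFrame(rows)
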