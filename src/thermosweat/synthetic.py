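"""Synthetic cohorts and trials with exported ground truth.

Emulates a paediatric/adult exercise-thermoregulation study: groups of
boys, girls, adult males and adult females walk 45 min on a treadmill at
a target metabolic heat production of 300 W·m⁻² in WARM (30 °C, 40 % RH)
or HOT (40 °C, 30 % RH) chambers.  Every latent quantity that the
analysis pipeline later estimates — onset times, plateau amplitudes,
whole-body sweat rates, heat-budget components — is generated from an
explicit ``TruthParams`` and exported for recovery scoring.

All randomness flows from a single integer seed through numpy's PCG64
generator, so a fixed seed reproduces the study byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .heat_balance import (
    Anthropometrics,
    Environment,
    GasExchange,
    heat_balance_summary,
)
from .records import TrialRecord
from .sweat_metrics import MassLedger, metabolic_mass_loss_rate, respiratory_mass_loss_rate

__all__ = [
    "TruthParams",
    "CONDITIONS",
    "GROUP_DISTRIBUTIONS",
    "generate_cohort",
    "simulate_trial",
    "simulate_lsr_series",
    "simulate_study",
    "export_truth",
]

#: Chamber conditions (Ta °C, RH fraction).
CONDITIONS = {"WARM": (30.0, 0.40), "HOT": (40.0, 0.30)}

#: Group-level anthropometric distributions: mean (SD) of age, height,
#: mass, with age truncation bounds.
GROUP_DISTRIBUTIONS = {
    "boy": {"sex": "male", "age": (13.5, 1.4, 10.0, 16.0),
            "height": (1.65, 0.12), "mass": (55.4, 14.8)},
    "girl": {"sex": "female", "age": (13.3, 1.9, 10.0, 16.0),
             "height": (1.59, 0.09), "mass": (51.0, 9.1)},
    "adult_male": {"sex": "male", "age": (26.8, 5.3, 19.0, 37.0),
                   "height": (1.81, 0.06), "mass": (77.4, 7.0)},
    "adult_female": {"sex": "female", "age": (28.5, 3.8, 19.0, 37.0),
                     "height": (1.64, 0.04), "mass": (62.4, 10.7)},
}


@dataclass(frozen=True)
class TruthParams:
    """Latent generator parameters — the quantities recovery tests score.

    Onset times are on the chamber clock: 10 min seated rest then 45 min
    of walking, so the default 13-min onset falls ~3 min into exercise.
    """

    onset_base: float = 13.0  # min, at age 13, female
    onset_age_slope: float = 0.25  # min·yr⁻¹
    onset_sex_offset: float = 0.6  # min, male − female
    onset_jitter_sd: float = 1.0  # min, between-participant
    arm_onset_delay: float = 1.0  # min, arm after back
    lsr_plateau_scale: float = 0.72  # (mg·cm⁻²·min⁻¹) per unit Ereq/Emax, back
    arm_plateau_factor: float = 0.78
    lsr_baseline: float = 0.05  # mg·cm⁻²·min⁻¹ resting
    lsr_rise_rate: float = 0.30  # min⁻¹
    wbsr_per_ereq: float = 1.6  # g·h⁻¹ per W of Ereq
    noise_sd_lsr: float = 0.05  # mg·cm⁻²·min⁻¹, marginal AR(1) SD
    ar1_rho: float = 0.8  # at the 5-s cadence
    tgi_rise: float = 0.13  # °C per W·kg⁻¹ of Hprod
    tgi_time_constant: float = 20.0  # min
    hprod_target: float = 300.0  # W·m⁻²
    hprod_noise_sd: float = 10.0  # W·m⁻², between-trial
    tsk_warm: float = 34.0  # °C
    tsk_hot: float = 37.2  # °C
    tsk_sd: float = 0.5
    rer_mean: float = 0.85
    rer_sd: float = 0.05
    clothing_mass: float = 0.30  # kg
    mass_noise_sd_g: float = 0.0  # measurement noise on the scale
    rest_min: float = 10.0
    exercise_min: float = 45.0
    seed: int = 0

    def __post_init__(self):
        for name in ("onset_jitter_sd", "noise_sd_lsr", "hprod_noise_sd",
                     "tsk_sd", "rer_sd", "mass_noise_sd_g"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not abs(self.ar1_rho) < 1:
            raise ValueError("ar1_rho must satisfy |rho| < 1")


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def speed_for_height(height: float) -> float:
    """Treadmill belt speed rule, km·h⁻¹ by stature (5.0–6.0 range)."""
    if height < 1.55:
        return 5.0
    if height <= 1.70:
        return 5.5
    return 6.0


def generate_cohort(
    n_per_group: int,
    truth: TruthParams | None = None,
    groups: tuple = ("boy", "girl"),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sample a cohort from the group anthropometric distributions.

    Heights and masses are truncated normals (3 SD, floored at plausible
    minima); BSA is always derived from sampled mass and height via
    Du Bois, never sampled directly.
    """
    truth = truth or TruthParams()
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = rng or np.random.default_rng(truth.seed)
    rows = []
    for group in groups:
        spec = GROUP_DISTRIBUTIONS[group]
        age_m, age_sd, age_lo, age_hi = spec["age"]
        ages = _truncnorm(rng, age_m, age_sd, age_lo, age_hi, n_per_group)
        h_m, h_sd = spec["height"]
        heights = _truncnorm(rng, h_m, h_sd, h_m - 3 * h_sd, h_m + 3 * h_sd, n_per_group)
        m_m, m_sd = spec["mass"]
        masses = _truncnorm(rng, m_m, m_sd, max(m_m - 3 * m_sd, 25.0), m_m + 3 * m_sd,
                            n_per_group)
        for i in range(n_per_group):
            anthro = Anthropometrics(
                mass=float(masses[i]), height=float(heights[i]),
                age=float(ages[i]), sex=spec["sex"],
            )
            rows.append({
                "participant": f"{group}_{i:03d}", "group": group,
                "sex": spec["sex"], "age": anthro.age, "height": anthro.height,
                "mass": anthro.mass, "bsa": anthro.bsa,
            })
    return pd.DataFrame(rows)


# ACSM-style walking economy: VO2 (mL·kg⁻¹·min⁻¹) = 3.5 + 0.1·v + 1.8·v·grade
# with v in m·min⁻¹.  Used only to invert the protocol: the incline is the
# value at which the implied heat production hits the trial target.
def _vo2_walking(mass: float, v_ms: float, incline: float) -> float:
    v_mpm = v_ms * 60.0
    return mass * (3.5 + 0.1 * v_mpm + 1.8 * v_mpm * incline / 100.0) / 1000.0


def solve_trial_workrate(
    anthro: Anthropometrics, v_ms: float, rer: float, hprod_target: float
) -> tuple[float, float]:
    """Incline (%) and VO2 (L·min⁻¹) that realize the target Hprod/BSA."""

    def gap(incline):
        vo2 = _vo2_walking(anthro.mass, v_ms, incline)
        hb = heat_balance_summary(
            anthropometrics=anthro, gas=GasExchange(vo2, rer),
            env=Environment(Ta=25.0, RH=0.5, v=v_ms), Tsk=33.0,
            speed=v_ms, incline=incline,
        )
        return hb.Hprod - hprod_target

    lo, hi = 0.0, 25.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError(
            f"target Hprod {hprod_target} W·m⁻² unreachable with incline in "
            f"[0, 25] % at speed {v_ms:.2f} m·s⁻¹"
        )
    incline = optimize.brentq(gap, lo, hi, xtol=1e-6)
    return float(incline), float(_vo2_walking(anthro.mass, v_ms, incline))


def simulate_trial(
    participant: pd.Series | dict,
    condition: str,
    truth: TruthParams | None = None,
    rng: np.random.Generator | None = None,
) -> TrialRecord:
    """Simulate one experimental trial for one participant.

    The treadmill incline and VO2 are solved so the realized Hprod/BSA
    equals the 300 W·m⁻² target plus trial-level noise; the mass ledger
    closes exactly on integrated sweat + respiratory + metabolic losses
    before optional scale noise.
    """
    truth = truth or TruthParams()
    rng = rng or np.random.default_rng(truth.seed)
    p = dict(participant)
    anthro = Anthropometrics(
        mass=p["mass"], height=p["height"], age=p["age"], sex=p["sex"], bsa=p.get("bsa", 0.0)
    )
    ta, rh = CONDITIONS[condition]
    v_ms = speed_for_height(anthro.height) / 3.6
    env = Environment(Ta=ta, RH=rh, v=v_ms)
    rer = float(np.clip(rng.normal(truth.rer_mean, truth.rer_sd), 0.7, 1.0))
    target = truth.hprod_target + rng.normal(0.0, truth.hprod_noise_sd)
    incline, vo2 = solve_trial_workrate(anthro, v_ms, rer, target)
    gas = GasExchange(vo2, rer)
    tsk_mu = truth.tsk_warm if condition == "WARM" else truth.tsk_hot
    tsk = float(rng.normal(tsk_mu, truth.tsk_sd))

    hb = heat_balance_summary(
        anthropometrics=anthro, gas=gas, env=env, Tsk=tsk, speed=v_ms, incline=incline
    )

    duration = truth.exercise_min
    wbsr_true = truth.wbsr_per_ereq * hb.Ereq_W  # g·h⁻¹
    sweat_g = wbsr_true * duration / 60.0
    resp_g = respiratory_mass_loss_rate(hb.M, anthro.bsa, env) * duration
    metab_g = metabolic_mass_loss_rate(gas) * duration
    noise_kg = rng.normal(0.0, truth.mass_noise_sd_g / 1000.0) if truth.mass_noise_sd_g else 0.0
    pre_clothed = anthro.mass + truth.clothing_mass
    post_clothed = pre_clothed - (sweat_g + resp_g + metab_g) / 1000.0 + noise_kg
    ledger = MassLedger(
        pre_clothed=pre_clothed, post_clothed=post_clothed,
        clothing_pre=truth.clothing_mass, clothing_post=truth.clothing_mass,
        duration=duration,
    )

    # gastrointestinal temperature: saturating rise scaled by Hprod per kg
    t_min = np.arange(0.0, truth.rest_min + duration + 1e-9, 0.25)
    t_ex = np.clip(t_min - truth.rest_min, 0.0, None)
    d_tgi = truth.tgi_rise * (hb.Hprod_W / anthro.mass)
    tgi = 37.0 + d_tgi * (1.0 - np.exp(-t_ex / truth.tgi_time_constant))
    tgi_df = pd.DataFrame({"time_s": t_min * 60.0, "tgi": tgi})

    usg = float(np.clip(rng.normal(1.016, 0.006), 1.002, 1.035))
    trial = TrialRecord(
        participant=p["participant"], group=p["group"], condition=condition,
        anthropometrics=anthro, env=env, gas=gas, speed=v_ms, incline=incline,
        tsk_mean=tsk, ledger=ledger, usg=usg, tgi=tgi_df,
        exercise_start_min=truth.rest_min,
        truth={
            "hprod_target": float(target), "wbsr_true": float(wbsr_true),
            "ereq": hb.Ereq, "emax": hb.Emax, "ratio": hb.ratio,
            "sweat_g": float(sweat_g), "resp_g": float(resp_g),
            "metab_g": float(metab_g), "delta_tgi": float(d_tgi),
        },
    )
    return trial


def _ar1_noise(rng, n, rho, marginal_sd):
    if marginal_sd == 0:
        return np.zeros(n)
    e = np.empty(n)
    e[0] = rng.normal(0.0, marginal_sd)
    innov_sd = marginal_sd * np.sqrt(1.0 - rho**2)
    w = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        e[i] = rho * e[i - 1] + w[i - 1]
    return e


def simulate_lsr_series(
    participant: pd.Series | dict,
    trial: TrialRecord,
    truth: TruthParams | None = None,
    rng: np.random.Generator | None = None,
    sites: tuple = ("back", "arm"),
) -> dict:
    """Ventilated-capsule LSR series at 5-s cadence for each site.

    LSR(t) = baseline + A·(1 − e^{−k (t − t0)})·1[t > t0] + AR(1) noise,
    with the onset t0 = base + slope·(age − 13) + offset·1[male] + jitter
    (resampled into the window if it falls outside) and the plateau A
    proportional to the trial's Ereq/Emax.  Returns
    {site: (DataFrame(time_s, lsr), truth_dict)}.
    """
    truth = truth or TruthParams()
    rng = rng or np.random.default_rng(truth.seed)
    p = dict(participant)
    total_min = truth.rest_min + truth.exercise_min
    t = np.arange(0.0, total_min * 60.0, 5.0) / 60.0  # minutes
    male = 1.0 if p["sex"] == "male" else 0.0
    ratio = trial.truth.get("ratio", 1.0)

    out = {}
    for site in sites:
        for _ in range(100):
            jitter = rng.normal(0.0, truth.onset_jitter_sd)
            t0 = (
                truth.onset_base
                + truth.onset_age_slope * (p["age"] - 13.0)
                + truth.onset_sex_offset * male
                + (truth.arm_onset_delay if site == "arm" else 0.0)
                + jitter
            )
            if truth.rest_min * 0.3 < t0 < total_min - 10.0:
                break
        else:  # pragma: no cover - pathological truth parameters
            raise ValueError("onset truth repeatedly falls outside the trial window")
        A = truth.lsr_plateau_scale * ratio * (
            truth.arm_plateau_factor if site == "arm" else 1.0
        )
        clean = truth.lsr_baseline + np.where(
            t > t0, A * (1.0 - np.exp(-truth.lsr_rise_rate * (t - t0))), 0.0
        )
        noisy = np.clip(clean + _ar1_noise(rng, len(t), truth.ar1_rho, truth.noise_sd_lsr), 0.0, None)
        df = pd.DataFrame({"time_s": t * 60.0, "lsr": noisy})
        out[site] = (df, {"t0": float(t0), "A": float(A), "k": truth.lsr_rise_rate,
                          "baseline": truth.lsr_baseline, "site": site})
    return out


def simulate_study(
    n_per_group: int,
    truth: TruthParams | None = None,
    groups: tuple = ("boy", "girl"),
    conditions: tuple = ("WARM", "HOT"),
    with_lsr: bool = True,
) -> dict:
    """End-to-end study bundle: cohort, trials, LSR series, truth table."""
    truth = truth or TruthParams()
    rng = np.random.default_rng(truth.seed)
    cohort = generate_cohort(n_per_group, truth, groups=groups, rng=rng)
    trials, lsr, truth_rows = [], {}, []
    for _, row in cohort.iterrows():
        for condition in conditions:
            trial = simulate_trial(row, condition, truth, rng)
            trials.append(trial)
            key = (row["participant"], condition)
            rec = {
                "participant": row["participant"], "group": row["group"],
                "sex": row["sex"], "age": row["age"], "condition": condition,
                **trial.truth,
            }
            if with_lsr:
                series = simulate_lsr_series(row, trial, truth, rng)
                lsr[key] = {s: df for s, (df, _) in series.items()}
                for s, (_, tr) in series.items():
                    rec[f"t0_{s}"] = tr["t0"]
                    rec[f"A_{s}"] = tr["A"]
            truth_rows.append(rec)
    return {
        "cohort": cohort,
        "trials": trials,
        "lsr": lsr,
        "truth": pd.DataFrame(truth_rows),
        "params": truth,
    }


def export_truth(study: dict, path) -> pd.DataFrame:
    """Write the per-trial latent-parameter table to CSV and return it."""
    truth: pd.DataFrame = study["truth"]
    truth.to_csv(path, index=False)
    return truth
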