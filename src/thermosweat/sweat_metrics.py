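"""Sweat-rate analytics: whole-body sweat rate from the mass ledger,
ventilated-capsule local sweat rate, Ramanathan mean skin temperature,
time-base resampling and the pre-trial hydration gate."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .heat_balance import (
    DomainError,
    Environment,
    GasExchange,
    LATENT_HEAT_SWEAT,
    respiratory_evaporative_loss,
    saturation_vapour_pressure,
)

__all__ = [
    "MassLedger",
    "CapsuleStream",
    "wbsr_corrected",
    "respiratory_mass_loss_rate",
    "metabolic_mass_loss_rate",
    "local_sweat_rate",
    "absolute_humidity",
    "resample_series",
    "mean_skin_temperature",
    "hydration_gate",
]

#: Ramanathan four-site weights (chest, shoulder, thigh, calf).
RAMANATHAN_WEIGHTS = {"chest": 0.30, "shoulder": 0.30, "thigh": 0.20, "calf": 0.20}

#: STPD gas densities, g·L⁻¹: CO2 out minus O2 in gives net metabolic mass loss.
CO2_DENSITY = 1.977
O2_DENSITY = 1.429

#: Specific gas constant of water vapour, J·kg⁻¹·K⁻¹.
RV = 461.5

USG_EUHYDRATED = 1.025
FLUID_ML_PER_KG = 5.0


@dataclass(frozen=True)
class MassLedger:
    """Pre/post clothed body and clothing masses of one trial.

    Duplicate weighings should be averaged before construction; nude
    mass is clothed mass minus clothing mass.
    """

    pre_clothed: float  # kg
    post_clothed: float  # kg
    clothing_pre: float  # kg
    clothing_post: float  # kg
    duration: float  # min

    def __post_init__(self) -> None:
        for name in ("pre_clothed", "post_clothed", "clothing_pre", "clothing_post"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")
        if not (0 < self.duration <= 300):
            raise DomainError(f"duration must be in (0, 300] min, got {self.duration}")

    @property
    def pre_nude(self) -> float:
        return self.pre_clothed - self.clothing_pre

    @property
    def post_nude(self) -> float:
        return self.post_clothed - self.clothing_post


@dataclass(frozen=True)
class CapsuleStream:
    """Raw ventilated-capsule record: influent/effluent absolute humidity.

    Anhydrous influent air has ``humidity_in`` identically zero.  Flow is
    the capsule ventilation rate (L·min⁻¹) and ``area`` the skin patch
    under the capsule (cm²).
    """

    time: np.ndarray  # s
    humidity_out: np.ndarray  # mg·L⁻¹
    humidity_in: np.ndarray | float = 0.0
    flow: float = 0.5  # L·min⁻¹
    area: float = 4.0  # cm²
    site: str = "back"

    def __post_init__(self) -> None:
        if self.flow <= 0 or self.area <= 0:
            raise DomainError("flow and area must be positive")


def average_duplicates(a: float, b: float, tolerance_g: float = 20.0) -> float:
    """Mean of duplicate mass measurements (kg); warns if they disagree
    by more than ``tolerance_g`` grams."""
    if abs(a - b) * 1000.0 > tolerance_g:
        warnings.warn(
            f"duplicate mass measurements differ by {abs(a - b) * 1000:.0f} g",
            stacklevel=2,
        )
    return (a + b) / 2.0


def respiratory_mass_loss_rate(
    M_area: float, bsa: float, env: Environment
) -> float:
    """Respiratory water loss rate, g·min⁻¹.

    The evaporative respiratory heat loss Eres (W·m⁻², from the heat
    budget) is scaled to absolute watts and divided by the latent heat
    of evaporation (2426 J·g⁻¹).
    """
    eres_w = respiratory_evaporative_loss(M_area, env) * bsa
    return eres_w / LATENT_HEAT_SWEAT * 60.0


def metabolic_mass_loss_rate(gas: GasExchange) -> float:
    """Net metabolic mass loss rate (CO2 exhaled minus O2 absorbed), g·min⁻¹.

    VCO2·ρ_CO2 − VO2·ρ_O2 = VO2·(1.977·RER − 1.429) at STPD.
    """
    return gas.VO2 * (CO2_DENSITY * gas.RER - O2_DENSITY)


def wbsr_corrected(
    ledger: MassLedger,
    gas: GasExchange,
    env: Environment,
    M_area: float,
    bsa: float,
) -> tuple[float, float]:
    """Whole-body sweat loss (g) and rate (g·h⁻¹), corrected for
    respiratory water and metabolic gas-exchange mass loss.

    Raises if post-exercise nude mass exceeds pre-exercise mass — trials
    involve no fluid intake, so mass can only fall.
    """
    delta_nude_g = (ledger.pre_nude - ledger.post_nude) * 1000.0
    if delta_nude_g < 0:
        raise DomainError(
            "post-exercise nude mass exceeds pre-exercise mass "
            "(impossible without fluid intake)"
        )
    resp_g = respiratory_mass_loss_rate(M_area, bsa, env) * ledger.duration
    metab_g = metabolic_mass_loss_rate(gas) * ledger.duration
    wbsl = delta_nude_g - resp_g - metab_g
    wbsr = wbsl / (ledger.duration / 60.0)
    return wbsl, wbsr


def absolute_humidity(rh: np.ndarray | float, T: np.ndarray | float) -> np.ndarray:
    """Absolute humidity (mg·L⁻¹) of air at relative humidity ``rh``
    (fraction) and temperature ``T`` (°C), via the ideal-gas water-vapour
    density at the Antoine saturation pressure."""
    p_kpa = np.asarray(rh, dtype=float) * np.vectorize(saturation_vapour_pressure)(T)
    t_k = np.asarray(T, dtype=float) + 273.15
    # ideal gas: rho = p / (Rv T); 1 kg·m⁻³ = 1 g·L⁻¹ = 1000 mg·L⁻¹
    rho_kg_m3 = p_kpa * 1000.0 / (RV * t_k)
    return rho_kg_m3 * 1000.0  # mg·L⁻¹


def local_sweat_rate(stream: CapsuleStream, clamp: bool = True) -> pd.Series:
    """Local sweat rate time series, mg·cm⁻²·min⁻¹.

    LSR(t) = flow × (humidity_out − humidity_in) / area.  Negative
    excursions (hygrometer noise with anhydrous influent) are clamped to
    zero when ``clamp`` is true.
    """
    delta = np.asarray(stream.humidity_out, dtype=float) - np.asarray(
        stream.humidity_in, dtype=float
    )
    lsr = stream.flow * delta / stream.area
    if clamp:
        lsr = np.clip(lsr, 0.0, None)
    return pd.Series(lsr, index=pd.Index(np.asarray(stream.time, float), name="time_s"))


def resample_series(series: pd.Series, rule: str = "minute_mean") -> pd.Series:
    """Resample a second-indexed series to the analysis cadences.

    ``minute_mean``
        left-closed 60-s window means, indexed by window start (minutes);
        used for onset-threshold analysis.
    ``five_min_report``
        the minute mean at each 5-min mark, the reporting cadence for
        trajectory analysis.

    Empty windows yield NaN, propagated explicitly.
    """
    t = np.asarray(series.index, dtype=float)
    if len(t) and np.any(np.diff(t) < 0):
        raise DomainError("timestamps must be monotone non-decreasing")
    idx = pd.to_timedelta(t, unit="s")
    s = pd.Series(series.to_numpy(dtype=float), index=idx)
    minute = s.resample("60s", closed="left", label="left").mean()
    minute.index = minute.index.total_seconds() / 60.0
    minute.index.name = "time_min"
    if rule == "minute_mean":
        return minute
    if rule == "five_min_report":
        return minute[np.isclose(np.asarray(minute.index) % 5.0, 0.0)]
    raise ValueError(f"unknown resampling rule {rule!r}")


def mean_skin_temperature(
    sites: pd.DataFrame, weights: dict[str, float] | None = None
) -> pd.Series:
    """Ramanathan weighted mean skin temperature (°C).

    Expects columns chest/shoulder/thigh/calf on a shared time base;
    default weights 0.3/0.3/0.2/0.2.  Overridden weights must sum to 1.
    """
    w = weights or RAMANATHAN_WEIGHTS
    if not np.isclose(sum(w.values()), 1.0):
        raise DomainError(f"site weights must sum to 1, got {sum(w.values())}")
    missing = set(w) - set(sites.columns)
    if missing:
        raise DomainError(f"missing skin-temperature sites: {sorted(missing)}")
    out = sum(w[site] * sites[site] for site in w)
    out.name = "tsk_mean"
    return out


def hydration_gate(usg: float, mass: float) -> tuple[bool, float]:
    """Pre-trial hydration check from urine specific gravity.

    Euhydrated iff USG < 1.025; otherwise the participant drinks
    5 mL·kg⁻¹ of water before the trial.  Returns (euhydrated, fluid_mL).
    """
    if not (1.000 <= usg <= 1.050):
        raise DomainError(f"USG {usg} outside plausible range [1.000, 1.050]")
    if mass <= 0:
        raise DomainError("mass must be positive")
    if usg < USG_EUHYDRATED:
        return True, 0.0
    return False, FLUID_ML_PER_KG * mass
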