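"""Partitional calorimetry for treadmill exercise in the heat.

Decomposes the human heat budget into metabolic heat production, dry
(convective + radiative) exchange, respiratory losses, the evaporative
requirement for heat balance (Ereq) and the environmental maximum
evaporative capacity (Emax), all expressed per unit body surface area
(W·m⁻²).  Sign convention follows the physiology literature: positive
C and R denote heat **loss** from the skin, negative values heat gain.

The compensability ratio Ereq/Emax > 1 marks uncompensable heat stress.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "Environment",
    "Anthropometrics",
    "GasExchange",
    "ClothingAndConstants",
    "HeatBalance",
    "du_bois_bsa",
    "saturation_vapour_pressure",
    "ambient_vapour_pressure",
    "metabolic_rate",
    "external_work",
    "heat_production",
    "convective_coefficient",
    "radiative_coefficient",
    "dry_heat_exchange",
    "respiratory_heat_loss",
    "evaporative_required",
    "evaporative_max",
    "heat_balance_summary",
]

#: Energy equivalent of 1 L O2 for pure carbohydrate oxidation (kJ).
E_CARB_KJ = 21.13
#: Energy equivalent of 1 L O2 for pure fat oxidation (kJ).
E_FAT_KJ = 19.62
#: Gravitational acceleration (m·s⁻²).
G0 = 9.81
#: Lewis relation between evaporative and convective coefficients (K·kPa⁻¹).
LEWIS = 16.5
#: Latent heat of sweat evaporation (J·g⁻¹).
LATENT_HEAT_SWEAT = 2426.0

# Antoine equation, water, mmHg form, valid ~1–100 °C.  Reproduces steam
# tables within 0.3 %.
ANTOINE_A = 8.07131
ANTOINE_B = 1730.63
ANTOINE_C = 233.426
MMHG_TO_KPA = 101.325 / 760.0


class DomainError(ValueError):
    """Physically impossible or out-of-contract input."""


@dataclass(frozen=True)
class Environment:
    """Ambient state of one chamber condition.

    Parameters
    ----------
    Ta : air temperature, °C.
    RH : relative humidity as a fraction in (0, 1].
    Pb : barometric pressure, mmHg (defaults to sea level).
    Tr : mean radiant temperature, °C; assumed equal to ``Ta`` when not
        measured, the usual chamber assumption.
    v : air speed over the skin, m·s⁻¹.  For treadmill walking without
        fans this equals belt speed.
    """

    Ta: float
    RH: float
    Pb: float = 760.0
    Tr: float | None = None
    v: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.RH <= 1.0):
            raise DomainError(f"RH must be in (0, 1], got {self.RH}")
        if self.Pb <= 0:
            raise DomainError(f"Pb must be positive, got {self.Pb}")
        if self.v < 0:
            raise DomainError(f"air speed must be >= 0, got {self.v}")
        if self.Tr is None:
            object.__setattr__(self, "Tr", self.Ta)
        if not math.isfinite(self.Tr):  # type: ignore[arg-type]
            raise DomainError("Tr must be finite")


@dataclass(frozen=True)
class Anthropometrics:
    """Participant body dimensions; BSA derived via Du Bois unless given."""

    mass: float  # kg
    height: float  # m
    age: float  # years
    sex: str  # "male" | "female"
    bsa: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.height <= 0:
            raise DomainError("mass and height must be positive")
        if self.sex not in ("male", "female"):
            raise DomainError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.bsa == 0.0:
            object.__setattr__(self, "bsa", du_bois_bsa(self.mass, self.height))
        if self.bsa <= 0.45:
            raise DomainError(
                f"BSA {self.bsa:.3f} m² <= 0.45 m²: outside the validity "
                "range of the Du Bois equation for children"
            )


@dataclass(frozen=True)
class GasExchange:
    """Mean steady-state gas exchange during exercise (STPD)."""

    VO2: float  # L·min⁻¹
    RER: float

    def __post_init__(self) -> None:
        if self.VO2 <= 0:
            raise DomainError(f"VO2 must be positive, got {self.VO2}")
        if not (0.6 <= self.RER <= 1.3):
            raise DomainError(f"RER {self.RER} outside plausible range [0.6, 1.3]")
        if not (0.7 <= self.RER <= 1.0):
            warnings.warn(
                f"RER {self.RER} outside [0.7, 1.0]: substrate energy "
                "equivalents are extrapolated",
                stacklevel=2,
            )


@dataclass(frozen=True)
class ClothingAndConstants:
    """Clothing properties and biophysical constants for minimal sportswear.

    ``Re_cl`` is the evaporative resistance of the clothing ensemble in
    m²·kPa·W⁻¹ (a resistance, so Emax is dimensionally consistent);
    ``f_cl`` the clothing area factor (≈1 for shorts and singlet);
    ``omega_max`` the maximum achievable skin wettedness.
    """

    Re_cl: float = 0.01
    f_cl: float = 1.0
    omega_max: float = 1.00
    epsilon: float = 0.95
    sigma: float = 5.67e-8
    Ar_ratio: float = 0.72
    lewis: float = LEWIS
    g0: float = G0

    def __post_init__(self) -> None:
        for name in ("Re_cl", "f_cl", "omega_max", "epsilon", "sigma", "Ar_ratio", "lewis", "g0"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be strictly positive")
        if self.omega_max > 1.0:
            raise DomainError("omega_max must be in (0, 1]")


@dataclass(frozen=True)
class HeatBalance:
    """The full steady-state heat budget of one trial (W·m⁻² unless noted)."""

    M: float
    Wk: float
    Hprod: float
    C: float
    R: float
    EresCres: float
    Ereq: float
    Emax: float
    Hprod_W: float
    Ereq_W: float
    ratio: float


def du_bois_bsa(mass: float, height: float, height_exp: float = 0.725) -> float:
    """Du Bois body surface area, m².

    BSA = 0.202 · mass^0.425 · height^height_exp with mass in kg and
    height in m.  The canonical height exponent is 0.725; 0.72 appears
    in some tabulations and may be selected.  Valid for BSA > 0.45 m²,
    which covers children and adults alike.
    """
    if mass <= 0 or height <= 0:
        raise DomainError("mass and height must be positive")
    return 0.202 * mass**0.425 * height**height_exp


def saturation_vapour_pressure(T: float) -> float:
    """Saturated water vapour pressure at ``T`` °C, kPa (Antoine equation).

    Uses the standard water constant set in mmHg form, converted to kPa.
    Warns outside the −10…60 °C validity window.
    """
    if not (-10.0 <= T <= 60.0):
        warnings.warn(
            f"temperature {T} °C outside Antoine validity window [-10, 60]",
            stacklevel=2,
        )
    p_mmhg = 10.0 ** (ANTOINE_A - ANTOINE_B / (ANTOINE_C + T))
    return p_mmhg * MMHG_TO_KPA


def ambient_vapour_pressure(env: Environment) -> float:
    """Ambient water vapour pressure Pa = RH · Psat(Ta), kPa."""
    return env.RH * saturation_vapour_pressure(env.Ta)


def metabolic_rate(gas: GasExchange, bsa: float) -> float:
    """Metabolic energy expenditure M, W·m⁻².

    M = VO2 · [ (RER−0.7)/0.3 · e_c + (1.0−RER)/0.3 · e_f ] / 60 × 1000 / BSA
    with e_c = 21.13 kJ·L⁻¹ (carbohydrate) and e_f = 19.62 kJ·L⁻¹ (fat):
    a linear substrate interpolation on RER between 0.7 and 1.0.
    """
    if bsa <= 0:
        raise DomainError("BSA must be positive")
    kj_per_l = ((gas.RER - 0.7) / 0.3) * E_CARB_KJ + ((1.0 - gas.RER) / 0.3) * E_FAT_KJ
    return gas.VO2 * kj_per_l / 60.0 * 1000.0 / bsa


def external_work(mass: float, v: float, incline: float, bsa: float, g0: float = G0) -> float:
    """External work rate against gravity on an inclined treadmill, W·m⁻².

    Wk = g0 · m · v · (i/100) / BSA, where ``incline`` is the treadmill
    grade in percent.  Zero on the level.
    """
    if bsa <= 0:
        raise DomainError("BSA must be positive")
    if incline < 0 or v < 0:
        raise DomainError("incline and speed must be >= 0")
    return g0 * mass * v * incline / 100.0 / bsa


def heat_production(M: float, Wk: float) -> float:
    """Metabolic heat production Hprod = M − Wk, W·m⁻²."""
    if M < Wk:
        warnings.warn("external work exceeds metabolic rate", stacklevel=2)
    return M - Wk


def convective_coefficient(env: Environment) -> float:
    """Convective heat-transfer coefficient for treadmill walking, W·m⁻²·K⁻¹.

    hc = 6.51 · v^0.391, corrected for barometric pressure by (Pb/760)^0.55.
    """
    if env.v <= 0:
        raise DomainError("air speed must be > 0 for treadmill convection")
    return 6.51 * env.v**0.391 * (env.Pb / 760.0) ** 0.55


def radiative_coefficient(Tsk: float, Tr: float, cc: ClothingAndConstants | None = None) -> float:
    """Radiative heat-transfer coefficient, W·m⁻²·K⁻¹.

    hr = 4 ε σ (Ar/BSA) · ((Tsk+Tr)/2 + 273.15)³, with skin emissivity
    0.95 and effective radiant area fraction 0.72 for a walking person.
    Depends only on the mean of the two temperatures.
    """
    cc = cc or ClothingAndConstants()
    t_mean_k = (Tsk + Tr) / 2.0 + 273.15
    return 4.0 * cc.epsilon * cc.sigma * cc.Ar_ratio * t_mean_k**3


def dry_heat_exchange(
    Tsk: float, env: Environment, cc: ClothingAndConstants | None = None
) -> tuple[float, float]:
    """Convective and radiative skin heat exchange (C, R), W·m⁻².

    C = hc·(Tsk − Ta), R = hr·(Tsk − Tr); positive values are heat loss.
    """
    hc = convective_coefficient(env)
    hr = radiative_coefficient(Tsk, env.Tr, cc)  # type: ignore[arg-type]
    return hc * (Tsk - env.Ta), hr * (Tsk - env.Tr)  # type: ignore[operator]


def respiratory_heat_loss(M: float, env: Environment) -> float:
    """Combined respiratory convective + evaporative heat loss, W·m⁻².

    Cres + Eres = 0.001516·M·(28.56 + 0.641·Pa − 0.885·Ta)
                + 0.00127·M·(59.34 + 0.53·Ta − 11.63·Pa)
    with M in W·m⁻² and Pa in kPa; linear in M.
    """
    if M < 0:
        raise DomainError("M must be >= 0")
    Pa = ambient_vapour_pressure(env)
    cres = 0.001516 * M * (28.56 + 0.641 * Pa - 0.885 * env.Ta)
    eres = 0.00127 * M * (59.34 + 0.53 * env.Ta - 11.63 * Pa)
    return cres + eres


def respiratory_evaporative_loss(M: float, env: Environment) -> float:
    """Evaporative component Eres alone, W·m⁻² (for mass-loss correction)."""
    Pa = ambient_vapour_pressure(env)
    return 0.00127 * M * (59.34 + 0.53 * env.Ta - 11.63 * Pa)


def evaporative_required(Hprod: float, C: float, R: float, EresCres: float) -> float:
    """Evaporative heat loss required for balance: Hprod − (C + R + Eres+Cres)."""
    return Hprod - (C + R + EresCres)


def evaporative_max(
    Tsk: float, env: Environment, cc: ClothingAndConstants | None = None
) -> float:
    """Maximum evaporative heat loss the environment permits, W·m⁻².

    Emax = ω_max (Psk,s − Pa) / (Re,cl + 1/(he·f_cl)) with
    he = hc · 16.5 · (760/Pb)^0.45 (Lewis relation with pressure
    correction) and Psk,s the saturation pressure at skin temperature.
    A non-positive result (Pa ≥ Psk,s) is returned with a warning: the
    environment blocks evaporation entirely.
    """
    cc = cc or ClothingAndConstants()
    psk_s = saturation_vapour_pressure(Tsk)
    pa = ambient_vapour_pressure(env)
    he = convective_coefficient(env) * cc.lewis * (760.0 / env.Pb) ** 0.45
    emax = cc.omega_max * (psk_s - pa) / (cc.Re_cl + 1.0 / (he * cc.f_cl))
    if emax <= 0:
        warnings.warn(
            "ambient vapour pressure at or above skin saturation pressure: "
            "Emax <= 0 (uncompensable by dryness)",
            stacklevel=2,
        )
    return emax


def heat_balance_summary(
    *,
    anthropometrics: Anthropometrics,
    gas: GasExchange,
    env: Environment,
    Tsk: float,
    speed: float,
    incline: float,
    constants: ClothingAndConstants | None = None,
) -> HeatBalance:
    """Compose the full heat budget of one trial.

    Returns every component per m² plus absolute Hprod and Ereq (W) and
    the compensability ratio Ereq/Emax.  The conservation identity
    Ereq + C + R + (Eres+Cres) = Hprod holds exactly by construction.
    """
    cc = constants or ClothingAndConstants()
    bsa = anthropometrics.bsa
    M = metabolic_rate(gas, bsa)
    Wk = external_work(anthropometrics.mass, speed, incline, bsa, cc.g0)
    Hprod = heat_production(M, Wk)
    C, R = dry_heat_exchange(Tsk, env, cc)
    resp = respiratory_heat_loss(M, env)
    Ereq = evaporative_required(Hprod, C, R, resp)
    Emax = evaporative_max(Tsk, env, cc)
    return HeatBalance(
        M=M,
        Wk=Wk,
        Hprod=Hprod,
        C=C,
        R=R,
        EresCres=resp,
        Ereq=Ereq,
        Emax=Emax,
        Hprod_W=Hprod * bsa,
        Ereq_W=Ereq * bsa,
        ratio=Ereq / Emax if Emax != 0 else math.inf,
    )
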