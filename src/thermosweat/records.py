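"""Trial-level record container binding metadata, environment and
time series, plus the heat-budget summary over a whole record."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .heat_balance import (
    Anthropometrics,
    ClothingAndConstants,
    Environment,
    GasExchange,
    HeatBalance,
    heat_balance_summary,
)
from .sweat_metrics import MassLedger

__all__ = ["TrialRecord", "trial_heat_balance"]


@dataclass
class TrialRecord:
    """One participant-trial: metadata, mass ledger and time series.

    ``lsr_streams`` maps capsule site ("back"/"arm") to a DataFrame with
    columns (time_s, abs_humidity_mg_per_L) or a precomputed LSR column;
    ``skin_temps`` has columns (time_s, chest, shoulder, thigh, calf);
    ``tgi`` has (time_s, tgi).
    """

    participant: str
    group: str  # boy | girl | adult_male | adult_female
    condition: str  # WARM | HOT
    anthropometrics: Anthropometrics
    env: Environment
    gas: GasExchange
    speed: float  # m·s⁻¹
    incline: float  # %
    tsk_mean: float  # °C, exercise mean
    ledger: MassLedger | None = None
    usg: float | None = None
    lsr_streams: dict = field(default_factory=dict)
    skin_temps: pd.DataFrame | None = None
    tgi: pd.DataFrame | None = None
    exercise_start_min: float = 10.0
    truth: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name in ("participant", "group", "condition"):
            if not getattr(self, name):
                raise ValueError(f"trial record missing field {name!r}")


def trial_heat_balance(
    trial: TrialRecord, constants: ClothingAndConstants | None = None
) -> HeatBalance:
    """Full partitional-calorimetry budget of one trial record."""
    trial.validate()
    return heat_balance_summary(
        anthropometrics=trial.anthropometrics,
        gas=trial.gas,
        env=trial.env,
        Tsk=trial.tsk_mean,
        speed=trial.speed,
        incline=trial.incline,
        constants=constants,
    )
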