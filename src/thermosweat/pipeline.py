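"""Pipeline configuration, trial-table IO and the staged analysis runner.

Binds the stages together: simulate → heat balance → sweat metrics →
onset detection → hierarchical inference → report.  Every run flows from
a single seed recorded in the report bundle, and each stage writes plain
CSV/JSON artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .heat_balance import Anthropometrics, Environment, GasExchange
from .inference import WBSRHierarchicalModel, endpoint_contrast
from .onset import OnsetCovariateModel, SegmentedOnsetRegressor
from .records import TrialRecord, trial_heat_balance
from .sweat_metrics import resample_series, wbsr_corrected
from .synthetic import CONDITIONS, TruthParams, export_truth, simulate_study

log = logging.getLogger("thermosweat")

__all__ = [
    "PipelineConfig",
    "load_config",
    "read_trial_inputs",
    "write_trials_csv",
    "heat_balance_table",
    "run_pipeline",
]

#: Schema of the flat trial-metadata table (one row per trial).
TRIAL_COLUMNS = [
    "participant", "group", "condition", "sex", "age", "height", "mass",
    "vo2", "rer", "speed", "incline", "tsk_mean", "pre_clothed",
    "post_clothed", "clothing_pre", "clothing_post", "duration", "usg",
]

#: Heat-budget output columns, one row per trial.
HEAT_BALANCE_COLUMNS = [
    "participant", "group", "condition", "hprod_w_m2", "hprod_w",
    "hprod_w_kg", "ereq_w", "c_plus_r_w_m2", "ereq_w_m2", "emax_w_m2",
    "ereq_emax",
]


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run; unknown keys rejected."""

    outdir: str = "results"
    seed: int = 0
    n_per_group: int = 20
    groups: tuple = ("boy", "girl")
    conditions: tuple = ("WARM", "HOT")
    onset_condition: str = "WARM"
    onset_grid_step: float = 0.1
    onset_bootstrap: int = 0  # 0 → delta-method CIs in the pipeline
    mcmc_chains: int = 2
    mcmc_warmup: int = 400
    mcmc_draws: int = 800
    truth_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("groups", "conditions"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def truth(self) -> TruthParams:
        return TruthParams(seed=self.seed, **self.truth_overrides)


def load_config(path) -> PipelineConfig:
    """Load a YAML or JSON configuration file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a JSON superset
    if not isinstance(data, dict):
        raise ValueError(f"configuration file {path} must contain a mapping")
    return PipelineConfig.from_dict(data)


def trials_to_frame(trials: list) -> pd.DataFrame:
    rows = []
    for tr in trials:
        rows.append({
            "participant": tr.participant, "group": tr.group,
            "condition": tr.condition, "sex": tr.anthropometrics.sex,
            "age": tr.anthropometrics.age, "height": tr.anthropometrics.height,
            "mass": tr.anthropometrics.mass, "vo2": tr.gas.VO2,
            "rer": tr.gas.RER, "speed": tr.speed, "incline": tr.incline,
            "tsk_mean": tr.tsk_mean,
            "pre_clothed": tr.ledger.pre_clothed if tr.ledger else np.nan,
            "post_clothed": tr.ledger.post_clothed if tr.ledger else np.nan,
            "clothing_pre": tr.ledger.clothing_pre if tr.ledger else np.nan,
            "clothing_post": tr.ledger.clothing_post if tr.ledger else np.nan,
            "duration": tr.ledger.duration if tr.ledger else np.nan,
            "usg": tr.usg,
        })
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def write_trials_csv(trials: list, path) -> None:
    trials_to_frame(trials).to_csv(path, index=False)


def read_trial_inputs(path) -> list:
    """Read a trial-metadata CSV into TrialRecord objects.

    Schema violations raise with the offending file, row and column
    named; a truncated or column-missing file never silently drops rows.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    from .sweat_metrics import MassLedger

    records = []
    for i, row in df.iterrows():
        for col in ("age", "height", "mass", "vo2", "rer"):
            if pd.isna(row[col]):
                raise ValueError(f"{path}: row {i}, column {col!r} is empty")
        try:
            ta, rh = CONDITIONS[row["condition"]]
            ledger = None
            if not pd.isna(row["pre_clothed"]):
                ledger = MassLedger(
                    pre_clothed=row["pre_clothed"], post_clothed=row["post_clothed"],
                    clothing_pre=row["clothing_pre"], clothing_post=row["clothing_post"],
                    duration=row["duration"],
                )
            records.append(TrialRecord(
                participant=str(row["participant"]), group=str(row["group"]),
                condition=str(row["condition"]),
                anthropometrics=Anthropometrics(
                    mass=row["mass"], height=row["height"],
                    age=row["age"], sex=str(row["sex"]),
                ),
                env=Environment(Ta=ta, RH=rh, v=row["speed"]),
                gas=GasExchange(row["vo2"], row["rer"]),
                speed=row["speed"], incline=row["incline"],
                tsk_mean=row["tsk_mean"], ledger=ledger,
                usg=None if pd.isna(row["usg"]) else float(row["usg"]),
            ))
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
    log.info("read %d trial records from %s", len(records), path)
    return records


def heat_balance_table(trials: list) -> pd.DataFrame:
    """One heat-budget row per trial, mirroring the standard reporting
    column set (Hprod in W·m⁻², W and W·kg⁻¹; C+R; Ereq; Emax; ratio)."""
    rows = []
    for tr in trials:
        hb = trial_heat_balance(tr)
        rows.append({
            "participant": tr.participant, "group": tr.group,
            "condition": tr.condition, "hprod_w_m2": hb.Hprod,
            "hprod_w": hb.Hprod_W, "hprod_w_kg": hb.Hprod_W / tr.anthropometrics.mass,
            "ereq_w": hb.Ereq_W, "c_plus_r_w_m2": hb.C + hb.R,
            "ereq_w_m2": hb.Ereq, "emax_w_m2": hb.Emax, "ereq_emax": hb.ratio,
        })
    return pd.DataFrame(rows, columns=HEAT_BALANCE_COLUMNS)


def sweat_table(trials: list) -> pd.DataFrame:
    """Corrected whole-body sweat loss/rate per trial."""
    rows = []
    for tr in trials:
        if tr.ledger is None:
            continue
        hb = trial_heat_balance(tr)
        wbsl, wbsr = wbsr_corrected(
            tr.ledger, tr.gas, tr.env, hb.M, tr.anthropometrics.bsa
        )
        rows.append({
            "participant": tr.participant, "group": tr.group,
            "condition": tr.condition, "sex": tr.anthropometrics.sex,
            "age": tr.anthropometrics.age, "wbsl_g": wbsl, "wbsr": wbsr,
        })
    return pd.DataFrame(rows)


def onset_table(study: dict, config: PipelineConfig) -> pd.DataFrame:
    """Segmented onset fits of every LSR series in the onset condition."""
    import warnings as _w

    truth = study["params"]
    ci_method = "bootstrap" if config.onset_bootstrap else "asymptotic"
    rows = []
    for (participant, condition), sites in study["lsr"].items():
        if condition != config.onset_condition:
            continue
        meta = study["cohort"].set_index("participant").loc[participant]
        for site, df in sites.items():
            series = resample_series(
                pd.Series(df["lsr"].to_numpy(), index=df["time_s"].to_numpy()),
                "minute_mean",
            ).dropna()
            est = SegmentedOnsetRegressor(
                grid_step=config.onset_grid_step, ci_method=ci_method,
                n_boot=config.onset_bootstrap or 500,
                random_state=config.seed,
            )
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                est.fit(series.index.to_numpy(), series.to_numpy())
            rows.append({
                "participant": participant, "site": site,
                "sex": meta["sex"], "age": meta["age"],
                **est.fit_.to_row(),
            })
    return pd.DataFrame(rows)


def _stage_simulate(config, outdir):
    study = simulate_study(
        config.n_per_group, config.truth(), groups=config.groups,
        conditions=config.conditions,
    )
    write_trials_csv(study["trials"], outdir / "trials.csv")
    export_truth(study, outdir / "truth.csv")
    return study


def run_pipeline(config: PipelineConfig, upto: str | None = None) -> dict:
    """Execute the stages (all, or through ``upto``) and write the
    report bundle under ``outdir``.

    Returns a dict of the in-memory tables.  Any stage failure raises a
    ``StageError`` naming the stage and carrying a stage-specific exit
    code.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "config": dataclasses.asdict(config)}
    (outdir / "config.json").write_text(json.dumps(report["config"], default=list, indent=1))

    stages = []

    def stage(name, fn):
        stages.append((name, fn))

    results: dict = {}

    stage("simulate", lambda: results.update(study=_stage_simulate(config, outdir)))

    def _heat():
        tbl = heat_balance_table(results["study"]["trials"])
        tbl.to_csv(outdir / "heat_balance.csv", index=False)
        results["heat_balance"] = tbl

    stage("heatbalance", _heat)

    def _sweat():
        tbl = sweat_table(results["study"]["trials"])
        tbl.to_csv(outdir / "wbsr.csv", index=False)
        results["wbsr"] = tbl

    stage("sweat", _sweat)

    def _onset():
        tbl = onset_table(results["study"], config)
        tbl.to_csv(outdir / "onsets.csv", index=False)
        results["onsets"] = tbl
        effects = []
        for site in tbl["site"].unique():
            sub = tbl[tbl["site"] == site]
            model = OnsetCovariateModel().fit(sub)
            et = model.effect_table()
            et.insert(0, "site", site)
            effects.append(et)
        results["onset_effects"] = pd.concat(effects, ignore_index=True)
        results["onset_effects"].to_csv(outdir / "onset_effects.csv", index=False)

    stage("onset", _onset)

    def _infer():
        contrasts, diagnostics = [], {}
        for condition in config.conditions:
            sub = results["wbsr"][results["wbsr"]["condition"] == condition]
            model = WBSRHierarchicalModel(
                n_chains=config.mcmc_chains, n_warmup=config.mcmc_warmup,
                n_draws=config.mcmc_draws, random_state=config.seed,
            ).fit(sub)
            diagnostics[condition] = model.diagnostics_
            for sex in ("male", "female"):
                c = model.age_contrast(sex)
                contrasts.append({
                    "condition": condition, "quantity": "wbsr_4yr_contrast",
                    "sex": sex, "mean": c.mean, "ci_lo": c.ci90[0],
                    "ci_hi": c.ci90[1], "pd": c.pd,
                })
            c = model.sex_contrast()
            contrasts.append({
                "condition": condition, "quantity": "wbsr_sex_contrast",
                "sex": "male-female", "mean": c.mean, "ci_lo": c.ci90[0],
                "ci_hi": c.ci90[1], "pd": c.pd,
            })
        results["contrasts"] = pd.DataFrame(contrasts)
        results["contrasts"].to_csv(outdir / "contrasts.csv", index=False)
        (outdir / "diagnostics.json").write_text(json.dumps(diagnostics, indent=1))
        results["diagnostics"] = diagnostics

    stage("infer", _infer)

    def _report():
        summary = (
            results["heat_balance"]
            .groupby(["condition", "group"])[
                ["hprod_w_m2", "ereq_w_m2", "emax_w_m2", "c_plus_r_w_m2", "ereq_emax"]
            ]
            .agg(["mean", "std"])
        )
        summary.to_csv(outdir / "heat_balance_summary.csv")
        results["summary"] = summary

    stage("report", _report)

    for i, (name, fn) in enumerate(stages):
        try:
            log.info("stage %s", name)
            fn()
        except Exception as exc:
            raise StageError(name, i + 2, str(exc)) from exc
        if upto is not None and name == upto:
            break
    return results


class StageError(RuntimeError):
    """Failure in one pipeline stage; carries a stage-specific exit code."""

    def __init__(self, stage: str, exit_code: int, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage
        self.exit_code = exit_code
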