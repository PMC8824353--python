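"""Run configuration and report assembly behind the command-line interface.

A :class:`RunConfig` names the input tables (or falls back to the built-in
synthetic defaults), the diet-change scenario, and the uncertainty /
sensitivity settings. Report builders return plain dicts that serialise
to JSON unchanged; the human-readable views round years to one decimal,
the machine output never rounds. Every report embeds a provenance block
(input digests, seed, draw count, T, m) sufficient to reproduce its
numbers.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Any, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import io as fsio
from .effect_engine import (
    DEFAULT_TIME_TO_FULL_EFFECT,
    DietChangeScenario,
    gain_in_le,
    per_group_gains,
)
from .food_model import (
    DEFAULT_ENERGY_DENSITIES,
    DietProfile,
    FoodGroup,
    PRESET_NAMES,
    preset_diet,
    total_energy,
)
from .lifetable import life_expectancy
from .quality import categorize, weighted_overall
from .synthetic_data import default_schedule, make_curveset
from .uncertainty import (
    DEFAULT_N_DRAWS,
    DEFAULT_SEED,
    SensitivityConfig,
    UncertaintyConfig,
    sensitivity_interval,
    uncertainty_interval,
)


class ScenarioBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    baseline: str | dict[str, float] = "TW"
    target: str | dict[str, float] = "OD"
    change_age: int = 20
    sex: str = "female"
    region: str = "synthetic"
    time_to_full_effect: float = DEFAULT_TIME_TO_FULL_EFFECT


class UncertaintyBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_draws: int = DEFAULT_N_DRAWS
    seed: int = DEFAULT_SEED
    percentiles: tuple[float, float] = (2.5, 97.5)


class SensitivityBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    m: float = 1.0


class RunConfig(BaseModel):
    """Full run configuration; unknown keys are rejected by name."""

    model_config = ConfigDict(extra="forbid")

    rates: Path | None = None
    hr_table: Path | None = None
    hr_metadata: Path | None = None
    densities: Path | None = None
    scenario: ScenarioBlock = Field(default_factory=ScenarioBlock)
    uncertainty: UncertaintyBlock = Field(default_factory=UncertaintyBlock)
    sensitivity: SensitivityBlock = Field(default_factory=SensitivityBlock)
    out_dir: Path | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False)


def _digest(path: Path | None) -> str:
    if path is None:
        return "builtin"
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _resolve_diet(spec: str | dict, label: str) -> DietProfile:
    if isinstance(spec, dict):
        return DietProfile(label, {FoodGroup(k): float(v) for k, v in spec.items()})
    name = str(spec)
    if name.upper() in PRESET_NAMES or name.lower() in ("optimal", "feasible", "typical"):
        alias = {"optimal": "OD", "feasible": "FA", "typical": "TW"}
        return preset_diet(alias.get(name.lower(), name))
    return fsio.read_diet(name)


def build_inputs(config: RunConfig):
    """Materialise (schedule, curves, densities, scenario) from a config."""
    sc = config.scenario
    if config.rates is not None:
        schedule = fsio.read_grouped_rates(config.rates)
        from .lifetable import expand_to_single_year

        schedule = expand_to_single_year(schedule)
    else:
        schedule = default_schedule(sex=sc.sex, region=sc.region)
    if config.hr_table is not None:
        meta = config.hr_metadata if config.hr_metadata is not None else config.hr_table
        curves = fsio.read_curves(config.hr_table, meta)
    else:
        curves = make_curveset()
    densities = (
        fsio.read_densities(config.densities)
        if config.densities is not None
        else DEFAULT_ENERGY_DENSITIES
    )
    scenario = DietChangeScenario(
        baseline=_resolve_diet(sc.baseline, "baseline"),
        target=_resolve_diet(sc.target, "target"),
        change_age=sc.change_age,
        time_to_full_effect=sc.time_to_full_effect,
        sex=sc.sex,
        region=sc.region,
    )
    return schedule, curves, densities, scenario


def provenance(config: RunConfig) -> dict[str, Any]:
    return {
        "rates_digest": _digest(config.rates),
        "hr_table_digest": _digest(config.hr_table),
        "densities_digest": _digest(config.densities),
        "seed": config.uncertainty.seed,
        "n_draws": config.uncertainty.n_draws,
        "time_to_full_effect": config.scenario.time_to_full_effect,
        "m": config.sensitivity.m,
    }


def le_report(config: RunConfig) -> dict[str, Any]:
    """Baseline and post-change LE at the configured age."""
    schedule, curves, densities, scenario = build_inputs(config)
    est = gain_in_le(scenario, schedule, curves, densities)
    return {
        "scenario": {
            "baseline": scenario.baseline.label,
            "target": scenario.target.label,
            "change_age": scenario.change_age,
            "sex": scenario.sex,
            "region": scenario.region,
        },
        "baseline_energy_kj": total_energy(scenario.baseline, densities),
        "target_energy_kj": total_energy(scenario.target, densities),
        "le_baseline": est.le_baseline,
        "le_target": est.le_target,
        "gain": est.gain,
        "provenance": provenance(config),
    }


def gain_report(config: RunConfig) -> dict[str, Any]:
    """Total gain with 95% UI and sensitivity interval, plus the per-group
    forest table and the weighted NutriGrade score."""
    schedule, curves, densities, scenario = build_inputs(config)
    ucfg = UncertaintyConfig(
        n_draws=config.uncertainty.n_draws,
        seed=config.uncertainty.seed,
        percentiles=config.uncertainty.percentiles,
    )
    SensitivityConfig(m=config.sensitivity.m)  # validate range

    est = gain_in_le(scenario, schedule, curves, densities)
    ui_lo, ui_hi = uncertainty_interval(scenario, schedule, curves, densities, ucfg)
    sens_lo, sens_hi = sensitivity_interval(scenario, schedule, curves, densities)
    group_gain = per_group_gains(scenario, schedule, curves, densities)

    rows = []
    for g in FoodGroup:
        delta = scenario.target[g] - scenario.baseline[g]
        if curves.get(g) is not None and curves[g].neutral:
            g_lo, g_hi = group_gain[g], group_gain[g]
        else:
            g_lo, g_hi = uncertainty_interval(
                scenario, schedule, curves, densities, ucfg, groups=[g]
            )
        rows.append(
            {
                "group": g.value,
                "delta_grams": delta,
                "gain_years": group_gain[g],
                "ui_lo": g_lo,
                "ui_hi": g_hi,
                "nutrigrade": curves[g].nutrigrade if g in curves else None,
            }
        )

    scores = {g: c.nutrigrade for g, c in curves.items()}
    try:
        overall = weighted_overall(scores, group_gain)
        overall_cat = categorize(overall).value
    except ValueError:
        overall, overall_cat = None, None

    return {
        "scenario": {
            "baseline": scenario.baseline.label,
            "target": scenario.target.label,
            "change_age": scenario.change_age,
            "sex": scenario.sex,
            "region": scenario.region,
            "time_to_full_effect": scenario.time_to_full_effect,
        },
        "le_baseline": est.le_baseline,
        "le_target": est.le_target,
        "gain": est.gain,
        "ui_lo": ui_lo,
        "ui_hi": ui_hi,
        "sens_lo": sens_lo,
        "sens_hi": sens_hi,
        "per_group": rows,
        "nutrigrade_overall": overall,
        "nutrigrade_category": overall_cat,
        "provenance": provenance(config),
    }


def sweep_age_report(
    config: RunConfig, ages: list[int], horizons: list[float] | None = None
) -> dict[str, Any]:
    """Gain per starting age, per food group and for the full diet change.

    ``horizons`` optionally sweeps several time-to-full-effect values
    (e.g. 5, 10, 30, 50 years).
    """
    schedule, curves, densities, scenario0 = build_inputs(config)
    horizons = horizons or [scenario0.time_to_full_effect]
    rows = []
    for T in horizons:
        for age in ages:
            scenario = DietChangeScenario(
                baseline=scenario0.baseline,
                target=scenario0.target,
                change_age=age,
                time_to_full_effect=T,
                sex=scenario0.sex,
                region=scenario0.region,
            )
            total = gain_in_le(scenario, schedule, curves, densities).gain
            per_group = per_group_gains(scenario, schedule, curves, densities)
            row = {"time_to_full_effect": T, "change_age": age, "total": total}
            row.update({g.value: per_group[g] for g in FoodGroup})
            rows.append(row)
    return {"rows": rows, "provenance": provenance(config)}


def round_years(value: float | None, ndigits: int = 1) -> float | None:
    """Presentation rounding for the human-readable views (1 decimal year)."""
    return None if value is None else round(value, ndigits)
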