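"""Turns a diet-change scenario into hazard multipliers and LE gains.

A scenario changes intake from a baseline diet to a target diet at a given
age. Each food group contributes a hazard ratio HR(to)/HR(from) read off
its dose-response curve; groups act as independent multiplicative
protective or risk factors, so the combined full effect is the product of
the per-group HRs. The full effect does not apply instantly: a linear
time-to-full-effect ramp scales the effect from 0 at the change age to
full after T years (default 10; e.g. 20% of maximum after 2 years), so the
mortality multiplier t years after the change is

    1 + min(t/T, 1) * (HR_full - 1),

evaluated at the midpoint of each model year. Life-years gained is the
difference in remaining life expectancy at the change age between the
modified and unmodified schedules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .food_model import (
    CurveSet,
    DietProfile,
    EnergyDensityTable,
    FoodGroup,
    NEUTRAL_GROUPS,
    hazard_ratio_for_change,
    require_energy_gate,
)
from .lifetable import MortalitySchedule, apply_hazard_trajectory, life_expectancy

DEFAULT_TIME_TO_FULL_EFFECT = 10.0


@dataclass(frozen=True)
class DietChangeScenario:
    """A sustained change from ``baseline`` to ``target`` at ``change_age``."""

    baseline: DietProfile
    target: DietProfile
    change_age: int
    time_to_full_effect: float = DEFAULT_TIME_TO_FULL_EFFECT
    sex: str = "female"
    region: str = "default"

    def __post_init__(self):
        if self.time_to_full_effect <= 0:
            raise ValueError("time to full effect must be > 0 years")

    def validate(self, schedule: MortalitySchedule, densities: EnergyDensityTable) -> None:
        """Check age range and apply the energy gate to both diets."""
        if not (schedule.start_age <= self.change_age <= schedule.max_age):
            raise ValueError(
                f"change age {self.change_age} outside schedule range "
                f"[{schedule.start_age}, {schedule.max_age}]"
            )
        require_energy_gate(self.baseline, densities)
        require_energy_gate(self.target, densities)


@dataclass(frozen=True)
class GainEstimate:
    """LE gain of a scenario: central estimate plus interval annotations."""

    le_baseline: float
    le_target: float
    per_group_gain: Mapping[FoodGroup, float] = field(default_factory=dict)
    ui_lo: float | None = None
    ui_hi: float | None = None
    sens_lo: float | None = None
    sens_hi: float | None = None

    @property
    def gain(self) -> float:
        return self.le_target - self.le_baseline


def ramp_fraction(t: float, T: float) -> float:
    """Fraction of the full hazard effect realised ``t`` years after change."""
    if t < 0:
        raise ValueError(f"time since change must be >= 0, got {t}")
    if T <= 0:
        raise ValueError(f"time to full effect must be > 0, got {T}")
    return min(t / T, 1.0)


def combined_hr(
    curves: CurveSet,
    baseline: DietProfile,
    target: DietProfile,
    groups: Iterable[FoodGroup] | None = None,
) -> float:
    """Product over food groups of the central HR for each intake change."""
    wanted = list(groups) if groups is not None else list(FoodGroup)
    hr = 1.0
    for g in wanted:
        if g not in curves:
            if g in NEUTRAL_GROUPS or baseline[g] == target[g]:
                continue  # no curve needed: neutral or no intake change
            raise KeyError(f"no dose-response curve for changed food group {g.value!r}")
        if curves[g].neutral:
            continue
        central, _, _ = hazard_ratio_for_change(curves[g], baseline[g], target[g])
        hr *= central
    return hr


def hazard_trajectory(
    hr_full: float, change_age: int, T: float, max_age: int
) -> dict[int, float]:
    """Age-indexed mortality multiplier implementing the linear ramp.

    For each model year the ramp is sampled at the year's midpoint
    (t = a - change_age + 0.5), so the first year after a change already
    carries a small part of the effect and the full HR applies once
    t >= T.
    """
    if hr_full <= 0 or not math.isfinite(hr_full):
        raise ValueError(f"combined hazard ratio must be finite and > 0, got {hr_full}")
    traj = {}
    for a in range(change_age, max_age + 1):
        f = ramp_fraction(a - change_age + 0.5, T)
        traj[a] = 1.0 + f * (hr_full - 1.0)
    return traj


def gain_in_le(
    scenario: DietChangeScenario,
    schedule: MortalitySchedule,
    curves: CurveSet,
    densities: EnergyDensityTable,
    groups: Iterable[FoodGroup] | None = None,
) -> GainEstimate:
    """Central LE gain of a scenario (no uncertainty annotations).

    ``groups`` restricts which food groups' changes are applied; all other
    groups are held at baseline. Both diets must pass the energy gate, else
    :class:`~foodspan.food_model.EnergyGateError` is raised and no estimate
    is reported.
    """
    scenario.validate(schedule, densities)
    hr_full = combined_hr(curves, scenario.baseline, scenario.target, groups)
    le0 = life_expectancy(schedule, scenario.change_age)
    traj = hazard_trajectory(
        hr_full, scenario.change_age, scenario.time_to_full_effect, schedule.max_age
    )
    modified = apply_hazard_trajectory(schedule, scenario.change_age, traj)
    le1 = life_expectancy(modified, scenario.change_age)
    return GainEstimate(le_baseline=le0, le_target=le1)


def per_group_gains(
    scenario: DietChangeScenario,
    schedule: MortalitySchedule,
    curves: CurveSet,
    densities: EnergyDensityTable,
) -> dict[FoodGroup, float]:
    """LE gain from changing each food group alone, others held at baseline.

    Mortality-neutral groups report 0. The per-group gains do not sum
    exactly to the joint total (life-table gains are not additive); the
    total is always computed jointly by :func:`gain_in_le`.
    """
    gains: dict[FoodGroup, float] = {}
    for g in FoodGroup:
        if (g in NEUTRAL_GROUPS and (g not in curves or curves[g].neutral)) or (
            g in curves and curves[g].neutral
        ):
            gains[g] = 0.0
            continue
        est = gain_in_le(scenario, schedule, curves, densities, groups=[g])
        gains[g] = est.gain
    return gains
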