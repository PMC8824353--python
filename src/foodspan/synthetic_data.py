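"""Synthetic inputs: parametric mortality schedules, hazard-ratio curve
sets, and a brute-force cohort simulator used as an independent oracle.

Everything here is invented plumbing so the engine can be built and tested
without external downloads. The default mortality schedules follow a
Gompertz-Makeham law h(x) = c + a*exp(b*x) calibrated so a 20-year-old's
baseline LE falls in a realistic adult range (~59 y male, ~62 y female).
The default dose-response curve set mimics the STRUCTURE of meta-analytic
hazard-ratio tables — protective curves falling from HR 1 at zero intake
to a plateau, harmful curves rising with intake, symmetric CI bands — but
its numbers are synthetic placeholders, NOT estimates transcribed from any
published meta-analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .food_model import (
    CurvePoint,
    DoseResponseCurve,
    FoodGroup,
    NEUTRAL_GROUPS,
)
from .lifetable import DEFAULT_MAX_AGE, MortalitySchedule
from .quality import DEFAULT_NUTRIGRADE_SCORES


@dataclass(frozen=True)
class GompertzMakehamParams:
    """Hazard h(x) = makeham + gompertz_a * exp(gompertz_b * x), x in years."""

    makeham: float = 6e-4
    gompertz_a: float = 2.8e-5
    gompertz_b: float = 0.095
    max_age: int = DEFAULT_MAX_AGE

    def __post_init__(self):
        if self.makeham < 0 or self.gompertz_a <= 0 or self.gompertz_b <= 0:
            raise ValueError("need makeham >= 0 and gompertz_a, gompertz_b > 0")

    def hazard(self, age: float) -> float:
        z = self.gompertz_b * age
        if z > 700:
            raise OverflowError(f"Gompertz hazard overflows at age {age}")
        return self.makeham + self.gompertz_a * math.exp(z)


#: Default parameters per sex; female frailty lower at all ages.
DEFAULT_GM_PARAMS = {
    "male": GompertzMakehamParams(6e-4, 2.8e-5, 0.095),
    "female": GompertzMakehamParams(4e-4, 1.35e-5, 0.101),
}


def make_schedule(
    params: GompertzMakehamParams, sex: str = "female", region: str = "synthetic"
) -> MortalitySchedule:
    """Single-year Gompertz-Makeham mortality schedule closed at max_age."""
    m = {a: params.hazard(a) for a in range(0, params.max_age + 1)}
    return MortalitySchedule(sex, region, params.max_age, m)


def default_schedule(sex: str = "female", region: str = "synthetic") -> MortalitySchedule:
    return make_schedule(DEFAULT_GM_PARAMS[sex], sex, region)


# (plateau dose g/day, HR at plateau, CI half-width). Protective groups have
# HR < 1 at high intake; harmful groups HR > 1. Synthetic placeholders.
DEFAULT_CURVE_EFFECTS: dict[FoodGroup, tuple[float, float, float]] = {
    FoodGroup.WHOLE_GRAINS: (225.0, 0.82, 0.05),
    FoodGroup.VEGETABLES: (400.0, 0.93, 0.03),
    FoodGroup.FRUITS: (400.0, 0.91, 0.04),
    FoodGroup.NUTS: (25.0, 0.86, 0.03),
    FoodGroup.LEGUMES: (200.0, 0.84, 0.07),
    FoodGroup.FISH: (200.0, 0.92, 0.03),
    FoodGroup.EGGS: (50.0, 1.04, 0.04),
    FoodGroup.MILK_DAIRY: (300.0, 1.03, 0.03),
    FoodGroup.REFINED_GRAINS: (150.0, 1.05, 0.04),
    FoodGroup.RED_MEAT: (100.0, 1.14, 0.04),
    FoodGroup.PROCESSED_MEAT: (50.0, 1.14, 0.04),
    FoodGroup.SSB: (500.0, 1.10, 0.05),
    FoodGroup.WHITE_MEAT: (75.0, 1.0, 0.0),
    FoodGroup.ADDED_OILS: (25.0, 1.0, 0.0),
}


def make_curveset(
    effects: dict[FoodGroup, tuple[float, float, float]] | None = None,
    n_points: int = 6,
) -> dict[FoodGroup, DoseResponseCurve]:
    """Piecewise-linear HR curves from (0, HR 1) to a plateau.

    ``effects`` maps each group to (plateau_dose, hr_at_plateau,
    ci_halfwidth); intermediate points are linear in dose so the curves are
    exactly the linear-interpolation surface, and CI half-widths shrink
    proportionally toward the HR-1 end (no uncertainty about a null
    change). White meat and added oils are emitted as neutral curves.
    """
    effects = dict(DEFAULT_CURVE_EFFECTS if effects is None else effects)
    curves: dict[FoodGroup, DoseResponseCurve] = {}
    for g, (dose1, hr1, halfw) in effects.items():
        if hr1 <= 0:
            raise ValueError(f"plateau HR for {g.value} must be > 0")
        if g in NEUTRAL_GROUPS:
            curves[g] = DoseResponseCurve(
                g, (), nutrigrade=DEFAULT_NUTRIGRADE_SCORES.get(g, 0.0), neutral=True
            )
            continue
        doses = [float(x) for x in np.linspace(0.0, dose1, n_points)]
        pts = []
        for d in doses:
            w = d / dose1 if dose1 > 0 else 0.0
            hr = 1.0 + w * (hr1 - 1.0)
            hw = w * halfw
            pts.append(CurvePoint(float(d), hr, hr - hw, hr + hw))
        curves[g] = DoseResponseCurve(
            g, tuple(pts), nutrigrade=DEFAULT_NUTRIGRADE_SCORES.get(g, 0.0)
        )
    return curves


def cohort_oracle(
    schedule: MortalitySchedule,
    start_age: int,
    trajectory: dict[int, float] | None,
    n: int,
    seed: int,
) -> tuple[float, float]:
    """Mean remaining lifetime of ``n`` simulated individuals, with its SE.

    Independent of the analytic life table: each individual is walked year
    by year with death probability q_a = m'_a / (1 + 0.5 m'_a) (m' the
    hazard-modified rate), deaths credit half a year, and survivors at the
    closure age draw an exponential tail with rate m'_terminal. Returns
    (sample mean, standard error).
    """
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    ages = np.arange(start_age, schedule.max_age + 1)
    m = schedule.rates_from(start_age).copy()
    if trajectory is not None:
        for i, a in enumerate(ages):
            if a in trajectory:
                m[i] *= trajectory[a]
    q = np.minimum(m / (1.0 + 0.5 * m), 1.0)

    lived = np.zeros(n)
    alive = np.ones(n, dtype=bool)
    for i in range(len(ages) - 1):  # terminal age handled by the tail
        if not alive.any():
            break
        dies = np.zeros(n, dtype=bool)
        dies[alive] = rng.uniform(size=int(alive.sum())) < q[i]
        lived[dies] += 0.5
        lived[alive & ~dies] += 1.0
        alive &= ~dies
    n_surv = int(alive.sum())
    if n_surv:
        lived[alive] += rng.exponential(scale=1.0 / m[-1], size=n_surv)
    mean = float(lived.mean())
    se = float(lived.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return mean, se
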