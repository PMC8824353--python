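"""Monte-Carlo uncertainty intervals and the m-parameterised sensitivity
hazard-ratio family.

Uncertainty intervals: for each of n replicates (default 200, fixed seed)
one uniform deviate u ~ U(0, 1) is drawn per food group and the group's
whole dose-response curve is placed between its 95% CI bands as
lo + u*(hi - lo), pointwise, preserving the curve's shape. The scenario's
LE gain is recomputed under each replicate curve set and the 95% UI is the
2.5th-97.5th percentile of the replicate gains (numpy linear-interpolation
percentiles). Draws are independent across groups and replicates. The
generator is numpy's default PCG64; the seed is part of the public
reproducibility contract.

Sensitivity family: to probe overlap between food-group effects (toward
the null) or meta-analytic over-adjustment (away from it), each hazard
ratio HR0 is replaced by

    HRa = HR0 + (1 - HR0) * (1 - m)          if HR0 <= 1,
    HRa = 1 / (HR0* + (1 - HR0*) * (1 - m))  if HR0 > 1, HR0* = 1/HR0,

with m in [0.5, 1.5]. m = 1 is the central model; m < 1 attenuates effects
toward HR = 1, m > 1 amplifies them. The reciprocal branch makes
protective and harmful effects behave symmetrically:
adjust_hr(h, m) * adjust_hr(1/h, m) = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .effect_engine import DietChangeScenario, gain_in_le
from .food_model import (
    CurvePoint,
    CurveSet,
    DoseResponseCurve,
    EnergyDensityTable,
    FoodGroup,
    NEUTRAL_GROUPS,
)
from .lifetable import MortalitySchedule

DEFAULT_N_DRAWS = 200
DEFAULT_SEED = 20190101  # fixed default seed, part of the reproducibility contract
M_LO, M_HI = 0.5, 1.5


@dataclass(frozen=True)
class UncertaintyConfig:
    n_draws: int = DEFAULT_N_DRAWS
    seed: int = DEFAULT_SEED
    percentiles: tuple[float, float] = (2.5, 97.5)

    def __post_init__(self):
        if self.n_draws < 2:
            raise ValueError("need at least 2 draws")
        lo, hi = self.percentiles
        if not (0 <= lo < hi <= 100):
            raise ValueError(f"percentiles must satisfy 0 <= lo < hi <= 100, got {self.percentiles}")


@dataclass(frozen=True)
class SensitivityConfig:
    m: float = 1.0

    def __post_init__(self):
        if not (M_LO <= self.m <= M_HI):
            raise ValueError(f"sensitivity parameter m must lie in [{M_LO}, {M_HI}], got {self.m}")


def adjust_hr(hr0: float, m: float) -> float:
    """Attenuate (m < 1) or amplify (m > 1) a hazard ratio toward/away from 1."""
    if hr0 <= 0:
        raise ValueError(f"hazard ratio must be > 0, got {hr0}")
    if not (M_LO <= m <= M_HI):
        raise ValueError(f"sensitivity parameter m must lie in [{M_LO}, {M_HI}], got {m}")
    if hr0 <= 1.0:
        return hr0 + (1.0 - hr0) * (1.0 - m)
    star = 1.0 / hr0
    return 1.0 / (star + (1.0 - star) * (1.0 - m))


def adjust_curve(curve: DoseResponseCurve, m: float) -> DoseResponseCurve:
    """Apply :func:`adjust_hr` to every tabulated HR of a curve.

    CI bands are adjusted with the same map so ordering is preserved
    (adjust_hr is monotone increasing in HR for fixed m).
    """
    if curve.neutral:
        return curve
    pts = tuple(
        CurvePoint(
            p.dose,
            adjust_hr(p.hr, m),
            min(adjust_hr(p.ci_lo, m), adjust_hr(p.ci_hi, m)),
            max(adjust_hr(p.ci_lo, m), adjust_hr(p.ci_hi, m)),
        )
        for p in curve.points
    )
    return DoseResponseCurve(curve.group, pts, curve.nutrigrade, False)


def adjust_curveset(curves: CurveSet, m: float) -> dict[FoodGroup, DoseResponseCurve]:
    return {g: adjust_curve(c, m) for g, c in curves.items()}


def draw_hr_set(
    curves: CurveSet,
    config: UncertaintyConfig,
    groups: Iterable[FoodGroup] | None = None,
) -> list[dict[FoodGroup, DoseResponseCurve]]:
    """Replicate curve sets for the Monte-Carlo uncertainty procedure.

    One uniform deviate per (replicate, food group); only groups listed in
    ``groups`` (default: all non-neutral) are perturbed, the rest stay
    central — per-group intervals redraw only the focal group.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    drawn = set(groups) if groups is not None else {
        g for g, c in curves.items() if not c.neutral
    }
    order = [g for g in FoodGroup if g in curves]  # fixed draw order
    out = []
    for _ in range(config.n_draws):
        u = rng.uniform(size=len(order))
        rep = {}
        for g, ug in zip(order, u):
            c = curves[g]
            rep[g] = c.blend(ug) if (g in drawn and not c.neutral) else c
        out.append(rep)
    return out


def uncertainty_interval(
    scenario: DietChangeScenario,
    schedule: MortalitySchedule,
    curves: CurveSet,
    densities: EnergyDensityTable,
    config: UncertaintyConfig = UncertaintyConfig(),
    groups: Iterable[FoodGroup] | None = None,
) -> tuple[float, float]:
    """95% UI of the LE gain across replicate HR draws.

    ``groups`` restricts both which groups are changed in the scenario and
    which are redrawn (per-group forest-plot intervals).
    """
    gains = replicate_gains(scenario, schedule, curves, densities, config, groups)
    lo, hi = config.percentiles
    return (
        float(np.percentile(gains, lo)),
        float(np.percentile(gains, hi)),
    )


def replicate_gains(
    scenario: DietChangeScenario,
    schedule: MortalitySchedule,
    curves: CurveSet,
    densities: EnergyDensityTable,
    config: UncertaintyConfig = UncertaintyConfig(),
    groups: Iterable[FoodGroup] | None = None,
) -> np.ndarray:
    """The raw per-replicate LE gains behind :func:`uncertainty_interval`."""
    draw_groups = None if groups is None else [g for g in groups]
    reps = draw_hr_set(curves, config, draw_groups)
    gains = np.empty(len(reps))
    for i, rep in enumerate(reps):
        gains[i] = gain_in_le(scenario, schedule, rep, densities, groups).gain
    return gains


def sensitivity_interval(
    scenario: DietChangeScenario,
    schedule: MortalitySchedule,
    curves: CurveSet,
    densities: EnergyDensityTable,
    groups: Iterable[FoodGroup] | None = None,
) -> tuple[float, float]:
    """LE gains under the attenuated (m = 0.5) and amplified (m = 1.5) models."""
    lo = gain_in_le(scenario, schedule, adjust_curveset(curves, M_LO), densities, groups).gain
    hi = gain_in_le(scenario, schedule, adjust_curveset(curves, M_HI), densities, groups).gain
    return (lo, hi)
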