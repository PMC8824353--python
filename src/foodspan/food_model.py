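"""Food groups, diet profiles, dose-response hazard-ratio curves, and the
energy-feasibility gate.

The model tracks 14 food groups. Each group carries a dose-response curve
giving the all-cause-mortality hazard ratio (HR) as a function of daily
intake in grams, tabulated from meta-analyses, together with 95% confidence
bands and a NutriGrade evidence score. Two groups (white meat, added plant
oils) are modelled as mortality-neutral: their curves are identically 1.

Diets are g/day intake vectors over all 14 groups. Three presets are
built in:

* ``TW`` - a typical Western diet (US/European consumption levels),
* ``OD`` - an optimized diet, each intake set where the dose-response
  curve plateaus (no further mortality benefit in moving intake),
* ``FA`` - a feasibility-approach diet, the per-group arithmetic midpoint
  of TW and OD.

A diet is only evaluated if its total energy lies strictly within
(4,000, 16,000) kJ/day, endpoints passing; outside that window the
calculator refuses to report estimates.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence


class FoodGroup(str, enum.Enum):
    """The 14 modelled food groups."""

    WHOLE_GRAINS = "whole_grains"
    VEGETABLES = "vegetables"
    FRUITS = "fruits"
    NUTS = "nuts"
    LEGUMES = "legumes"
    FISH = "fish"
    EGGS = "eggs"
    MILK_DAIRY = "milk_dairy"
    REFINED_GRAINS = "refined_grains"
    RED_MEAT = "red_meat"
    PROCESSED_MEAT = "processed_meat"
    WHITE_MEAT = "white_meat"
    SSB = "ssb"
    ADDED_OILS = "added_oils"


#: Groups modelled as having no mortality effect (HR identically 1).
NEUTRAL_GROUPS = frozenset({FoodGroup.WHITE_MEAT, FoodGroup.ADDED_OILS})


class GateResult(str, enum.Enum):
    PASS = "pass"
    REJECT_LOW = "reject_low"
    REJECT_HIGH = "reject_high"


#: Energy-feasibility window, kJ/day. Strict inequalities: diets at exactly
#: 4,000 or 16,000 kJ/day pass.
ENERGY_GATE_LOW_KJ = 4_000.0
ENERGY_GATE_HIGH_KJ = 16_000.0


class EnergyGateError(ValueError):
    """Raised when a diet falls outside the energy-feasibility window."""

    def __init__(self, label: str, energy_kj: float, result: "GateResult"):
        self.label = label
        self.energy_kj = energy_kj
        self.result = result
        bound = (
            f"below {ENERGY_GATE_LOW_KJ:.0f}"
            if result is GateResult.REJECT_LOW
            else f"above {ENERGY_GATE_HIGH_KJ:.0f}"
        )
        super().__init__(
            f"estimates not reported: diet {label!r} has total energy "
            f"{energy_kj:.0f} kJ/day, {bound} kJ/day"
        )


def _require_all_groups(mapping: Mapping[FoodGroup, float], what: str) -> None:
    missing = [g.value for g in FoodGroup if g not in mapping]
    if missing:
        raise KeyError(f"{what} missing food groups: {', '.join(missing)}")
    extra = [k for k in mapping if not isinstance(k, FoodGroup)]
    if extra:
        raise KeyError(f"{what} has unknown food groups: {extra}")


@dataclass(frozen=True)
class DietProfile:
    """A diet: g/day intake for every food group."""

    label: str
    intake: Mapping[FoodGroup, float]

    def __post_init__(self):
        _require_all_groups(self.intake, f"diet {self.label!r}")
        for g, v in self.intake.items():
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"diet {self.label!r}: intake for {g.value} must be a finite non-negative number, got {v}")
        object.__setattr__(self, "intake", dict(self.intake))

    def __getitem__(self, group: FoodGroup) -> float:
        return self.intake[group]

    def replace(self, label: str, **grams: float) -> "DietProfile":
        """Return a copy with the named groups' intakes overridden.

        Keyword names are food-group identifiers, e.g. ``legumes=200``.
        """
        new = dict(self.intake)
        for name, v in grams.items():
            new[FoodGroup(name)] = float(v)
        return DietProfile(label, new)

    def to_dict(self) -> dict:
        return {"label": self.label, "intake": {g.value: v for g, v in self.intake.items()}}

    @classmethod
    def from_dict(cls, d: Mapping) -> "DietProfile":
        return cls(d["label"], {FoodGroup(k): float(v) for k, v in d["intake"].items()})


# Preset intakes (g/day), typical Western (TW) and optimized (OD); the
# feasibility-approach diet (FA) is the per-group TW-OD midpoint.
_TW = {
    FoodGroup.WHOLE_GRAINS: 50.0,
    FoodGroup.VEGETABLES: 250.0,
    FoodGroup.FRUITS: 200.0,
    FoodGroup.NUTS: 0.0,
    FoodGroup.LEGUMES: 0.0,
    FoodGroup.FISH: 50.0,
    FoodGroup.EGGS: 50.0,
    FoodGroup.MILK_DAIRY: 300.0,
    FoodGroup.REFINED_GRAINS: 150.0,
    FoodGroup.RED_MEAT: 100.0,
    FoodGroup.PROCESSED_MEAT: 50.0,
    FoodGroup.WHITE_MEAT: 75.0,
    FoodGroup.SSB: 500.0,
    FoodGroup.ADDED_OILS: 25.0,
}
_OD = {
    FoodGroup.WHOLE_GRAINS: 225.0,
    FoodGroup.VEGETABLES: 400.0,
    FoodGroup.FRUITS: 400.0,
    FoodGroup.NUTS: 25.0,
    FoodGroup.LEGUMES: 200.0,
    FoodGroup.FISH: 200.0,
    FoodGroup.EGGS: 25.0,
    FoodGroup.MILK_DAIRY: 200.0,
    FoodGroup.REFINED_GRAINS: 50.0,
    FoodGroup.RED_MEAT: 0.0,
    FoodGroup.PROCESSED_MEAT: 0.0,
    FoodGroup.WHITE_MEAT: 50.0,
    FoodGroup.SSB: 0.0,
    FoodGroup.ADDED_OILS: 25.0,
}
_FA = {g: (_TW[g] + _OD[g]) / 2.0 for g in FoodGroup}

PRESET_NAMES = ("TW", "FA", "OD")


def preset_diet(name: str) -> DietProfile:
    """Return one of the built-in diet presets.

    ``name`` is ``"TW"`` (typical Western), ``"FA"`` (feasibility approach,
    the TW-OD midpoint for every group) or ``"OD"`` (optimized).
    """
    key = name.upper()
    if key == "TW":
        return DietProfile("TW", _TW)
    if key == "FA":
        return DietProfile("FA", _FA)
    if key == "OD":
        return DietProfile("OD", _OD)
    raise ValueError(f"unknown diet preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}")


@dataclass(frozen=True)
class EnergyDensityTable:
    """kJ per gram for each food group."""

    density: Mapping[FoodGroup, float]

    def __post_init__(self):
        _require_all_groups(self.density, "energy-density table")
        for g, v in self.density.items():
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"density for {g.value} must be finite and >= 0, got {v}")
        object.__setattr__(self, "density", dict(self.density))

    def __getitem__(self, group: FoodGroup) -> float:
        return self.density[group]


# Default densities (kJ/g): seeded from typical food-composition values and
# calibrated so the TW and OD presets total 8,085 and 7,615 kJ/day.
DEFAULT_ENERGY_DENSITIES = EnergyDensityTable(
    {
        FoodGroup.WHOLE_GRAINS: 4.808,
        FoodGroup.VEGETABLES: 1.186,
        FoodGroup.FRUITS: 2.148,
        FoodGroup.NUTS: 24.375,
        FoodGroup.LEGUMES: 3.872,
        FoodGroup.FISH: 6.672,
        FoodGroup.EGGS: 6.513,
        FoodGroup.MILK_DAIRY: 2.599,
        FoodGroup.REFINED_GRAINS: 10.713,
        FoodGroup.RED_MEAT: 10.262,
        FoodGroup.PROCESSED_MEAT: 13.739,
        FoodGroup.WHITE_MEAT: 6.998,
        FoodGroup.SSB: 1.842,
        FoodGroup.ADDED_OILS: 36.528,
    }
)


def total_energy(diet: DietProfile, densities: EnergyDensityTable) -> float:
    """Total energy of a diet, kJ/day: sum of intake x density over groups."""
    return sum(diet[g] * densities[g] for g in FoodGroup)


def check_energy_gate(diet: DietProfile, densities: EnergyDensityTable) -> GateResult:
    """Classify a diet against the (4,000, 16,000) kJ/day feasibility window."""
    e = total_energy(diet, densities)
    if e < ENERGY_GATE_LOW_KJ:
        return GateResult.REJECT_LOW
    if e > ENERGY_GATE_HIGH_KJ:
        return GateResult.REJECT_HIGH
    return GateResult.PASS


def require_energy_gate(diet: DietProfile, densities: EnergyDensityTable) -> None:
    """Raise :class:`EnergyGateError` if the diet fails the energy gate."""
    result = check_energy_gate(diet, densities)
    if result is not GateResult.PASS:
        raise EnergyGateError(diet.label, total_energy(diet, densities), result)


@dataclass(frozen=True)
class CurvePoint:
    dose: float  # g/day
    hr: float
    ci_lo: float
    ci_hi: float


@dataclass(frozen=True)
class DoseResponseCurve:
    """One food group's HR-vs-intake curve with 95% CI bands.

    HR(d) is evaluated by linear interpolation between tabulated points and
    flat (plateau) extrapolation beyond the first/last dose. Because diet
    changes use the ratio HR(to)/HR(from), the curve's reference category
    (where the meta-analysis anchored HR = 1) cancels and need not be stored.
    """

    group: FoodGroup
    points: Sequence[CurvePoint]
    nutrigrade: float = 0.0
    neutral: bool = False

    def __post_init__(self):
        if self.neutral and not self.points:
            object.__setattr__(self, "points", (CurvePoint(0.0, 1.0, 1.0, 1.0),))
        pts = tuple(self.points)
        if not pts:
            raise ValueError(f"curve for {self.group.value} has no points")
        doses = [p.dose for p in pts]
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ValueError(f"curve for {self.group.value}: doses must be strictly increasing")
        for p in pts:
            if min(p.hr, p.ci_lo, p.ci_hi) <= 0:
                raise ValueError(f"curve for {self.group.value}: HR and CI bands must be positive")
            if not (p.ci_lo <= p.hr <= p.ci_hi):
                raise ValueError(
                    f"curve for {self.group.value}: need ci_lo <= hr <= ci_hi at dose {p.dose}"
                )
        if self.neutral and any(p.hr != 1.0 or p.ci_lo != 1.0 or p.ci_hi != 1.0 for p in pts):
            raise ValueError(f"neutral curve for {self.group.value} must have HR = CI = 1 everywhere")
        if not (0.0 <= self.nutrigrade <= 10.0):
            raise ValueError(f"NutriGrade score must lie in [0, 10], got {self.nutrigrade}")
        object.__setattr__(self, "points", pts)

    def _evaluate(self, dose: float, band: str) -> float:
        if dose < 0:
            raise ValueError(f"dose must be non-negative, got {dose}")
        pts = self.points
        vals = [getattr(p, band) for p in pts]
        if dose <= pts[0].dose:
            return vals[0]
        if dose >= pts[-1].dose:
            return vals[-1]
        for (p0, v0), (p1, v1) in zip(zip(pts, vals), zip(pts[1:], vals[1:])):
            if p0.dose <= dose <= p1.dose:
                w = (dose - p0.dose) / (p1.dose - p0.dose)
                return v0 + w * (v1 - v0)
        raise AssertionError("unreachable")  # pragma: no cover

    def hr_at(self, dose: float) -> float:
        """Central HR at a dose (interpolated, plateau beyond curve ends)."""
        return self._evaluate(dose, "hr")

    def blend(self, u: float) -> "DoseResponseCurve":
        """Place the whole curve between its CI bands: lo + u*(hi - lo) pointwise.

        ``u`` in [0, 1]; u = 0 gives the lower band, u = 1 the upper. Used by
        the uncertainty procedure, which draws one u per group per replicate
        so the within-curve shape is preserved.
        """
        if self.neutral:
            return self
        pts = tuple(
            CurvePoint(p.dose, p.ci_lo + u * (p.ci_hi - p.ci_lo), p.ci_lo, p.ci_hi)
            for p in self.points
        )
        # blended hr may sit anywhere within [ci_lo, ci_hi]; invariant holds
        return DoseResponseCurve(self.group, pts, self.nutrigrade, False)


def hazard_ratio_for_change(
    curve: DoseResponseCurve, from_dose: float, to_dose: float
) -> tuple[float, float, float]:
    """HR of moving intake from ``from_dose`` to ``to_dose`` g/day.

    Returns (central, lower, upper) as the ratio HR(to)/HR(from) evaluated on
    the central curve and on each CI band. Neutral curves return (1, 1, 1).
    """
    if from_dose < 0 or to_dose < 0:
        raise ValueError("doses must be non-negative")
    if curve.neutral:
        return (1.0, 1.0, 1.0)
    out = []
    for band in ("hr", "ci_lo", "ci_hi"):
        out.append(curve._evaluate(to_dose, band) / curve._evaluate(from_dose, band))
    return tuple(out)  # type: ignore[return-value]


CurveSet = Mapping[FoodGroup, DoseResponseCurve]


def validate_curveset(curves: CurveSet, groups: Iterable[FoodGroup] | None = None) -> None:
    """Check that every requested non-neutral group has a curve."""
    wanted = list(groups) if groups is not None else list(FoodGroup)
    missing = [g.value for g in wanted if g not in curves and g not in NEUTRAL_GROUPS]
    if missing:
        raise KeyError(f"no dose-response curve for food groups: {', '.join(missing)}")
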