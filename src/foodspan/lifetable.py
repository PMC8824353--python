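"""Period life tables: age-grouped mortality rates, single-year expansion,
remaining life expectancy, and hazard-modified schedules.

The engine follows standard period life-table methodology. Age-specific
mortality rates m_a (deaths per person-year) are converted to annual death
probabilities with the uniform-deaths-within-the-year assumption

    q_a = m_a / (1 + 0.5 * m_a),   capped at 1,

survivorship l is accumulated from the query age, each lived year credits
l_a * (1 - q_a) full years plus half a year for deaths (l_a * q_a * 0.5),
and the open-ended terminal interval at the closure age contributes
l_terminal / m_terminal person-years (constant-hazard tail). Remaining life
expectancy is total person-years divided by l at the query age, i.e. it is
always conditional on survival to that age.

With this q-from-m conversion the constant-rate life table is exact:
(1 - 0.5 q) / q = 1 / m, so a schedule with constant rate m has remaining
LE exactly 1/m at every age regardless of the closure age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

DEFAULT_MAX_AGE = 110


@dataclass(frozen=True)
class AgeBand:
    """One age band: [start, end) in whole years; ``end=None`` means open-ended."""

    start: int
    end: int | None
    rate: float

    def __post_init__(self):
        if self.end is not None and self.end <= self.start:
            raise ValueError(f"band [{self.start}, {self.end}) is empty or reversed")
        if self.rate < 0 or not math.isfinite(self.rate):
            raise ValueError(f"band starting at {self.start}: rate must be finite and >= 0")


@dataclass(frozen=True)
class AgeGroupedRates:
    """All-cause mortality rates in age bands for one sex and region."""

    sex: str
    region: str
    bands: Sequence[AgeBand]

    def __post_init__(self):
        bands = tuple(sorted(self.bands, key=lambda b: b.start))
        if not bands:
            raise ValueError("no age bands")
        for a, b in zip(bands, bands[1:]):
            if a.end is None:
                raise ValueError(f"open-ended band starting at {a.start} is not last")
            if a.end < b.start:
                raise ValueError(f"gap between band ending at {a.end} and band starting at {b.start}")
            if a.end > b.start:
                raise ValueError(f"bands starting at {a.start} and {b.start} overlap")
        if bands[-1].end is not None:
            raise ValueError("final band must be open-ended")
        if bands[-1].rate <= 0:
            raise ValueError("open-ended band must have rate > 0 (life expectancy diverges otherwise)")
        object.__setattr__(self, "bands", bands)

    @property
    def start_age(self) -> int:
        return self.bands[0].start


@dataclass(frozen=True)
class MortalitySchedule:
    """Single-year mortality rates from ``start_age`` through ``max_age``."""

    sex: str
    region: str
    max_age: int
    m: Mapping[int, float]

    def __post_init__(self):
        ages = sorted(self.m)
        if not ages:
            raise ValueError("empty schedule")
        if ages != list(range(ages[0], self.max_age + 1)):
            raise ValueError(
                f"rates must cover every single-year age from {ages[0]} to max_age={self.max_age}"
            )
        for a, r in self.m.items():
            if r < 0 or not math.isfinite(r):
                raise ValueError(f"rate at age {a} must be finite and >= 0")
        if self.m[self.max_age] <= 0:
            raise ValueError("terminal-age rate must be > 0")
        object.__setattr__(self, "m", dict(self.m))

    @property
    def start_age(self) -> int:
        return min(self.m)

    def rates_from(self, age: int) -> np.ndarray:
        """Rates as an array for ages ``age..max_age`` inclusive."""
        return np.array([self.m[a] for a in range(age, self.max_age + 1)])


def expand_to_single_year(grouped: AgeGroupedRates, max_age: int = DEFAULT_MAX_AGE) -> MortalitySchedule:
    """Expand banded rates to single-year ages, piecewise-constant.

    Every age in a band receives the band's rate unchanged; ages in the
    open-ended band up to ``max_age`` receive that band's rate.
    """
    open_start = grouped.bands[-1].start
    if max_age < open_start:
        raise ValueError(f"max_age={max_age} precedes the open band starting at {open_start}")
    m: dict[int, float] = {}
    for band in grouped.bands:
        end = band.end if band.end is not None else max_age + 1
        for a in range(band.start, min(end, max_age + 1)):
            m[a] = band.rate
    return MortalitySchedule(grouped.sex, grouped.region, max_age, m)


def life_expectancy(schedule: MortalitySchedule, age: int) -> float:
    """Remaining life expectancy at ``age``, conditional on survival to it."""
    if age < schedule.start_age or age > schedule.max_age:
        raise ValueError(
            f"age {age} outside schedule range [{schedule.start_age}, {schedule.max_age}]"
        )
    m = schedule.rates_from(age)
    q = np.minimum(m[:-1] / (1.0 + 0.5 * m[:-1]), 1.0)
    surv = np.concatenate([[1.0], np.cumprod(1.0 - q)])
    person_years = float(np.sum(surv[:-1] * (1.0 - q) + surv[:-1] * q * 0.5))
    person_years += surv[-1] / m[-1]  # open terminal interval
    return person_years


def apply_hazard_trajectory(
    schedule: MortalitySchedule, start_age: int, multiplier: Mapping[int, float]
) -> MortalitySchedule:
    """Multiply rates from ``start_age`` up by an age-indexed hazard multiplier.

    Rates below ``start_age`` are untouched; the input schedule is not
    modified. ``multiplier`` must cover every age from ``start_age`` through
    the closure age and be strictly positive.
    """
    new = dict(schedule.m)
    for a in range(max(start_age, schedule.start_age), schedule.max_age + 1):
        try:
            h = multiplier[a]
        except KeyError:
            raise KeyError(f"hazard multiplier not defined for age {a}") from None
        if h <= 0 or not math.isfinite(h):
            raise ValueError(f"hazard multiplier at age {a} must be finite and > 0, got {h}")
        new[a] = schedule.m[a] * h
    return MortalitySchedule(schedule.sex, schedule.region, schedule.max_age, new)
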