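"""Readers and writers for the tabular input/output formats.

Formats
-------
rates CSV       sex, region, age_start, age_end (empty = open-ended), rate
                — one row per age band. A GBD results-tool export layout
                (location/sex/age/val columns, ages like "20 to 24" or
                "95 plus") is also accepted and mapped onto the same
                structure.
HR CSV          group, dose_g, hr, ci_lo, ci_hi — one row per tabulated
                dose-response point.
metadata CSV    group, nutrigrade, neutral — per-curve evidence score and
                the neutral flag.
densities CSV   group, kj_per_g.
diet YAML/JSON  mapping of the 14 group identifiers to g/day, plus an
                optional "label".
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .food_model import (
    CurvePoint,
    DietProfile,
    DoseResponseCurve,
    EnergyDensityTable,
    FoodGroup,
)
from .lifetable import AgeBand, AgeGroupedRates, MortalitySchedule

_GBD_AGE_RE = re.compile(r"^\s*(\d+)\s*(?:to\s*(\d+)|plus|\+)?\s*(?:years?)?\s*$", re.I)


def _parse_gbd_age(text: str) -> tuple[int, int | None]:
    """Parse a GBD age-group label like '20 to 24', '<1 year', '95 plus'."""
    t = str(text).strip().lower()
    if t.startswith("<"):
        return 0, int(re.sub(r"\D", "", t) or 1)
    m = _GBD_AGE_RE.match(t)
    if not m:
        raise ValueError(f"cannot parse age group {text!r}")
    start = int(m.group(1))
    end = int(m.group(2)) + 1 if m.group(2) else None
    return start, end


def read_grouped_rates(path: str | Path) -> AgeGroupedRates:
    """Read one sex/region extract of age-banded mortality rates.

    Accepts either the native layout (sex, region, age_start, age_end,
    rate) or a GBD results-tool export (location, sex, age, val).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    cols = {c.lower().strip(): c for c in df.columns}
    if "age_start" in cols and "rate" in cols:
        sex = str(df[cols["sex"]].iloc[0]) if "sex" in cols else "unknown"
        region = str(df[cols["region"]].iloc[0]) if "region" in cols else "unknown"
        bands = []
        for _, row in df.iterrows():
            end_raw = row[cols["age_end"]] if "age_end" in cols else None
            end = None if end_raw is None or pd.isna(end_raw) or str(end_raw).strip() == "" else int(end_raw)
            bands.append(AgeBand(int(row[cols["age_start"]]), end, float(row[cols["rate"]])))
    elif "age" in cols and "val" in cols:
        sex = str(df[cols["sex"]].iloc[0]).lower() if "sex" in cols else "unknown"
        region = str(df[cols["location"]].iloc[0]) if "location" in cols else "unknown"
        bands = []
        for _, row in df.iterrows():
            start, end = _parse_gbd_age(row[cols["age"]])
            bands.append(AgeBand(start, end, float(row[cols["val"]])))
    else:
        raise ValueError(
            f"{path}: unrecognised rate layout; expected columns "
            "(sex, region, age_start, age_end, rate) or GBD-style (location, sex, age, val)"
        )
    return AgeGroupedRates(sex=sex, region=region, bands=bands)


def write_grouped_rates(rates: AgeGroupedRates, path: str | Path) -> None:
    rows = [
        {
            "sex": rates.sex,
            "region": rates.region,
            "age_start": b.start,
            "age_end": "" if b.end is None else b.end,
            "rate": b.rate,
        }
        for b in rates.bands
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_schedule(schedule: MortalitySchedule, path: str | Path) -> None:
    """Dump a single-year schedule as age,rate CSV for inspection."""
    pd.DataFrame(
        {"age": sorted(schedule.m), "rate": [schedule.m[a] for a in sorted(schedule.m)]}
    ).to_csv(path, index=False)


def read_curves(hr_path: str | Path, metadata_path: str | Path) -> dict[FoodGroup, DoseResponseCurve]:
    """Read dose-response curves (points CSV) plus their metadata CSV."""
    meta = pd.read_csv(metadata_path, float_precision="round_trip")
    meta_by_group: dict[FoodGroup, tuple[float, bool]] = {}
    for _, row in meta.iterrows():
        g = FoodGroup(str(row["group"]).strip())
        neutral = str(row.get("neutral", "false")).strip().lower() in ("1", "true", "yes")
        meta_by_group[g] = (float(row["nutrigrade"]), neutral)

    pts = pd.read_csv(hr_path, float_precision="round_trip")
    curves: dict[FoodGroup, DoseResponseCurve] = {}
    for name, sub in pts.groupby("group"):
        g = FoodGroup(str(name).strip())
        nutrigrade, neutral = meta_by_group.get(g, (0.0, False))
        sub = sub.sort_values("dose_g")
        points = tuple(
            CurvePoint(float(r.dose_g), float(r.hr), float(r.ci_lo), float(r.ci_hi))
            for r in sub.itertuples()
        )
        curves[g] = DoseResponseCurve(g, points, nutrigrade=nutrigrade, neutral=neutral)
    for g, (nutrigrade, neutral) in meta_by_group.items():
        if neutral and g not in curves:
            curves[g] = DoseResponseCurve(g, (), nutrigrade=nutrigrade, neutral=True)
    return curves


def write_curves(
    curves: Mapping[FoodGroup, DoseResponseCurve], hr_path: str | Path, metadata_path: str | Path
) -> None:
    rows = []
    for g, c in curves.items():
        for p in c.points:
            rows.append(
                {"group": g.value, "dose_g": p.dose, "hr": p.hr, "ci_lo": p.ci_lo, "ci_hi": p.ci_hi}
            )
    pd.DataFrame(rows).to_csv(hr_path, index=False)
    meta = [
        {"group": g.value, "nutrigrade": c.nutrigrade, "neutral": c.neutral}
        for g, c in curves.items()
    ]
    pd.DataFrame(meta).to_csv(metadata_path, index=False)


def read_densities(path: str | Path) -> EnergyDensityTable:
    df = pd.read_csv(path, float_precision="round_trip")
    return EnergyDensityTable(
        {FoodGroup(str(r.group).strip()): float(r.kj_per_g) for r in df.itertuples()}
    )


def write_densities(densities: EnergyDensityTable, path: str | Path) -> None:
    pd.DataFrame(
        [{"group": g.value, "kj_per_g": densities[g]} for g in FoodGroup]
    ).to_csv(path, index=False)


def read_diet(path: str | Path) -> DietProfile:
    """Read a diet profile from YAML or JSON."""
    p = Path(path)
    text = p.read_text()
    data = json.loads(text) if p.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of food groups to g/day")
    label = str(data.pop("label", p.stem))
    intake = {FoodGroup(k): float(v) for k, v in data.items()}
    return DietProfile(label, intake)


def write_diet(diet: DietProfile, path: str | Path) -> None:
    p = Path(path)
    data: dict = {"label": diet.label}
    data.update({g.value: diet.intake[g] for g in FoodGroup})
    if p.suffix.lower() == ".json":
        p.write_text(json.dumps(data, indent=2) + "\n")
    else:
        p.write_text(yaml.safe_dump(data, sort_keys=False))
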