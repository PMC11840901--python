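"""Population / results file formats and scenario-config parsing.

The population CSV has one row per child with the columns

    id, community, gender, age_years, weight_kg, height_m, pal,
    perception, scib, healthy_bmi[, tdei0]

Units are fixed by the column names (kg and m, never cm). Rows with missing
or unparseable required values are excluded, counted per field and reported
— mirroring how the calibration data were cleaned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .core import Population, bmr_children
from .scenarios import InterventionSpec, ScenarioConfig
from .synthpop import baseline_tdei

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "id",
    "community",
    "gender",
    "age_years",
    "weight_kg",
    "height_m",
    "pal",
    "perception",
    "scib",
    "healthy_bmi",
)
_NUMERIC = ("age_years", "weight_kg", "height_m", "pal", "scib", "healthy_bmi")


class SchemaError(ValueError):
    """The population file is missing a required column."""


@dataclass
class ExclusionReport:
    """Counts of rows dropped for missing/unparseable required fields."""

    total_rows: int
    retained: int
    excluded_by_field: dict[str, int] = field(default_factory=dict)

    @property
    def excluded(self) -> int:
        return self.total_rows - self.retained

    @property
    def pct_excluded(self) -> float:
        return 100.0 * self.excluded / self.total_rows if self.total_rows else 0.0

    def __str__(self) -> str:
        per_field = ", ".join(
            f"{k}: {v}" for k, v in self.excluded_by_field.items() if v
        ) or "none"
        return (
            f"{self.retained}/{self.total_rows} children retained "
            f"({self.pct_excluded:.1f}% excluded; by field: {per_field})"
        )


def read_population(path: Union[str, Path]) -> tuple[Population, ExclusionReport]:
    """Read a population CSV, dropping and counting incomplete rows.

    ``tdei0`` is derived as BMR x PAL when the column is absent.
    """
    df = pd.read_csv(path, dtype={"id": str})
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing required column(s) {missing_cols}")
    total = len(df)
    if total == 0:
        raise ValueError(f"{path}: no data rows")

    for col in _NUMERIC:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df[list(REQUIRED_COLUMNS)].isna()
    excluded_by_field = {c: int(bad[c].sum()) for c in REQUIRED_COLUMNS}
    keep = ~bad.any(axis=1)
    df = df[keep]
    report = ExclusionReport(
        total_rows=total, retained=len(df), excluded_by_field=excluded_by_field
    )
    if report.excluded:
        logger.info("%s: %s", path, report)
    if len(df) == 0:
        raise ValueError(f"{path}: all rows excluded for missing values")

    if "tdei0" in df.columns and df["tdei0"].notna().all():
        tdei0 = pd.to_numeric(df["tdei0"]).to_numpy(float)
    else:
        bmr0 = bmr_children(
            df["gender"].to_numpy(str),
            df["age_years"].to_numpy(int),
            df["weight_kg"].to_numpy(float),
        )
        tdei0 = baseline_tdei(bmr0, df["pal"].to_numpy(float))

    pop = Population(
        ids=df["id"].to_numpy(str),
        community=df["community"].to_numpy(str),
        gender=df["gender"].to_numpy(str),
        age0=df["age_years"].to_numpy(int),
        height0=df["height_m"].to_numpy(float),
        weight0=df["weight_kg"].to_numpy(float),
        pal0=df["pal"].to_numpy(float),
        tdei0=tdei0,
        scib=df["scib"].to_numpy(float),
        healthy_bmi=df["healthy_bmi"].to_numpy(float),
        perception=df["perception"].to_numpy(str),
    )
    return pop, report


def write_population(pop: Population, path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        {
            "id": pop.ids,
            "community": pop.community,
            "gender": pop.gender,
            "age_years": pop.age0,
            "weight_kg": pop.weight0,
            "height_m": pop.height0,
            "pal": pop.pal0,
            "perception": (
                pop.perception if pop.perception is not None else ["about_right"] * len(pop)
            ),
            "scib": pop.scib,
            "healthy_bmi": pop.healthy_bmi,
            "tdei0": pop.tdei0,
        }
    )
    df.to_csv(path, index=False)


def split_by_community(pop: Population) -> dict[str, Population]:
    """One Population per community label (each its own norm-sharing group)."""
    out = {}
    for name in np.unique(pop.community):
        out[str(name)] = pop.take(np.flatnonzero(pop.community == name))
    return out


def load_scenario_config(path: Union[str, Path]) -> ScenarioConfig:
    """Flat key-value scenario config (YAML, which subsumes JSON).

    Keys: w_hb, delta_pal, delta_kcal, adherence, months, reps, seed, label.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a flat mapping of scenario keys")
    known = {"w_hb", "delta_pal", "delta_kcal", "adherence", "months", "reps", "seed", "label"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
    intervention = None
    if any(k in raw for k in ("delta_pal", "delta_kcal")):
        intervention = InterventionSpec(
            delta_pal=float(raw.get("delta_pal", 0.0)),
            delta_kcal=float(raw.get("delta_kcal", 0.0)),
            adherence_fraction=float(raw.get("adherence", 0.25)),
            label=str(raw.get("label", "custom intervention")),
        )
    return ScenarioConfig(
        w_hb=float(raw.get("w_hb", 0.5)),
        intervention=intervention,
        months=int(raw.get("months", 36)),
        seed=int(raw.get("seed", 0)),
        bootstrap_reps=int(raw.get("reps", 1000)),
        label=str(raw.get("label", "custom")),
    )


def trajectory_frame(results: dict[str, dict[str, object]]) -> pd.DataFrame:
    """Tidy long table (scenario, community, month, median_bmi)."""
    rows = []
    for community, per_scenario in results.items():
        for scenario, res in per_scenario.items():
            traj = getattr(res, "trajectory", None)
            if traj is None:
                continue
            for month, m in enumerate(traj.median_bmi):
                rows.append(
                    {
                        "scenario": scenario,
                        "community": community,
                        "month": month,
                        "median_bmi": m,
                    }
                )
    return pd.DataFrame(rows)
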