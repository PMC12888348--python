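"""Long-format CSV input/output, schema validation and run configuration.

The canonical interchange format is tidy long-format CSV: one row per
observation (subject x visit x time). Column names are remappable via a
schema mapping because studies export under many dialects; defaults are
``subject``, ``visit``, ``time_min``, ``hco3`` for bicarbonate tables and
``subject``, ``visit``, ``time_min`` plus one column per symptom for GI
tables. Times are integer minutes post-ingestion.
"""

from __future__ import annotations

import logging
import math
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("bicarbkin")

#: Canonical symptom names of the 12-item GI questionnaire, in questionnaire order.
SYMPTOMS: tuple[str, ...] = (
    "reflux",
    "heartburn",
    "bloating",
    "upper_abdominal_cramps",
    "vomiting",
    "nausea",
    "intestinal_cramps",
    "flatulence",
    "urge_to_defecate",
    "loose_stool",
    "dizziness",
    "headache",
)

#: Nominal sampling schedule: baseline plus every 30 min to 240 min (nine samples).
NOMINAL_SCHEDULE: tuple[int, ...] = tuple(range(0, 241, 30))


class SchemaError(ValueError):
    """A required column is absent from the input table."""


class ValidationError(ValueError):
    """A row or record violates a domain invariant."""


class ParseError(ValueError):
    """A cell could not be parsed as the expected type."""


@dataclass(frozen=True)
class BicarbSeries:
    """One subject-visit's observed (time, [HCO3-]) knots.

    times are strictly increasing integer-valued minutes including 0;
    concentrations are finite and positive, in mmol/L.
    """

    subject_id: str
    visit: int
    times: tuple[float, ...]
    concentrations: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.concentrations):
            raise ValidationError(
                f"{self.subject_id} visit {self.visit}: times and concentrations "
                f"differ in length ({len(self.times)} vs {len(self.concentrations)})"
            )
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.size and not np.all(np.diff(t) > 0):
            raise ValidationError(
                f"{self.subject_id} visit {self.visit}: times must be strictly increasing"
            )
        if t.size and t[0] != 0:
            raise ValidationError(
                f"{self.subject_id} visit {self.visit}: series must include time 0"
            )
        if not np.all(np.isfinite(c)) or np.any(c <= 0):
            raise ValidationError(
                f"{self.subject_id} visit {self.visit}: concentrations must be finite and > 0"
            )


@dataclass(frozen=True)
class GIResponse:
    """One subject-visit-timepoint's 12 raw symptom ratings (Likert 1-10)."""

    subject_id: str
    visit: int
    time_min: int
    ratings: Mapping[str, int]

    def __post_init__(self) -> None:
        missing = set(SYMPTOMS) - set(self.ratings)
        extra = set(self.ratings) - set(SYMPTOMS)
        if missing or extra:
            raise ValidationError(
                f"{self.subject_id} visit {self.visit} t={self.time_min}: ratings must "
                f"cover exactly the 12 symptoms (missing={sorted(missing)}, extra={sorted(extra)})"
            )
        for name, r in self.ratings.items():
            if not (isinstance(r, (int, np.integer)) and 1 <= r <= 10):
                raise ValidationError(
                    f"{self.subject_id} visit {self.visit} t={self.time_min}: "
                    f"rating for {name} is {r!r}, must be an integer in 1..10"
                )


@dataclass(frozen=True)
class RunConfig:
    """Analysis configuration shared across pipeline stages.

    thresholds are increases above baseline (mmol/L) whose crossing times and
    exceedance probabilities are computed; mc_probability_cutoff is the
    predefined probability above which a time point is flagged as one where
    most individuals would meet the criterion.
    """

    grid_start_min: int = 0
    grid_end_min: int = 240
    thresholds: tuple[float, ...] = (5.0, 6.0)
    mc_iterations: int = 100_000
    mc_probability_cutoff: float = 0.80
    rng_seed: int = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.grid_end_min <= self.grid_start_min:
            raise ValidationError("grid_end_min must exceed grid_start_min")
        if any(t <= 0 for t in self.thresholds):
            raise ValidationError("thresholds must be positive")
        if self.mc_iterations < 1:
            raise ValidationError("mc_iterations must be >= 1")
        if not 0 < self.mc_probability_cutoff < 1:
            raise ValidationError("mc_probability_cutoff must be in (0, 1)")


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Read a TOML key-value file mirroring RunConfig; kwargs override file values."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    if "thresholds" in raw:
        raw["thresholds"] = tuple(float(t) for t in raw["thresholds"])
    cfg = RunConfig(**raw)
    if overrides:
        overrides = {k: v for k, v in overrides.items() if v is not None}
        cfg = replace(cfg, **overrides)
    return cfg


DEFAULT_BICARB_SCHEMA: Mapping[str, str] = {
    "subject": "subject",
    "visit": "visit",
    "time_min": "time_min",
    "hco3": "hco3",
}


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: required column {col!r} not found "
                              f"(have {list(df.columns)})")


def read_bicarb_table(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> list[BicarbSeries]:
    """Read a long-format bicarbonate CSV into one BicarbSeries per (subject, visit).

    schema maps canonical field names (subject, visit, time_min, hco3) to the
    file's column names. Duplicated (subject, visit, time) rows are rejected,
    never silently collapsed.
    """
    sch = dict(DEFAULT_BICARB_SCHEMA)
    if schema:
        sch.update(schema)
    # round_trip parsing so write->read reproduces every float bit-for-bit
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, list(sch.values()), path)
    df = df.rename(columns={v: k for k, v in sch.items()})

    hco3 = pd.to_numeric(df["hco3"], errors="coerce")
    bad = df.index[hco3.isna() & df["hco3"].notna()]
    if len(bad):
        row = int(bad[0])
        raise ParseError(
            f"{path}: non-numeric concentration {df.loc[row, 'hco3']!r} at data row {row + 1}"
        )
    df["hco3"] = hco3

    dup = df.duplicated(subset=["subject", "visit", "time_min"], keep=False)
    if dup.any():
        r = df[dup].iloc[0]
        raise ValidationError(
            f"{path}: duplicate timepoint for subject {r['subject']} "
            f"visit {r['visit']} t={r['time_min']} min"
        )

    out: list[BicarbSeries] = []
    for (subj, visit), grp in df.groupby(["subject", "visit"], sort=True):
        grp = grp.sort_values("time_min")
        out.append(
            BicarbSeries(
                subject_id=str(subj),
                visit=int(visit),
                times=tuple(float(t) for t in grp["time_min"]),
                concentrations=tuple(float(c) for c in grp["hco3"]),
            )
        )
    logger.info("read %d series (%d rows) from %s", len(out), len(df), path)
    return out


def write_bicarb_table(series: Sequence[BicarbSeries], path: str | Path) -> None:
    """Write BicarbSeries collection as canonical long-format CSV."""
    rows = [
        {"subject": s.subject_id, "visit": s.visit, "time_min": t, "hco3": c}
        for s in series
        for t, c in zip(s.times, s.concentrations)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_gi_table(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> list[GIResponse]:
    """Read a long-format GI symptom CSV into one GIResponse per (subject, visit, time).

    Expects the 12 symptom columns (canonical names in SYMPTOMS) plus subject,
    visit and time_min; schema remaps any of these. Ratings are validated to 1..10.
    """
    sch: dict[str, str] = {"subject": "subject", "visit": "visit", "time_min": "time_min"}
    sch.update({s: s for s in SYMPTOMS})
    if schema:
        sch.update(schema)
    df = pd.read_csv(path)
    _require_columns(df, list(sch.values()), path)
    df = df.rename(columns={v: k for k, v in sch.items()})

    out: list[GIResponse] = []
    for _, row in df.iterrows():
        out.append(
            GIResponse(
                subject_id=str(row["subject"]),
                visit=int(row["visit"]),
                time_min=int(row["time_min"]),
                ratings={s: int(row[s]) for s in SYMPTOMS},
            )
        )
    logger.info("read %d GI responses from %s", len(out), path)
    return out


def write_gi_table(responses: Sequence[GIResponse], path: str | Path) -> None:
    rows = [
        {"subject": r.subject_id, "visit": r.visit, "time_min": r.time_min,
         **{s: r.ratings[s] for s in SYMPTOMS}}
        for r in responses
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
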