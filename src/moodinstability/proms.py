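"""Domain types, scale definitions, validation, and CSV I/O for longitudinal PROM data.

The package works on long-format tables: one row per participant x scheduled
assessment x scale, carrying the scale total score plus (optionally) the
participant's SF-12 mental/physical component summary T-scores for that
assessment and time-invariant covariates (diagnostic group, sex, race, age at
enrollment).  Time is an integer index of scheduled bi-monthly assessments,
not a calendar date: the analyses downstream define their windows in numbers
of assessments, so a date column, when present, is converted by rounding
elapsed days / 61 to the nearest index.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Group",
    "Sex",
    "Race",
    "ScaleDefinition",
    "SCALES",
    "Participant",
    "PromSeries",
    "FunctioningRecord",
    "LongitudinalDataset",
    "SchemaError",
    "ValidationError",
    "read_dataset",
    "write_dataset",
    "CSV_COLUMNS",
]

DAYS_PER_ASSESSMENT = 61  # bi-monthly cadence


class Group(str, enum.Enum):
    """Diagnostic group: bipolar disorder, psychiatric comparison, healthy control."""

    BD = "BD"
    PC = "PC"
    HC = "HC"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Race(str, enum.Enum):
    """Dichotomized to match the functioning-model coding (reference: white)."""

    WHITE = "white"
    NON_WHITE = "non_white"


class SchemaError(ValueError):
    """A required column is missing or the schema mapping is invalid."""


class ValidationError(ValueError):
    """Row-level content violates a scale range or an enum domain."""


@dataclass(frozen=True)
class ScaleDefinition:
    """A bounded ordinal PROM scale with contiguous severity bands."""

    name: str
    min_score: int
    max_score: int
    severity_bands: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        if self.min_score >= self.max_score:
            raise ValueError(f"{self.name}: min_score must be < max_score")
        bands = self.severity_bands
        if bands[0][1] != self.min_score or bands[-1][2] != self.max_score:
            raise ValueError(f"{self.name}: severity bands must cover the scale range")
        for (_, _, hi_prev), (_, lo, hi) in zip(bands, bands[1:]):
            if lo != hi_prev + 1 or lo > hi:
                raise ValueError(f"{self.name}: severity bands must be contiguous and ordered")

    def in_range(self, score: float) -> bool:
        return self.min_score <= score <= self.max_score

    def band(self, score: int) -> str:
        for label, lo, hi in self.severity_bands:
            if lo <= score <= hi:
                return label
        raise ValueError(f"score {score} outside {self.name} range")


#: The three mood scales the pipeline analyzes.  PHQ-9 measures depression
#: (9 items, 0-27), ASRM (hypo)mania (5 items, each 1-5, totals 5-25; >=6
#: flags a manic presentation), GAD-7 anxiety (7 items, 0-21).
SCALES: dict[str, ScaleDefinition] = {
    "PHQ9": ScaleDefinition(
        "PHQ9",
        0,
        27,
        (
            ("minimal", 0, 4),
            ("mild", 5, 9),
            ("moderate", 10, 14),
            ("moderately_severe", 15, 19),
            ("severe", 20, 27),
        ),
    ),
    "ASRM": ScaleDefinition("ASRM", 5, 25, (("normal", 5, 5), ("elevated", 6, 25))),
    "GAD7": ScaleDefinition(
        "GAD7",
        0,
        21,
        (("minimal", 0, 4), ("mild", 5, 9), ("moderate", 10, 14), ("severe", 15, 21)),
    ),
}


@dataclass(frozen=True)
class Participant:
    participant_id: str
    group: Group
    sex: Sex
    race: Race
    age_at_enrollment: float

    def __post_init__(self) -> None:
        if self.age_at_enrollment < 0:
            raise ValueError("age_at_enrollment must be non-negative")


@dataclass
class PromSeries:
    """One participant's ordered, possibly gappy score series for one scale.

    ``observations`` is a list of ``(time_index, score)`` with strictly
    increasing non-negative integer time indices; ``score`` is ``None`` for a
    scheduled assessment with a missing response.
    """

    participant_id: str
    scale: str
    observations: list[tuple[int, Optional[int]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}")
        sdef = SCALES[self.scale]
        prev = -1
        for t, score in self.observations:
            if t <= prev:
                raise ValidationError(
                    f"{self.participant_id}/{self.scale}: time_index not strictly increasing at {t}"
                )
            if t < 0:
                raise ValidationError("time_index must be non-negative")
            if score is not None and not sdef.in_range(score):
                raise ValidationError(
                    f"{self.participant_id}/{self.scale}: score {score} outside "
                    f"[{sdef.min_score}, {sdef.max_score}]"
                )
            prev = t

    def non_missing(self) -> list[tuple[int, int]]:
        return [(t, s) for t, s in self.observations if s is not None]


@dataclass(frozen=True)
class FunctioningRecord:
    """SF-12 component summaries for one assessment (normed T-scores, mean 50, SD 10)."""

    participant_id: str
    time_index: int
    mcs: float
    pcs: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mcs) and np.isfinite(self.pcs)):
            raise ValidationError("MCS/PCS T-scores must be finite")


@dataclass
class LongitudinalDataset:
    participants: dict[str, Participant]
    series: dict[tuple[str, str], PromSeries]  # (participant_id, scale) -> series
    functioning: dict[str, list[FunctioningRecord]]

    def __post_init__(self) -> None:
        for pid, scale in self.series:
            if pid not in self.participants:
                raise ValidationError(f"series participant {pid!r} not in participants")
        for pid in self.functioning:
            if pid not in self.participants:
                raise ValidationError(f"functioning participant {pid!r} not in participants")

    def series_for_scale(self, scale: str) -> list[PromSeries]:
        return [s for (pid, sc), s in sorted(self.series.items()) if sc == scale]

    @property
    def n_participants(self) -> int:
        return len(self.participants)


# Fixed long-format column order for write_dataset / read_dataset round-trips.
CSV_COLUMNS = [
    "participant_id",
    "group",
    "sex",
    "race",
    "age_at_enrollment",
    "time_index",
    "scale",
    "score",
    "mcs",
    "pcs",
]

DEFAULT_SCHEMA: dict[str, str] = {c: c for c in CSV_COLUMNS}

_REQUIRED = ["participant_id", "group", "time_index", "scale"]


def _to_enum(enum_cls, raw: str, row: int, what: str):
    try:
        return enum_cls(raw)
    except ValueError:
        allowed = ", ".join(e.value for e in enum_cls)
        raise ValidationError(f"row {row}: unknown {what} {raw!r} (allowed: {allowed})") from None


def read_dataset(path: str | Path, schema: Optional[Mapping[str, str]] = None) -> LongitudinalDataset:
    """Read and validate a long-format PROM CSV.

    ``schema`` maps canonical column names (see ``CSV_COLUMNS``) to the names
    used in the file.  Rows with an empty ``scale`` contribute covariates and
    functioning T-scores only.  Out-of-range scores and unknown group / sex /
    race / scale labels raise :class:`ValidationError` naming the offending
    rows; a missing required column raises :class:`SchemaError`.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    # round_trip float parsing keeps write/read an exact identity
    df = pd.read_csv(path, dtype={colmap["participant_id"]: str}, float_precision="round_trip")
    missing_cols = [c for c in _REQUIRED if colmap[c] not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing required column(s): {missing_cols} in {path}")
    inverse = {v: k for k, v in colmap.items() if v in df.columns}
    df = df.rename(columns=inverse)

    errors: list[str] = []
    participants: dict[str, Participant] = {}
    obs: dict[tuple[str, str], list[tuple[int, Optional[int]]]] = {}
    functioning: dict[str, dict[int, FunctioningRecord]] = {}

    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        pid = str(row.participant_id)
        if pid not in participants:
            participants[pid] = Participant(
                participant_id=pid,
                group=_to_enum(Group, str(row.group), i, "group"),
                sex=_to_enum(Sex, str(getattr(row, "sex", "male")), i, "sex"),
                race=_to_enum(Race, str(getattr(row, "race", "white")), i, "race"),
                age_at_enrollment=float(getattr(row, "age_at_enrollment", 0.0)),
            )
        t = int(row.time_index)
        scale = row.scale if isinstance(row.scale, str) and row.scale else None
        if scale is not None:
            if scale not in SCALES:
                errors.append(f"row {i}: unknown scale {scale!r}")
                continue
            raw_score = getattr(row, "score", None)
            score: Optional[int]
            if raw_score is None or (isinstance(raw_score, float) and np.isnan(raw_score)):
                score = None
            else:
                score = int(raw_score)
                if not SCALES[scale].in_range(score):
                    sdef = SCALES[scale]
                    errors.append(
                        f"row {i}: {scale} score {score} outside [{sdef.min_score}, {sdef.max_score}]"
                    )
                    continue
            key = (pid, scale)
            obs.setdefault(key, [])
            if any(t == t0 for t0, _ in obs[key]):
                errors.append(f"row {i}: duplicate score for {pid}/{scale} at time {t}")
                continue
            obs[key].append((t, score))
        mcs = getattr(row, "mcs", None)
        pcs = getattr(row, "pcs", None)
        if mcs is not None and pcs is not None and np.isfinite(mcs) and np.isfinite(pcs):
            functioning.setdefault(pid, {})
            if t not in functioning[pid]:
                functioning[pid][t] = FunctioningRecord(pid, t, float(mcs), float(pcs))

    if errors:
        raise ValidationError("invalid rows:\n" + "\n".join(errors))

    series = {
        key: PromSeries(key[0], key[1], sorted(rows)) for key, rows in obs.items()
    }
    func = {
        pid: [recs[t] for t in sorted(recs)] for pid, recs in functioning.items()
    }
    return LongitudinalDataset(participants, series, func)


def write_dataset(ds: LongitudinalDataset, path: str | Path) -> None:
    """Write ``ds`` as long-format CSV (column order ``CSV_COLUMNS``), losslessly.

    Missing scores become empty cells.  Functioning T-scores are repeated on
    every row of the same assessment; assessments with functioning data but no
    PROM row are written with empty scale/score fields.
    """
    rows: list[dict] = []
    func_lookup: dict[tuple[str, int], FunctioningRecord] = {
        (r.participant_id, r.time_index): r
        for recs in ds.functioning.values()
        for r in recs
    }
    covered: set[tuple[str, int]] = set()
    for (pid, scale), series in sorted(ds.series.items()):
        p = ds.participants[pid]
        for t, score in series.observations:
            fr = func_lookup.get((pid, t))
            covered.add((pid, t))
            rows.append(
                {
                    "participant_id": pid,
                    "group": p.group.value,
                    "sex": p.sex.value,
                    "race": p.race.value,
                    "age_at_enrollment": p.age_at_enrollment,
                    "time_index": t,
                    "scale": scale,
                    "score": score,
                    "mcs": fr.mcs if fr else None,
                    "pcs": fr.pcs if fr else None,
                }
            )
    for (pid, t), fr in sorted(func_lookup.items()):
        if (pid, t) not in covered:
            p = ds.participants[pid]
            rows.append(
                {
                    "participant_id": pid,
                    "group": p.group.value,
                    "sex": p.sex.value,
                    "race": p.race.value,
                    "age_at_enrollment": p.age_at_enrollment,
                    "time_index": t,
                    "scale": None,
                    "score": None,
                    "mcs": fr.mcs,
                    "pcs": fr.pcs,
                }
            )
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    df.to_csv(path, index=False)


def dates_to_time_index(dates: Sequence, origin=None) -> list[int]:
    """Convert calendar dates to scheduled assessment indices.

    Elapsed days since ``origin`` (default: earliest date) are divided by the
    61-day bi-monthly interval and rounded to the nearest integer.
    """
    d = pd.to_datetime(pd.Series(list(dates)))
    if origin is None:
        origin = d.min()
    days = (d - pd.to_datetime(origin)).dt.days
    return [int(round(x / DAYS_PER_ASSESSMENT)) for x in days]
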