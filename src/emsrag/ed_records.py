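"""ED-encounter data model, table I/O, and the seeded synthetic case generator.

The schema mirrors the MIMIC-IV-ED tables (edstays, diagnosis, medrecon,
pyxis, triage, vitalsign): one encounter per ``stay_id`` with demographics,
triage acuity, free-text diagnoses, two medication lists, and serial vital
signs (triage measurement plus at least one in-ED re-measurement). The
synthetic generator produces clinically plausible cases from packaged
vocabularies so every downstream stage is testable without the real dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .errors import ConfigurationError, ReferentialError, SchemaError

WALK_IN = "WALK IN"
AMBULANCE = "AMBULANCE"

#: Plausible-range defaults for generated vitals. Configuration, not dogma:
#: units are degF, beats/min, breaths/min, %, mmHg, mmHg, 0-10 scale.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "temperature": (95.0, 104.0),
    "heartrate": (40, 180),
    "resprate": (8, 40),
    "o2sat": (85, 100),
    "sbp": (90, 200),
    "dbp": (50, 120),
    "pain": (0, 10),
}


class VitalsMeasurement(BaseModel):
    """One set of vital signs, taken at triage or at an in-ED reassessment."""

    phase_label: Literal["triage", "reassessment"]
    temperature: float  # degrees Fahrenheit
    heartrate: float    # beats per minute
    resprate: float     # breaths per minute
    o2sat: float        # percent
    sbp: float          # mmHg
    dbp: float          # mmHg
    pain: int           # 0 (none) .. 10 (worst)

    @model_validator(mode="after")
    def _check_physiology(self) -> "VitalsMeasurement":
        if not 0 <= self.o2sat <= 100:
            raise ValueError(f"o2sat {self.o2sat} outside [0, 100]")
        if not 0 <= self.pain <= 10:
            raise ValueError(f"pain {self.pain} outside [0, 10]")
        if not self.sbp > self.dbp > 0:
            raise ValueError(f"require sbp > dbp > 0, got {self.sbp}/{self.dbp}")
        return self


class PatientCase(BaseModel):
    """One ED encounter; the ground truth injected into generated dialogues."""

    stay_id: str
    gender: Literal["F", "M"]
    arrival_transport: str
    acuity: int = Field(ge=1, le=5)
    chief_complaint: str
    diagnoses: list[str]
    meds_reported: list[str]
    meds_administered: list[str]
    vitals: list[VitalsMeasurement]
    synthetic: bool = False

    @model_validator(mode="after")
    def _check_lists(self) -> "PatientCase":
        for name in ("diagnoses", "meds_reported", "meds_administered", "vitals"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")
        return self


@dataclass(frozen=True)
class Vocabulary:
    """Term lists feeding the generator; packaged synthetic lists by default."""

    diagnoses: tuple[str, ...]
    medications: tuple[str, ...]
    complaints: tuple[str, ...]

    def validate(self) -> None:
        for name in ("diagnoses", "medications", "complaints"):
            if not getattr(self, name):
                raise ConfigurationError(f"vocabulary list '{name}' is empty")


def _load_wordlist(name: str) -> tuple[str, ...]:
    text = resources.files("emsrag.data").joinpath(name).read_text(encoding="utf-8")
    return tuple(line.strip() for line in text.splitlines() if line.strip())


def default_vocabulary() -> Vocabulary:
    return Vocabulary(
        diagnoses=_load_wordlist("diagnoses.txt"),
        medications=_load_wordlist("medications.txt"),
        complaints=_load_wordlist("complaints.txt"),
    )


def _draw_vitals(
    rng: np.random.Generator,
    ranges: Mapping[str, tuple[float, float]],
    phase_label: str,
) -> VitalsMeasurement:
    lo, hi = ranges["temperature"]
    temperature = round(float(rng.uniform(lo, hi)), 1)
    heartrate = int(rng.integers(int(ranges["heartrate"][0]), int(ranges["heartrate"][1]) + 1))
    resprate = int(rng.integers(int(ranges["resprate"][0]), int(ranges["resprate"][1]) + 1))
    o2sat = int(rng.integers(int(ranges["o2sat"][0]), int(ranges["o2sat"][1]) + 1))
    sbp = int(rng.integers(int(ranges["sbp"][0]), int(ranges["sbp"][1]) + 1))
    dbp_hi = min(int(ranges["dbp"][1]), sbp - 10)
    dbp_lo = min(int(ranges["dbp"][0]), dbp_hi)
    dbp = int(rng.integers(dbp_lo, dbp_hi + 1))
    pain = int(rng.integers(int(ranges["pain"][0]), int(ranges["pain"][1]) + 1))
    return VitalsMeasurement(
        phase_label=phase_label,
        temperature=temperature,
        heartrate=heartrate,
        resprate=resprate,
        o2sat=o2sat,
        sbp=sbp,
        dbp=dbp,
        pain=pain,
    )


def generate_cases(
    n: int,
    seed: int,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    vocab: Vocabulary | None = None,
    walk_in_rate: float = 0.2,
    n_vitals: int = 2,
) -> list[PatientCase]:
    """Generate ``n`` seeded synthetic encounters.

    Acuity is drawn uniformly from 1..5; arrival transport is AMBULANCE with
    probability ``1 - walk_in_rate``. Identical arguments reproduce an
    identical case list. Each case carries ``n_vitals`` measurements
    (triage first, then reassessments).
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if n_vitals < 2:
        raise ConfigurationError("n_vitals must be >= 2 (triage + reassessment)")
    ranges = dict(DEFAULT_RANGES, **(ranges or {}))
    vocab = vocab or default_vocabulary()
    vocab.validate()

    rng = np.random.default_rng(seed)
    base_id = int(rng.integers(10_000_000, 90_000_000))
    cases: list[PatientCase] = []
    for i in range(n):
        n_rep = int(rng.integers(1, 4))
        n_adm = int(rng.integers(1, 3))
        meds_reported = [str(m) for m in rng.choice(vocab.medications, size=n_rep, replace=False)]
        meds_administered = [str(m) for m in rng.choice(vocab.medications, size=n_adm, replace=False)]
        vitals = [_draw_vitals(rng, ranges, "triage")]
        vitals += [_draw_vitals(rng, ranges, "reassessment") for _ in range(n_vitals - 1)]
        cases.append(
            PatientCase(
                stay_id=str(base_id + i),
                gender="F" if rng.random() < 0.5 else "M",
                arrival_transport=WALK_IN if rng.random() < walk_in_rate else AMBULANCE,
                acuity=int(rng.integers(1, 6)),
                chief_complaint=str(rng.choice(vocab.complaints)),
                diagnoses=[str(rng.choice(vocab.diagnoses))],
                meds_reported=meds_reported,
                meds_administered=meds_administered,
                vitals=vitals,
            )
        )
    return cases


def filter_ambulance(cases: Sequence[PatientCase]) -> list[PatientCase]:
    """Drop walk-in arrivals, preserving order (arrival_transport filter)."""
    return [c for c in cases if c.arrival_transport != WALK_IN]


# ---------------------------------------------------------------------------
# Table I/O (MIMIC-IV-ED column layout)
# ---------------------------------------------------------------------------

_VITAL_COLS = ["temperature", "heartrate", "resprate", "o2sat", "sbp", "dbp", "pain"]

REQUIRED_COLUMNS: dict[str, list[str]] = {
    "edstays": ["stay_id", "gender", "arrival_transport"],
    "triage": ["stay_id", "acuity", "chiefcomplaint"] + _VITAL_COLS,
    "vitalsign": ["stay_id"] + _VITAL_COLS,
    "diagnosis": ["stay_id", "icd_title"],
    "medrecon": ["stay_id", "name"],
    "pyxis": ["stay_id", "name"],
}


def write_ed_tables(cases: Sequence[PatientCase], directory: str | Path) -> dict[str, Path]:
    """Write cases as the six CSV tables; returns table-name -> path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows: dict[str, list[dict]] = {name: [] for name in REQUIRED_COLUMNS}
    for c in cases:
        rows["edstays"].append(
            {"stay_id": c.stay_id, "gender": c.gender, "arrival_transport": c.arrival_transport}
        )
        triage = c.vitals[0]
        rows["triage"].append(
            {
                "stay_id": c.stay_id,
                "acuity": c.acuity,
                "chiefcomplaint": c.chief_complaint,
                **{k: getattr(triage, k) for k in _VITAL_COLS},
            }
        )
        for v in c.vitals[1:]:
            rows["vitalsign"].append(
                {"stay_id": c.stay_id, **{k: getattr(v, k) for k in _VITAL_COLS}}
            )
        rows["diagnosis"] += [{"stay_id": c.stay_id, "icd_title": d} for d in c.diagnoses]
        rows["medrecon"] += [{"stay_id": c.stay_id, "name": m} for m in c.meds_reported]
        rows["pyxis"] += [{"stay_id": c.stay_id, "name": m} for m in c.meds_administered]

    paths = {}
    for name, cols in REQUIRED_COLUMNS.items():
        path = directory / f"{name}.csv"
        pd.DataFrame(rows[name], columns=cols).to_csv(path, index=False)
        paths[name] = path
    return paths


def _read_table(name: str, path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"stay_id": str})
    for col in REQUIRED_COLUMNS[name]:
        if col not in df.columns:
            raise SchemaError(f"table '{name}' is missing required column '{col}'")
    return df


def read_ed_tables(paths: Mapping[str, str | Path]) -> list[PatientCase]:
    """Join the six tables on stay_id back into PatientCase records.

    Vitals are ordered triage-first, then vitalsign rows in file order.
    """
    missing = set(REQUIRED_COLUMNS) - set(paths)
    if missing:
        raise SchemaError(f"missing table file(s): {sorted(missing)}")
    tables = {name: _read_table(name, paths[name]) for name in REQUIRED_COLUMNS}

    stays = tables["edstays"]
    known = set(stays["stay_id"])
    for name in ("triage", "vitalsign", "diagnosis", "medrecon", "pyxis"):
        orphans = set(tables[name]["stay_id"]) - known
        if orphans:
            raise ReferentialError(
                f"table '{name}' references stay_id(s) absent from edstays: {sorted(orphans)[:5]}"
            )

    def _vitals_from_row(row: pd.Series, phase: str) -> VitalsMeasurement:
        return VitalsMeasurement(
            phase_label=phase,
            **{k: (int(row[k]) if k == "pain" else float(row[k])) for k in _VITAL_COLS},
        )

    grouped = {
        name: dict(tuple(tables[name].groupby("stay_id", sort=False)))
        for name in ("triage", "vitalsign", "diagnosis", "medrecon", "pyxis")
    }
    cases = []
    for _, stay in stays.iterrows():
        sid = stay["stay_id"]
        if sid not in grouped["triage"]:
            raise ReferentialError(f"stay_id {sid} has no triage row")
        triage_row = grouped["triage"][sid].iloc[0]
        vitals = [_vitals_from_row(triage_row, "triage")]
        if sid in grouped["vitalsign"]:
            for _, row in grouped["vitalsign"][sid].iterrows():
                vitals.append(_vitals_from_row(row, "reassessment"))
        cases.append(
            PatientCase(
                stay_id=sid,
                gender=stay["gender"],
                arrival_transport=stay["arrival_transport"],
                acuity=int(triage_row["acuity"]),
                chief_complaint=str(triage_row["chiefcomplaint"]),
                diagnoses=list(grouped["diagnosis"].get(sid, pd.DataFrame({"icd_title": []}))["icd_title"]),
                meds_reported=list(grouped["medrecon"].get(sid, pd.DataFrame({"name": []}))["name"]),
                meds_administered=list(grouped["pyxis"].get(sid, pd.DataFrame({"name": []}))["name"]),
                vitals=vitals,
            )
        )
    return cases


def write_cases_jsonl(cases: Iterable[PatientCase], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for c in cases:
            fh.write(c.model_dump_json() + "\n")


def read_cases_jsonl(path: str | Path) -> list[PatientCase]:
    with open(path, encoding="utf-8") as fh:
        return [PatientCase.model_validate(json.loads(line)) for line in fh if line.strip()]
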