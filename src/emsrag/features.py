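"""Protocol feature registry: what to extract, how to query, where truth lives.

The ten evaluated features mirror the German emergency-protocol fields
covered by the ED schema: four nominal (diagnosis, chief complaint, the two
medication lists) and six numeric (blood pressure, heart rate, O2 saturation,
respiration rate, temperature, pain score). Each carries its retrieval query
string ``q_data``; the exact strings are editable configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .ed_records import PatientCase


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    kind: str  # "nominal" | "numeric"
    q_data: str
    truth: Callable[[PatientCase], list]


def _vitals_values(case: PatientCase, attr: str) -> list[float]:
    return [getattr(v, attr) for v in case.vitals[:2]]


FEATURES: tuple[FeatureSpec, ...] = (
    FeatureSpec(
        "Diagnosis",
        "nominal",
        "diagnosis, condition, assessment, medical diagnosis",
        lambda c: list(c.diagnoses),
    ),
    FeatureSpec(
        "Chief complaint",
        "nominal",
        "complaint, chief complaint, presenting symptom",
        lambda c: [c.chief_complaint],
    ),
    FeatureSpec(
        "Medication patient reported",
        "nominal",
        "med reported, home medication, pharmaceuticals, drugs, and medications",
        lambda c: list(c.meds_reported),
    ),
    FeatureSpec(
        "Medication administered",
        "nominal",
        "med given, administered medication, pharmaceuticals, drugs, and medications",
        lambda c: list(c.meds_administered),
    ),
    FeatureSpec(
        "Blood Pressure",
        "numeric",
        "blood pressure, systolic, diastolic, mmHg",
        lambda c: [x for v in c.vitals[:2] for x in (v.sbp, v.dbp)],
    ),
    FeatureSpec(
        "Heart rate",
        "numeric",
        "heart rate, pulse, beats per minute",
        lambda c: _vitals_values(c, "heartrate"),
    ),
    FeatureSpec(
        "O2 saturation",
        "numeric",
        "oxygen saturation, o2 sat, spo2",
        lambda c: _vitals_values(c, "o2sat"),
    ),
    FeatureSpec(
        "Respiration rate",
        "numeric",
        "respiration rate, breathing rate, breaths per minute",
        lambda c: _vitals_values(c, "resprate"),
    ),
    FeatureSpec(
        "Temperature",
        "numeric",
        "temperature, fever, degrees",
        lambda c: _vitals_values(c, "temperature"),
    ),
    FeatureSpec(
        "Pain score",
        "numeric",
        "pain score, pain level, pain scale",
        # recorded once, at triage
        lambda c: [float(c.vitals[0].pain)],
    ),
)

FEATURES_BY_NAME = {f.name: f for f in FEATURES}
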