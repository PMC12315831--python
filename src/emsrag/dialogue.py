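"""Dialogue generation: four-phase initial dialogues and hierarchical refinement.

An initial English dialogue is generated phase by phase from prompt templates
whose placeholders carry the encounter's ground-truth values (the four phases:
ambulance contact, triage with initial vitals, medication administration with
re-measured vitals, hospital arrival; the triage acuity selects the template's
tone variant). Refinement then applies the hierarchical expansion method: each
section is outlined and summarized, cumulative summaries of the already
refined sections provide continuity, a Current-Events block restates all
medical facts introduced so far, and the refined text is translated into
German by a backend call.
"""

from __future__ import annotations

import re
from importlib import resources
from typing import Mapping, Sequence

from pydantic import BaseModel, Field

from .backends import GenerationRequest, TextBackend
from .ed_records import PatientCase, VitalsMeasurement
from .errors import BackendError, ConfigurationError, TemplateError


class SectionTemplate(BaseModel):
    phase: int = Field(ge=1, le=4)
    body: str
    acuity_variant: str | None = None


class Utterance(BaseModel):
    speaker: str
    text: str


class Section(BaseModel):
    phase: int
    utterances: list[Utterance]

    def text(self) -> str:
        return "\n".join(f"{u.speaker}: {u.text}" for u in self.utterances)


class SummaryChain(BaseModel):
    section_summaries: list[str] = Field(default_factory=list)
    cumulative_summaries: list[str] = Field(default_factory=list)


class Dialogue(BaseModel):
    dialogue_id: str
    case_ref: str
    language: str
    stage: str  # "initial" | "refined"
    sections: list[Section]
    summaries: SummaryChain = Field(default_factory=SummaryChain)
    meta: dict = Field(default_factory=dict)

    def text(self) -> str:
        return "\n".join(s.text() for s in self.sections)


# ---------------------------------------------------------------------------
# Acuity bands and fact schedule
# ---------------------------------------------------------------------------

ACUITY_BANDS = {1: "critical", 2: "critical", 3: "urgent", 4: "minor", 5: "minor"}

_TONE_INSTRUCTIONS = {
    "critical": "Tone: life-threatening emergency; urgent, terse exchanges.",
    "urgent": "Tone: serious but controlled; focused clinical questioning.",
    "minor": "Tone: low-acuity visit; calm and reassuring conversation.",
}


def _fmt(x: float) -> str:
    return f"{x:g}"


def phase_facts(case: PatientCase, phase: int) -> list[tuple[str, str]]:
    """Ground-truth facts introduced in a given phase, as (key, value) pairs."""
    triage = case.vitals[0]
    reassess = case.vitals[1] if len(case.vitals) > 1 else case.vitals[0]
    if phase == 1:
        return [("complaint", case.chief_complaint), ("patient gender", case.gender)]
    if phase == 2:
        facts = [
            ("temperature", _fmt(triage.temperature)),
            ("heart rate", _fmt(triage.heartrate)),
            ("respiration rate", _fmt(triage.resprate)),
            ("oxygen saturation", _fmt(triage.o2sat)),
            ("blood pressure", f"{_fmt(triage.sbp)}/{_fmt(triage.dbp)}"),
            ("pain score", str(triage.pain)),
        ]
        facts += [("med reported", m) for m in case.meds_reported]
        return facts
    if phase == 3:
        facts = [("med given", m) for m in case.meds_administered]
        facts += [
            ("temperature", _fmt(reassess.temperature)),
            ("heart rate", _fmt(reassess.heartrate)),
            ("respiration rate", _fmt(reassess.resprate)),
            ("oxygen saturation", _fmt(reassess.o2sat)),
            ("blood pressure", f"{_fmt(reassess.sbp)}/{_fmt(reassess.dbp)}"),
        ]
        return facts
    if phase == 4:
        return [("diagnosis", d) for d in case.diagnoses]
    raise ConfigurationError(f"phase must be 1..4, got {phase}")


def build_context(case: PatientCase) -> dict[str, str]:
    """Placeholder mapping for the default templates."""
    triage = case.vitals[0]
    reassess = case.vitals[1] if len(case.vitals) > 1 else case.vitals[0]
    band = ACUITY_BANDS[case.acuity]

    def vit(v: VitalsMeasurement, suffix: str) -> dict[str, str]:
        return {
            f"temperature_{suffix}": _fmt(v.temperature),
            f"heartrate_{suffix}": _fmt(v.heartrate),
            f"resprate_{suffix}": _fmt(v.resprate),
            f"o2sat_{suffix}": _fmt(v.o2sat),
            f"bp_{suffix}": f"{_fmt(v.sbp)}/{_fmt(v.dbp)}",
            f"pain_{suffix}": str(v.pain),
        }

    return {
        "stay_id": case.stay_id,
        "gender": case.gender,
        "acuity": str(case.acuity),
        "tone": band,
        "tone_instruction": _TONE_INSTRUCTIONS[band],
        "chief_complaint": case.chief_complaint,
        "diagnoses_lines": "\n".join(f"- diagnosis is {d}" for d in case.diagnoses),
        "meds_reported_lines": "\n".join(f"- med reported is {m}" for m in case.meds_reported),
        "meds_administered_lines": "\n".join(
            f"- med given is {m}" for m in case.meds_administered
        ),
        **vit(triage, "triage"),
        **vit(reassess, "reassess"),
    }


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

_PLACEHOLDER = re.compile(r"\{([a-z_][a-z_0-9]*)\}")


def render_template(tmpl: SectionTemplate, mapping: Mapping[str, str]) -> str:
    """Substitute every ``{placeholder}``; unresolved names raise TemplateError."""

    def _sub(m: re.Match) -> str:
        name = m.group(1)
        if name not in mapping:
            raise TemplateError(f"unresolved placeholder '{name}' in phase-{tmpl.phase} template")
        return str(mapping[name])

    return _PLACEHOLDER.sub(_sub, tmpl.body)


def load_default_templates() -> list[SectionTemplate]:
    templates = []
    for phase in (1, 2, 3, 4):
        body = (
            resources.files("emsrag.templates").joinpath(f"phase{phase}.txt").read_text("utf-8")
        )
        templates.append(SectionTemplate(phase=phase, body=body))
    return templates


def select_template(
    templates: Sequence[SectionTemplate], phase: int, acuity: int
) -> SectionTemplate:
    band = ACUITY_BANDS[acuity]
    candidates = [t for t in templates if t.phase == phase]
    if not candidates:
        raise ConfigurationError(f"no template for phase {phase}")
    for t in candidates:
        if t.acuity_variant == band:
            return t
    for t in candidates:
        if t.acuity_variant is None:
            return t
    return candidates[0]


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _parse_utterances(text: str) -> list[Utterance]:
    utterances = []
    for line in text.splitlines():
        m = re.match(r"^\s*([A-Za-z]+)\s*:\s*(.+)$", line)
        if m:
            utterances.append(Utterance(speaker=m.group(1), text=m.group(2)))
    return utterances


def generate_initial_dialogue(
    case: PatientCase,
    templates: Sequence[SectionTemplate] | None,
    backend: TextBackend,
    max_tokens: int = 1500,
    temperature: float = 0.7,
    seed: int = 0,
) -> Dialogue:
    """Four-phase English dialogue whose text embeds the case's ground truth."""
    templates = list(templates) if templates else load_default_templates()
    context = build_context(case)
    sections = []
    for phase in (1, 2, 3, 4):
        tmpl = select_template(templates, phase, case.acuity)
        prompt = render_template(tmpl, context)
        try:
            reply = backend.generate(
                GenerationRequest(
                    prompt=prompt, max_tokens=max_tokens, temperature=temperature, seed=seed
                )
            )
        except BackendError as exc:
            raise BackendError(f"phase {phase}: {exc}") from exc
        sections.append(Section(phase=phase, utterances=_parse_utterances(reply)))
    d = Dialogue(
        dialogue_id=f"d-{case.stay_id}",
        case_ref=case.stay_id,
        language="en",
        stage="initial",
        sections=sections,
    )
    d.meta["token_count"] = len(d.text().split())
    return d


def build_current_events(case: PatientCase, through_phase: int) -> str:
    """Summary block of every medical fact introduced at or before a phase."""
    if not 1 <= through_phase <= 4:
        raise ConfigurationError(f"through_phase must be 1..4, got {through_phase}")
    lines = []
    for phase in range(1, through_phase + 1):
        lines += [f"- {k} is {v}" for k, v in phase_facts(case, phase)]
    return "Current Events:\n" + "\n".join(lines)


_REFINE_PROMPT = """[[refine-section]] phase={phase} tone={tone}
Section outline: {outline}
Section summary: {summary}
Cumulative summary of refined sections so far: {cumulative}
{current_events}
Facts:
{facts}

Keep the dialogue grounded in the Current Events and appropriate to an
emergency scene. Clinicians speak to each other in clinical terminology and
to the patient in plain, courteous language. Match the patient's manner of
speaking to their clinical condition. Write the dialogue in German.
"""


def refine_dialogue(
    d: Dialogue,
    case: PatientCase,
    backend: TextBackend,
    max_tokens: int = 1500,
    temperature: float = 0.7,
    seed: int = 0,
) -> Dialogue:
    """Hierarchical expansion of an initial dialogue into a refined German one.

    Per section: outline and summary of the initial section, cumulative
    summaries of the *already refined* earlier sections, the Current-Events
    block, and the section's fact block are assembled into the refinement
    prompt; the refined text is then translated (en -> de).
    """
    if d.stage != "initial":
        raise ConfigurationError("refine_dialogue expects an initial-stage dialogue")
    if case.stay_id != d.case_ref:
        raise ConfigurationError("case does not match dialogue.case_ref")
    band = ACUITY_BANDS[case.acuity]

    def _gen(prompt: str, section_idx: int) -> str:
        try:
            return backend.generate(
                GenerationRequest(
                    prompt=prompt, max_tokens=max_tokens, temperature=temperature, seed=seed
                )
            )
        except BackendError as exc:
            raise BackendError(f"section {section_idx}: {exc}") from exc

    refined_sections: list[Section] = []
    section_summaries: list[str] = []
    cumulative_summaries: list[str] = []
    refined_summaries: list[str] = []
    for i, section in enumerate(d.sections):
        phase = section.phase
        init_text = section.text()
        outline = _gen(f"[[outline]]\nText:\n{init_text}", i)
        summary = _gen(f"[[summary]]\nText:\n{init_text}", i)
        section_summaries.append(summary)
        cumulative = " ".join(refined_summaries) if refined_summaries else "(none)"
        if i >= 1:
            cumulative_summaries.append(cumulative)
        facts = "\n".join(f"- {k} is {v}" for k, v in phase_facts(case, phase))
        prompt = _REFINE_PROMPT.format(
            phase=phase,
            tone=band,
            outline=outline,
            summary=summary,
            cumulative=cumulative,
            current_events=build_current_events(case, phase),
            facts=facts,
        )
        refined_en = _gen(prompt, i)
        refined_de = backend.translate(refined_en, "en", "de")
        refined_sections.append(Section(phase=phase, utterances=_parse_utterances(refined_de)))
        refined_summaries.append(_gen(f"[[summary]]\nText:\n{refined_de}", i))

    refined = Dialogue(
        dialogue_id=d.dialogue_id,
        case_ref=d.case_ref,
        language="de",
        stage="refined",
        sections=refined_sections,
        summaries=SummaryChain(
            section_summaries=section_summaries, cumulative_summaries=cumulative_summaries
        ),
    )
    refined.meta["token_count"] = len(refined.text().split())
    return refined


# ---------------------------------------------------------------------------
# Degenerate-output detection
# ---------------------------------------------------------------------------

def _normalize_utterance(u: Utterance) -> str:
    return re.sub(r"[^\w\s]", "", u.text.lower()).strip()


def detect_degenerate(d: Dialogue, max_repeats: int = 3) -> tuple[bool, str | None]:
    """Flag dialogues trapped in repetitive adjacent-utterance loops.

    Flags when a normalized pair of adjacent utterances repeats at least
    ``max_repeats`` times consecutively; returns the offending span text.
    """
    norm = [_normalize_utterance(u) for s in d.sections for u in s.utterances]
    raw = [u.text for s in d.sections for u in s.utterances]
    for i in range(len(norm) - 1):
        a, b = norm[i], norm[i + 1]
        count = 1
        j = i + 2
        while j + 1 < len(norm) and norm[j] == a and norm[j + 1] == b:
            count += 1
            j += 2
        if count >= max_repeats:
            return True, " / ".join(raw[i : i + 2 * count])
    return False, None
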