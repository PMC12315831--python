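"""End-to-end orchestration: records -> PRAM -> dialogues -> extraction -> metrics.

This is the whole evaluation loop at desk scale with the deterministic mock
backends: generate synthetic encounters, drop walk-ins, anonymize with PRAM,
generate initial and refined dialogues, run RAG extraction for every protocol
feature on both stages, and score the answers against the (PRAM-swapped)
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .backends import MockTextBackend
from .dialogue import Dialogue, generate_initial_dialogue, refine_dialogue
from .ed_records import PatientCase, filter_ambulance, generate_cases
from .features import FEATURES
from .metrics import EvalConfig, GroundTruthItem, MetricReport, evaluate_corpus
from .pram import PramConfig, apply_pram
from .rag import ExtractionAnswer, RagQuery, extract_feature, pre_translate


def build_ground_truth(cases: list[PatientCase]) -> list[GroundTruthItem]:
    """Truth items per dialogue: one per value for numeric features, one item
    holding all values for nominal features."""
    items: list[GroundTruthItem] = []
    for case in cases:
        did = f"d-{case.stay_id}"
        for feat in FEATURES:
            values = feat.truth(case)
            if feat.kind == "numeric":
                items += [GroundTruthItem(did, feat.name, [v]) for v in values]
            else:
                items.append(GroundTruthItem(did, feat.name, values))
    return items


def extract_all_features(
    text: str, dialogue_id: str, backend, k: int = 12
) -> list[ExtractionAnswer]:
    return [
        extract_feature(
            text,
            RagQuery(feature=f.name, q_data=f.q_data, k=k),
            embedder=backend,
            gen_backend=backend,
            dialogue_id=dialogue_id,
        )
        for f in FEATURES
    ]


@dataclass
class PipelineResult:
    cases: list[PatientCase]
    pram_cases: list[PatientCase]
    initial_dialogues: list[Dialogue]
    refined_dialogues: list[Dialogue]
    truths: list[GroundTruthItem]
    initial_answers: list[ExtractionAnswer] = field(default_factory=list)
    refined_answers: list[ExtractionAnswer] = field(default_factory=list)
    initial_reports: list[MetricReport] = field(default_factory=list)
    refined_reports: list[MetricReport] = field(default_factory=list)


def run_pipeline(
    n_cases: int,
    seed: int,
    backend: MockTextBackend | None = None,
    pram_config: PramConfig | None = None,
    eval_config: EvalConfig | None = None,
    walk_in_rate: float = 0.2,
    top_k: int = 12,
) -> PipelineResult:
    """Full mock-backend pipeline; deterministic under (n_cases, seed)."""
    backend = backend or MockTextBackend()
    pram_config = pram_config or PramConfig(seed=seed)
    eval_config = eval_config or EvalConfig()

    cases = filter_ambulance(generate_cases(n_cases, seed=seed, walk_in_rate=walk_in_rate))
    pram_cases = apply_pram(cases, pram_config, backend)

    initial = [generate_initial_dialogue(c, None, backend) for c in pram_cases]
    refined = [refine_dialogue(d, c, backend) for d, c in zip(initial, pram_cases)]

    truths = build_ground_truth(pram_cases)
    initial_answers = [
        a
        for d in initial
        for a in extract_all_features(d.text(), d.dialogue_id, backend, k=top_k)
    ]
    refined_answers = [
        a
        for d in refined
        for a in extract_all_features(pre_translate(d, backend), d.dialogue_id, backend, k=top_k)
    ]

    initial_reports = evaluate_corpus(initial_answers, truths, backend, eval_config)
    refined_reports = evaluate_corpus(refined_answers, truths, backend, eval_config)
    return PipelineResult(
        cases=cases,
        pram_cases=pram_cases,
        initial_dialogues=initial,
        refined_dialogues=refined,
        truths=truths,
        initial_answers=initial_answers,
        refined_answers=refined_answers,
        initial_reports=initial_reports,
        refined_reports=refined_reports,
    )
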