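"""Retrieval-augmented extraction of protocol features from dialogue text.

Four steps: (1) split the dialogue into overlapping 200-character chunks,
(2) embed the chunks and index them for cosine (inner-product on unit
vectors) similarity search, (3) retrieve the top k = 12 chunks for the
feature's retrieval query string ``q_data``, (4) assemble a dynamic prompt
and let the generation backend (temperature 0.2) return the extracted values
as a list, with a "No information available." sentinel for misses. Refined
German dialogues are translated back to English before extraction.
"""

from __future__ import annotations

import re
from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field

from .backends import GenerationRequest, NO_INFO, TextBackend
from .dialogue import Dialogue
from .errors import BackendError, ConfigurationError, TemplateError

DEFAULT_CHUNK_SIZE = 200
DEFAULT_OVERLAP = 40
DEFAULT_TOP_K = 12


class Chunk(BaseModel):
    dialogue_id: str = ""
    start: int = Field(ge=0)
    text: str


class RagQuery(BaseModel):
    feature: str
    q_data: str
    k: int = Field(default=DEFAULT_TOP_K, ge=1)


class ExtractionAnswer(BaseModel):
    feature: str
    values: list[str] = Field(default_factory=list)
    no_info: bool = False
    retrieved_offsets: list[int] = Field(default_factory=list)
    dialogue_id: str = ""


def chunk_text(
    text: str,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    overlap: int = DEFAULT_OVERLAP,
    dialogue_id: str = "",
) -> list[Chunk]:
    """Overlapping character windows covering the whole text.

    Starts step by ``chunk_size - overlap`` from 0; chunking stops once a
    window reaches the end of the text (the final chunk is truncated there).
    Offsets are 0-based half-open ``[start, start + len)``.
    """
    if not text:
        raise ConfigurationError("cannot chunk empty text")
    if overlap < 0 or overlap >= chunk_size:
        raise ConfigurationError(f"require 0 <= overlap < chunk_size, got {overlap}/{chunk_size}")
    step = chunk_size - overlap
    chunks = []
    start = 0
    while True:
        chunks.append(Chunk(dialogue_id=dialogue_id, start=start, text=text[start : start + chunk_size]))
        if start + chunk_size >= len(text):
            break
        start += step
    return chunks


class ChunkIndex:
    """In-memory inner-product similarity index over unit-norm chunk vectors."""

    def __init__(self, chunks: Sequence[Chunk], vectors: np.ndarray):
        if len(chunks) != vectors.shape[0]:
            raise ConfigurationError("one vector per chunk required")
        self.chunks = list(chunks)
        self.vectors = vectors

    def __len__(self) -> int:
        return len(self.chunks)

    def query(self, vector: np.ndarray, k: int) -> list[tuple[Chunk, float]]:
        sims = self.vectors @ vector
        starts = np.array([c.start for c in self.chunks])
        order = np.lexsort((starts, -sims))[: min(k, len(self.chunks))]
        return [(self.chunks[i], float(sims[i])) for i in order]


def build_index(chunks: Sequence[Chunk], embedder) -> ChunkIndex:
    if not chunks:
        raise ConfigurationError("cannot index an empty chunk list")
    try:
        vectors = np.asarray(embedder.embed([c.text for c in chunks]), dtype=float)
    except BackendError as exc:
        raise BackendError(f"embedding chunks failed (first offset 0): {exc}") from exc
    return ChunkIndex(chunks, vectors)


def retrieve_top_k(index: ChunkIndex, q: RagQuery, embedder) -> list[Chunk]:
    """Top-k chunks by descending similarity; ties break on ascending offset."""
    qvec = np.asarray(embedder.embed([q.q_data]), dtype=float)[0]
    return [c for c, _ in index.query(qvec, q.k)]


DEFAULT_RAG_TEMPLATE = """[[extract]]
You extract protocol fields from an emergency-care dialogue transcript.
Context:
{context}
Query: list every value for {feature} ({q_data}).
Reply with the values as a list, or exactly "No information available." if absent.
"""

EMPTY_CONTEXT_MARKER = "[no context retrieved]"


def assemble_prompt(template: str, retrieved: Sequence[Chunk], q: RagQuery) -> str:
    """Fill the context and query slots; unresolved placeholders raise."""
    context = "\n".join(c.text for c in retrieved) if retrieved else EMPTY_CONTEXT_MARKER
    prompt = template.format_map(
        {"context": context, "feature": q.feature, "q_data": q.q_data}
    )
    leftover = re.search(r"\{[a-z_]+\}", prompt)
    if leftover:
        raise TemplateError(f"unresolved placeholder {leftover.group(0)} in RAG template")
    return prompt


_NO_INFO_RE = re.compile(r"^\s*no information available\.?\s*$", re.IGNORECASE)


def parse_answer(reply: str, feature: str, dialogue_id: str = "") -> ExtractionAnswer:
    """Parse a backend reply into a value list, recognizing the sentinel.

    Accepts newline-, semicolon- or comma-delimited lists and bulleted lines.
    """
    if not isinstance(reply, str):
        raise TypeError("reply must be a string")
    if _NO_INFO_RE.match(reply.strip()):
        return ExtractionAnswer(feature=feature, values=[], no_info=True, dialogue_id=dialogue_id)
    values: list[str] = []
    for line in reply.splitlines():
        line = re.sub(r"^\s*[-*•]\s*", "", line).strip()
        if not line:
            continue
        parts = line.split(";") if ";" in line else (line.split(",") if "," in line else [line])
        values += [p.strip() for p in parts if p.strip()]
    return ExtractionAnswer(feature=feature, values=values, no_info=False, dialogue_id=dialogue_id)


def extract_feature(
    dialogue_text: str,
    q: RagQuery,
    embedder,
    gen_backend: TextBackend,
    template: str = DEFAULT_RAG_TEMPLATE,
    temperature: float = 0.2,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    overlap: int = DEFAULT_OVERLAP,
    dialogue_id: str = "",
) -> ExtractionAnswer:
    """Chunk -> index -> retrieve -> prompt -> generate -> parse for one feature."""
    chunks = chunk_text(dialogue_text, chunk_size, overlap, dialogue_id)
    index = build_index(chunks, embedder)
    retrieved = retrieve_top_k(index, q, embedder)
    prompt = assemble_prompt(template, retrieved, q)
    reply = gen_backend.generate(
        GenerationRequest(prompt=prompt, max_tokens=256, temperature=temperature)
    )
    answer = parse_answer(reply, q.feature, dialogue_id)
    answer.retrieved_offsets = [c.start for c in retrieved]
    return answer


def pre_translate(d: Dialogue, backend: TextBackend) -> str:
    """Translate a refined German dialogue back to English for extraction."""
    if d.language != "de":
        raise ConfigurationError(f"pre_translate expects a German dialogue, got '{d.language}'")
    return backend.translate(d.text(), "de", "en")
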