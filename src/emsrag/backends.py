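"""Pluggable text-backend contracts plus deterministic mock implementations.

The pipeline depends on four model roles -- dialogue generation, sentence
embedding, translation, and sentence-level sentiment -- each behind a small
contract so that hosted or local models can be plugged in later. The mock
implementations shipped here are pure functions of their inputs: the mock
generator *echoes every injected fact verbatim* (which is what makes
end-to-end extraction testable with known ground truth), the embedder is a
character-n-gram feature hasher, translation is the identity with a language
tag rewrite, and sentiment is a word-lexicon majority vote.
"""

from __future__ import annotations

import re
import zlib
from typing import Iterable, Protocol, Sequence

import numpy as np
from pydantic import BaseModel, Field

from .errors import BackendError


class GenerationRequest(BaseModel):
    prompt: str
    max_tokens: int = Field(default=1500, ge=1)
    temperature: float = Field(default=0.7, ge=0.0)
    seed: int = 0


class TextBackend(Protocol):
    """Contract every backend (mock, local, api) must satisfy."""

    def generate(self, req: GenerationRequest) -> str: ...

    def embed(self, texts: Sequence[str]) -> np.ndarray: ...

    def translate(self, text: str, source_lang: str, target_lang: str) -> str: ...

    def sentiment(self, sentence: str) -> str: ...


# ---------------------------------------------------------------------------
# Hash embedder
# ---------------------------------------------------------------------------

def hash_embed(texts: Sequence[str], dim: int = 256) -> np.ndarray:
    """Signed character-n-gram feature hashing, L2-normalized per row.

    Deterministic across processes (CRC32, not Python's salted hash). The
    empty string maps to a fixed reserved unit vector.
    """
    if dim < 8:
        raise BackendError("embedding dim must be >= 8")
    out = np.zeros((len(texts), dim), dtype=np.float64)
    for i, text in enumerate(texts):
        s = text.lower().strip()
        if not s:
            out[i, 0] = 1.0
            continue
        padded = f" {s} "
        for n in (3, 4):
            for j in range(len(padded) - n + 1):
                h = zlib.crc32(padded[j : j + n].encode("utf-8"))
                sign = 1.0 if (h >> 17) & 1 else -1.0
                out[i, h % dim] += sign
        norm = np.linalg.norm(out[i])
        if norm == 0.0:  # pathological all-cancelling text
            out[i, 0] = 1.0
        else:
            out[i] /= norm
    return out


class HashEmbedder:
    """Deterministic embedder satisfying the ``embed`` part of the contract."""

    def __init__(self, dim: int = 256):
        self.dim = dim

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        return hash_embed(list(texts), self.dim)


# ---------------------------------------------------------------------------
# Lexicon sentiment
# ---------------------------------------------------------------------------

POSITIVE_WORDS = frozenset(
    "good fine stable better calm okay improving comfortable relieved thank "
    "thanks safe clear steady reassuring".split()
)
NEGATIVE_WORDS = frozenset(
    "pain painful worse severe dizzy unconscious bleeding critical distress "
    "weak afraid nausea vomiting emergency collapsed struggling".split()
)


def lexicon_sentiment(
    sentence: str,
    positive: frozenset[str] = POSITIVE_WORDS,
    negative: frozenset[str] = NEGATIVE_WORDS,
) -> str:
    """Majority-count sentiment over lexicon hits; ties and misses -> neutral."""
    tokens = re.findall(r"[a-zäöüß']+", sentence.lower())
    pos = sum(t in positive for t in tokens)
    neg = sum(t in negative for t in tokens)
    if pos > neg:
        return "positive"
    if neg > pos:
        return "negative"
    return "neutral"


# ---------------------------------------------------------------------------
# Mock generator
# ---------------------------------------------------------------------------

FACT_LINE = re.compile(r"^- (?P<key>[a-z][a-z ]*?) is (?P<value>.+)$")
NO_INFO = "No information available."

# Speaker tags: M = medic/paramedic, N = nurse, P = patient.
_SPEAKER_BY_KEY = {
    "complaint": "P",
    "med reported": "P",
    "med given": "N",
}

_PHASE_OPENERS = {
    1: [("M", "Ambulance unit on scene."), ("P", "Please help me.")],
    2: [("N", "Starting triage assessment now.")],
    3: [("N", "Giving the ordered medication now.")],
    4: [("M", "We have arrived at the hospital.")],
}
_REFINE_FILLER = [
    ("M", "Please stay calm for me."),
    ("P", "Thank you, I will try."),
    ("N", "We will take good care of you."),
]


def _parse_facts(prompt: str) -> list[tuple[str, str]]:
    facts: list[tuple[str, str]] = []
    in_block = False
    for line in prompt.splitlines():
        if line.strip() == "Facts:":
            in_block = True
            continue
        if in_block:
            m = FACT_LINE.match(line.strip())
            if m:
                facts.append((m.group("key"), m.group("value")))
            elif not line.strip():
                in_block = False
    return facts


def _fact_utterances(facts: Iterable[tuple[str, str]]) -> list[str]:
    lines = []
    for key, value in facts:
        speaker = _SPEAKER_BY_KEY.get(key, "M")
        lines.append(f"{speaker}: {key} is {value}.")
    return lines


def _truncate_tokens(text: str, max_tokens: int) -> str:
    tokens = text.split()
    if len(tokens) <= max_tokens:
        return text
    # crude whitespace-token cap; real backends count model tokens
    count = 0
    out_lines = []
    for line in text.splitlines():
        n = len(line.split())
        if count + n > max_tokens:
            break
        out_lines.append(line)
        count += n
    return "\n".join(out_lines)


class MockTextBackend:
    """Referentially transparent stand-in for all four model roles.

    ``generate`` dispatches on a tag in the first prompt line:

    - ``[[dialogue-section]]`` / ``[[refine-section]]`` -> speaker-tagged
      utterances echoing every line of the prompt's ``Facts:`` block;
    - ``[[outline]]`` / ``[[summary]]`` -> deterministic digests of the
      fact sentences found in the given text;
    - ``[[extract]]`` -> scans the ``Context:`` block for canonical fact
      sentences (``<key> is <value>.``) whose key occurs in the query
      keyword list, returning a semicolon-joined value list;
    - ``[[normalize]]`` -> returns the term unchanged.
    """

    def __init__(self, embed_dim: int = 256):
        self._embedder = HashEmbedder(embed_dim)

    # -- contract -----------------------------------------------------------
    def embed(self, texts: Sequence[str]) -> np.ndarray:
        return self._embedder.embed(texts)

    def translate(self, text: str, source_lang: str, target_lang: str) -> str:
        return text  # identity mock; the caller rewrites the language tag

    def sentiment(self, sentence: str) -> str:
        return lexicon_sentiment(sentence)

    def generate(self, req: GenerationRequest) -> str:
        prompt = req.prompt
        first = prompt.lstrip().splitlines()[0] if prompt.strip() else ""
        if "[[dialogue-section]]" in first:
            out = self._section(prompt, refined=False)
        elif "[[refine-section]]" in first:
            out = self._section(prompt, refined=True)
        elif "[[outline]]" in first:
            out = self._outline(prompt)
        elif "[[summary]]" in first:
            out = self._summary(prompt)
        elif "[[extract]]" in first:
            out = self._extract(prompt)
        elif "[[normalize]]" in first:
            out = prompt.splitlines()[-1].strip()
        else:
            raise BackendError("mock backend: no recognized template tag in prompt")
        return _truncate_tokens(out, req.max_tokens)

    # -- handlers -----------------------------------------------------------
    def _section(self, prompt: str, refined: bool) -> str:
        m = re.search(r"phase=(\d)", prompt)
        phase = int(m.group(1)) if m else 1
        facts = _parse_facts(prompt)
        lines = [f"{s}: {t}" for s, t in _PHASE_OPENERS.get(phase, [])]
        lines += _fact_utterances(facts)
        if refined:
            lines += [f"{s}: {t}" for s, t in _REFINE_FILLER]
        return "\n".join(lines)

    # anchored to line ends so decimals and dosage strings survive intact;
    # lines truncated at chunk boundaries (no trailing period) never match
    _FACT_SENTENCE = re.compile(r"\b([a-z][a-z ]*?) is (.+)\.\s*$")

    @classmethod
    def _scan_facts(cls, text: str) -> list[tuple[str, str]]:
        found = []
        for line in text.splitlines():
            m = cls._FACT_SENTENCE.search(line)
            if m:
                found.append((m.group(1), m.group(2)))
        return found

    @classmethod
    def _fact_sentences(cls, text: str) -> list[str]:
        return [f"{k} is {v}" for k, v in cls._scan_facts(text)]

    def _outline(self, prompt: str) -> str:
        keys = [s.split(" is ")[0] for s in self._fact_sentences(prompt)]
        return "Outline: " + "; ".join(dict.fromkeys(keys))

    def _summary(self, prompt: str) -> str:
        return "Summary: " + "; ".join(self._fact_sentences(prompt))

    def _extract(self, prompt: str) -> str:
        context = ""
        query = ""
        m = re.search(r"Context:\n(?P<ctx>.*?)\nQuery:", prompt, re.DOTALL)
        if m:
            context = m.group("ctx")
        m = re.search(r"Query:(?P<q>.*)$", prompt, re.DOTALL)
        if m:
            query = m.group("q").lower()
        keywords = [k.strip() for k in re.split(r"[;,()]", query) if k.strip()]
        values: list[str] = []
        for key, value in self._scan_facts(context):
            if key in keywords and value not in values:
                values.append(value)
        return "; ".join(values) if values else NO_INFO
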