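"""Evaluation harness: tolerant matching, confusion tallies, F1 with Delta-method
confidence intervals, and the dialogue-quality statistics.

Matching follows the extraction protocol: numbers are pulled with
``\\d+\\.?\\d*`` and accepted on exact equality, integer-rounded word-boundary
presence, or a +/-0.5 deviation; nominal terms are normalized by a rule table
(abbreviation expansion, compound splitting) and matched by cosine similarity
of their embeddings against a configurable threshold. True negatives are
deliberately absent: the generation pipeline injects every ground-truth item
into the dialogue, so there is no legitimate case of non-extraction. Per
truth item: matched -> TP; answered-but-unmatched -> FP; empty or
"no information" -> FN, so TP+FP+FN equals the item count n.

Dialogue-quality statistics: a one-sided Wilcoxon signed-rank test on paired
positive-sentence proportions (sentiment drift), a two-sided paired Wilcoxon
on dual-judge composite ratings, and quadratically weighted Cohen's kappa
with an asymptotic confidence interval.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import (
    CoverageError,
    DegenerateTestError,
    UndefinedMetricError,
)
from .rag import ExtractionAnswer

# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

_NUMBER_RE = re.compile(r"\d+\.?\d*")


def extract_numbers(text: str) -> list[float]:
    """All maximal digit(.digit) substrings, in document order."""
    return [float(m) for m in _NUMBER_RE.findall(text)]


def _round_half_up(x: float, digits: int = 0) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def match_numeric(answer_text: str, truth_value: float, tolerance: float = 0.5) -> bool:
    """Numeric presence check: exact, integer-rounded at a word boundary,
    or within +/- tolerance."""
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    numbers = extract_numbers(answer_text)
    for num in numbers:
        if num == truth_value or abs(num - truth_value) <= tolerance + 1e-9:
            return True
    rounded = int(_round_half_up(truth_value))
    return re.search(rf"\b{rounded}\b", answer_text) is not None


DEFAULT_NORMALIZATION_RULES: dict[str, list[str]] = {
    "n/v": ["Nausea", "Vomiting"],
    "nausea vomiting": ["Nausea", "Vomiting"],
    "nausea/vomiting": ["Nausea", "Vomiting"],
    "sob": ["Shortness of breath"],
    "c/p": ["Chest pain"],
    "loc": ["Loss of consciousness"],
    "abd pain": ["Abdominal pain"],
    "fever chills": ["Fever", "Chills"],
}


def normalize_nominal(
    term: str,
    rules: Mapping[str, list[str]] | None = None,
    llm_backend=None,
) -> list[str]:
    """Expand abbreviations and split compounds by rule table.

    The optional LLM backend is consulted only when the rules miss (off in
    tests); unknown terms pass through unchanged.
    """
    rules = DEFAULT_NORMALIZATION_RULES if rules is None else rules
    key = term.strip().lower()
    if key in rules:
        return list(rules[key])
    if llm_backend is not None:
        from .backends import GenerationRequest

        reply = llm_backend.generate(
            GenerationRequest(prompt=f"[[normalize]]\n{term}", max_tokens=64, temperature=0.0)
        )
        return [p.strip() for p in reply.split(";") if p.strip()] or [term]
    return [term]


def match_nominal(
    candidates: Sequence[str],
    truth_term: str,
    embedder,
    threshold: float = 0.8,
) -> tuple[bool, float | None]:
    """Best cosine similarity of any candidate against the truth term.

    Returns (matched, best_score); an empty candidate list is unmatched with
    score None.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if not candidates:
        return False, None
    vectors = np.asarray(embedder.embed([truth_term] + list(candidates)), dtype=float)
    sims = vectors[1:] @ vectors[0]
    best = float(np.max(sims))
    return best >= threshold, best


# ---------------------------------------------------------------------------
# Confusion counts and reports
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    feature: str
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn


@dataclass
class GroundTruthItem:
    """One evaluated unit: a single value for numeric features, the full value
    set for nominal features (one item per dialogue)."""

    dialogue_id: str
    feature: str
    values: list


@dataclass
class MetricReport:
    feature: str
    n: int
    tp: int
    fp: int
    fn: int
    precision: float  # percent
    recall: float     # percent
    f1: float         # percent
    ci_low: float | None = None
    ci_high: float | None = None

    def rounded(self) -> dict:
        out = {
            "feature": self.feature,
            "n": self.n,
            "precision": _round_half_up(self.precision, 2),
            "recall": _round_half_up(self.recall, 2),
            "f1": _round_half_up(self.f1, 2),
        }
        if self.ci_low is not None:
            out["ci_low"] = _round_half_up(self.ci_low, 2)
            out["ci_high"] = _round_half_up(self.ci_high, 2)
        return out


@dataclass
class EvalConfig:
    threshold: float = 0.8
    tolerance: float = 0.5
    rules: Mapping[str, list[str]] | None = None
    llm_backend: object | None = None


def _item_matched(
    item: GroundTruthItem,
    answer: ExtractionAnswer,
    kind: str,
    embedder,
    config: EvalConfig,
) -> bool:
    answer_text = " ; ".join(answer.values)
    if kind == "numeric":
        # numeric items carry exactly one value
        return match_numeric(answer_text, float(item.values[0]), config.tolerance)
    candidates = [
        part for v in answer.values for part in normalize_nominal(v, config.rules, config.llm_backend)
    ]
    for truth_value in item.values:
        components = normalize_nominal(str(truth_value), config.rules, config.llm_backend)
        for comp in components:
            matched, _ = match_nominal(candidates, comp, embedder, config.threshold)
            if not matched:
                return False
    return True


def tally_confusion(
    answers: Mapping[tuple[str, str], ExtractionAnswer],
    truths: Sequence[GroundTruthItem],
    kind: str,
    embedder,
    config: EvalConfig | None = None,
) -> ConfusionCounts:
    """Per truth item: matched -> TP; non-empty unmatched -> FP; empty -> FN."""
    if not truths:
        raise CoverageError("no ground-truth items supplied")
    config = config or EvalConfig()
    feature = truths[0].feature
    counts = ConfusionCounts(feature=feature)
    for item in truths:
        key = (item.dialogue_id, item.feature)
        if key not in answers:
            raise CoverageError(f"no answer record for {key}")
        answer = answers[key]
        if answer.no_info or not answer.values:
            counts.fn += 1
        elif _item_matched(item, answer, kind, embedder, config):
            counts.tp += 1
        else:
            counts.fp += 1
    return counts


def precision_recall_f1(c: ConfusionCounts) -> MetricReport:
    """Precision/recall/F1 in percent (CI left unset)."""
    if c.tp + c.fp == 0:
        raise UndefinedMetricError(f"{c.feature}: tp + fp = 0, precision undefined")
    if c.tp + c.fn == 0:
        raise UndefinedMetricError(f"{c.feature}: tp + fn = 0, recall undefined")
    precision = c.tp / (c.tp + c.fp)
    recall = c.tp / (c.tp + c.fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return MetricReport(
        feature=c.feature,
        n=c.n,
        tp=c.tp,
        fp=c.fp,
        fn=c.fn,
        precision=100 * precision,
        recall=100 * recall,
        f1=100 * f1,
    )


def f1_from_percentages(precision_pct: float, recall_pct: float) -> float:
    """Harmonic mean of precision and recall given in percent."""
    if precision_pct + recall_pct == 0:
        return 0.0
    return 2 * precision_pct * recall_pct / (precision_pct + recall_pct)


def f1_delta_ci(c: ConfusionCounts, level: float = 0.95) -> tuple[float, float]:
    """Delta-method CI for F1 = 2tp / (2tp + fp + fn), in percent, clipped.

    (tp, fp, fn) are treated as one multinomial draw of size n; the variance
    is the first-order propagation of the multinomial covariance through F1.
    """
    n = c.n
    if n == 0:
        raise UndefinedMetricError("all counts zero; F1 undefined")
    x = np.array([c.tp, c.fp, c.fn], dtype=float)
    p = x / n
    denom = 2 * x[0] + x[1] + x[2]
    f1 = 2 * x[0] / denom
    grad = np.array(
        [2 * (x[1] + x[2]) / denom**2, -2 * x[0] / denom**2, -2 * x[0] / denom**2]
    )
    cov = n * (np.diag(p) - np.outer(p, p))
    var = float(grad @ cov @ grad)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(max(var, 0.0))
    low = float(np.clip(100 * (f1 - half), 0.0, 100.0))
    high = float(np.clip(100 * (f1 + half), 0.0, 100.0))
    return low, high


def evaluate_corpus(
    answers: Sequence[ExtractionAnswer],
    truths: Sequence[GroundTruthItem],
    embedder,
    config: EvalConfig | None = None,
    feature_kinds: Mapping[str, str] | None = None,
    level: float = 0.95,
) -> list[MetricReport]:
    """One MetricReport (with CI) per feature, in the registry's table order."""
    from .features import FEATURES

    config = config or EvalConfig()
    kinds = feature_kinds or {f.name: f.kind for f in FEATURES}
    answer_map = {(a.dialogue_id, a.feature): a for a in answers}
    truth_by_feature: dict[str, list[GroundTruthItem]] = {}
    for item in truths:
        truth_by_feature.setdefault(item.feature, []).append(item)

    reports = []
    for name in kinds:
        if name not in truth_by_feature:
            raise CoverageError(f"no ground truth for feature '{name}'")
        counts = tally_confusion(
            answer_map, truth_by_feature[name], kinds[name], embedder, config
        )
        report = precision_recall_f1(counts)
        report.ci_low, report.ci_high = f1_delta_ci(counts, level)
        reports.append(report)
    return reports


def reports_to_csv(reports: Sequence[MetricReport], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["feature", "n", "precision", "recall", "f1", "ci_low", "ci_high"]
        )
        writer.writeheader()
        for r in reports:
            writer.writerow(r.rounded())


# ---------------------------------------------------------------------------
# Dialogue-quality statistics
# ---------------------------------------------------------------------------

@dataclass
class SentimentSeries:
    """Paired per-dialogue proportions of positive-labeled sentences."""

    original: list[float]
    refined: list[float]

    def __post_init__(self) -> None:
        if len(self.original) != len(self.refined):
            raise ValueError("paired series must have equal lengths")
        for x in list(self.original) + list(self.refined):
            if not 0 <= x <= 1:
                raise ValueError("proportions must lie in [0, 1]")


def signed_rank_statistic(diffs: Sequence[float]) -> float:
    """W+ = sum of average ranks of |d| over positive differences (zeros dropped)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    return float(ranks[d > 0].sum())


def _wilcoxon(diffs: np.ndarray, alternative: str) -> tuple[float, float]:
    d = diffs[diffs != 0]
    if d.size == 0:
        raise DegenerateTestError("all paired differences are zero")
    res = stats.wilcoxon(d, alternative=alternative, zero_method="wilcox", correction=False)
    return signed_rank_statistic(d), float(res.pvalue)


def sentiment_drift_test(s: SentimentSeries) -> tuple[float, float]:
    """One-sided signed-rank test of H1: refined positivity < original.

    The null is that refined positivity is greater than or equal to the
    original's. Returns (W+, one-sided p).
    """
    diffs = np.asarray(s.refined, dtype=float) - np.asarray(s.original, dtype=float)
    return _wilcoxon(diffs, alternative="less")


def paired_judge_test(
    composites_a: Sequence[float], composites_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided paired signed-rank test on dual-judge composite ratings."""
    a = np.asarray(composites_a, dtype=float)
    b = np.asarray(composites_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length series of length >= 2")
    return _wilcoxon(a - b, alternative="two-sided")


def composite_scores(ratings: np.ndarray) -> np.ndarray:
    """Mean across rating dimensions, one composite per item."""
    return np.asarray(ratings, dtype=float).mean(axis=1)


@dataclass
class RatingMatrix:
    """Item x dimension ratings on the 1-3 scale for two raters."""

    rater_a: np.ndarray
    rater_b: np.ndarray

    def __post_init__(self) -> None:
        self.rater_a = np.asarray(self.rater_a)
        self.rater_b = np.asarray(self.rater_b)
        if self.rater_a.shape != self.rater_b.shape:
            raise ValueError("rating matrices must have equal shapes")
        for arr in (self.rater_a, self.rater_b):
            if not np.isin(arr, [1, 2, 3]).all():
                raise ValueError("ratings must be in {1, 2, 3}")

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        return self.rater_a.ravel(), self.rater_b.ravel()


def weighted_kappa(
    a: Sequence[int],
    b: Sequence[int],
    categories: Sequence[int] = (1, 2, 3),
    level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Quadratically weighted Cohen's kappa with asymptotic CI, clipped to [-1, 1].

    Disagreement weights are (i - j)^2 / (c - 1)^2; the variance is the
    Fleiss-Cohen-Everitt large-sample formula.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length rating vectors of length >= 2")
    cats = list(categories)
    c = len(cats)
    index = {cat: i for i, cat in enumerate(cats)}
    n = a.size
    table = np.zeros((c, c))
    for x, y in zip(a, b):
        table[index[x], index[y]] += 1
    p = table / n
    # agreement weights v = 1 - disagreement
    i_idx, j_idx = np.meshgrid(np.arange(c), np.arange(c), indexing="ij")
    v = 1.0 - (i_idx - j_idx) ** 2 / (c - 1) ** 2
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = float((p * v).sum())
    pe = float((np.outer(row, col) * v).sum())
    if pe == 1.0:
        if po == 1.0:
            return 1.0, (1.0, 1.0)
        raise DegenerateTestError("chance agreement is 1; kappa undefined")
    kappa = (po - pe) / (1 - pe)
    if po == 1.0:
        return 1.0, (1.0, 1.0)

    v_row = (v * col[None, :]).sum(axis=1)  # E[v | rater A gave i]
    v_col = (v * row[:, None]).sum(axis=0)  # E[v | rater B gave j]
    term = (
        p * (v * (1 - pe) - (v_row[:, None] + v_col[None, :]) * (1 - po)) ** 2
    ).sum()
    var = (term - (po * pe - 2 * pe + po) ** 2) / (n * (1 - pe) ** 4)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(max(float(var), 0.0))
    ci = (
        float(np.clip(kappa - half, -1.0, 1.0)),
        float(np.clip(kappa + half, -1.0, 1.0)),
    )
    return float(kappa), ci
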