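"""Adapted Post-Randomization Method (PRAM) for ED encounter records.

PRAM replaces attribute values by draws from a row-stochastic transition
matrix. The adaptation here forces replacement (zero self-transition
probability) and restricts swaps to *semantically similar* values:

- free-text categories (diagnoses, medications, complaints) are embedded,
  reduced by PCA, L2-normalized, grouped by constrained equal-size k-means,
  pruned of at most one >3-sigma cosine-distance outlier per cluster, and
  swapped uniformly within their cluster;
- numeric vitals are swapped within the quantile bin of the attribute's
  empirical pool, which keeps every swapped value inside the observed
  plausible range.

Gender and stay_id are never perturbed, so gender-specific diagnoses and
medications stay consistent in downstream dialogue generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import kmeans_plusplus
from sklearn.decomposition import PCA

from .ed_records import PatientCase
from .errors import (
    ConfigurationError,
    DimensionError,
    NormalizationError,
    UnswappableClusterError,
)


@dataclass
class TermEmbeddingSet:
    """Unique terms with one embedding row each."""

    terms: list[str]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        if len(self.terms) != len(set(self.terms)):
            raise ConfigurationError("terms must be unique")
        if self.vectors.shape[0] != len(self.terms):
            raise ConfigurationError("one vector per term required")


@dataclass
class ClusterModel:
    k: int
    assignment: dict[str, int]
    centers: np.ndarray
    removed_outliers: list[str] = field(default_factory=list)

    def members(self, cluster_id: int) -> list[str]:
        return [t for t, c in self.assignment.items() if c == cluster_id]


@dataclass
class TransitionMatrix:
    """Square row-stochastic matrix with zero diagonal and uniform rows."""

    categories: list[str]
    probs: np.ndarray

    def __post_init__(self) -> None:
        m = len(self.categories)
        if m < 2:
            raise UnswappableClusterError("transition matrix needs >= 2 categories")
        if self.probs.shape != (m, m):
            raise ConfigurationError("probs must be m x m")
        if not np.allclose(np.diag(self.probs), 0.0):
            raise ConfigurationError("diagonal must be zero")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-12):
            raise ConfigurationError("rows must sum to 1")


class PramConfig(BaseModel):
    sample_size: int = Field(default=1000, ge=1)
    k_clusters: int = Field(default=100, ge=1)
    pca_dim: int = Field(default=65, ge=1)
    outlier_sigma: float = Field(default=3.0, gt=0)
    seed: int = 0
    numeric_bins: int = Field(default=10, ge=1)


# ---------------------------------------------------------------------------
# Embedding-space operations
# ---------------------------------------------------------------------------

def embed_terms(terms: Sequence[str], embedder) -> TermEmbeddingSet:
    """Embed the deduplicated term list (first-occurrence order kept)."""
    unique = list(dict.fromkeys(terms))
    if not unique:
        raise ConfigurationError("no terms to embed")
    return TermEmbeddingSet(terms=unique, vectors=np.asarray(embedder.embed(unique), dtype=float))


def pca_reduce(es: TermEmbeddingSet, dim: int) -> TermEmbeddingSet:
    """Project onto the top ``dim`` principal components (orthonormal basis)."""
    n, d = es.vectors.shape
    if dim > min(n, d):
        raise DimensionError(f"dim {dim} exceeds min(n_terms={n}, d={d})")
    rank = int(np.linalg.matrix_rank(es.vectors - es.vectors.mean(axis=0)))
    if dim > rank:
        raise DimensionError(f"dim {dim} exceeds available rank {rank}")
    pca = PCA(n_components=dim, svd_solver="full", random_state=0)
    reduced = pca.fit_transform(es.vectors)
    return TermEmbeddingSet(terms=list(es.terms), vectors=reduced)


def l2_normalize(es: TermEmbeddingSet) -> TermEmbeddingSet:
    norms = np.linalg.norm(es.vectors, axis=1)
    zero = np.where(norms == 0)[0]
    if zero.size:
        raise NormalizationError(f"zero vector for term '{es.terms[zero[0]]}'")
    return TermEmbeddingSet(terms=list(es.terms), vectors=es.vectors / norms[:, None])


def cluster_equal_size(es: TermEmbeddingSet, k: int, seed: int, max_iter: int = 100) -> ClusterModel:
    """Constrained k-means: k clusters whose sizes differ by at most one.

    kmeans++ initialization, then alternating (a) capacity-constrained
    assignment solved exactly as a rectangular assignment problem over
    cluster slots and (b) centroid update, until the assignment is stable.
    Deterministic under ``seed``.
    """
    X = es.vectors
    n = X.shape[0]
    if k > n:
        raise ConfigurationError(f"k={k} exceeds number of terms {n}")
    base, extra = divmod(n, k)
    capacities = [base + (1 if j < extra else 0) for j in range(k)]

    centers, _ = kmeans_plusplus(X, n_clusters=k, random_state=seed)
    slot_cluster = np.repeat(np.arange(k), capacities)
    labels = np.full(n, -1)
    for _ in range(max_iter):
        # cost of putting point i into a slot of cluster j
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        cost = d2[:, slot_cluster]
        row, col = linear_sum_assignment(cost)
        new_labels = slot_cluster[col[np.argsort(row)]]
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            centers[j] = X[labels == j].mean(axis=0)
    assignment = {t: int(c) for t, c in zip(es.terms, labels)}
    return ClusterModel(k=k, assignment=assignment, centers=centers)


def cosine_distance(v: np.ndarray, w: np.ndarray) -> float:
    denom = np.linalg.norm(v) * np.linalg.norm(w)
    if denom == 0:
        return 1.0
    return float(1.0 - np.dot(v, w) / denom)


def prune_outliers(cm: ClusterModel, es: TermEmbeddingSet, sigma: float = 3.0) -> ClusterModel:
    """Remove at most the single most extreme outlier per cluster.

    A term is an outlier when its cosine distance to the cluster center
    exceeds mean + sigma * sd of the within-cluster distances; only the
    farthest such term is removed, never more than one.
    """
    index = {t: i for i, t in enumerate(es.terms)}
    assignment = dict(cm.assignment)
    removed = list(cm.removed_outliers)
    for j in range(cm.k):
        members = [t for t, c in assignment.items() if c == j]
        if not members:
            continue
        dists = np.array([cosine_distance(es.vectors[index[t]], cm.centers[j]) for t in members])
        mean, sd = dists.mean(), dists.std()
        worst = int(np.argmax(dists))
        if dists[worst] > mean + sigma * sd:
            removed.append(members[worst])
            del assignment[members[worst]]
    return ClusterModel(k=cm.k, assignment=assignment, centers=cm.centers, removed_outliers=removed)


def nearest_cluster(cm: ClusterModel, vector: np.ndarray) -> int:
    d2 = ((cm.centers - vector[None, :]) ** 2).sum(axis=1)
    return int(np.argmin(d2))


# ---------------------------------------------------------------------------
# Transition matrices and swapping
# ---------------------------------------------------------------------------

def build_transition_matrix(cluster_members: Sequence[str], original: str) -> TransitionMatrix:
    """Uniform zero-diagonal matrix over the cluster containing ``original``."""
    members = list(cluster_members)
    if original not in members:
        raise UnswappableClusterError(f"'{original}' not among cluster members")
    m = len(members)
    if m < 2:
        raise UnswappableClusterError(f"singleton cluster for '{original}' cannot be swapped")
    probs = (np.ones((m, m)) - np.eye(m)) / (m - 1)
    return TransitionMatrix(categories=members, probs=probs)


def pram_swap_nominal(value: str, tm: TransitionMatrix, rng: np.random.Generator) -> str:
    try:
        i = tm.categories.index(value)
    except ValueError:
        raise KeyError(f"value '{value}' not in transition matrix") from None
    j = rng.choice(len(tm.categories), p=tm.probs[i])
    return tm.categories[int(j)]


def _quantile_bin_members(pool: np.ndarray, value: float, bins: int) -> np.ndarray:
    edges = np.quantile(pool, np.linspace(0, 1, bins + 1))
    # right-closed last bin; clamp value into the observed support
    idx = int(np.searchsorted(edges[1:-1], value, side="right"))
    lo, hi = edges[idx], edges[idx + 1]
    return pool[(pool >= lo) & (pool <= hi)]


def pram_swap_numeric(
    value: float, pool: Sequence[float], bins: int, rng: np.random.Generator
) -> float:
    """Swap within the value's quantile bin of the attribute pool.

    The result stays inside the observed pool range and differs from the
    input whenever the bin holds another distinct value.
    """
    pool_arr = np.asarray(pool, dtype=float)
    if np.unique(pool_arr).size < 2:
        raise UnswappableClusterError("constant attribute pool cannot be swapped")
    members = np.unique(_quantile_bin_members(pool_arr, value, bins))
    alternatives = members[members != value]
    if alternatives.size == 0:
        return float(value)
    return float(rng.choice(alternatives))


def _swap_bp_pair(
    pair: tuple[float, float],
    pool: Sequence[tuple[float, float]],
    bins: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Swap (sbp, dbp) jointly (binned on sbp) so sbp > dbp is preserved."""
    pairs = list(dict.fromkeys(pool))
    if len(pairs) < 2:
        raise UnswappableClusterError("constant blood-pressure pool cannot be swapped")
    sbps = np.asarray([p[0] for p in pairs])
    members = _quantile_bin_members(sbps, pair[0], bins)
    lo, hi = members.min(), members.max()
    candidates = [p for p in pairs if lo <= p[0] <= hi and p != tuple(pair)]
    if not candidates:
        candidates = [p for p in pairs if p != tuple(pair)]
    return candidates[int(rng.integers(len(candidates)))]


# ---------------------------------------------------------------------------
# Corpus-level PRAM
# ---------------------------------------------------------------------------

_NOMINAL_FIELDS = ("diagnoses", "meds_reported", "meds_administered")
_NUMERIC_VITALS = ("temperature", "heartrate", "resprate", "o2sat", "pain")


def _build_cluster_pipeline(
    terms: Sequence[str], config: PramConfig, embedder
) -> tuple[ClusterModel, TermEmbeddingSet]:
    es = embed_terms(terms, embedder)
    n = len(es.terms)
    rank = int(np.linalg.matrix_rank(es.vectors - es.vectors.mean(axis=0)))
    dim = max(1, min(config.pca_dim, rank))
    es = l2_normalize(pca_reduce(es, dim))
    k = max(1, min(config.k_clusters, n // 2))
    cm = cluster_equal_size(es, k, seed=config.seed)
    cm = prune_outliers(cm, es, config.outlier_sigma)
    return cm, es


def _cluster_of(term: str, cm: ClusterModel, es: TermEmbeddingSet) -> int:
    if term in cm.assignment:
        return cm.assignment[term]
    # removed outliers (and unseen terms) map to the nearest cluster center
    idx = es.terms.index(term)
    return nearest_cluster(cm, es.vectors[idx])


def _swap_term(term: str, cm: ClusterModel, es: TermEmbeddingSet, rng: np.random.Generator) -> str:
    cluster = _cluster_of(term, cm, es)
    members = cm.members(cluster)
    if term in members:
        tm = build_transition_matrix(members, term)
        return pram_swap_nominal(term, tm, rng)
    candidates = [m for m in members if m != term]
    if not candidates:
        raise UnswappableClusterError(f"no replacement available for '{term}'")
    return candidates[int(rng.integers(len(candidates)))]


def apply_pram(
    cases: Sequence[PatientCase], config: PramConfig, embedder
) -> list[PatientCase]:
    """Replace every nominal target value and every numeric vital, per case.

    Nominal targets are the diagnoses, both medication lists, and the chief
    complaint; each is replaced by a cluster-mate (never itself). Numeric
    vitals are swapped within quantile bins of their corpus-wide pools, with
    blood pressure swapped as an (sbp, dbp) pair. Gender, stay_id, acuity and
    arrival transport are preserved; outputs are flagged synthetic.
    """
    if not cases:
        return []
    rng = np.random.default_rng(config.seed)

    sample = list(cases)
    if len(sample) > config.sample_size:
        idx = rng.choice(len(sample), size=config.sample_size, replace=False)
        sample = [sample[i] for i in sorted(idx)]

    diag_terms = [d for c in sample for d in c.diagnoses]
    med_terms = [m for c in sample for m in c.meds_reported + c.meds_administered]
    complaint_terms = [c.chief_complaint for c in sample]
    # corpus values outside the sample must still be mappable
    diag_terms += [d for c in cases for d in c.diagnoses]
    med_terms += [m for c in cases for m in c.meds_reported + c.meds_administered]
    complaint_terms += [c.chief_complaint for c in cases]

    models = {
        "diagnosis": _build_cluster_pipeline(diag_terms, config, embedder),
        "medication": _build_cluster_pipeline(med_terms, config, embedder),
        "complaint": _build_cluster_pipeline(complaint_terms, config, embedder),
    }

    pools = {
        attr: np.asarray([getattr(v, attr) for c in cases for v in c.vitals], dtype=float)
        for attr in _NUMERIC_VITALS
    }
    bp_pool = [(v.sbp, v.dbp) for c in cases for v in c.vitals]

    out: list[PatientCase] = []
    for case in cases:
        cm_d, es_d = models["diagnosis"]
        cm_m, es_m = models["medication"]
        cm_c, es_c = models["complaint"]
        new_vitals = []
        for v in case.vitals:
            sbp, dbp = _swap_bp_pair((v.sbp, v.dbp), bp_pool, config.numeric_bins, rng)
            updates = {
                attr: pram_swap_numeric(getattr(v, attr), pools[attr], config.numeric_bins, rng)
                for attr in _NUMERIC_VITALS
            }
            updates["pain"] = int(updates["pain"])
            new_vitals.append(v.model_copy(update={**updates, "sbp": sbp, "dbp": dbp}))
        out.append(
            case.model_copy(
                update={
                    "diagnoses": [_swap_term(d, cm_d, es_d, rng) for d in case.diagnoses],
                    "meds_reported": [_swap_term(m, cm_m, es_m, rng) for m in case.meds_reported],
                    "meds_administered": [
                        _swap_term(m, cm_m, es_m, rng) for m in case.meds_administered
                    ],
                    "chief_complaint": _swap_term(case.chief_complaint, cm_c, es_c, rng),
                    "vitals": new_vitals,
                    "synthetic": True,
                }
            )
        )
    return out
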