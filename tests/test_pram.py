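"""PRAM: embedding pipeline, constrained clustering, transition matrices, swaps."""

import itertools
from collections import Counter

import numpy as np
import pytest
from scipy import stats

from emsrag.backends import MockTextBackend
from emsrag.errors import (
    ConfigurationError,
    DimensionError,
    NormalizationError,
    UnswappableClusterError,
)
from emsrag.pram import (
    ClusterModel,
    PramConfig,
    TermEmbeddingSet,
    apply_pram,
    build_transition_matrix,
    cluster_equal_size,
    embed_terms,
    l2_normalize,
    pca_reduce,
    pram_swap_nominal,
    pram_swap_numeric,
    prune_outliers,
)


class TestEmbedTerms:
    def test_deduplicates(self, backend):
        es = embed_terms(["a", "a", "b"], backend)
        assert es.terms == ["a", "b"]
        assert es.vectors.shape[0] == 2

    def test_identical_terms_identical_vectors(self, backend):
        es = embed_terms(["pneumonia", "sepsis", "pneumonia"], backend)
        again = embed_terms(["pneumonia"], backend)
        np.testing.assert_allclose(es.vectors[0], again.vectors[0])


class TestPca:
    def test_matches_eigendecomposition_oracle(self, rng):
        """Projection equals the covariance eigendecomposition up to sign."""
        X = rng.normal(size=(10, 4))
        es = TermEmbeddingSet(terms=[f"t{i}" for i in range(10)], vectors=X)
        reduced = pca_reduce(es, 2).vectors

        Xc = X - X.mean(axis=0)
        w, V = np.linalg.eigh(Xc.T @ Xc / 10)
        order = np.argsort(w)[::-1]
        oracle = Xc @ V[:, order[:2]]
        for j in range(2):  # sign alignment per component
            if np.dot(oracle[:, j], reduced[:, j]) < 0:
                oracle[:, j] *= -1
        assert np.linalg.norm(oracle - reduced) < 1e-8

    def test_rank_one_matrix_keeps_all_variance(self):
        base = np.outer(np.arange(1, 7, dtype=float), [1.0, 2.0, 3.0])
        es = TermEmbeddingSet(terms=[f"t{i}" for i in range(6)], vectors=base)
        reduced = pca_reduce(es, 1)
        total = ((base - base.mean(0)) ** 2).sum()
        kept = (reduced.vectors ** 2).sum()
        assert kept == pytest.approx(total)

    def test_dim_exceeding_rank_raises(self):
        base = np.outer(np.arange(6, dtype=float), [1.0, 2.0, 3.0])
        es = TermEmbeddingSet(terms=[f"t{i}" for i in range(6)], vectors=base)
        with pytest.raises(DimensionError):
            pca_reduce(es, 2)


class TestL2Normalize:
    def test_closed_form(self):
        es = TermEmbeddingSet(terms=["x"], vectors=np.array([[3.0, 4.0]]))
        np.testing.assert_allclose(l2_normalize(es).vectors, [[0.6, 0.8]])

    def test_idempotent_and_unit_norm(self, rng):
        es = TermEmbeddingSet(terms=[f"t{i}" for i in range(6)], vectors=rng.normal(size=(6, 3)))
        once = l2_normalize(es)
        np.testing.assert_allclose(np.linalg.norm(once.vectors, axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(l2_normalize(once).vectors, once.vectors, atol=1e-12)

    def test_zero_vector_names_term(self):
        es = TermEmbeddingSet(terms=["ok", "null"], vectors=np.array([[1.0, 0.0], [0.0, 0.0]]))
        with pytest.raises(NormalizationError, match="null"):
            l2_normalize(es)


class TestConstrainedKMeans:
    def test_equal_sizes(self, rng):
        es = TermEmbeddingSet(terms=[f"t{i}" for i in range(100)], vectors=rng.normal(size=(100, 5)))
        cm = cluster_equal_size(es, 10, seed=1)
        assert sorted(Counter(cm.assignment.values()).values()) == [10] * 10

    def test_sizes_differ_by_at_most_one_when_not_divisible(self, rng):
        es = TermEmbeddingSet(terms=[f"t{i}" for i in range(11)], vectors=rng.normal(size=(11, 3)))
        sizes = sorted(Counter(cluster_equal_size(es, 3, seed=0).assignment.values()).values())
        assert sizes == [3, 4, 4]

    def test_matches_brute_force_on_separated_clouds(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (3, 2)), rng.normal(5, 0.1, (3, 2))])
        terms = [f"t{i}" for i in range(6)]
        cm = cluster_equal_size(TermEmbeddingSet(terms=terms, vectors=X), 2, seed=0)

        best = None
        for combo in itertools.combinations(range(6), 3):
            groups = [list(combo), [i for i in range(6) if i not in combo]]
            sse = sum(((X[g] - X[g].mean(0)) ** 2).sum() for g in groups)
            if best is None or sse < best[0]:
                best = (sse, frozenset(combo))
        found = frozenset(i for i, t in enumerate(terms) if cm.assignment[t] == cm.assignment["t0"])
        assert found in (best[1], frozenset(range(6)) - best[1])

    def test_deterministic_under_seed(self, rng):
        es = TermEmbeddingSet(terms=[f"t{i}" for i in range(30)], vectors=rng.normal(size=(30, 4)))
        assert cluster_equal_size(es, 5, seed=7).assignment == cluster_equal_size(es, 5, seed=7).assignment

    def test_k_exceeding_terms_raises(self, rng):
        es = TermEmbeddingSet(terms=["a", "b"], vectors=rng.normal(size=(2, 2)))
        with pytest.raises(ConfigurationError):
            cluster_equal_size(es, 3, seed=0)


class TestPruneOutliers:
    def _single_cluster(self, vectors):
        terms = [f"v{i}" for i in range(len(vectors))]
        es = TermEmbeddingSet(terms=terms, vectors=vectors)
        center = vectors.mean(axis=0, keepdims=True)
        cm = ClusterModel(k=1, assignment={t: 0 for t in terms}, centers=center)
        return cm, es

    def test_identical_vectors_nothing_removed(self):
        cm, es = self._single_cluster(np.tile([1.0, 0.0], (5, 1)))
        assert prune_outliers(cm, es, 3.0).removed_outliers == []

    def test_antipodal_outlier_removed(self, rng):
        V = np.tile([1.0, 0.0], (21, 1)) + np.vstack([rng.normal(0, 0.01, (20, 2)), [[0.0, 0.0]]])
        V[20] = [-1.0, 0.0]
        V /= np.linalg.norm(V, axis=1, keepdims=True)
        cm, es = self._single_cluster(V)
        cm.centers = V[:20].mean(axis=0, keepdims=True)
        pruned = prune_outliers(cm, es, 3.0)
        assert pruned.removed_outliers == ["v20"]
        assert "v20" not in pruned.assignment

    def test_only_single_most_extreme_removed(self, rng):
        """Two gross outliers, but only the farther one may be removed."""
        V = np.tile([1.0, 0.0], (22, 1)) + np.vstack([rng.normal(0, 0.001, (20, 2)), np.zeros((2, 2))])
        V[20] = [0.0, 1.0]   # far
        V[21] = [-1.0, 0.0]  # farther
        V /= np.linalg.norm(V, axis=1, keepdims=True)
        cm, es = self._single_cluster(V)
        cm.centers = V[:20].mean(axis=0, keepdims=True)
        pruned = prune_outliers(cm, es, 3.0)
        assert pruned.removed_outliers == ["v21"]
        assert "v20" in pruned.assignment

    def test_accounting_identity(self, backend, rng):
        """Assigned terms plus removed outliers equal the input terms."""
        terms = [f"term number {i}" for i in range(40)]
        es = l2_normalize(embed_terms(terms, backend))
        cm = prune_outliers(cluster_equal_size(es, 8, seed=0), es, 1.0)
        assert len(cm.assignment) + len(cm.removed_outliers) == 40


class TestTransitionMatrix:
    def test_five_members_quarter_probability(self):
        tm = build_transition_matrix([f"dx{i}" for i in range(5)], "dx0")
        assert np.allclose(np.diag(tm.probs), 0.0)
        off = tm.probs[~np.eye(5, dtype=bool)]
        assert np.allclose(off, 0.25)
        assert np.allclose(tm.probs.sum(axis=1), 1.0, atol=1e-12)

    def test_two_members_forced_swap(self, rng):
        tm = build_transition_matrix(["a", "b"], "a")
        assert tm.probs[0, 1] == 1.0
        assert pram_swap_nominal("a", tm, rng) == "b"

    @pytest.mark.parametrize("m", [2, 3, 7, 20])
    def test_rows_sum_to_one(self, m):
        tm = build_transition_matrix([f"c{i}" for i in range(m)], "c0")
        assert np.allclose(tm.probs.sum(axis=1), 1.0, atol=1e-12)

    def test_singleton_cluster_raises(self):
        with pytest.raises(UnswappableClusterError):
            build_transition_matrix(["only"], "only")

    def test_original_never_returned(self, rng):
        tm = build_transition_matrix(["a", "b", "c"], "a")
        assert all(pram_swap_nominal("a", tm, rng) != "a" for _ in range(200))

    def test_unknown_value_raises(self, rng):
        tm = build_transition_matrix(["a", "b"], "a")
        with pytest.raises(KeyError):
            pram_swap_nominal("zzz", tm, rng)

    def test_swap_frequencies_uniform_chi_square(self, rng):
        """10^4 draws from a 5-member row stay consistent with uniform 1/4."""
        members = [f"dx{i}" for i in range(5)]
        tm = build_transition_matrix(members, "dx0")
        draws = Counter(pram_swap_nominal("dx0", tm, rng) for _ in range(10_000))
        observed = [draws[m] for m in members[1:]]
        assert draws["dx0"] == 0
        _, p = stats.chisquare(observed)
        assert p > 0.01


class TestNumericSwap:
    def test_two_value_pool_forced(self, rng):
        assert pram_swap_numeric(78, [78, 80], bins=1, rng=rng) == 80

    def test_all_swaps_within_pool_range(self, rng):
        pool = rng.integers(40, 181, size=1000).astype(float)
        lo, hi = pool.min(), pool.max()
        for value in rng.choice(pool, size=200):
            swapped = pram_swap_numeric(float(value), pool, bins=10, rng=rng)
            assert lo <= swapped <= hi

    def test_pool_max_stays_at_or_below_max(self, rng):
        pool = [10.0, 20.0, 30.0, 40.0]
        assert pram_swap_numeric(40.0, pool, bins=2, rng=rng) <= 40.0

    def test_constant_pool_raises(self, rng):
        with pytest.raises(UnswappableClusterError):
            pram_swap_numeric(5.0, [5.0, 5.0, 5.0], bins=1, rng=rng)


class TestApplyPram:
    def test_invariants(self, cases, backend):
        config = PramConfig(seed=11)
        out = apply_pram(cases, config, backend)
        assert len(out) == len(cases)
        for before, after in zip(cases, out):
            assert after.gender == before.gender
            assert after.stay_id == before.stay_id
            assert after.synthetic
            assert all(a != b for a, b in zip(before.diagnoses, after.diagnoses))
            assert after.chief_complaint != before.chief_complaint
            assert all(a != b for a, b in zip(before.meds_reported, after.meds_reported))
            assert all(
                a != b for a, b in zip(before.meds_administered, after.meds_administered)
            )
            for v in after.vitals:
                assert v.sbp > v.dbp > 0
                assert 0 <= v.pain <= 10

    def test_deterministic(self, cases, backend):
        config = PramConfig(seed=11)
        a = apply_pram(cases, config, backend)
        b = apply_pram(cases, config, backend)
        assert [c.model_dump() for c in a] == [c.model_dump() for c in b]
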