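"""Similarity-function contracts: sub-tree kernels, assignment, final scores."""

import itertools
import math

import numpy as np
import pytest

from fapscreen.chemgraph import AtomLabel
from fapscreen.encoder import FlexibleLeaf, RigidLeaf, build_encoded
from fapscreen.fixtures import (
    perturb_synthetic_molecule,
    random_encoded_molecule,
    random_synthetic_molecule,
)
from fapscreen.gmmfit import GaussianComponent, Gmm1D
from fapscreen.simfun import (
    SimConfig,
    fap_oa_similarity,
    fap_sum_similarity,
    flexible_similarity,
    label_similarity,
    optimal_assignment,
    rigid_similarity,
    screen,
    similarity_matrix,
)

L_C_RING = AtomLabel("C", True, 1)
L_C_CHAIN = AtomLabel("C", False, 1)
L_N = AtomLabel("N", False, 0)
L_O = AtomLabel("O", False, 0)


def _unit_gmm(mean):
    return Gmm1D([GaussianComponent(1.0, mean, 1.0)])


class TestLabelSimilarity:
    def test_identical(self):
        assert label_similarity(L_C_RING, AtomLabel("C", True, 1)) == 1.0

    @pytest.mark.parametrize("other", [L_C_CHAIN, AtomLabel("N", True, 1), AtomLabel("C", True, 2)])
    def test_any_field_mismatch(self, other):
        assert label_similarity(L_C_RING, other) == 0.0


class TestRigidSimilarity:
    def test_identical_multisets(self):
        r = [RigidLeaf(L_C_RING, 2), RigidLeaf(L_N, 3)]
        assert rigid_similarity(r, list(r)) == 1.0

    def test_disjoint(self):
        assert rigid_similarity([RigidLeaf(L_C_RING, 2)], [RigidLeaf(L_N, 2)]) == 0.0

    def test_multiset_min_counts(self):
        # {a, a, b} vs {a, c}: intersection 1, union 4 -> 1/4
        a, b, c = RigidLeaf(L_C_RING, 1), RigidLeaf(L_N, 2), RigidLeaf(L_O, 3)
        assert rigid_similarity([a, a, b], [a, c]) == 0.25

    def test_empty_conventions(self):
        assert rigid_similarity([], []) == 1.0
        assert rigid_similarity([], [RigidLeaf(L_N, 1)]) == 0.0


class TestFlexibleSimilarity:
    def test_identical_leaves(self):
        f = [FlexibleLeaf(L_C_CHAIN, _unit_gmm(3.0)), FlexibleLeaf(L_N, _unit_gmm(5.0))]
        assert flexible_similarity(f, list(f)) == pytest.approx(1.0)

    def test_single_leaves_reduce_to_gmm_correlation(self):
        f1 = [FlexibleLeaf(L_C_CHAIN, _unit_gmm(0.0))]
        f2 = [FlexibleLeaf(L_C_CHAIN, _unit_gmm(2.0))]
        assert flexible_similarity(f1, f2) == pytest.approx(math.exp(-1.0))

    def test_label_mismatch_kills_term(self):
        f1 = [FlexibleLeaf(L_C_CHAIN, _unit_gmm(3.0))]
        f2 = [FlexibleLeaf(L_N, _unit_gmm(3.0))]
        assert flexible_similarity(f1, f2) == 0.0

    def test_empty_conventions(self):
        assert flexible_similarity([], []) == 1.0
        assert flexible_similarity([], [FlexibleLeaf(L_N, _unit_gmm(1.0))]) == 0.0

    def test_permutation_invariant_identity(self, rng):
        leaves = [
            FlexibleLeaf(L_C_CHAIN, _unit_gmm(float(m))) for m in rng.uniform(2, 9, 5)
        ]
        shuffled = [leaves[k] for k in rng.permutation(5)]
        assert flexible_similarity(leaves, shuffled) == pytest.approx(1.0, abs=1e-12)


class TestOptimalAssignment:
    def test_identity_matrix(self):
        a = optimal_assignment(np.eye(3))
        assert a.total == pytest.approx(3.0)
        assert a.mapping == {0: 0, 1: 1, 2: 2}

    def test_two_by_two(self):
        a = optimal_assignment(np.array([[0.9, 0.1], [0.2, 0.8]]))
        assert a.mapping == {0: 0, 1: 1}
        assert a.total == pytest.approx(1.7)

    def test_brute_force_oracle_rectangular(self, rng):
        for _ in range(30):
            rows = int(rng.integers(1, 5))
            cols = int(rng.integers(rows, 7))
            s = rng.random((rows, cols))
            best = max(
                sum(s[i, p[i]] for i in range(rows))
                for p in itertools.permutations(range(cols), rows)
            )
            assert optimal_assignment(s).total == pytest.approx(best)

    def test_transposed_matrix_same_total(self, rng):
        s = rng.random((3, 6))
        assert optimal_assignment(s).total == pytest.approx(optimal_assignment(s.T).total)


class TestFinalScores:
    def test_self_similarity_one(self, rng):
        for _ in range(10):
            m = random_encoded_molecule(rng)
            assert fap_oa_similarity(m, m) == 1.0

    def test_symmetry_exact(self, rng):
        for _ in range(25):
            a = random_encoded_molecule(rng)
            b = random_encoded_molecule(rng)
            assert fap_oa_similarity(a, b) == fap_oa_similarity(b, a)
            assert fap_sum_similarity(a, b) == fap_sum_similarity(b, a)

    def test_matrix_transpose_identity(self, rng):
        a = random_encoded_molecule(rng)
        b = random_encoded_molecule(rng)
        assert np.array_equal(similarity_matrix(a, b), similarity_matrix(b, a).T)

    def test_no_common_labels_scores_zero(self):
        a = build_encoded("a", [L_C_CHAIN, L_C_CHAIN], {(0, 1): ("rigid", 1)})
        b = build_encoded("b", [L_N, L_N], {(0, 1): ("rigid", 2)})
        assert fap_oa_similarity(a, b) == 0.0

    def test_all_rigid_pair_uses_rigid_only(self):
        # weight shifts entirely to the rigid sub-tree for all-rigid molecules
        a = build_encoded("a", [L_C_RING, L_C_RING], {(0, 1): ("rigid", 1)})
        b = build_encoded("b", [L_C_RING, L_C_RING], {(0, 1): ("rigid", 1)})
        assert fap_oa_similarity(a, b) == 1.0

    def test_size_mismatch_penalized(self, rng):
        small = random_synthetic_molecule(rng, n_atoms=3)
        grown_payloads = dict(small.payloads)
        labels = list(small.labels) + [L_N, L_O]
        for i in range(3):
            grown_payloads[(i, 3)] = ("rigid", 4)
            grown_payloads[(i, 4)] = ("rigid", 5)
        grown_payloads[(3, 4)] = ("rigid", 1)
        big = build_encoded("big", labels, grown_payloads)
        score = fap_oa_similarity(small.encode(), big)
        assert score <= 3.0 / 5.0 + 1e-12

    def test_sum_variant_equals_matrix_mean(self, rng):
        a = random_encoded_molecule(rng)
        b = random_encoded_molecule(rng)
        s = similarity_matrix(a, b)
        assert fap_sum_similarity(a, b) == pytest.approx(float(s.mean()))

    def test_sum_variant_self_not_necessarily_one(self, rng):
        m = random_encoded_molecule(rng, n_atoms=6)
        assert fap_sum_similarity(m, m) <= 1.0

    def test_bounded_on_random_pairs(self, rng):
        for _ in range(50):
            a = random_encoded_molecule(rng)
            b = random_encoded_molecule(rng)
            for val in (fap_oa_similarity(a, b), fap_sum_similarity(a, b)):
                assert 0.0 <= val <= 1.0

    def test_monotone_under_mean_shift(self, rng):
        from fapscreen.fixtures import shift_family

        family = shift_family(rng, n_atoms=7)
        ref = family[0]
        scores = [fap_oa_similarity(ref, shifted) for shifted in family]
        assert scores[0] == pytest.approx(1.0)
        assert all(s1 >= s2 - 1e-12 for s1, s2 in zip(scores, scores[1:]))

    def test_literal_sum_range(self, rng):
        cfg = SimConfig(w_rigid=1.0, w_flex=1.0, literal_sum=True)
        a = random_encoded_molecule(rng)
        assert fap_oa_similarity(a, a, cfg) == pytest.approx(2.0)


class TestScreen:
    def test_query_in_library_ranks_first(self, rng):
        mols = [random_encoded_molecule(rng, name=f"m{i}") for i in range(5)]
        ranking = screen(mols[2], mols)
        assert ranking.iloc[0]["name"] == "m2"
        assert ranking.iloc[0]["score"] == 1.0

    def test_identical_copies_tie(self, rng):
        m = random_encoded_molecule(rng, name="m")
        ranking = screen(m, [m, m, m])
        assert np.all(ranking["score"].to_numpy() == 1.0)

    def test_permutation_invariant_scores(self, rng):
        mols = [random_encoded_molecule(rng, name=f"m{i}") for i in range(6)]
        query = random_encoded_molecule(rng, name="q")
        r1 = screen(query, mols).set_index("name")["score"]
        r2 = screen(query, mols[::-1]).set_index("name")["score"]
        assert (r1.sort_index() == r2.sort_index()).all()
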