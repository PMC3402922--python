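"""Base aligner: enumeration, candidates, support matrix, scores, extraction."""

import numpy as np
import pytest

from compalign import (
    IdentitySimilarity,
    NetworkError,
    ReactionNetwork,
    UniformSimilarity,
    align,
    build_support,
    candidate_mappings,
    enumerate_subnetworks,
    extract_alignment,
    extract_alignment_bruteforce,
    iterate_scores,
    mds_compress,
)
from compalign.aligner import CandidateMapping, Subnetwork

from conftest import make_path


def path3():
    return ReactionNetwork(edges=[("a", "b"), ("b", "c")])


class TestEnumerateSubnetworks:
    @pytest.mark.parametrize("k,expected", [(1, 3), (2, 5), (3, 6)])
    def test_path3_counts(self, k, expected):
        subs = enumerate_subnetworks(path3(), k)
        assert len(subs) == expected

    def test_connectedness_required(self):
        net = ReactionNetwork(edges=[("a", "b"), ("c", "d")])
        subs = {s.nodes for s in enumerate_subnetworks(net, 2)}
        assert ("a", "b") in subs and ("a", "c") not in subs

    def test_deterministic_order(self):
        a = [s.nodes for s in enumerate_subnetworks(path3(), 3)]
        b = [s.nodes for s in enumerate_subnetworks(path3(), 3)]
        assert a == b == sorted(a, key=lambda t: (len(t), t))

    def test_k_below_one_rejected(self):
        with pytest.raises(NetworkError):
            enumerate_subnetworks(path3(), 0)


class TestCandidateMappings:
    def test_uncompressed_toy_gives_20(self, toy):
        p, pbar, sim = toy
        cands = candidate_mappings(
            enumerate_subnetworks(p, 1),
            enumerate_subnetworks(pbar, 1, side="second"),
            sim,
            net_left=p,
            net_right=pbar,
        )
        assert len(cands) == 20

    def test_compressed_toy_gives_6(self, toy):
        p, pbar, sim = toy
        cp = mds_compress(p, 1).levels[1]
        cq = mds_compress(pbar, 1).levels[1]
        cands = candidate_mappings(
            enumerate_subnetworks(cp, 1),
            enumerate_subnetworks(cq, 1, side="second"),
            sim,
            net_left=cp,
            net_right=cq,
        )
        assert len(cands) == 6

    def test_uniform_similarity_gives_equal_homologies(self, toy):
        p, pbar, _ = toy
        cands = candidate_mappings(
            enumerate_subnetworks(p, 2),
            enumerate_subnetworks(pbar, 2, side="second"),
            UniformSimilarity(),
            net_left=p,
            net_right=pbar,
        )
        assert len({c.homology for c in cands}) == 1

    def test_one_to_many_constraint(self, toy):
        p, pbar, sim = toy
        cands = candidate_mappings(
            enumerate_subnetworks(p, 2),
            enumerate_subnetworks(pbar, 2, side="second"),
            sim,
            net_left=p,
            net_right=pbar,
        )
        assert all(min(len(c.left), len(c.right)) == 1 for c in cands)

    def test_missing_similarity_named(self, toy):
        p, pbar, _ = toy
        from compalign import DictSimilarity

        with pytest.raises(KeyError, match="a"):
            candidate_mappings(
                enumerate_subnetworks(p, 1),
                enumerate_subnetworks(pbar, 1, side="second"),
                DictSimilarity({}),
                net_left=p,
                net_right=pbar,
            )


class TestBuildSupport:
    def test_toy_bb_column_has_five_fifths(self, toy):
        p, pbar, sim = toy
        cands = candidate_mappings(
            enumerate_subnetworks(p, 1),
            enumerate_subnetworks(pbar, 1, side="second"),
            sim,
            net_left=p,
            net_right=pbar,
        )
        support = build_support(cands, p, pbar)
        j = next(
            i for i, c in enumerate(cands) if c.key == (("b",), ("b'",))
        )
        col = support.matrix[:, j].toarray().ravel()
        nonzero = {cands[i].key: col[i] for i in np.nonzero(col)[0]}
        assert nonzero == {
            (("a",), ("a'",)): pytest.approx(0.2),
            (("c",), ("c'",)): pytest.approx(0.2),
            (("c",), ("d'",)): pytest.approx(0.2),
            (("d",), ("c'",)): pytest.approx(0.2),
            (("d",), ("d'",)): pytest.approx(0.2),
        }

    def test_two_isolated_nodes_give_self_support(self):
        left = ReactionNetwork(nodes=["x"])
        right = ReactionNetwork(nodes=["y"])
        cands = candidate_mappings(
            enumerate_subnetworks(left, 1),
            enumerate_subnetworks(right, 1, side="second"),
            UniformSimilarity(),
            net_left=left,
            net_right=right,
        )
        support = build_support(cands, left, right)
        assert support.matrix.toarray().tolist() == [[1.0]]

    def test_columns_sum_to_one(self, toy):
        p, pbar, sim = toy
        cands = candidate_mappings(
            enumerate_subnetworks(p, 2),
            enumerate_subnetworks(pbar, 2, side="second"),
            sim,
            net_left=p,
            net_right=pbar,
        )
        support = build_support(cands, p, pbar)
        sums = np.asarray(support.matrix.sum(axis=0)).ravel()
        assert np.allclose(sums, 1.0)

    def test_dimension_and_memory_estimate(self, toy):
        p, pbar, sim = toy
        cands = candidate_mappings(
            enumerate_subnetworks(p, 1),
            enumerate_subnetworks(pbar, 1, side="second"),
            sim,
            net_left=p,
            net_right=pbar,
        )
        support = build_support(cands, p, pbar)
        assert support.dimension == 20
        assert support.memory_estimate == 400


class TestIterateScores:
    def _support(self, toy):
        p, pbar, sim = toy
        cp = mds_compress(p, 1).levels[1]
        cq = mds_compress(pbar, 1).levels[1]
        cands = candidate_mappings(
            enumerate_subnetworks(cp, 1),
            enumerate_subnetworks(cq, 1, side="second"),
            sim,
            net_left=cp,
            net_right=cq,
        )
        return build_support(cands, cp, cq)

    def test_gamma_zero_returns_homology(self, toy):
        support = self._support(toy)
        h = np.array([c.homology for c in support.candidates])
        out = iterate_scores(support, h, gamma=0.0)
        assert np.allclose(out, h / h.sum())

    def test_identity_support_is_fixed_point(self, toy):
        import scipy.sparse as sp

        support = self._support(toy)
        support.matrix = sp.identity(support.dimension, format="csr")
        h = np.array([c.homology for c in support.candidates])
        out = iterate_scores(support, h, gamma=0.7)
        assert np.allclose(out, h / h.sum())

    def test_bidirectional_support_dominates(self, toy):
        """With uniform homology the doubly supported supernode pair wins."""
        support = self._support(toy)
        h = np.ones(support.dimension)
        out = iterate_scores(support, h, gamma=0.7, max_iter=100)
        scores = {c.key: s for c, s in zip(support.candidates, out)}
        top = scores[(("a+b",), ("a'+b'",))]
        for key, val in scores.items():
            if key != (("a+b",), ("a'+b'",)):
                assert top > val

    def test_sum_preserved(self, toy):
        support = self._support(toy)
        h = np.array([c.homology for c in support.candidates])
        out = iterate_scores(support, h, gamma=0.7)
        assert out.sum() == pytest.approx(1.0)


def _cand(left, right, h=0.5):
    return CandidateMapping(
        left=Subnetwork("first", tuple(left)),
        right=Subnetwork("second", tuple(right)),
        homology=h,
    )


class TestExtractAlignment:
    def test_conflicting_candidates_keep_higher_score(self):
        cands = [_cand(["b"], ["x"]), _cand(["b"], ["y"])]
        res = extract_alignment(cands, np.array([0.6, 0.4]))
        assert [m.right for m in res.mappings] == [("x",)]

    def test_disjoint_candidates_all_selected(self):
        cands = [_cand(["a"], ["x"]), _cand(["b"], ["y"]), _cand(["c"], ["z"])]
        res = extract_alignment(cands, np.array([0.2, 0.5, 0.3]))
        assert len(res.mappings) == 3

    def test_result_is_maximal(self):
        cands = [_cand(["a"], ["x"]), _cand(["a"], ["y"]), _cand(["b"], ["y"])]
        res = extract_alignment(cands, np.array([0.5, 0.4, 0.3]))
        chosen_l = {v for m in res.mappings for v in m.left}
        chosen_r = {v for m in res.mappings for v in m.right}
        for c in cands:
            selected = any(
                m.left == c.left.nodes and m.right == c.right.nodes
                for m in res.mappings
            )
            if not selected:
                assert not (
                    chosen_l.isdisjoint(c.left.nodes)
                    and chosen_r.isdisjoint(c.right.nodes)
                )

    def test_identity_alignment_on_identical_paths(self):
        left = make_path(3, "x")
        right = make_path(3, "x")
        res = align(left, right, 1, sim=IdentitySimilarity())
        assert sorted((m.left[0], m.right[0]) for m in res.mappings) == [
            ("x0", "x0"),
            ("x1", "x1"),
            ("x2", "x2"),
        ]

    def test_greedy_matches_bruteforce_on_small_instances(self):
        for n in (2, 3):
            left = make_path(n, "u")
            right = make_path(n, "u")
            res = align(left, right, 1, sim=IdentitySimilarity())
            brute = extract_alignment_bruteforce(res.candidates, res.scores)
            assert sum(m.score for m in res.mappings) == pytest.approx(
                sum(m.score for m in brute.mappings)
            )


class TestAlign:
    def test_compressed_toy_contains_ab_mapping(self, toy):
        p, pbar, sim = toy
        cp = mds_compress(p, 1).levels[1]
        cq = mds_compress(pbar, 1).levels[1]
        res = align(cp, cq, 1, sim=sim)
        keys = {(m.left, m.right) for m in res.mappings}
        assert (("a+b",), ("a'+b'",)) in keys
        assert len(res.mappings) == 2
        assert res.support_dimension == 6

    def test_empty_network_gives_empty_result(self, toy):
        p, _, sim = toy
        res = align(ReactionNetwork(), p, 1, sim=sim)
        assert res.mappings == []

    def test_self_alignment_recovers_identity(self):
        net = ReactionNetwork(
            edges=[("a", "b"), ("a", "c"), ("c", "d"), ("b", "e"), ("e", "f")]
        )
        res = align(net, net, 1, sim=IdentitySimilarity())
        assert len(res.mappings) == net.n_nodes
        assert all(m.left == m.right for m in res.mappings)
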