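"""Q score, correspondences and average-linkage clustering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from conftest import toy_interface
from xtalface.clustering import (average_linkage_cluster,
                                 build_correspondence, q_or_none, q_score)
from xtalface.config import PipelineConfig
from xtalface.structure_model import DomainInstance


def _hmm_domain(entry, chain, n=40, coverage=1.0, pfam="PF1"):
    mapped = int(round(n * coverage))
    return DomainInstance(f"{entry}_{chain}", pfam, "F1", None, chain,
                          [(1, n)], {i: i for i in range(1, mapped + 1)},
                          n)


class TestCorrespondence:
    def test_identical_sequences_identity_kind(self):
        a = toy_interface({(1, 5)}, entry_id="E1")
        b = toy_interface({(1, 5)}, entry_id="E2")
        corr = build_correspondence(a, b)
        assert corr.kind == "identity"
        assert corr.covered_fraction == 1.0

    def test_homologs_use_hmm_positions(self):
        a = toy_interface({(1, 5)}, seq_a="A" * 40, entry_id="E1")
        b = toy_interface({(1, 5)}, seq_a="C" * 40, entry_id="E2")
        idx = {("E1", "A"): [_hmm_domain("E1", "A")],
               ("E1", "B"): [_hmm_domain("E1", "B")],
               ("E2", "A"): [_hmm_domain("E2", "A", coverage=0.95)],
               ("E2", "B"): [_hmm_domain("E2", "B", coverage=0.95)]}
        corr = build_correspondence(a, b, idx)
        assert corr.kind == "hmm"
        assert corr.covered_fraction >= 0.9

    def test_low_coverage_gives_no_correspondence(self):
        """60% model coverage on one side: the pair is incomparable."""
        a = toy_interface({(1, 5)}, seq_a="A" * 40, entry_id="E1")
        b = toy_interface({(1, 5)}, seq_a="C" * 40, entry_id="E2")
        idx = {("E1", "A"): [_hmm_domain("E1", "A")],
               ("E1", "B"): [_hmm_domain("E1", "B")],
               ("E2", "A"): [_hmm_domain("E2", "A", coverage=0.60)],
               ("E2", "B"): [_hmm_domain("E2", "B", coverage=0.60)]}
        assert build_correspondence(a, b, idx) is None
        assert q_or_none(a, b, idx) is None

    def test_incompatible_family_keys_raise(self):
        a = toy_interface({(1, 5)}, arch="(F)")
        b = toy_interface({(1, 5)}, arch="(G)")
        with pytest.raises(ValueError, match="incompatible"):
            build_correspondence(a, b)


class TestQScore:
    def test_identical_copy_scores_one(self):
        a = toy_interface({(1, 5), (2, 6), (9, 4)})
        b = toy_interface({(1, 5), (2, 6), (9, 4)}, entry_id="COPY")
        assert q_score(a, b, build_correspondence(a, b)) == 1.0

    def test_disjoint_contacts_score_zero(self):
        a = toy_interface({(1, 5), (2, 6)})
        b = toy_interface({(11, 25), (12, 26)}, entry_id="E2")
        assert q_score(a, b, build_correspondence(a, b)) == 0.0

    def test_partial_overlap_is_jaccard(self):
        a = toy_interface({(1, 5), (2, 6)})
        b = toy_interface({(1, 5), (3, 7)}, entry_id="E2")
        assert q_score(a, b, build_correspondence(a, b)) == \
            pytest.approx(1.0 / 3.0)

    def test_symmetric(self):
        a = toy_interface({(1, 5), (2, 6), (3, 9)})
        b = toy_interface({(1, 5), (3, 7)}, entry_id="E2")
        assert q_score(a, b, build_correspondence(a, b)) == \
            q_score(b, a, build_correspondence(b, a))

    def test_chain_relabel_invariance(self):
        """Homodimer side labels are arbitrary: flipping the sides of one
        interface must not change Q (max over both orderings)."""
        a = toy_interface({(1, 5), (2, 6)})
        b = toy_interface({(5, 1), (6, 2)}, entry_id="E2")
        assert q_score(a, b, build_correspondence(a, b)) == 1.0

    @given(st.sets(st.tuples(st.integers(1, 30), st.integers(1, 30)),
                   min_size=1, max_size=25),
           st.sets(st.tuples(st.integers(1, 30), st.integers(1, 30)),
                   min_size=1, max_size=25))
    @settings(max_examples=60, deadline=None)
    def test_bounded_and_self_identical(self, pa, pb):
        a = toy_interface(pa)
        b = toy_interface(pb, entry_id="E2")
        q = q_score(a, b, build_correspondence(a, b))
        assert 0.0 <= q <= 1.0
        assert q_score(a, a, build_correspondence(a, a)) == 1.0


def scipy_reference_partition(q: np.ndarray, threshold: float) -> list:
    """Independent dendrogram oracle: scipy average linkage on 1-Q, cut
    at distance 1-threshold."""
    d = squareform(1.0 - q, checks=False)
    z = linkage(d, method="average")
    labels = fcluster(z, t=1.0 - threshold, criterion="distance")
    groups = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    return sorted(sorted(g) for g in groups.values())


class TestAverageLinkage:
    def test_all_similar_single_cluster(self):
        q = np.ones((4, 4))
        assert average_linkage_cluster(q) == [[0, 1, 2, 3]]

    def test_all_dissimilar_singletons(self):
        q = np.eye(5)
        assert average_linkage_cluster(q) == [[0], [1], [2], [3], [4]]

    def test_hand_computed_three_item_dendrogram(self):
        """Q(1,2)=0.8, Q(1,3)=Q(2,3)=0.1: {1,2} forms, then the merge
        with {3} averages 0.1 < 0.30 and is refused."""
        q = np.array([[1.0, 0.8, 0.1],
                      [0.8, 1.0, 0.1],
                      [0.1, 0.1, 1.0]])
        assert average_linkage_cluster(q, threshold=0.30) == [[0, 1], [2]]

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            n = int(rng.integers(2, 50))
            q = rng.random((n, n))
            q = (q + q.T) / 2
            np.fill_diagonal(q, 1.0)
            mine = sorted(sorted(c) for c in
                          average_linkage_cluster(q, threshold=0.30))
            assert mine == scipy_reference_partition(q, 0.30)

    def test_order_permutation_invariance(self):
        rng = np.random.default_rng(5)
        n = 12
        q = rng.random((n, n))
        q = (q + q.T) / 2
        np.fill_diagonal(q, 1.0)
        base = sorted(sorted(c) for c in average_linkage_cluster(q))
        perm = rng.permutation(n)
        qp = q[np.ix_(perm, perm)]
        permuted = sorted(sorted(perm[c].tolist()) for c in
                          average_linkage_cluster(qp))
        assert base == permuted


class TestClusterAnnotation:
    def test_benchmark_counts(self, benchmark_result):
        """The conserved dimer spans k forms, k entries, k proteins."""
        res, truth, _ = benchmark_result
        top = res.chain_clusters[0]
        exp = truth["expected_top_cluster"]
        assert top.n_crystal_forms == exp["n_crystal_forms"]
        assert top.n_entries == exp["n_entries"]
        assert top.n_uniprots == exp["n_entries"]
        assert 0.0 < top.min_seq_identity < 1.0
        assert top.q_avg_internal >= res.config.q_cluster

    def test_singleton_convention(self, benchmark_result):
        res, _, _ = benchmark_result
        singles = [c for c in res.chain_clusters if len(c.members) == 1]
        assert singles
        for c in singles:
            assert c.n_crystal_forms == c.n_entries == 1
            assert c.q_avg_internal == 1.0

    def test_assembly_fraction_full_for_deposited_dimer(self,
                                                        benchmark_result):
        res, _, _ = benchmark_result
        top = res.chain_clusters[0]
        assert top.author_fraction == 1.0
        assert top.pisa_fraction == 1.0
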