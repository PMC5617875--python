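"""Cluster-based segmentation DP: scoring functions, solvers, stitching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_cluster_score
from simseg import (
    ClusterModel,
    ScoringModel,
    build_position_scores,
    chunk_and_segment,
    objective_score,
    phi_transform,
    segment,
    segment_naive,
)


def random_scoring(rng, n, K, function="icor", mode="nu", M=None, M0=None):
    sm = ScoringModel(
        function=function,
        epsilon=float(rng.choice([1.0, 2.0, 3.0])),
        nu=float(rng.uniform(0.5, 3.0)),
        M=float(rng.uniform(0, 2)) if M is None else M,
        M0=(float(rng.uniform(0, 2)) if M0 is None else M0),
        nuisance_mode=mode,
    )
    sm.position_scores = rng.uniform(-1, 1, size=(n, K + 1))
    if mode == "compensate":
        sm.position_scores[:, 0] = 0.0
    return sm


class TestPhiTransform:
    def test_identity_at_epsilon_one(self):
        assert phi_transform(0.7, 1.0) == pytest.approx(0.7)

    def test_cube_of_negative(self):
        assert phi_transform(-0.5, 3.0) == pytest.approx(-0.125)

    def test_limit_behaviour(self):
        # large epsilon: fixed points +-1, interior collapses to 0
        assert phi_transform(1.0, 200.0) == pytest.approx(1.0)
        assert phi_transform(-1.0, 200.0) == pytest.approx(-1.0)
        assert phi_transform(0.5, 200.0) == pytest.approx(0.0, abs=1e-12)

    def test_domain_check(self):
        with pytest.raises(ValueError):
            phi_transform(1.5, 2.0)
        with pytest.raises(ValueError):
            phi_transform(0.5, 0.5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        t=st.floats(-1, 1),
        s=st.floats(-1, 1),
        eps=st.sampled_from([1.0, 2.0, 3.0, 5.0, 10.0]),
    )
    def test_odd_and_monotone(self, t, s, eps):
        assert phi_transform(-t, eps) == pytest.approx(-phi_transform(t, eps))
        lo, hi = sorted((t, s))
        assert phi_transform(lo, eps) <= phi_transform(hi, eps) + 1e-12


class TestPositionScores:
    def make_model(self, labels, pos_sim=None, cc_sim=None, K=2):
        labels = np.asarray(labels)
        return ClusterModel(
            labels=labels,
            centers=np.zeros((K, 3)),
            K=K,
            pos_cluster_sim=pos_sim,
            cluster_cluster_sim=cc_sim,
        )

    def test_ccls_indicator(self):
        model = self.make_model([1, 1, 2])
        sm = build_position_scores(model, ScoringModel(function="ccls"))
        np.testing.assert_allclose(
            sm.position_scores[:, 1:], [[1, -1], [1, -1], [-1, 1]]
        )

    def test_icor_epsilon_one_is_identity(self):
        rng = np.random.default_rng(0)
        pos_sim = rng.uniform(-1, 1, size=(5, 2))
        model = self.make_model([1, 1, 2, 2, 0], pos_sim=pos_sim)
        sm = build_position_scores(model, ScoringModel(function="icor", epsilon=1.0))
        np.testing.assert_allclose(sm.position_scores[:, 1:], pos_sim)

    def test_ccor_epsilon_two_signed_square(self):
        cc = np.array([[1.0, -0.6], [-0.6, 1.0]])
        model = self.make_model([1, 2], cc_sim=cc)
        sm = build_position_scores(model, ScoringModel(function="ccor", epsilon=2.0))
        expected = np.sign(cc) * cc**2
        np.testing.assert_allclose(sm.position_scores[0, 1:], expected[0])
        np.testing.assert_allclose(sm.position_scores[1, 1:], expected[1])

    def test_nu_mode_nuisance_column(self):
        model = self.make_model([1, 0, 2])
        sm = build_position_scores(
            model, ScoringModel(function="ccls", nu=2.5, nuisance_mode="nu")
        )
        np.testing.assert_allclose(sm.position_scores[:, 0], [-2.5, 2.5, -2.5])


class TestSegmentDP:
    def test_two_blocks_small_penalty(self):
        # labels [1,1,2,2,2], match/mismatch scoring, M = 0.5:
        # two segments, total = M + (2 - M) + (3 - M) = 4.5
        model = ClusterModel(labels=np.array([1, 1, 2, 2, 2]), centers=np.zeros((2, 3)), K=2)
        sm = build_position_scores(model, ScoringModel(function="ccls", M=0.5))
        seg = segment(sm)
        assert seg.breakpoints == [2]
        assert [s.cluster for s in seg.segments] == [1, 2]
        assert seg.score == pytest.approx(4.5)

    def test_two_blocks_large_penalty_single_segment(self):
        # nu parametrization: the nuisance column scores -nu for labelled
        # positions, so the best single segment is the majority cluster.
        # (Under M-compensation a lone nuisance segment would net +M instead.)
        model = ClusterModel(labels=np.array([1, 1, 2, 2, 2]), centers=np.zeros((2, 3)), K=2)
        sm = build_position_scores(
            model, ScoringModel(function="ccls", M=10.0, nuisance_mode="nu")
        )
        seg = segment(sm)
        assert len(seg) == 1
        assert seg.segments[0].cluster == 2
        assert seg.score == pytest.approx(1.0)  # 10 + (3 - 2) - 10

    def test_uniform_labels_single_segment(self):
        model = ClusterModel(labels=np.array([1, 1, 1, 1]), centers=np.zeros((2, 3)), K=2)
        sm = build_position_scores(model, ScoringModel(function="ccls", M=0.5))
        seg = segment(sm)
        assert len(seg) == 1 and seg.segments[0].cluster == 1

    def test_empty_and_all_nuisance(self):
        sm = ScoringModel(function="ccls", nuisance_mode="nu", nu=2.0, M=1.0)
        sm.position_scores = np.zeros((0, 3))
        assert len(segment(sm, 0)) == 0
        model = ClusterModel(labels=np.zeros(4, dtype=int), centers=np.zeros((2, 3)), K=2)
        sm = build_position_scores(
            model, ScoringModel(function="ccls", nu=2.0, nuisance_mode="nu", M=1.0)
        )
        seg = segment(sm)
        assert len(seg) == 1 and seg.segments[0].cluster == 0

    @pytest.mark.parametrize("function", ["ccls", "icor", "ccor"])
    @pytest.mark.parametrize("mode", ["compensate", "nu"])
    def test_fast_equals_naive_and_oracle(self, function, mode):
        seed = {"ccls": 1, "icor": 2, "ccor": 3}[function] * 10 + len(mode)
        rng = np.random.default_rng(seed)
        for _ in range(8):
            n = int(rng.integers(2, 9))
            K = int(rng.integers(2, 4))
            sm = random_scoring(rng, n, K, function=function, mode=mode)
            fast, naive = segment(sm), segment_naive(sm)
            assert fast.score == pytest.approx(naive.score, abs=1e-9)
            assert fast.breakpoints == naive.breakpoints
            assert fast.clusters == naive.clusters
            assert fast.score == pytest.approx(brute_cluster_score(sm, n), abs=1e-9)
            assert objective_score(sm, fast) == pytest.approx(fast.score, abs=1e-9)

    def test_consecutive_segments_differ_in_cluster(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            sm = random_scoring(rng, 40, 3)
            seg = segment(sm)
            cl = seg.clusters
            assert all(cl[i] != cl[i + 1] for i in range(len(cl) - 1))
            assert seg.segments[0].start == 1 and seg.segments[-1].end == 40

    def test_cluster_relabeling_leaves_breakpoints_and_score(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            K = 3
            sm = random_scoring(rng, 30, K)
            perm = rng.permutation(K) + 1
            sm2 = ScoringModel(
                function=sm.function, epsilon=sm.epsilon, nu=sm.nu,
                M=sm.M, M0=sm.M0, nuisance_mode=sm.nuisance_mode,
            )
            # column perm[a] of sm2 = column a of sm (consistent relabeling)
            sm2.position_scores = np.empty_like(sm.position_scores)
            sm2.position_scores[:, 0] = sm.position_scores[:, 0]
            for a in range(1, K + 1):
                sm2.position_scores[:, perm[a - 1]] = sm.position_scores[:, a]
            s1, s2 = segment(sm), segment(sm2)
            assert s1.score == pytest.approx(s2.score, abs=1e-9)
            assert s1.breakpoints == s2.breakpoints
            for a, b in zip(s1.segments, s2.segments):
                if a.cluster == 0:
                    assert b.cluster == 0
                else:
                    assert b.cluster == perm[a.cluster - 1]

    def test_prefix_identity_exact_on_integers(self):
        rng = np.random.default_rng(13)
        n, K = 200, 4
        w = rng.integers(-3, 4, size=(n, K + 1)).astype(float)
        cs = np.zeros((n + 1, K + 1))
        np.cumsum(w, axis=0, out=cs[1:])
        for i in range(1, n + 1):
            direct = w[i - 1 :].cumsum(axis=0)  # s(i, k, a) for k = i..n
            via_prefix = cs[i:] - cs[i - 1]
            assert np.array_equal(direct, via_prefix)

    def test_scaled_scores_interval_count_nonincreasing_in_M(self):
        rng = np.random.default_rng(14)
        for _ in range(6):
            n, K = 30, 3
            sm = ScoringModel(function="icor", nuisance_mode="nu", M=0.0, M0=None)
            sm.position_scores = rng.uniform(0, 1, size=(n, K + 1))
            counts = []
            for M in (0, 0.5, 1, 2, 5, 10):
                smm = ScoringModel(function="icor", nuisance_mode="nu", M=float(M))
                smm.position_scores = sm.position_scores
                counts.append(len(segment(smm)))
            assert counts == sorted(counts, reverse=True)


class TestChunking:
    def blocky_scoring(self, rng, n, K, block=50):
        sm = ScoringModel(function="icor", M=3.0, nuisance_mode="nu", nu=2.0)
        labels = np.repeat(rng.integers(1, K + 1, size=n // block + 1), block)[:n]
        w = np.full((n, K + 1), -0.5)
        w[:, 0] = -2.0
        w[np.arange(n), labels] = 0.9 + rng.normal(0, 0.02, n).clip(-0.1, 0.1)
        sm.position_scores = np.clip(w, -1, 1)
        return sm

    def test_single_chunk_identical_to_segment(self):
        rng = np.random.default_rng(15)
        sm = self.blocky_scoring(rng, 300, 3)
        whole = segment(sm)
        ch = chunk_and_segment(sm, chunk_size=1000, overlap=100)
        assert ch.breakpoints == whole.breakpoints and ch.clusters == whole.clusters

    def test_stitching_reproduces_whole_run(self):
        rng = np.random.default_rng(16)
        sm = self.blocky_scoring(rng, 2000, 4)
        whole = segment(sm)
        ch = chunk_and_segment(sm, chunk_size=700, overlap=200)
        assert ch.breakpoints == whole.breakpoints
        assert ch.clusters == whole.clusters
        assert ch.score == pytest.approx(whole.score, rel=1e-9)

    def test_each_position_owned_once(self):
        rng = np.random.default_rng(17)
        sm = self.blocky_scoring(rng, 900, 3)
        ch = chunk_and_segment(sm, chunk_size=400, overlap=100)
        assert ch.segments[0].start == 1 and ch.segments[-1].end == 900
        for a, b in zip(ch.segments, ch.segments[1:]):
            assert b.start == a.end + 1

    def test_invalid_chunk_geometry(self):
        sm = ScoringModel(function="icor")
        sm.position_scores = np.zeros((10, 3))
        with pytest.raises(ValueError):
            chunk_and_segment(sm, chunk_size=100, overlap=100)
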