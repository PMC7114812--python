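import numpy as np
import pytest

from tadshift.hic_io import BinInterval, ContactMatrix, TAD, TADSet, ValidationError
from tadshift.split_merge import (
    SplitScoreRecord,
    TADMatch,
    classify_splits_mergers,
    corner_split_ratio,
    ihs_score,
    lms_score,
    match_tads,
    scc_score,
    zscore_scores,
)
from tadshift.tad_caller import (
    BoundaryDensity,
    BoundaryPairDensity,
    CallerConfig,
    CallerState,
    caller_state,
)


def make_state(n, lefts, rights, pairs, min_tad_size=10):
    """Hand-built caller state with unit-mass atoms at given positions."""
    fl = np.zeros(n)
    for b in lefts:
        fl[b] = 1.0
    fl /= fl.sum()
    fr = np.zeros(n)
    for b in rights:
        fr[b] = 1.0
    fr /= fr.sum()
    grid = np.zeros((n, n))
    for (i, j), w in pairs.items():
        grid[i, j] = w
    grid /= grid.sum()
    return CallerState(
        n=n,
        straps=[],
        profile=None,
        f_left=BoundaryDensity(fl, "left"),
        f_right=BoundaryDensity(fr, "right"),
        f_pair=BoundaryPairDensity(grid),
        config=CallerConfig(min_tad_size=min_tad_size),
    )


class TestMatchTads:
    def test_self_match_single_chain(self):
        # a lone corner cluster at (0, 99): the reference TAD matches
        # itself in one step
        st = make_state(100, [0], [99], {(0, 99): 1.0})
        (m,) = match_tads([TAD(BinInterval(0, 100))], st)
        assert [(c.left, c.right) for c in m.chain] == [(0, 100)]
        assert m.chain_probability == pytest.approx(1.0)

    def test_chain_matches_exhaustive_enumeration(self):
        # sharp atoms at boundaries {0, 50, 100} (edge-bin convention:
        # shared edge 49): reference [0, 100) splits into [0, 50) +
        # [50, 100); the greedy chain and its probability coincide with
        # brute-force enumeration of all boundary chains inside [0, 100)
        n = 100
        pairs = {(0, 49): 2.0, (49, 99): 2.0}
        st = make_state(n, [0, 49], [49, 99], pairs)
        (m,) = match_tads([TAD(BinInterval(0, 100))], st)
        assert [(c.left, c.right) for c in m.chain] == [(0, 50), (50, 100)]

        fl, fr, fp = st.f_left.density, st.f_right.density, st.f_pair.grid

        def chain_prob(edges):
            p, l0 = 1.0, 0
            for e in edges:
                p *= fl[l0] * fr[e] * fp[l0, e]
                l0 = e
            return p

        # all admissible chains over the candidate edges {49, 99}
        best = max(chain_prob(ch) for ch in ([99], [49, 99]))
        assert m.chain_probability == pytest.approx(best)
        assert best > 0

    def test_tie_breaks_toward_smaller_gamma(self):
        n = 60
        pairs = {(0, 20): 1.0, (0, 40): 1.0, (21, 59): 1.0, (41, 59): 1.0}
        st = make_state(n, [0], [20, 40, 59], pairs, min_tad_size=5)
        (m,) = match_tads([TAD(BinInterval(0, 60))], st)
        assert m.chain[0].right - 1 == 20  # equal products: smaller wins

    def test_chain_tiles_reference_exactly(self):
        rng = np.random.default_rng(0)
        n = 120
        pairs = {
            (int(i), int(j)): float(w)
            for i, j, w in zip(
                rng.integers(0, 50, 20),
                rng.integers(60, 119, 20),
                rng.random(20) + 0.1,
            )
        }
        st = make_state(n, [0, 30], [59, 119], pairs)
        for iv in [BinInterval(0, 120), BinInterval(10, 100)]:
            (m,) = match_tads([TAD(iv)], st)
            assert m.chain[0].left == iv.left
            assert m.chain[-1].right == iv.right
            for a, b in zip(m.chain, m.chain[1:]):
                assert a.right == b.left

    def test_reference_outside_matrix_rejected(self):
        st = make_state(50, [0], [49], {(0, 49): 1.0})
        with pytest.raises(ValidationError):
            match_tads([TAD(BinInterval(10, 80))], st)


def toy_match():
    """Big TAD [0, 4) split into [0, 2) + [2, 4)."""
    return TADMatch(
        TAD(BinInterval(0, 4)),
        [BinInterval(0, 2), BinInterval(2, 4)],
        1.0,
    )


class TestCornerSplitRatio:
    def test_identical_conditions_zero(self):
        m = ContactMatrix(np.arange(16, dtype=float).reshape(4, 4) + 1)
        assert corner_split_ratio(m, m, toy_match()) == 0.0

    def test_hand_arithmetic_toy(self):
        m1 = ContactMatrix(np.full((4, 4), 4.0))  # ratio 4/4 = 1
        v2 = np.ones((4, 4))
        v2[:2, :2] = 4.0
        v2[2:, 2:] = 4.0  # chain squares 4, corners 1 -> ratio 1/4
        m2 = ContactMatrix(v2)
        assert corner_split_ratio(m1, m2, toy_match()) == pytest.approx(0.75)

    def test_symmetric_in_conditions(self):
        rng = np.random.default_rng(1)
        m1 = ContactMatrix(rng.random((4, 4)) + 0.5)
        m2 = ContactMatrix(rng.random((4, 4)) + 0.5)
        assert corner_split_ratio(m1, m2, toy_match()) == pytest.approx(
            corner_split_ratio(m2, m1, toy_match())
        )

    def test_whole_tad_chain_scores_zero(self):
        match = TADMatch(TAD(BinInterval(0, 4)), [BinInterval(0, 4)], 1.0)
        m = ContactMatrix(np.ones((4, 4)))
        assert corner_split_ratio(m, m, match) == 0.0

    def test_zero_sub_mean_rejected(self):
        v = np.ones((4, 4))
        v[:2, :2] = 0.0
        v[2:, 2:] = 0.0
        m = ContactMatrix(v)
        with pytest.raises(ValidationError):
            corner_split_ratio(m, m, toy_match())


class TestSimilarityScores:
    def test_identities(self):
        rng = np.random.default_rng(2)
        b = rng.poisson(3.0, (40, 40)).astype(float)
        b = np.triu(b) + np.triu(b, 1).T
        assert scc_score(b, b) == pytest.approx(1.0)
        assert lms_score(b, b) == pytest.approx(1.0, abs=1e-9)
        assert ihs_score(b, b) == pytest.approx(1.0)

    def test_scc_independent_blocks_near_zero(self):
        rng = np.random.default_rng(3)
        a = rng.random((100, 100))
        b = rng.random((100, 100))
        assert abs(scc_score(a, b)) < 0.1

    def test_scc_bounds(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            a = rng.poisson(2.0, (30, 30)).astype(float)
            b = a + rng.normal(0, 1.0, (30, 30))
            s = scc_score(a, np.abs(b))
            assert -1.0 <= s <= 1.0

    def test_scc_degenerate_rejected(self):
        a = np.ones((5, 5))
        with pytest.raises(ValidationError):
            scc_score(a, a)

    def test_lms_monotone_under_noise(self):
        rng = np.random.default_rng(5)
        base = rng.poisson(5.0, (60, 60)).astype(float)
        base = np.triu(base) + np.triu(base, 1).T
        light = np.abs(base + rng.normal(0, 0.5, base.shape))
        heavy = np.abs(base + rng.normal(0, 8.0, base.shape))
        assert lms_score(base, heavy) < lms_score(base, light)

    def test_lms_r_truncated(self):
        a = np.ones((5, 5)) + np.eye(5)
        assert 0.0 <= lms_score(a, a, r=50) <= 1.0

    def test_ihs_contrast_inversion(self):
        # two-level pattern and its negative: every hash bit flips
        rng = np.random.default_rng(6)
        a = np.where(rng.random((8, 8)) < 0.4, np.e - 1, 0.0)
        b = (np.e - 1) - a
        assert ihs_score(a, b) <= 0.5

    def test_ihs_constant_blocks(self):
        a = np.full((10, 10), 7.0)
        assert ihs_score(a, a) == pytest.approx(1.0)


class TestClassify:
    def _records(self, scores, n_subs):
        recs = []
        for s, k in zip(scores, n_subs):
            chain = (
                [BinInterval(0, 10)]
                if k == 1
                else [BinInterval(0, 5), BinInterval(5, 10)]
            )
            recs.append(
                SplitScoreRecord(
                    match=TADMatch(TAD(BinInterval(0, 10)), chain, 1.0),
                    csr=s,
                )
            )
        return recs

    def test_cutoff_and_chain_length(self):
        recs = self._records([0.1, 0.75, 0.9], [2, 2, 1])
        classify_splits_mergers(recs, cutoff=0.45)
        assert [r.called for r in recs] == [False, True, False]

    def test_split_sites_at_junctions(self):
        recs = self._records([0.75], [2])
        classify_splits_mergers(recs, cutoff=0.45)
        assert recs[0].split_sites_bp == [5 * 10_000]

    def test_counts_monotone_in_cutoff(self):
        rng = np.random.default_rng(7)
        recs = self._records(rng.random(50), [2] * 50)
        counts = []
        for cut in (0.1, 0.3, 0.5, 0.7, 0.9):
            classify_splits_mergers(recs, cutoff=cut)
            counts.append(sum(r.called for r in recs))
        assert counts == sorted(counts, reverse=True)


class TestZScore:
    def test_hand_example(self):
        out = zscore_scores([1.0, 2.0, 3.0])
        assert np.allclose(out, [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_constant_series_zeros(self):
        assert np.all(zscore_scores([2.0, 2.0, 2.0]) == 0)

    def test_normalization_identity(self):
        rng = np.random.default_rng(8)
        x = rng.random((5, 8))
        out = zscore_scores(x)
        assert np.allclose(out.mean(axis=-1), 0, atol=1e-12)
        assert np.allclose(out.std(axis=-1), 1, atol=1e-12)


class TestEndToEndMatch:
    def test_identical_conditions_yield_no_calls(self, five_tad_matrix):
        from tadshift.evaluation import compare_conditions

        m, _ = five_tad_matrix
        records, t1, t2 = compare_conditions(
            m, m, CallerConfig(seed=3), cutoff=0.45
        )
        assert t1.intervals() == t2.intervals()
        assert not any(r.called for r in records)
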