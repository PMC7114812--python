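import numpy as np
import pytest

from tadshift.hic_io import BinInterval, ContactMatrix, ValidationError
from tadshift.simulator import SimulationConfig, simulate_matrix
from tadshift.tad_caller import (
    BoundaryDensity,
    BoundaryPairDensity,
    CallerConfig,
    Strap,
    _gauss_ll,
    boundary_density_mcmc,
    boundary_pair_density,
    call_tads,
    caller_state,
    corner_boundary_profile,
    edge_probability_profile,
    estimate_all_straps,
    estimate_strap_edges,
    fit_gaussian_pair,
    tad_probability,
)
from tadshift.evaluation import boundary_recovery


class TestGaussianPair:
    def test_closed_form_mle(self):
        gp = fit_gaussian_pair([2, 4], [0, 0, 0, 4])
        assert gp.mu1 == pytest.approx(3)
        assert gp.sigma1 == pytest.approx(1)
        assert gp.mu2 == pytest.approx(1)
        assert gp.sigma2 == pytest.approx(np.sqrt(3))

    def test_identical_samples_symmetric(self):
        gp = fit_gaussian_pair([1.0, 2.0, 3.5], [1.0, 2.0, 3.5])
        assert gp.mu1 == gp.mu2
        assert gp.sigma1 == gp.sigma2

    def test_single_value_rejected(self):
        with pytest.raises(ValidationError):
            fit_gaussian_pair([1.0], [1.0, 2.0])


def exhaustive_strap(row, i, window):
    """Brute-force (L, R) maximizing the three-segment Gaussian LR."""
    n = len(row)
    a, b = max(0, i - window), min(n, i + window + 1)
    x = row[a:b]
    w = b - a
    s1 = np.r_[0, np.cumsum(x)]
    s2 = np.r_[0, np.cumsum(x * x)]
    best, best_lr = None, -np.inf
    for left in range(0, i - a + 1):
        for right in range(i - a, w):
            if right + 1 - left < 2:
                continue
            if 0 < left < 2 or 0 < w - (right + 1) < 2:
                continue
            lr = -_gauss_ll(s1, s2, 0, w)
            if left > 0:
                lr += _gauss_ll(s1, s2, 0, left)
            lr += _gauss_ll(s1, s2, left, right + 1)
            if right + 1 < w:
                lr += _gauss_ll(s1, s2, right + 1, w)
            if lr > best_lr:
                best_lr, best = float(lr), (a + left, a + right)
    return best


class TestStrapEdges:
    def test_clean_plateau(self, step_row_matrix):
        s = estimate_strap_edges(step_row_matrix, 50, window=50)
        assert (s.left_edge, s.right_edge) == (40, 60)
        assert s.valid

    def test_constant_row_invalid(self):
        m = ContactMatrix(np.full((50, 50), 2.0))
        s = estimate_strap_edges(m, 25, window=50)
        assert not s.valid

    def test_matches_exhaustive_on_clean_steps(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            n = 60
            lo, hi = int(rng.integers(5, 20)), int(rng.integers(35, 55))
            row = np.ones(n)
            row[lo:hi] = 4.0
            i = int(rng.integers(lo, hi))
            m = ContactMatrix(np.tile(row, (n, 1)))
            s = estimate_strap_edges(m, i, window=50)
            assert (s.left_edge, s.right_edge) == exhaustive_strap(row, i, 50)

    def test_near_exhaustive_under_noise(self):
        # fixed-seed noisy steps: binary segmentation within +-1 bin of
        # the brute-force optimum in the vast majority of cases
        rng = np.random.default_rng(3)
        close = 0
        trials = 30
        for _ in range(trials):
            n = 60
            lo, hi = int(rng.integers(5, 20)), int(rng.integers(35, 55))
            row = np.abs(np.ones(n) + rng.normal(0, 0.3, n))
            row[lo:hi] += 3.0
            i = int(rng.integers(lo, hi))
            m = ContactMatrix(np.tile(row, (n, 1)))
            s = estimate_strap_edges(m, i, window=50)
            oL, oR = exhaustive_strap(row, i, 50)
            if abs(s.left_edge - oL) <= 1 and abs(s.right_edge - oR) <= 1:
                close += 1
        assert close >= trials - 2

    def test_zero_row_invalid(self):
        v = np.ones((30, 30))
        v[4] = 0.0
        v[:, 4] = 0.0
        s = estimate_strap_edges(ContactMatrix(v), 4, window=10)
        assert not s.valid


class TestCornerProfile:
    def test_peaks_at_true_boundaries(self, five_tad_matrix):
        m, layout = five_tad_matrix
        prof = corner_boundary_profile(m, window=40)
        for b in (100, 200, 300, 400):
            # strong z in a small neighborhood of each boundary
            assert prof[b - 2 : b + 3].max() > 2.5

    def test_flat_matrix_has_no_strong_peaks(self):
        rng = np.random.default_rng(5)
        k = rng.poisson(1.0, size=(300, 300))
        m = ContactMatrix((np.triu(k) + np.triu(k, 1).T).astype(float))
        prof = corner_boundary_profile(m, window=40)
        assert prof.max() < 4.5  # consistent with a max of ~300 nulls


class TestEdgeProfile:
    def test_atom_peaks_and_sums(self):
        straps = [Strap(i, 30, 70, 1.0) for i in range(10)]
        prof = edge_probability_profile(straps, 100)
        assert prof.e_left.sum() == pytest.approx(1.0, abs=1e-9)
        assert prof.e_right.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.argmax(prof.e_left) == 30
        assert np.argmax(prof.e_right) == 70
        # symmetric around the atom
        assert prof.e_left[29] == pytest.approx(prof.e_left[31], rel=1e-6)

    def test_uniform_edges_flat(self):
        rng = np.random.default_rng(0)
        lefts = rng.integers(0, 200, 400)
        straps = [
            Strap(i, int(l), int(l) + 10, 1.0) for i, l in enumerate(lefts)
        ]
        prof = edge_probability_profile(straps, 200, bandwidth=None)
        inner = prof.e_left[20:180]
        assert inner.max() / inner.min() < 1.5

    def test_no_valid_straps_rejected(self):
        with pytest.raises(ValidationError):
            edge_probability_profile(
                [Strap(0, 0, 1, 0.0, valid=False)], 10
            )


class TestBoundaryMcmc:
    def test_constant_evidence_flat(self):
        bd = boundary_density_mcmc(np.full(40, 1 / 40), seed=1)
        assert bd.density.sum() == pytest.approx(1.0, abs=1e-6)
        assert bd.density.max() - bd.density.min() < 0.05 / 40

    def test_step_evidence_localized(self):
        rng = np.random.default_rng(0)
        x = np.r_[np.full(20, 0.001), np.full(20, 0.05)]
        x = np.clip(x + rng.normal(0, 0.0005, 40), 0, None)
        bd = boundary_density_mcmc(x, seed=2)
        assert bd.density[20:].sum() > bd.density[:20].sum()
        # two independent seeds agree closely per bin
        bd2 = boundary_density_mcmc(x, seed=99)
        assert np.abs(bd.density - bd2.density).max() < 0.02

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(1)
        x = np.clip(rng.normal(0.01, 0.002, 50), 0, None)
        a = boundary_density_mcmc(x, seed=7)
        b = boundary_density_mcmc(x, seed=7)
        assert np.array_equal(a.density, b.density)

    def test_final_bin_always_closes_partition(self):
        rng = np.random.default_rng(2)
        x = np.clip(rng.normal(0.01, 0.002, 30), 0, None)
        bd = boundary_density_mcmc(x, seed=3)
        assert bd.change_freq[-1] == pytest.approx(1.0)

    def test_nan_rejected(self):
        x = np.full(10, 0.1)
        x[3] = np.nan
        with pytest.raises(ValidationError):
            boundary_density_mcmc(x)


class TestPairDensity:
    def test_atom_maximal_at_pair(self):
        straps = [Strap(i, 30, 70, 1.0) for i in range(5)]
        fp = boundary_pair_density(straps, n=100)
        assert np.unravel_index(np.argmax(fp.grid), fp.grid.shape) == (30, 70)

    def test_nonnegative_and_normalized(self):
        rng = np.random.default_rng(4)
        straps = [
            Strap(i, int(l), int(l + rng.integers(5, 30)), 1.0)
            for i, l in enumerate(rng.integers(0, 150, 50))
        ]
        fp = boundary_pair_density(straps, n=200)
        assert np.all(fp.grid >= 0)
        # grid cell area is 1, so the grid total is the plane integral
        assert fp.grid.sum() == pytest.approx(1.0, abs=0.02)

    def test_too_few_straps_rejected(self):
        with pytest.raises(ValidationError):
            boundary_pair_density([Strap(0, 0, 5, 1.0)], n=10)


class TestTadProbability:
    def test_zero_support(self):
        fL = BoundaryDensity(np.zeros(10))
        fR = BoundaryDensity(np.zeros(10))
        fP = BoundaryPairDensity(np.zeros((10, 10)))
        assert tad_probability(fL, fR, fP, BinInterval(2, 6)) == 0.0

    def test_brute_force_nine_terms(self):
        fl = np.zeros(3)
        fl[0] = 0.5
        fr = np.zeros(3)
        fr[2] = 0.5
        fP = BoundaryPairDensity(np.ones((3, 3)))
        expect = sum(
            fl[i] * fr[j] * 1.0 for i in range(3) for j in range(3)
        )
        got = tad_probability(
            BoundaryDensity(fl), BoundaryDensity(fr), fP, BinInterval(0, 3)
        )
        assert got == pytest.approx(expect)

    def test_monotone_in_interval_inclusion(self):
        rng = np.random.default_rng(8)
        fl = rng.random(20)
        fr = rng.random(20)
        grid = rng.random((20, 20))
        fL, fR = BoundaryDensity(fl), BoundaryDensity(fr)
        fP = BoundaryPairDensity(grid)
        inner = tad_probability(fL, fR, fP, BinInterval(5, 12))
        outer = tad_probability(fL, fR, fP, BinInterval(3, 15))
        assert outer >= inner


class TestCallTads:
    def test_all_zero_matrix_empty(self):
        m = ContactMatrix(np.zeros((200, 200)))
        assert len(call_tads(m)) == 0

    def test_too_small_matrix_warns_empty(self):
        m = ContactMatrix(np.ones((10, 10)))
        with pytest.warns(UserWarning):
            tads = call_tads(m, CallerConfig(min_tad_size=30))
        assert len(tads) == 0

    def test_boundary_recovery_five_tads(self, five_tad_matrix):
        m, layout = five_tad_matrix
        tads = call_tads(m, CallerConfig(seed=1))
        assert boundary_recovery(tads, layout, tolerance=2) >= 0.9

    def test_no_crossing_pairs(self, five_tad_matrix):
        m, _ = five_tad_matrix
        tads = call_tads(m, CallerConfig(seed=1))
        ivs = tads.intervals()
        for i, a in enumerate(ivs):
            for b in ivs[i + 1 :]:
                assert not a.crosses(b)

    def test_nested_configuration_crossing_free(self):
        # one 200-bin domain enclosing two 100-bin sub-domains at higher
        # intensity, flanked by independent domains
        layout = [
            BinInterval(0, 100),
            BinInterval(100, 200),
            BinInterval(200, 300),
        ]
        cfg = SimulationConfig(
            n_tads=3, size_min=100, size_max=100, n_merges=0,
            mu_min=3, mu_max=3, background_mu=1.0, seed=9,
        )
        m = simulate_matrix(layout, cfg, np.random.default_rng(9))
        tads = call_tads(m, CallerConfig(seed=2))
        ivs = tads.intervals()
        for i, a in enumerate(ivs):
            for b in ivs[i + 1 :]:
                assert not a.crosses(b)

    def test_deterministic_under_seed(self, five_tad_matrix):
        m, _ = five_tad_matrix
        a = call_tads(m, CallerConfig(seed=5))
        b = call_tads(m, CallerConfig(seed=5))
        assert a.intervals() == b.intervals()


class TestCallerStateDensities:
    def test_densities_normalized(self, five_tad_matrix):
        m, _ = five_tad_matrix
        st = caller_state(m, CallerConfig(seed=1))
        assert st.profile.e_left.sum() == pytest.approx(1.0, abs=1e-9)
        assert st.profile.e_right.sum() == pytest.approx(1.0, abs=1e-9)
        assert st.f_left.density.sum() == pytest.approx(1.0, abs=1e-6)
        assert st.f_right.density.sum() == pytest.approx(1.0, abs=1e-6)
        assert st.f_pair.grid.sum() == pytest.approx(1.0, abs=1e-6)
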