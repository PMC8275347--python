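"""Mixing-ratio estimators: projection, grid criteria, maximum likelihood."""

import numpy as np
import pytest

from epmix.deconvolution import (
    GradientAscentConfig,
    deconvolve,
    grid_alpha,
    grid_objective,
    log_likelihood,
    mle_alpha,
    projection_alpha,
    restrict_to_pairs,
)
from epmix.profiling import CombinationProfile, SampleProfileSet, normalize_with_pseudocount


def _pset(sample_id, counts):
    return SampleProfileSet(
        sample_id,
        {
            f"p{i}": CombinationProfile(f"p{i}", np.asarray(c))
            for i, c in enumerate(counts)
        },
        n_states=len(counts[0]),
    )


class TestProjection:
    def test_worked_example(self):
        A = np.array([[1.0, 0, 0, 0]])
        B = np.array([[0.0, 1, 0, 0]])
        T = np.array([[0.5, 0.5, 0, 0]])
        alpha, per_pair, n = projection_alpha(A, B, T)
        assert alpha == pytest.approx(0.5)
        assert n == 1

    def test_pure_endpoints(self):
        rng = np.random.default_rng(0)
        A = rng.dirichlet([1] * 4, 10)
        B = rng.dirichlet([1] * 4, 10)
        assert projection_alpha(A, B, A)[0] == pytest.approx(1.0)
        assert projection_alpha(A, B, B)[0] == pytest.approx(0.0)

    def test_identical_training_vectors_skipped(self):
        A = np.array([[0.25, 0.25, 0.25, 0.25], [0.7, 0.1, 0.1, 0.1]])
        B = np.array([[0.25, 0.25, 0.25, 0.25], [0.1, 0.7, 0.1, 0.1]])
        T = 0.5 * A + 0.5 * B
        alpha, _, n = projection_alpha(A, B, T)
        assert n == 1 and alpha == pytest.approx(0.5)
        with pytest.raises(ValueError):
            projection_alpha(A, A, T)


class TestGrid:
    def test_exact_convex_combination_recovered(self):
        rng = np.random.default_rng(1)
        A = normalize_with_pseudocount(rng.integers(0, 50, (20, 4)) + 1)
        B = normalize_with_pseudocount(rng.integers(0, 50, (20, 4)) + 1)
        T = 0.30 * A + 0.70 * B
        for criterion in ("sse", "kld"):
            assert grid_alpha(A, B, T, criterion)[0] == pytest.approx(0.30)

    def test_pure_test_set(self):
        rng = np.random.default_rng(2)
        A = rng.dirichlet([0.5] * 4, 5)
        B = rng.dirichlet([0.5] * 4, 5)
        assert grid_alpha(A, B, A, "sse")[0] == 1.0

    def test_midpoint_pair(self):
        A = np.array([[0.7, 0.1, 0.1, 0.1]])
        B = np.array([[0.1, 0.7, 0.1, 0.1]])
        T = np.array([[0.4, 0.4, 0.1, 0.1]])
        for criterion in ("sse", "kld"):
            assert grid_alpha(A, B, T, criterion)[0] == pytest.approx(0.50)

    def test_returned_alpha_minimizes_full_scan(self):
        rng = np.random.default_rng(3)
        A = rng.dirichlet([0.5] * 4, 15)
        B = rng.dirichlet([0.5] * 4, 15)
        T = normalize_with_pseudocount(rng.integers(0, 30, (15, 4)) + 1)
        for criterion in ("sse", "kld"):
            alpha, alphas, obj = grid_alpha(A, B, T, criterion)
            assert obj[list(alphas).index(alpha)] == obj.min()

    def test_non_positive_probabilities_rejected_for_kld(self):
        A = np.array([[0.5, 0.5, 0.0, 0.0]])
        with pytest.raises(ValueError):
            grid_objective(A, A, A, "kld")


class TestMLE:
    PA = np.array([[0.9, 0.1]])
    PB = np.array([[0.1, 0.9]])

    def test_interior_stationary_point(self):
        alpha, _ = mle_alpha(self.PA, self.PB, np.array([[80, 20]]))
        assert alpha == pytest.approx(0.875, abs=0.005)

    def test_boundary_maximum(self):
        alpha, _ = mle_alpha(self.PA, self.PB, np.array([[90, 10]]))
        assert alpha == 1.0

    def test_symmetric_counts_give_half(self):
        alpha, _ = mle_alpha(self.PA, self.PB, np.array([[50, 50]]))
        assert alpha == pytest.approx(0.5)

    def test_trace_non_decreasing(self):
        rng = np.random.default_rng(4)
        PA = rng.dirichlet([0.5] * 4, 30)
        PB = rng.dirichlet([0.5] * 4, 30)
        N = rng.integers(0, 40, (30, 4))
        _, trace = mle_alpha(PA, PB, N)
        lls = [ll for _, ll in trace]
        assert all(b >= a for a, b in zip(lls, lls[1:]))

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(5)
        grid = np.arange(1001) / 1000
        for _ in range(10):
            PA = rng.dirichlet([0.5] * 4, 20)
            PB = rng.dirichlet([0.5] * 4, 20)
            true = rng.uniform()
            N = np.stack(
                [rng.multinomial(50, true * a + (1 - true) * b) for a, b in zip(PA, PB)]
            )
            alpha, _ = mle_alpha(PA, PB, N)
            scan = grid[np.argmax(log_likelihood(grid, PA, PB, N))]
            assert abs(alpha - scan) <= 0.005

    def test_zero_probability_rejected(self):
        with pytest.raises(ValueError):
            mle_alpha(np.array([[1.0, 0.0]]), self.PB, np.array([[1, 1]]))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GradientAscentConfig(step=-1)


class TestDeconvolveFrontEnd:
    def _profiles(self, seed=0, n=25, cov=200, true_alpha=0.3):
        rng = np.random.default_rng(seed)
        PA = rng.dirichlet([0.5] * 4, n)
        PB = rng.dirichlet([0.5] * 4, n)
        NA = np.stack([rng.multinomial(cov, p) for p in PA])
        NB = np.stack([rng.multinomial(cov, p) for p in PB])
        q = true_alpha * PA + (1 - true_alpha) * PB
        NT = np.stack([rng.multinomial(cov, p) for p in q])
        return _pset("A", NA), _pset("B", NB), _pset("T", NT)

    @pytest.mark.parametrize("method", ["projection", "sse", "kld", "mle"])
    def test_recovers_mixture_approximately(self, method):
        tA, tB, tT = self._profiles()
        res = deconvolve(tA, tB, tT, method)
        assert res.alpha_A == pytest.approx(0.3, abs=0.1)
        assert res.n_pairs_used == 25

    @pytest.mark.parametrize("method", ["projection", "mle"])
    def test_swap_symmetry_exact(self, method):
        tA, tB, tT = self._profiles(seed=6)
        a = deconvolve(tA, tB, tT, method).alpha_A
        b = deconvolve(tB, tA, tT, method).alpha_A
        assert a + b == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("method", ["sse", "kld"])
    def test_swap_symmetry_within_grid_step(self, method):
        tA, tB, tT = self._profiles(seed=7)
        a = deconvolve(tA, tB, tT, method).alpha_A
        b = deconvolve(tB, tA, tT, method).alpha_A
        assert abs(a + b - 1.0) <= 0.01 + 1e-12

    def test_two_state_profiles_accepted(self):
        rng = np.random.default_rng(8)
        NA = rng.integers(1, 50, (10, 2))
        NB = rng.integers(1, 50, (10, 2))
        res = deconvolve(_pset("A", NA), _pset("B", NB), _pset("T", NA), "mle")
        assert 0.0 <= res.alpha_A <= 1.0

    def test_pair_subset_restriction(self):
        tA, tB, tT = self._profiles()
        res = deconvolve(tA, tB, tT, "mle", pair_subset=["p0", "p1", "p2"])
        assert res.n_pairs_used == 3
        with pytest.raises(ValueError):
            deconvolve(tA, tB, tT, "mle", pair_subset=["nope"])

    def test_restrict_identity(self):
        tA, tB, tT = self._profiles()
        out = restrict_to_pairs([tA, tB, tT], tA.pair_ids)
        assert out[0].pair_ids == tA.pair_ids
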