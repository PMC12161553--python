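"""Hopfield dynamics: sign rule, Hebbian storage, energy descent, attractors."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hopforecast.hopfield import (
    FitConfig,
    energy,
    hebbian_weights,
    run_to_convergence,
    sgn,
    update_sweep,
)


class TestSgn:
    @pytest.mark.parametrize("value, expected", [(0.0, 1), (2.5, 1), (-0.1, -1)])
    def test_values(self, value, expected):
        assert sgn(value) == expected

    @pytest.mark.parametrize("bad", [float("nan"), float("inf")])
    def test_non_finite_rejected(self, bad):
        with pytest.raises(ValueError):
            sgn(bad)


class TestHebbianWeights:
    def test_single_pattern_outer_product(self):
        W = hebbian_weights([[1, -1, 1]])
        expected = np.array([[0, -1, 1], [-1, 0, -1], [1, -1, 0]]) / 3
        np.testing.assert_allclose(W, expected)

    def test_orthogonal_pair_cancels(self):
        np.testing.assert_allclose(hebbian_weights([[1, 1], [1, -1]]), np.zeros((2, 2)))

    def test_stored_pattern_is_fixed_point(self):
        rng = np.random.default_rng(0)
        pattern = rng.choice([-1, 1], size=9)
        W = hebbian_weights([pattern])
        final, trace = update_sweep(W, pattern, config=FitConfig(threshold_scale=0.0))
        np.testing.assert_array_equal(final, pattern)
        assert trace.flips == 0

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            hebbian_weights(np.empty((0, 3)))
        with pytest.raises(ValueError):
            hebbian_weights([[1, 0, 1]])


class TestEnergy:
    def test_zero_weights(self):
        assert energy(np.zeros((3, 3)), [1, -1, 1]) == 0.0

    def test_pair_coupling(self):
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert energy(W, [1, 1]) == -1.0

    def test_threshold_term(self):
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert energy(W, [1, 1], T=[0.5, 0.5], threshold_scale=1.0) == 0.0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            energy(np.zeros((2, 2)), [1, 1, 1])


class TestUpdateSweep:
    def test_sequential_two_neuron_example(self):
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        final, trace = update_sweep(W, [1, -1], T=[0.0, 0.0])
        np.testing.assert_array_equal(final, [-1, -1])
        assert [s.net for s in trace.steps] == [-1.0, -1.0]

    def test_fixed_point_unchanged(self):
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        final, trace = update_sweep(W, [1, 1], T=[0.0, 0.0])
        np.testing.assert_array_equal(final, [1, 1])
        assert trace.flips == 0

    def test_stochastic_mode_reproducible_per_seed(self):
        rng = np.random.default_rng(5)
        W = hebbian_weights(rng.choice([-1, 1], size=(2, 8)))
        T = np.full(8, 0.4)
        config = FitConfig(update_mode="stochastic", seed=11)
        x0 = rng.choice([-1, 1], size=8)
        a = update_sweep(W, x0, T, config)
        b = update_sweep(W, x0, T, config)
        np.testing.assert_array_equal(a[0], b[0])
        assert [s.new for s in a[1].steps] == [s.new for s in b[1].steps]


def random_symmetric_weights(rng, n):
    A = rng.normal(size=(n, n))
    W = (A + A.T) / 2
    np.fill_diagonal(W, 0.0)
    return W


class TestConvergence:
    def test_immediate_convergence_at_fixed_point(self):
        pattern = np.array([1, -1, 1, -1])
        W = hebbian_weights([pattern])
        result = run_to_convergence(W, pattern, config=FitConfig(threshold_scale=0.0))
        assert result.converged and result.sweeps == 1

    @given(st.integers(0, 40))
    def test_energy_never_increases_along_deterministic_traces(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 10))
        W = random_symmetric_weights(rng, n)
        T = rng.uniform(0, 1, n)
        x0 = rng.choice([-1, 1], size=n)
        result = run_to_convergence(W, x0, T, FitConfig(), record_trace=True)
        energies = [energy(W, x0, T, 1.0)] + result.trace.energies
        assert all(a >= b - 1e-12 for a, b in zip(energies, energies[1:]))

    def test_deterministic_runs_always_reach_fixed_points(self):
        rng = np.random.default_rng(7)
        count = 0
        while count < 200:
            n = int(rng.integers(2, 13))
            W = random_symmetric_weights(rng, n)
            for _ in range(10):
                x0 = rng.choice([-1, 1], size=n)
                result = run_to_convergence(W, x0, config=FitConfig(j_max=2**n))
                assert result.converged
                count += 1

    def test_fixed_points_match_exhaustive_enumeration(self):
        rng = np.random.default_rng(9)
        for n in (2, 3, 4):
            W = random_symmetric_weights(rng, n)
            T = rng.uniform(0, 0.5, n)
            lam = 1.0

            def is_fixed(x):
                return all(
                    sgn(float(W[j] @ x) - lam * T[j]) == x[j] for j in range(n)
                )

            brute = {
                x for x in itertools.product((-1, 1), repeat=n) if is_fixed(np.array(x))
            }
            reached = set()
            for x in itertools.product((-1, 1), repeat=n):
                result = run_to_convergence(W, np.array(x), T, FitConfig())
                assert result.converged
                reached.add(tuple(result.state))
            assert reached == brute

    def test_single_bit_corruptions_recalled_at_n7(self):
        rng = np.random.default_rng(13)
        pattern = rng.choice([-1, 1], size=7)
        W = hebbian_weights([pattern])
        for j in range(7):
            x0 = pattern.copy()
            x0[j] *= -1
            result = run_to_convergence(W, x0, config=FitConfig(threshold_scale=0.0))
            np.testing.assert_array_equal(result.state, pattern)

    def test_pattern_recall_in_low_load_regime(self):
        # two stored patterns at n=20: states one bit away recover the pattern
        rng = np.random.default_rng(21)
        recovered = total = 0
        for _ in range(5):
            patterns = rng.choice([-1, 1], size=(2, 20))
            W = hebbian_weights(patterns)
            for pattern in patterns:
                for j in rng.choice(20, size=10, replace=False):
                    x0 = pattern.copy()
                    x0[j] *= -1
                    result = run_to_convergence(
                        W, x0, config=FitConfig(threshold_scale=0.0)
                    )
                    total += 1
                    recovered += int(np.array_equal(result.state, pattern))
        assert recovered / total >= 0.95

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            run_to_convergence(np.zeros((3, 3)), [1, 1])
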