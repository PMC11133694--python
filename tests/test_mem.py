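"""Pairwise maximum-entropy model: energies, moments, fitting, accuracy."""

import numpy as np
import pytest

from energyscape import (
    MEMParams,
    MomentSet,
    boltzmann_distribution,
    empirical_moments,
    empirical_pattern_frequencies,
    fit_accuracy,
    fit_independent_mem,
    fit_pairwise_mem,
    model_moments,
    pattern_energy,
)
from energyscape.mem import all_patterns, enumerate_energies

from conftest import random_params


class TestPatternEnergy:
    def test_zero_model(self):
        p = MEMParams(h=np.zeros(3), J=np.zeros((3, 3)))
        assert pattern_energy(p, [1, -1, 1]) == 0.0

    @pytest.mark.parametrize(
        "sigma,expected",
        [((1, 1), -0.3), ((1, -1), -0.7), ((-1, 1), 1.3), ((-1, -1), -0.3)],
    )
    def test_two_network_hand_values(self, sigma, expected):
        # E = -(h1 s1 + h2 s2) - J12 s1 s2 with h=(0.5,-0.5), J12=0.3
        p = MEMParams(h=np.array([0.5, -0.5]), J=np.array([[0, 0.3], [0.3, 0]]))
        assert pattern_energy(p, np.array(sigma)) == pytest.approx(expected)

    def test_enumeration_matches_single_evaluation(self):
        p = random_params(4, seed=11)
        e = enumerate_energies(p)
        pats = all_patterns(4)
        for k in range(16):
            assert e[k] == pytest.approx(pattern_energy(p, pats[k]))

    def test_length_mismatch(self):
        p = MEMParams(h=np.zeros(2), J=np.zeros((2, 2)))
        with pytest.raises(ValueError):
            pattern_energy(p, [1, 1, 1])


class TestBoltzmann:
    def test_uniform_for_zero_model(self):
        p = MEMParams(h=np.zeros(9), J=np.zeros((9, 9)))
        t = boltzmann_distribution(p)
        np.testing.assert_allclose(t.probabilities, 1 / 512)

    def test_single_network_closed_form(self):
        p = MEMParams(h=np.array([0.5 * np.log(3)]), J=np.zeros((1, 1)))
        t = boltzmann_distribution(p)
        # P(+1) = e^h / (e^h + e^-h) = 0.75; pattern index 1 is "+1"
        assert t.probabilities[1] == pytest.approx(0.75)
        assert t.probabilities[0] == pytest.approx(0.25)

    def test_normalisation(self):
        t = boltzmann_distribution(random_params(6, seed=2))
        assert t.probabilities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_gauge_invariance(self):
        # shifting all energies by a constant leaves probabilities unchanged
        p = random_params(4, seed=5)
        t = boltzmann_distribution(p)
        shifted = t.energies + 7.3
        w = np.exp(-(shifted - shifted.min()))
        np.testing.assert_allclose(w / w.sum(), t.probabilities, atol=1e-14)


class TestMoments:
    def test_constant_data(self):
        vals = np.ones((1, 3, 5), dtype=np.int8)
        m = empirical_moments(vals)
        np.testing.assert_allclose(m.mean_activity, 1.0)
        np.testing.assert_allclose(m.pairwise, 1.0)

    def test_hand_averages(self):
        cols = np.array([[1, -1], [1, -1]])  # columns (+1,+1), (-1,-1)
        m = empirical_moments(cols)
        np.testing.assert_allclose(m.mean_activity, [0, 0])
        assert m.pairwise[0, 1] == pytest.approx(1.0)
        anti = np.array([[1, -1], [-1, 1]])
        assert empirical_moments(anti).pairwise[0, 1] == pytest.approx(-1.0)

    def test_model_moments_uniform(self):
        p = MEMParams(h=np.zeros(3), J=np.zeros((3, 3)))
        m = model_moments(boltzmann_distribution(p))
        np.testing.assert_allclose(m.mean_activity, 0, atol=1e-14)
        np.testing.assert_allclose(m.pairwise - np.eye(3), 0, atol=1e-14)

    def test_model_moments_single_network(self):
        p = MEMParams(h=np.array([0.5 * np.log(3)]), J=np.zeros((1, 1)))
        m = model_moments(boltzmann_distribution(p))
        assert m.mean_activity[0] == pytest.approx(0.5)

    def test_model_moments_match_sampled_empirical(self):
        # moments under the enumerated law equal the expectation of data moments
        p = random_params(3, seed=8)
        t = boltzmann_distribution(p)
        exact = model_moments(t)
        pats = all_patterns(3).astype(float)
        mean = t.probabilities @ pats
        np.testing.assert_allclose(exact.mean_activity, mean, atol=1e-12)


class TestIndependentFit:
    def test_zero_mean_gives_zero_field(self):
        p = fit_independent_mem(np.zeros(4))
        np.testing.assert_array_equal(p.h, 0)
        np.testing.assert_array_equal(p.J, 0)

    def test_closed_form(self):
        p = fit_independent_mem(np.array([0.5]))
        assert p.h[0] == pytest.approx(np.arctanh(0.5))

    def test_round_trip_through_model_moments(self):
        target = np.array([-0.6, 0.1, 0.45])
        m = model_moments(boltzmann_distribution(fit_independent_mem(target)))
        np.testing.assert_allclose(m.mean_activity, target, atol=1e-12)

    def test_saturated_mean_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            p = fit_independent_mem(np.array([1.0, 0.0]))
        assert np.isfinite(p.h).all()


class TestPairwiseFit:
    def test_recovers_known_model_from_exact_moments(self):
        truth = random_params(4, seed=42, field_scale=0.3, coupling_scale=0.3)
        m = model_moments(boltzmann_distribution(truth))
        target = MomentSet(m.mean_activity, m.pairwise, source="empirical")
        fitted, diag = fit_pairwise_mem(target, tol=1e-8)
        assert diag.converged
        np.testing.assert_allclose(fitted.h, truth.h, atol=1e-4)
        np.testing.assert_allclose(fitted.J, truth.J, atol=1e-4)

    def test_null_couplings_recovered_from_independent_data(self):
        rng = np.random.default_rng(0)
        truth = fit_independent_mem(np.array([0.3, -0.2, 0.1]))
        t = boltzmann_distribution(truth)
        idx = rng.choice(8, size=200_000, p=t.probabilities)
        vals = all_patterns(3)[idx].T
        fitted, diag = fit_pairwise_mem(empirical_moments(vals), tol=1e-6)
        assert diag.converged
        # couplings of an independent generator vanish up to sampling error
        se = 3 / np.sqrt(200_000)
        off = fitted.J[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 3 * se + 1e-3

    def test_stopping_contract(self):
        m = model_moments(boltzmann_distribution(random_params(3, seed=1)))
        target = MomentSet(m.mean_activity, m.pairwise, source="empirical")
        _, diag = fit_pairwise_mem(target, tol=1e-6)
        assert diag.converged and diag.max_moment_gap < 1e-6

    def test_moment_matching_at_convergence(self):
        # fixed point of the ML gradient: model moments equal the target
        m = model_moments(boltzmann_distribution(random_params(5, seed=9)))
        target = MomentSet(m.mean_activity, m.pairwise, source="empirical")
        fitted, _ = fit_pairwise_mem(target, tol=1e-7)
        got = model_moments(boltzmann_distribution(fitted))
        np.testing.assert_allclose(got.mean_activity, target.mean_activity, atol=1e-6)
        np.testing.assert_allclose(got.pairwise, target.pairwise, atol=1e-6)


class TestFitAccuracy:
    def _fit_both(self, freq, n):
        emp_mean = freq @ all_patterns(n)
        independent = boltzmann_distribution(fit_independent_mem(emp_mean))
        return independent

    def test_perfect_pairwise_model_gives_R_one(self):
        p = random_params(3, seed=3)
        t = boltzmann_distribution(p)
        freq = t.probabilities.copy()
        independent = self._fit_both(freq, 3)
        diag = fit_accuracy(freq, independent, t)
        assert diag.D2 == 0.0
        assert diag.R == 1.0

    def test_pairwise_equal_to_independent_gives_R_zero(self):
        p = random_params(3, seed=4)
        freq = boltzmann_distribution(p).probabilities
        independent = self._fit_both(freq, 3)
        diag = fit_accuracy(freq, independent, independent)
        assert diag.D1 == diag.D2
        assert diag.R == 0.0

    def test_strongly_coupled_synthetic_oracle(self):
        truth = random_params(4, seed=7, field_scale=0.2, coupling_scale=0.8)
        t = boltzmann_distribution(truth)
        freq = t.probabilities
        m = model_moments(t)
        independent = boltzmann_distribution(fit_independent_mem(m.mean_activity))
        fitted, _ = fit_pairwise_mem(
            MomentSet(m.mean_activity, m.pairwise, source="empirical"), tol=1e-8
        )
        diag = fit_accuracy(freq, independent, boltzmann_distribution(fitted))
        assert diag.R > 0.9
        assert diag.pearson_r > 0.99

    def test_R_increases_with_sample_size(self):
        # more data: pairwise fit explains an increasing share of D1
        truth = random_params(4, seed=12, field_scale=0.2, coupling_scale=0.6)
        t = boltzmann_distribution(truth)
        medians = []
        for size in (500, 5000, 50000):
            rs = []
            for seed in range(7):
                rng = np.random.default_rng(100 + seed)
                idx = rng.choice(16, size=size, p=t.probabilities)
                vals = all_patterns(4)[idx].T
                m = empirical_moments(vals)
                freq = empirical_pattern_frequencies(idx, 4)
                independent = boltzmann_distribution(fit_independent_mem(m.mean_activity))
                fitted, _ = fit_pairwise_mem(m, tol=1e-6)
                rs.append(fit_accuracy(freq, independent, boltzmann_distribution(fitted)).R)
            medians.append(np.median(rs))
        assert medians[0] < medians[2]
        assert medians[2] > 0.95

    def test_degenerate_empirical_distribution_warns(self):
        p = MEMParams(h=np.zeros(2), J=np.zeros((2, 2)))
        t = boltzmann_distribution(p)
        with pytest.warns(UserWarning, match="R undefined"):
            diag = fit_accuracy(np.full(4, 0.25), t, t)
        assert diag.R is None
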