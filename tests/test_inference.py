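import math

import numpy as np
import pandas as pd
import pytest

from tigerpop import life_history as lh
from tigerpop.environment import SurveillanceTable, generate_synthetic_environment
from tigerpop.inference import (
    BasinHoppingConfig,
    ModelObjective,
    ModeSamples,
    PosteriorModeSet,
    acceptance_probability,
    basin_hopping_mcmc,
    data_loglik,
    expected_output,
    mode_posterior_mass,
    pooled_sem,
    sample_mode,
    sensitivity,
)


class TestPooledSem:
    def test_equal_groups_reduce_to_sqrt_two(self):
        # algebra: equal n and s collapse the formula to s * sqrt(2)
        assert pooled_sem(12, 12, 1.7, 1.7) == pytest.approx(1.7 * math.sqrt(2), rel=1e-12)

    def test_zero_sems_give_zero(self):
        assert pooled_sem(5, 9, 0.0, 0.0) == 0.0

    def test_direct_formula_evaluation(self):
        # independent arithmetic: (1/10+1/5)*(10*9*1 + 5*4*4)/13 = 0.3*170/13
        expected = math.sqrt(0.3 * 170.0 / 13.0)
        assert pooled_sem(10, 5, 1.0, 2.0) == pytest.approx(expected, rel=1e-12)

    def test_single_trap_rejected(self):
        with pytest.raises(ValueError):
            pooled_sem(1, 5, 1.0, 1.0)


def _table(rows):
    return SurveillanceTable(pd.DataFrame(rows))


class TestDataLoglik:
    def test_single_window_perfect_match(self):
        obs = _table([{"province": "A", "window_end": "2009-06-01",
                       "n_traps": 10, "mean_eggs": 5.0, "sem": 1.0}])
        sim = {("A", pd.Timestamp("2009-06-01")): 5.0}
        assert data_loglik(obs, sim) == pytest.approx(math.log(1 / math.sqrt(2 * math.pi)))

    def test_two_window_fixture_hand_evaluation(self):
        obs = _table([
            {"province": "A", "window_end": "2009-06-01", "n_traps": 10,
             "mean_eggs": 5.0, "sem": 1.0},
            {"province": "A", "window_end": "2009-06-15", "n_traps": 10,
             "mean_eggs": 8.0, "sem": 2.0},
        ])
        sim = {("A", pd.Timestamp("2009-06-01")): 5.0,
               ("A", pd.Timestamp("2009-06-15")): 8.0}
        sp = pooled_sem(10, 10, 1.0, 2.0)
        expected = (-math.log(1.0 * math.sqrt(2 * math.pi))
                    - math.log(2.0 * math.sqrt(2 * math.pi))
                    - math.log(sp * math.sqrt(2 * math.pi)))
        assert data_loglik(obs, sim) == pytest.approx(expected, rel=1e-12)

    def test_first_window_of_year_has_no_difference_term(self):
        rows = [
            {"province": "A", "window_end": "2009-06-01", "n_traps": 10,
             "mean_eggs": 5.0, "sem": 1.0},
            {"province": "A", "window_end": "2010-06-01", "n_traps": 10,
             "mean_eggs": 9.0, "sem": 1.0},
        ]
        obs = _table(rows)
        assert obs.data["first_of_year"].all()
        sim = {("A", pd.Timestamp("2009-06-01")): 5.0,
               ("A", pd.Timestamp("2010-06-01")): 9.0}
        # two level terms only: no pooled-SEM normalization appears
        assert data_loglik(obs, sim) == pytest.approx(
            2 * math.log(1 / math.sqrt(2 * math.pi)))

    def test_doubling_residuals_costs_quadratically(self):
        obs = _table([{"province": "A", "window_end": "2009-06-01",
                       "n_traps": 10, "mean_eggs": 5.0, "sem": 1.0}])
        base = data_loglik(obs, {("A", pd.Timestamp("2009-06-01")): 5.0})
        l1 = data_loglik(obs, {("A", pd.Timestamp("2009-06-01")): 6.0})
        l2 = data_loglik(obs, {("A", pd.Timestamp("2009-06-01")): 7.0})
        assert base - l1 == pytest.approx(0.5)
        assert base - l2 == pytest.approx(2.0)


def _noiseless_obs(theta, envs, sem=1.0):
    """Noise-free synthetic surveillance with a unit reported SEM."""
    from tigerpop.environment import generate_synthetic_surveillance

    obs = generate_synthetic_surveillance(theta, envs, noise_sd=0.0, seed=42)
    df = obs.data.copy()
    df["sem"] = sem
    return SurveillanceTable(df)


@pytest.fixture(scope="module")
def tiny_objective(theta):
    envs = {"A": generate_synthetic_environment(seed=41, years=2)}
    prior = lh.default_prior()
    prior.mean[:] = theta.values  # prior centred at the generating truth
    return ModelObjective(_noiseless_obs(theta, envs), envs, prior,
                          free=["T_crt", "CPP"])


class TestObjective:
    def test_zero_at_prior_mean_with_perfect_data(self, tiny_objective):
        val = tiny_objective.value(tiny_objective.x0())
        assert val.f == pytest.approx(0.0, abs=1e-10)
        assert val.prior_term == pytest.approx(0.0, abs=1e-12)

    def test_decomposes_into_prior_and_data_terms(self, tiny_objective):
        x = tiny_objective.x0() + np.array([0.8, -0.4])
        val = tiny_objective.value(x)
        assert val.f == pytest.approx(val.prior_term + val.data_term, rel=1e-12)
        assert val.prior_term > 0 and val.data_term > 0

    def test_out_of_bounds_is_rejected_with_infinity(self, tiny_objective):
        x = tiny_objective.x0().copy()
        x[1] = 30.0  # photoperiod threshold beyond 24 h
        assert tiny_objective(x) == np.inf

    def test_diagonal_prior_reduces_to_standardized_squares(self, theta):
        # pure prior displacement: f = 1/2 sum z^2 for a diagonal covariance
        prior = lh.default_prior()
        prior.mean[:] = theta.values
        envs = {"A": generate_synthetic_environment(seed=41, years=2)}
        obj = ModelObjective(_noiseless_obs(theta, envs), envs, prior,
                             free=["delta_T"])
        sd = math.sqrt(prior.cov[lh.PARAM_NAMES.index("delta_T"),
                                 lh.PARAM_NAMES.index("delta_T")])
        # delta_T shifts water temperature; its data effect is nonzero, so
        # compare the prior term only
        val = obj.value(np.array([1.5]))
        assert val.prior_term == pytest.approx(0.5 * (1.5 / sd) ** 2, rel=1e-9)

    def test_nondiagonal_prior_block_matches_dense_quadratic_form(self, theta):
        prior = lh.default_prior()
        prior.mean[:] = theta.values
        names = ["T_crt", "CPP", "p_n"]
        idx = [lh.PARAM_NAMES.index(n) for n in names]
        block = np.array([[4.0, 1.0, 0.0], [1.0, 2.0, 0.3], [0.0, 0.3, 0.5]])
        prior.cov[np.ix_(idx, idx)] = block
        envs = {"A": generate_synthetic_environment(seed=41, years=2)}
        obj = ModelObjective(_noiseless_obs(theta, envs), envs, prior, free=names)
        dx = np.array([0.5, -0.3, 0.05])
        val = obj.value(obj.x0() + dx)
        oracle = 0.5 * dx @ np.linalg.inv(block) @ dx
        assert val.prior_term == pytest.approx(oracle, rel=1e-6)


class TestAcceptanceProbability:
    def test_equal_objectives_always_accept(self):
        assert acceptance_probability(3.0, 3.0, 5.0) == 1.0

    def test_downhill_always_accepts(self):
        assert acceptance_probability(3.0, 1.0, 0.5) == 1.0

    def test_uphill_two_at_unit_temperature(self):
        assert acceptance_probability(1.0, 3.0, 1.0) == pytest.approx(math.exp(-2))

    def test_infinite_tolerance_accepts_everything(self):
        assert acceptance_probability(1.0, 100.0, 1e12) == pytest.approx(1.0, abs=1e-9)

    def test_unit_temperature_is_metropolis_hastings(self):
        # the ratio of posterior densities exp(-(f'-f)) is the MH criterion
        for f, fp in [(0.0, 0.7), (2.0, 1.1), (5.0, 5.0)]:
            mh = min(1.0, math.exp(f - fp))
            assert acceptance_probability(f, fp, 1.0) == pytest.approx(mh, rel=1e-12)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            acceptance_probability(1.0, 2.0, 0.0)


def _double_well(x):
    return float(10.0 * min((x[0] - 2.0) ** 2, (x[0] + 2.0) ** 2))


class TestBasinHopping:
    def test_double_well_finds_both_minima(self):
        cfg = BasinHoppingConfig(n_chains=8, n_phases=2, iters_per_phase=150,
                                 T_high=20.0, T_low=0.05, dedupe_dist=1.0)
        modes = basin_hopping_mcmc(_double_well, [(-6.0, 6.0)], cfg, seed=3)
        centers = sorted(m.theta[0] for m in modes)
        assert any(abs(c - (-2.0)) < 0.2 for c in centers)
        assert any(abs(c - 2.0) < 0.2 for c in centers)

    def test_quadratic_bowl_single_mode(self):
        cfg = BasinHoppingConfig(n_chains=4, n_phases=2, iters_per_phase=150,
                                 T_high=10.0, T_low=0.05, dedupe_dist=1.0)
        modes = basin_hopping_mcmc(lambda x: float((x[0] - 1.0) ** 2 + x[1] ** 2),
                                   [(-5.0, 5.0), (-5.0, 5.0)], cfg, seed=4)
        assert len(modes) == 1
        assert modes[0].theta == pytest.approx([1.0, 0.0], abs=0.2)

    def test_same_seed_identical_modes(self):
        cfg = BasinHoppingConfig(n_chains=3, n_phases=1, iters_per_phase=80)
        a = basin_hopping_mcmc(_double_well, [(-6.0, 6.0)], cfg, seed=9)
        b = basin_hopping_mcmc(_double_well, [(-6.0, 6.0)], cfg, seed=9)
        assert [tuple(m.theta) for m in a] == [tuple(m.theta) for m in b]

    def test_no_finite_objective_raises(self):
        with pytest.raises(RuntimeError):
            basin_hopping_mcmc(lambda x: np.inf, [(-1.0, 1.0)],
                               BasinHoppingConfig(n_chains=2, n_phases=1,
                                                  iters_per_phase=10), seed=1)


class TestSampleMode:
    def test_tempered_gaussian_widens_by_temperature(self):
        # f = x^2/2 -> stationary law at T_ann is N(0, T_ann)
        T = 10.0
        samples, _ = sample_mode(lambda x: 0.5 * float(x[0] ** 2), [0.0],
                                 [(-100.0, 100.0)], T_ann=T, n_samples=800,
                                 seed=7, thin=10, burn=500, scale_frac=0.02)
        var = samples.var()
        assert var == pytest.approx(T, rel=0.25)

    def test_default_sample_count_is_one_hundred(self):
        samples, fvals = sample_mode(lambda x: float(x[0] ** 2), [0.0],
                                     [(-10.0, 10.0)], seed=1)
        assert samples.shape == (100, 1) and fvals.shape == (100,)

    def test_seed_reproducibility(self):
        a, _ = sample_mode(lambda x: float(x[0] ** 2), [0.0], [(-10.0, 10.0)], seed=5)
        b, _ = sample_mode(lambda x: float(x[0] ** 2), [0.0], [(-10.0, 10.0)], seed=5)
        assert np.array_equal(a, b)


def _mixture_modes(w1=0.7, m1=-4.0, m2=4.0, n=10_000, seed=0):
    """Two-component 1-D Gaussian mixture posterior with known weights."""
    rng = np.random.default_rng(seed)

    def f(x):
        p = (w1 * math.exp(-0.5 * (x - m1) ** 2) / math.sqrt(2 * math.pi)
             + (1 - w1) * math.exp(-0.5 * (x - m2) ** 2) / math.sqrt(2 * math.pi))
        return -math.log(p)

    modes = []
    for label, m in (("A", m1), ("B", m2)):
        s = rng.normal(m, 1.0, size=n)[:, None]
        modes.append(ModeSamples(label, s, np.array([f(v[0]) for v in s])))
    return PosteriorModeSet(modes)


class TestModePosteriorMass:
    def test_single_mode_has_unit_mass(self, rng):
        s = rng.normal(0.0, 1.0, size=(200, 1))
        ms = PosteriorModeSet([ModeSamples("A", s, 0.5 * s[:, 0] ** 2)])
        for T_tol in (0.5, 1.0, 10.0):
            assert mode_posterior_mass(ms, T_tol) == pytest.approx([1.0])

    def test_symmetric_modes_split_evenly(self, rng):
        a = rng.normal(-3.0, 1.0, size=(2000, 1))
        b = rng.normal(3.0, 1.0, size=(2000, 1))
        ms = PosteriorModeSet([
            ModeSamples("A", a, np.full(2000, 1.0)),
            ModeSamples("B", b, np.full(2000, 1.0))])
        masses = mode_posterior_mass(ms, 1.0)
        assert masses == pytest.approx([0.5, 0.5], abs=0.05)

    def test_recovers_known_mixture_weights(self):
        ms = _mixture_modes(w1=0.7, n=10_000, seed=11)
        masses = mode_posterior_mass(ms, T_tol=1.0)
        assert masses[0] == pytest.approx(0.7, abs=0.03)
        assert masses[1] == pytest.approx(0.3, abs=0.03)

    def test_invariant_to_duplicating_samples(self):
        ms = _mixture_modes(w1=0.6, n=2000, seed=3)
        masses = mode_posterior_mass(ms, 1.0)
        dup = PosteriorModeSet([
            ModeSamples("A", np.vstack([ms.modes[0].samples] * 2),
                        np.concatenate([ms.modes[0].f_values] * 2)),
            ms.modes[1]])
        masses_dup = mode_posterior_mass(dup, 1.0)
        assert masses_dup == pytest.approx(masses, rel=1e-9)

    def test_invalid_tolerance_rejected(self):
        ms = _mixture_modes(n=50)
        with pytest.raises(ValueError):
            mode_posterior_mass(ms, 0.0)


class TestExpectedOutput:
    def test_identical_samples_reproduce_single_simulation(self, tiny_objective):
        x = tiny_objective.x0()
        sim = tiny_objective.simulate_windows(tiny_objective.unpack(x))
        df = expected_output(np.vstack([x, x, x]), tiny_objective)
        for _, row in df.iterrows():
            key = (row["province"], row["window_end"])
            assert row["y_mean"] == pytest.approx(sim[key], rel=1e-12)
            assert row["y_lo"] == pytest.approx(sim[key], rel=1e-12)

    def test_two_sample_average(self, tiny_objective):
        x1 = tiny_objective.x0()
        x2 = x1 + np.array([0.5, 0.2])
        s1 = tiny_objective.simulate_windows(tiny_objective.unpack(x1))
        s2 = tiny_objective.simulate_windows(tiny_objective.unpack(x2))
        df = expected_output(np.vstack([x1, x2]), tiny_objective)
        row = df.iloc[3]
        key = (row["province"], row["window_end"])
        assert row["y_mean"] == pytest.approx(0.5 * (s1[key] + s2[key]), rel=1e-12)


class TestSensitivity:
    def test_identity_covariance_unit_parameters(self):
        s = sensitivity(np.ones(4), np.eye(4))
        assert np.allclose(s.H, np.eye(4))

    def test_quadratic_scaling_in_parameter_magnitude(self):
        theta = np.array([1.0, 2.0, 3.0])
        base = sensitivity(theta, np.eye(3)).H
        scaled = sensitivity(3.0 * theta, np.eye(3)).H
        assert np.allclose(scaled, 9.0 * base)

    def test_random_spd_matches_dense_inverse_oracle(self, rng):
        A = rng.normal(size=(3, 3))
        Sigma = A @ A.T + 0.5 * np.eye(3)
        theta = rng.uniform(0.5, 2.0, size=3)
        s = sensitivity(theta, Sigma)
        oracle = np.diag(theta) @ np.linalg.inv(Sigma) @ np.diag(theta)
        assert np.allclose(s.H, oracle, rtol=1e-10)

    def test_symmetry_and_named_diagonal(self, rng):
        A = rng.normal(size=(3, 3))
        Sigma = A @ A.T + 0.5 * np.eye(3)
        s = sensitivity(np.ones(3), Sigma, names=["a", "b", "c"])
        assert np.allclose(s.H, s.H.T)
        assert list(s.per_parameter().index) == ["a", "b", "c"]

    def test_singular_covariance_ridge_then_error(self):
        sing = np.zeros((2, 2))
        s = sensitivity(np.ones(2), sing)  # ridge rescues an all-zero matrix
        assert np.all(np.isfinite(s.H))
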