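"""Likelihood, fitting, AICc and profile-likelihood machinery."""

import numpy as np
import pytest

from focusdyn.inference import (CHI2_95_DROP, Channel, Dataset, FitProblem,
                                ParamBound, aicc, delta_aicc, fit, joint_fit,
                                log_likelihood, profile_ci, reduced_chisq)
from focusdyn.models import ModelSpec, ODEParams, simulate


def make_dataset(times, xbar, sd, n=20, kind="infected_cells",
                 error_model="absolute"):
    return Dataset(channels=(Channel(kind=kind, times=np.asarray(times),
                                     xbar=np.asarray(xbar, dtype=float),
                                     sd=np.asarray(sd, dtype=float),
                                     n_reps=n, error_model=error_model),))


class GaussianMeanProblem:
    """Toy likelihood with known sigma: l(mu) = -sum (x-mu)^2 / (2 s^2).

    Used as a closed-form oracle for the profile-CI machinery: the 95%
    interval must equal xbar +/- 1.96 * s / sqrt(n).
    """

    def __init__(self, x, sigma):
        self.x = np.asarray(x, dtype=float)
        self.sigma = sigma
        self.free = {"mu": ParamBound(-100.0, 100.0, "linear", init=0.0)}

    @property
    def n_points(self):
        return self.x.size

    def loglik(self, values):
        return float(-0.5 * np.sum((self.x - values["mu"]) ** 2)
                     / self.sigma**2)


class TestLogLikelihood:
    def test_perfect_fit_reduces_to_normalization(self):
        ds = make_dataset([1, 2, 3], [5.0, 6.0, 7.0], [2.0, 2.0, 2.0], n=4)
        sme = 0.5
        var = 4.0 / 4 + 0.25
        ll = log_likelihood([np.array([5.0, 6.0, 7.0])], ds, sme)
        assert ll == pytest.approx(-0.5 * 3 * np.log(var))

    def test_monotone_in_residual_magnitude(self):
        ds = make_dataset([1, 2], [1.0, 2.0], [1.0, 1.0])
        lls = [log_likelihood([np.array([1.0 + d, 2.0])], ds, 0.3)
               for d in (0.0, 0.5, 1.0, 2.0)]
        assert all(a > b for a, b in zip(lls, lls[1:]))

    def test_gradient_matches_finite_differences(self):
        """Analytic d l / d f_k = (xbar_k - f_k) / sigma_k^2."""
        ds = make_dataset([1, 2, 3], [2.0, 4.0, 8.0], [1.0, 2.0, 0.5], n=10)
        f = np.array([2.5, 3.0, 9.0])
        sme = 0.7
        var = ds.channels[0].sd**2 / 10 + sme**2
        eps = 1e-6
        for k in range(3):
            up, down = f.copy(), f.copy()
            up[k] += eps
            down[k] -= eps
            num = (log_likelihood([up], ds, sme)
                   - log_likelihood([down], ds, sme)) / (2 * eps)
            assert num == pytest.approx((ds.channels[0].xbar[k] - f[k])
                                        / var[k], rel=1e-4)

    def test_zero_variance_rejected(self):
        ds = make_dataset([1], [1.0], [0.0])
        with pytest.raises(ValueError):
            log_likelihood([np.array([1.0])], ds, 0.0)

    def test_relative_channel_guards_nonpositive_predictions(self):
        ds = make_dataset([1], [2.0], [0.5], error_model="relative")
        assert log_likelihood([np.array([-1.0])], ds, 0.1) == -np.inf


class TestAICc:
    def test_formula_arithmetic(self):
        assert aicc(0.0, 2, 10) == pytest.approx(4 + 12 / 7)
        with pytest.raises(ValueError):
            aicc(0.0, 9, 10)

    def test_penalty_strictly_increases_with_k(self):
        assert aicc(-5.0, 3, 12) > aicc(-5.0, 2, 12)

    def test_deltas_relative_to_best(self):
        class F:
            def __init__(self, a):
                self.aicc = a
        deltas = delta_aicc([F(10.0), F(7.5), F(30.0)])
        assert deltas == [2.5, 0.0, 22.5]


def _cc_problem(dataset, T0=5000.0, free_sigma=True):
    free = {"beta_c": ParamBound(1e-9, 1e-3, "log", init=1e-6)}
    if free_sigma:
        free["sigma_me"] = ParamBound(1e-4, 1e3, "log", init=1.0)
    return FitProblem(spec=ModelSpec.from_name("CC"), dataset=dataset,
                      base=ODEParams(T0=T0, I0=1.0), free=free, t0=0.0)


class TestFit:
    def test_noiseless_self_consistency(self):
        """Data generated by CC at known beta_c is recovered to 0.1%."""
        true = 2e-6
        times = np.arange(24.0, 241.0, 24.0)
        traj = simulate(ModelSpec.from_name("CC"),
                        ODEParams(T0=5000.0, I0=1.0, beta_c=true),
                        np.concatenate([[0.0], times]))
        ds = make_dataset(times, traj["I"][1:], np.full(times.size, 1.0))
        res = fit(_cc_problem(ds), n_restarts=4, seed=0)
        assert res.estimates["beta_c"] == pytest.approx(true, rel=1e-3)

    def test_deterministic_given_seed(self):
        times = np.arange(24.0, 241.0, 24.0)
        traj = simulate(ModelSpec.from_name("CC"),
                        ODEParams(T0=5000.0, I0=1.0, beta_c=2e-6),
                        np.concatenate([[0.0], times]))
        ds = make_dataset(times, traj["I"][1:] * 1.03,
                          np.full(times.size, 2.0))
        r1 = fit(_cc_problem(ds), n_restarts=3, seed=42)
        r2 = fit(_cc_problem(ds), n_restarts=3, seed=42)
        assert r1.estimates == r2.estimates
        assert r1.loglik == r2.loglik

    def test_joint_of_identical_datasets_matches_single(self):
        times = np.arange(24.0, 241.0, 24.0)
        traj = simulate(ModelSpec.from_name("CC"),
                        ODEParams(T0=5000.0, I0=1.0, beta_c=2e-6),
                        np.concatenate([[0.0], times]))
        ds = make_dataset(times, traj["I"][1:] * 1.05,
                          np.full(times.size, 2.0))
        single = fit(_cc_problem(ds), n_restarts=3, seed=0)
        p1, p2 = _cc_problem(ds), _cc_problem(ds)
        p1.name, p2.name = "a", "b"
        joint = joint_fit([p1, p2], shared=("beta_c", "sigma_me"),
                          n_restarts=3, seed=0)
        assert joint.estimates["beta_c"] == pytest.approx(
            single.estimates["beta_c"], rel=1e-3)


class TestProfileCI:
    def test_matches_gaussian_closed_form(self):
        rng = np.random.default_rng(0)
        sigma, n = 2.0, 25
        x = rng.normal(3.0, sigma, n)
        prob = GaussianMeanProblem(x, sigma)
        res = joint_fit([prob], n_restarts=4, seed=0)
        mu_hat = res.estimates["mu"]
        assert mu_hat == pytest.approx(x.mean(), abs=1e-4)
        ci = profile_ci([prob], res, "mu", n_grid=200, seed=0)
        half = 1.96 * sigma / np.sqrt(n)
        assert ci.identifiable
        assert ci.lower == pytest.approx(x.mean() - half, abs=0.02)
        assert ci.upper == pytest.approx(x.mean() + half, abs=0.02)

    def test_boundary_parameter_gives_one_sided_interval(self):
        """A parameter whose likelihood rises toward the lower bound."""
        class Decreasing:
            free = {"a": ParamBound(1e-3, 10.0, "log", init=1.0)}
            n_points = 5

            def loglik(self, values):
                return -5.0 * values["a"]

        prob = Decreasing()
        res = joint_fit([prob], n_restarts=4, seed=0)
        ci = profile_ci([prob], res, "a", n_grid=30, seed=0)
        assert ci.lower_open and not ci.upper_open
        assert not ci.identifiable

    def test_flat_profile_flagged_nonidentifiable(self):
        class Flat:
            free = {"a": ParamBound(1e-3, 10.0, "log", init=1.0)}
            n_points = 5

            def loglik(self, values):
                return 0.0

        prob = Flat()
        res = joint_fit([prob], n_restarts=2, seed=0)
        ci = profile_ci([prob], res, "a", n_grid=10, seed=0)
        assert not ci.identifiable
        assert ci.lower_open and ci.upper_open


class TestReducedChisq:
    def test_perfect_fit_is_zero(self):
        times = np.arange(24.0, 241.0, 24.0)
        traj = simulate(ModelSpec.from_name("CC"),
                        ODEParams(T0=5000.0, I0=1.0, beta_c=2e-6),
                        np.concatenate([[0.0], times]))
        ds = make_dataset(times, traj["I"][1:], np.full(times.size, 3.0))
        prob = _cc_problem(ds)
        chi = reduced_chisq(prob, {"beta_c": 2e-6, "sigma_me": 1.0})
        assert chi == pytest.approx(0.0, abs=1e-6)

    def test_one_sigma_residuals_scale(self):
        """Residuals of exactly one standard error give ~ n/(n-k)."""
        times = np.arange(24.0, 241.0, 24.0)
        traj = simulate(ModelSpec.from_name("CC"),
                        ODEParams(T0=5000.0, I0=1.0, beta_c=2e-6),
                        np.concatenate([[0.0], times]))
        n_reps = 16
        se = 2.0
        ds = make_dataset(times, traj["I"][1:] + se,
                          np.full(times.size, se * np.sqrt(n_reps)),
                          n=n_reps)
        prob = _cc_problem(ds, free_sigma=False)
        chi = reduced_chisq(prob, {"beta_c": 2e-6})
        n_pts, k = times.size, 1
        assert chi == pytest.approx(n_pts / (n_pts - k), rel=1e-6)
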