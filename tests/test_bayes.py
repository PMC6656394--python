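"""Joint posterior density, MCMC sampler correctness and calibration."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.distance import cdist

import kpsize as kp
from kpsize.bayes import ModelState, PriorSpec
from kpsize.regression import AreaRecord, RegressionObservation
from kpsize.spatial import JITTER


def obs(y, w=1.0, x=(1.0, 0.0, 0.0), area_id="a"):
    return RegressionObservation(area_id, "m", y, w, tuple(x))


def site(i, lon, lat, H):
    return AreaRecord(f"s{i}", f"s{i}", lon, lat, 1000.0, H)


def oracle_log_posterior(state, observations, areas, priors=PriorSpec()):
    """Independent term-by-term re-summation using scipy densities."""
    lp = 0.0
    for o in observations:
        mean = float(np.dot(o.x, state.beta))
        lp += stats.norm.logpdf(o.y, mean, math.sqrt(state.tau2 * o.w))
    observed = [a for a in areas if a.has_H]
    if observed:
        coords = np.array([a.coords for a in observed])
        H = np.array([a.H for a in observed])
        K = state.sigma2 * np.exp(-state.phi * cdist(coords, coords))
        K += np.eye(len(observed)) * JITTER * state.sigma2
        lp += stats.multivariate_normal(
            np.full(len(observed), state.mu), K
        ).logpdf(H)
    for b in state.beta:
        lp += stats.norm.logpdf(b, 0, math.sqrt(priors.beta_var))
    lp += stats.norm.logpdf(state.mu, priors.mu_mean,
                            math.sqrt(priors.mu_var))
    lp += stats.uniform.logpdf(state.phi, 0, priors.phi_upper)
    lp += stats.gamma.logpdf(1 / state.tau2, priors.tau2_shape,
                             scale=1 / priors.tau2_rate) \
        - 2 * math.log(state.tau2)  # Jacobian of v -> 1/v
    lp += stats.gamma.logpdf(1 / state.sigma2, priors.sigma2_shape,
                             scale=1 / priors.sigma2_rate) \
        - 2 * math.log(state.sigma2)
    return lp


class TestLogPosterior:
    def test_outside_uniform_support(self):
        state = ModelState(np.zeros(3), 1.0, 0.0, 1.0, 10.5)
        assert kp.log_posterior(state, [], []) == -np.inf

    def test_regression_term_at_the_mode(self):
        """A single observation at its fitted mean with unit variance
        contributes the standard-normal constant -log(2*pi)/2."""
        state = ModelState(np.array([-3.0, 0.0, 0.0]), 1.0, 2.0, 1.0, 5.0)
        areas = [site(0, 0, 0, 2.0)]  # H = mu
        with_obs = kp.log_posterior(state, [obs(-3.0)], areas)
        without = kp.log_posterior(state, [], areas)
        assert with_obs - without == pytest.approx(-0.5 * math.log(2 * math.pi))

    def test_matches_term_by_term_oracle(self, default_study):
        observations = kp.prepare_observations(
            default_study.estimates, default_study.areas
        )
        areas = [a for a in default_study.areas if a.has_H][:5]
        state = ModelState(np.array([2.62, -0.79, 0.63]), 0.65, 2.55, 0.86,
                           7.68)
        ours = kp.log_posterior(state, observations, areas)
        oracle = oracle_log_posterior(state, observations, areas)
        assert ours == pytest.approx(oracle, abs=1e-10)

    def test_reduces_to_wls_loglik_plus_priors(self, rng):
        """tau2*w = 1 and no GP data: the data part is exactly the
        weighted-least-squares Gaussian log likelihood."""
        X = np.column_stack([np.ones(8), rng.normal(size=8),
                             rng.normal(size=8)])
        beta = np.array([1.0, -0.5, 0.2])
        y = X @ beta + rng.normal(size=8)
        observations = [obs(y[i], 1.0, tuple(X[i])) for i in range(8)]
        state = ModelState(beta, 1.0, 0.0, 1.0, 5.0)
        prior_only = kp.log_posterior(
            ModelState(beta, 1.0, 0.0, 1.0, 5.0), [], []
        )
        wls = float(np.sum(stats.norm.logpdf(y, X @ beta, 1.0)))
        assert kp.log_posterior(state, observations, []) == pytest.approx(
            prior_only + wls, abs=1e-10
        )


class TestPosteriorSummary:
    def test_constant_draws(self):
        d = kp.PosteriorDraws(np.full((200, 3), 2.0), np.full(200, 0.5),
                              np.full(200, 1.0), np.full(200, 1.0),
                              np.full(200, 5.0))
        s = kp.posterior_summary(d)
        assert s.loc["beta0"].tolist() == pytest.approx([2.0, 2.0, 2.0])

    def test_quantile_rule_on_integer_ladder(self):
        x = np.arange(1.0, 1001.0)
        d = kp.PosteriorDraws(np.column_stack([x, x, x]), x, x, x, x)
        s = kp.posterior_summary(d)
        assert s.loc["tau2", "median"] == pytest.approx(500.5)
        assert s.loc["tau2", "q_low"] == pytest.approx(25.975)
        assert s.loc["tau2", "q_high"] == pytest.approx(975.025)

    def test_minimum_draw_count(self):
        x = np.ones(50)
        d = kp.PosteriorDraws(np.column_stack([x, x, x]), x, x, x, x)
        with pytest.raises(ValueError):
            kp.posterior_summary(d)


class TestSampler:
    def test_deterministic_given_seed(self, default_study):
        observations = kp.prepare_observations(
            default_study.estimates, default_study.areas
        )
        areas = [a for a in default_study.areas if a.has_H]
        cfg = kp.MCMCConfig(n_iter=800, n_burn=400, seed=9)
        a = kp.run_mcmc(observations, areas, cfg)
        b = kp.run_mcmc(observations, areas, cfg)
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.phi, b.phi)

    def test_two_seeds_agree_within_posterior_spread(self, default_study):
        observations = kp.prepare_observations(
            default_study.estimates, default_study.areas
        )
        areas = [a for a in default_study.areas if a.has_H]
        d1 = kp.run_mcmc(observations, areas,
                         kp.MCMCConfig(n_iter=4000, n_burn=2000, seed=1))
        d2 = kp.run_mcmc(observations, areas,
                         kp.MCMCConfig(n_iter=4000, n_burn=2000, seed=2))
        f1, f2 = d1.to_frame(), d2.to_frame()
        for name in f1.columns:
            gap = abs(f1[name].median() - f2[name].median())
            assert gap < 0.5 * f1[name].std(), name

    def test_fixed_parameters_stay_fixed(self):
        d = kp.run_mcmc([], [], kp.MCMCConfig(n_iter=300, n_burn=100, seed=0),
                        fixed={"mu": 1.5, "phi": 3.0})
        assert np.all(d.mu == 1.5) and np.all(d.phi == 3.0)


class TestSimulationBasedCalibration:
    """Draw parameters from the prior, data from the model, and check the
    rank of each true parameter among its posterior draws is uniform."""

    N_SIMS = 40
    N_BINS = 4
    THIN = 50

    def test_rank_statistics_uniform(self):
        # narrow proper priors: generating y from the shipped N(0, 1e6)
        # coefficient priors produces astronomically overflowing fractions;
        # the positive-centered GP mean keeps generated prevalences >= 0
        priors = PriorSpec(beta_var=1.0, mu_mean=5.0, mu_var=1.0,
                           phi_upper=10.0, tau2_shape=4.0, tau2_rate=2.0,
                           sigma2_shape=4.0, sigma2_rate=2.0)
        rng = np.random.default_rng(2024)
        coords = rng.uniform(0, 1, (10, 2))
        logN = rng.uniform(8, 12, 10)
        w = rng.uniform(0.2, 1.0, (10, 2))
        D = cdist(coords, coords)
        ranks = {k: [] for k in
                 ["beta0", "beta1", "beta2", "tau2", "mu", "sigma2", "phi"]}
        for s in range(self.N_SIMS):
            while True:  # redraw in the (rare) case of a negative prevalence
                beta = rng.normal(0, 1, 3)
                tau2 = 1 / rng.gamma(4.0, 1 / 2.0)
                mu = rng.normal(5.0, 1.0)
                sigma2 = 1 / rng.gamma(4.0, 1 / 2.0)
                phi = rng.uniform(0, 10)
                K = sigma2 * np.exp(-phi * D) + np.eye(10) * JITTER * sigma2
                H = rng.multivariate_normal(np.full(10, mu), K)
                if np.all(H >= 0):
                    break
            areas = [site(i, *coords[i], float(H[i])) for i in range(10)]
            observations = []
            for i in range(10):
                x = (1.0, float(logN[i]), float(H[i]))
                for j in range(2):
                    y = rng.normal(np.dot(x, beta),
                                   math.sqrt(tau2 * w[i, j]))
                    observations.append(obs(y, float(w[i, j]), x, f"s{i}"))
            draws = kp.run_mcmc(
                observations, areas,
                kp.MCMCConfig(n_iter=2000, n_burn=1000, seed=10_000 + s),
                priors=priors,
            )
            thin = draws.to_frame().iloc[:: self.THIN]
            truth = dict(beta0=beta[0], beta1=beta[1], beta2=beta[2],
                         tau2=tau2, mu=mu, sigma2=sigma2, phi=phi)
            for name, tv in truth.items():
                ranks[name].append(int(np.sum(thin[name].to_numpy() < tv)))
        L = math.ceil(1000 / self.THIN) + 1  # ranks take values 0..L-1
        for name, r in ranks.items():
            counts = np.bincount(
                np.minimum(np.array(r) * self.N_BINS // L, self.N_BINS - 1),
                minlength=self.N_BINS,
            )
            chi2 = np.sum(
                (counts - self.N_SIMS / self.N_BINS) ** 2
                / (self.N_SIMS / self.N_BINS)
            )
            p = stats.chi2.sf(chi2, self.N_BINS - 1)
            assert p > 0.01, f"{name}: SBC chi-square p={p:.4f} ({counts})"
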