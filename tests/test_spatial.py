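"""Variogram, GP likelihood, kriging and LOOCV imputation."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.distance import cdist

import kpsize as kp
from kpsize.regression import AreaRecord
from kpsize.simulate import SimulationConfig, generate_areas
from kpsize.spatial import JITTER


def site(i, lon, lat, H):
    return AreaRecord(f"s{i}", f"s{i}", lon, lat, 1000.0, H)


#: compact window on which a decay of ~7.7 per degree leaves strong
#: nearest-neighbour correlation (as in the source analysis, where the
#: areas cluster much more densely than uniform-over-country placement)
COMPACT = dict(bbox=(-5.0, -4.0, 6.0, 7.0), missing_H_fraction=0.0)


class TestEmpiricalVariogram:
    def test_single_pair_mean_squared_difference(self):
        areas = [site(0, 0.0, 0.0, 2.0), site(1, 1.0, 0.0, 4.0)]
        bins = kp.empirical_variogram(areas, [0.5, 1.5])
        assert bins.values[0] == pytest.approx(4.0)  # (2-4)^2, no 1/2 factor
        assert bins.counts[0] == 1

    def test_constant_field_is_zero(self):
        areas = [site(i, float(i), 0.0, 3.3) for i in range(5)]
        bins = kp.empirical_variogram(areas, [0.0, 2.0, 5.0])
        assert np.all(bins.values[bins.counts > 0] == 0.0)

    def test_matches_exhaustive_pair_loop(self):
        areas = [site(0, 0, 0, 1.0), site(1, 1, 0, 2.0),
                 site(2, 1, 1, 3.0), site(3, 0, 1, 4.0)]
        edges = [0.0, 1.1, 2.0]
        bins = kp.empirical_variogram(areas, edges)
        # brute force over all 6 unordered pairs
        expected = {0: [], 1: []}
        for a, b in itertools.combinations(areas, 2):
            d = math.dist(a.coords, b.coords)
            k = 0 if d <= 1.1 else 1
            expected[k].append((a.H - b.H) ** 2)
        for k in (0, 1):
            assert bins.counts[k] == len(expected[k])
            assert bins.values[k] == pytest.approx(np.mean(expected[k]))

    def test_empty_bins_reported_as_missing(self):
        areas = [site(0, 0.0, 0.0, 1.0), site(1, 0.1, 0.0, 2.0)]
        bins = kp.empirical_variogram(areas, [0.0, 0.2, 5.0, 10.0])
        assert bins.counts[1] == bins.counts[2] == 0
        assert np.isnan(bins.values[1]) and np.isnan(bins.values[2])

    def test_requires_observed_areas(self):
        with pytest.raises(ValueError):
            kp.empirical_variogram([site(0, 0, 0, None)], [0, 1])


class TestVariogramCurveFit:
    @staticmethod
    def _bins(sigma2, phi, mids, counts=None):
        mids = np.asarray(mids, float)
        v = sigma2 * (1 - np.exp(-phi * mids))
        counts = np.ones_like(mids, int) * 10 if counts is None else counts
        edges = np.concatenate([[0.0], mids + np.diff(mids, prepend=0) / 2])
        return kp.VariogramBins(edges, mids, v, counts)

    def test_noiseless_inversion(self):
        bins = self._bins(1.0, 5.0, [0.05, 0.1, 0.2, 0.4, 0.8, 1.6])
        s2, phi = kp.fit_variogram_curve(bins)
        assert s2 == pytest.approx(1.0, abs=1e-6)
        assert phi == pytest.approx(5.0, abs=1e-5)

    def test_small_perturbation_small_error(self, rng):
        mids = [0.05, 0.1, 0.2, 0.4, 0.8, 1.6]
        bins = self._bins(1.0, 5.0, mids)
        bins.values = bins.values * (1 + rng.normal(0, 0.02, len(mids)))
        s2, phi = kp.fit_variogram_curve(bins)
        assert abs(s2 - 1.0) < 0.1 and abs(phi - 5.0) / 5.0 < 0.1

    def test_flat_variogram_unidentifiable(self):
        bins = self._bins(1.0, 5.0, [0.1, 0.2, 0.4])
        bins.values = np.full(3, 0.7)
        with pytest.raises(RuntimeError, match="unidentifiable"):
            kp.fit_variogram_curve(bins)


class TestGPLogLikelihood:
    def test_single_area_at_the_mean(self):
        p = kp.GPParams(mu=2.0, sigma2=1.7, phi=3.0)
        ll = kp.gp_log_likelihood(p, [site(0, 0, 0, 2.0)])
        assert ll == pytest.approx(-0.5 * math.log(2 * math.pi * 1.7),
                                   abs=1e-7)

    def test_distant_areas_factorize(self):
        p = kp.GPParams(mu=2.0, sigma2=1.0, phi=5.0)
        areas = [site(0, 0, 0, 2.5), site(1, 100, 0, 1.5)]
        ll = kp.gp_log_likelihood(p, areas)
        indep = sum(
            stats.norm.logpdf(a.H, 2.0, math.sqrt(1.0 + JITTER))
            for a in areas
        )
        assert ll == pytest.approx(indep, abs=1e-10)

    def test_matches_dense_mvn_oracle(self, rng):
        areas = [site(i, *rng.uniform(0, 1, 2), float(rng.normal(2.5, 1)))
                 for i in range(5)]
        p = kp.GPParams(mu=2.5, sigma2=0.9, phi=4.0)
        coords = np.array([a.coords for a in areas])
        H = np.array([a.H for a in areas])
        K = p.sigma2 * np.exp(-p.phi * cdist(coords, coords))
        K += np.eye(5) * JITTER * p.sigma2
        oracle = stats.multivariate_normal(np.full(5, p.mu), K).logpdf(H)
        assert kp.gp_log_likelihood(p, areas) == pytest.approx(oracle,
                                                               abs=1e-8)

    def test_permutation_invariant(self, rng):
        areas = [site(i, *rng.uniform(0, 1, 2), float(rng.normal(2.5, 1)))
                 for i in range(6)]
        p = kp.GPParams(mu=2.0, sigma2=1.0, phi=2.0)
        perm = [areas[i] for i in rng.permutation(6)]
        assert kp.gp_log_likelihood(p, areas) == pytest.approx(
            kp.gp_log_likelihood(p, perm), rel=1e-12
        )


class TestKriging:
    def test_exact_interpolation_at_observed_site(self):
        p = kp.GPParams(2.0, 1.0, 3.0)
        areas = [site(0, 0, 0, 3.1), site(1, 1, 1, 1.9)]
        mean, var = kp.krige(p, areas, np.array([[0.0, 0.0]]))
        assert mean[0] == pytest.approx(3.1)
        assert var[0] == 0.0

    def test_prior_limit_far_from_data(self):
        p = kp.GPParams(2.0, 1.3, 3.0)
        areas = [site(0, 0, 0, 3.1)]
        mean, var = kp.krige(p, areas, np.array([[500.0, 500.0]]))
        assert mean[0] == pytest.approx(2.0, abs=1e-9)
        assert var[0] == pytest.approx(1.3, abs=1e-9)

    def test_matches_conditional_mvn_oracle(self):
        p = kp.GPParams(mu=2.5, sigma2=0.8, phi=4.0)
        areas = [site(0, 0.0, 0.0, 3.0), site(1, 0.3, 0.1, 2.2)]
        tgt = np.array([[0.1, 0.25]])
        mean, var = kp.krige(p, areas, tgt)
        coords = np.array([a.coords for a in areas])
        H = np.array([3.0, 2.2])
        K = p.sigma2 * np.exp(-p.phi * cdist(coords, coords))
        K += np.eye(2) * JITTER * p.sigma2
        k = (p.sigma2 * np.exp(-p.phi * cdist(coords, tgt)))[:, 0]
        mo = p.mu + k @ np.linalg.solve(K, H - p.mu)
        vo = p.sigma2 - k @ np.linalg.solve(K, k)
        assert mean[0] == pytest.approx(mo, abs=1e-8)
        assert var[0] == pytest.approx(vo, abs=1e-8)

    def test_variance_bounded_and_shrinks_with_data(self, rng):
        p = kp.GPParams(2.5, 1.0, 3.0)
        areas = [site(i, *rng.uniform(0, 1, 2), float(rng.normal(2.5, 1)))
                 for i in range(8)]
        tgt = np.array([[0.5, 0.5]])
        prev = np.inf
        for n in range(1, 9):
            _, var = kp.krige(p, areas[:n], tgt)
            assert 0.0 <= var[0] <= p.sigma2
            assert var[0] <= prev + 1e-12
            prev = var[0]


class TestMLEAndLOOCV:
    def test_mle_recovers_truth_at_100_sites(self):
        errs = {"mu": [], "sigma2": [], "phi": []}
        truth = kp.GPParams(2.55, 0.86, 7.68)
        for seed in range(20):
            areas = generate_areas(
                SimulationConfig(seed=seed, n_areas=100, gp=truth, **COMPACT)
            )
            est = kp.fit_gp_mle(areas)
            errs["mu"].append(abs(est.mu - truth.mu) / truth.mu)
            errs["sigma2"].append(abs(est.sigma2 - truth.sigma2) / truth.sigma2)
            errs["phi"].append(abs(est.phi - truth.phi) / truth.phi)
        for name, e in errs.items():
            assert np.median(e) < 0.25, f"{name}: median error {np.median(e)}"

    def test_constant_field_gives_zero_loocv(self):
        areas = [site(i, float(i), 0.0, 2.0) for i in range(5)]
        assert kp.loocv_imputation_mse(areas, "mean") == pytest.approx(0.0)
        assert kp.loocv_imputation_mse(areas, "kriging") == pytest.approx(
            0.0, abs=1e-6
        )

    def test_no_spatial_signal_control(self):
        """With an essentially i.i.d. field the two imputers should tie."""
        diffs = []
        for seed in range(20):
            areas = generate_areas(
                SimulationConfig(seed=seed, n_areas=31,
                                 gp=kp.GPParams(2.55, 0.86, 300.0), **COMPACT)
            )
            mk = kp.loocv_imputation_mse(areas, "kriging")
            mm = kp.loocv_imputation_mse(areas, "mean")
            diffs.append(abs(mk - mm) / mm)
        assert np.mean(diffs) < 0.10
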