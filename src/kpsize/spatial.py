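"""Spatial Gaussian-process model for HIV prevalence.

Prevalence at area coordinates ``s`` is modelled as a stationary GP with a
constant mean and exponential covariance,

    Cov(H(s_i), H(s_j)) = sigma2 * exp(-phi * ||s_i - s_j||),

with ``||.||`` the Euclidean distance on (lon, lat) in decimal degrees.
Missing prevalence values are imputed by kriging — the conditional normal
of the GP given the observed areas.  The empirical variogram (average
squared prevalence difference per distance bin) is used as a diagnostic
and to initialize maximum-likelihood estimation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist

from .regression import AreaRecord

#: Relative jitter added to the covariance diagonal to stabilize Cholesky
#: factorizations (there is no nugget term in the model).
JITTER = 1e-8


@dataclass(frozen=True)
class GPParams:
    """Mean (percent), marginal variance (percent^2) and decay (per degree)."""

    mu: float
    sigma2: float
    phi: float

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError(f"sigma2 must be > 0, got {self.sigma2}")
        if self.phi <= 0:
            raise ValueError(f"phi must be > 0, got {self.phi}")


@dataclass
class VariogramBins:
    """Binned empirical variogram: midpoints, per-bin values, pair counts."""

    edges: np.ndarray
    midpoints: np.ndarray
    values: np.ndarray  # NaN for empty bins
    counts: np.ndarray

    def nonempty(self) -> "VariogramBins":
        keep = self.counts > 0
        return VariogramBins(
            self.edges, self.midpoints[keep], self.values[keep], self.counts[keep]
        )


def _observed(areas: Sequence[AreaRecord]) -> tuple[np.ndarray, np.ndarray]:
    obs = [a for a in areas if a.has_H]
    coords = np.array([a.coords for a in obs], float).reshape(len(obs), 2)
    H = np.array([a.H for a in obs], float)
    return coords, H


def exponential_covariance(
    coords_a: np.ndarray, coords_b: np.ndarray, sigma2: float, phi: float
) -> np.ndarray:
    """Dense covariance block sigma2 * exp(-phi * D) between two site sets."""
    return sigma2 * np.exp(-phi * cdist(coords_a, coords_b))


def empirical_variogram(
    areas: Sequence[AreaRecord], edges: Sequence[float]
) -> VariogramBins:
    """Average squared prevalence difference per distance bin.

    For every unordered pair of observed areas whose Euclidean distance
    falls in bin k the squared difference ``(H_i - H_j)**2`` is accumulated;
    the bin value is the plain average over its pairs (no 1/2 factor, so the
    theoretical curve for the exponential GP is ``sigma2*(1 - exp(-phi*m))``
    up to the factor-two convention of this estimator).  Empty bins carry
    count 0 and value NaN.
    """
    coords, H = _observed(areas)
    if len(H) < 2:
        raise ValueError("need at least 2 areas with observed prevalence")
    edges = np.asarray(edges, float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing with >= 2 entries")
    iu, ju = np.triu_indices(len(H), k=1)
    d = np.linalg.norm(coords[iu] - coords[ju], axis=1)
    sq = (H[iu] - H[ju]) ** 2
    # right-closed bins (I_{k-1}, I_k]; the lowest edge is inclusive too
    k = np.searchsorted(edges, d, side="left") - 1
    k[d == edges[0]] = 0
    nbins = len(edges) - 1
    in_range = (k >= 0) & (k < nbins)
    values = np.full(nbins, np.nan)
    counts = np.zeros(nbins, int)
    for b in range(nbins):
        mask = in_range & (k == b)
        counts[b] = int(mask.sum())
        if counts[b]:
            values[b] = sq[mask].mean()
    mids = 0.5 * (edges[:-1] + edges[1:])
    return VariogramBins(edges=edges, midpoints=mids, values=values, counts=counts)


def fit_variogram_curve(bins: VariogramBins) -> tuple[float, float]:
    """Weighted least-squares fit of ``sigma2 * (1 - exp(-phi m))``.

    Bins are weighted by their pair counts.  Used for diagnostics and to
    initialize the MLE; not itself an estimator of record.  Returns
    ``(sigma2, phi)``.

    Raises
    ------
    RuntimeError
        On non-convergence or when the bins carry no distance signal
        (a flat variogram leaves phi unidentifiable).
    """
    nb = bins.nonempty()
    if len(nb.values) < 3:
        raise ValueError("need >= 3 nonempty bins to fit the variogram curve")
    m, v, c = nb.midpoints, nb.values, nb.counts
    if np.ptp(v) < 1e-12 * max(1.0, abs(v).max()):
        raise RuntimeError(
            "flat empirical variogram: decay rate phi is unidentifiable"
        )
    s0 = float(v.max())
    half = v >= 0.5 * s0
    m_half = m[half].min() if half.any() else m.mean()
    p0 = (s0 if s0 > 0 else 1.0, math.log(2.0) / max(m_half, 1e-6))
    try:
        popt, _ = optimize.curve_fit(
            lambda mm, s2, ph: s2 * (1.0 - np.exp(-ph * mm)),
            m,
            v,
            p0=p0,
            sigma=1.0 / np.sqrt(c),
            bounds=([1e-12, 1e-8], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"variogram curve fit failed to converge (start {p0})"
        ) from exc
    return float(popt[0]), float(popt[1])


def _chol(coords: np.ndarray, sigma2: float, phi: float):
    K = exponential_covariance(coords, coords, sigma2, phi)
    K[np.diag_indices_from(K)] += JITTER * sigma2
    try:
        return cho_factor(K, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - jittered
        raise RuntimeError("covariance not positive definite after jitter") from exc


def gp_log_likelihood(params: GPParams, areas: Sequence[AreaRecord]) -> float:
    """Log density of the observed prevalences under the exponential GP."""
    coords, H = _observed(areas)
    if len(H) == 0:
        raise ValueError("no areas with observed prevalence")
    cf = _chol(coords, params.sigma2, params.phi)
    r = H - params.mu
    alpha = cho_solve(cf, r)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    return float(-0.5 * (len(H) * math.log(2 * math.pi) + logdet + r @ alpha))


def krige(
    params: GPParams,
    areas: Sequence[AreaRecord],
    targets: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Kriging (conditional-normal) prediction at target coordinates.

    mean = mu + v(s)' Sigma^{-1} (H - mu 1),  var = sigma2 - v(s)' Sigma^{-1} v(s)

    A target that coincides exactly with an observed site returns that
    site's value with variance 0.  Targets far from all data revert to the
    prior ``(mu, sigma2)``.  Returns arrays shaped like ``targets[:, 0]``.
    """
    coords, H = _observed(areas)
    if len(H) == 0:
        raise ValueError("kriging requires at least one observed area")
    targets = np.atleast_2d(np.asarray(targets, float))
    cf = _chol(coords, params.sigma2, params.phi)
    V = exponential_covariance(coords, targets, params.sigma2, params.phi)
    alpha = cho_solve(cf, H - params.mu)
    mean = params.mu + V.T @ alpha
    SinvV = cho_solve(cf, V)
    var = params.sigma2 - np.einsum("ij,ij->j", V, SinvV)
    var = np.clip(var, 0.0, params.sigma2)
    # exact-interpolation special case: coincident target <- observed value
    D = cdist(targets, coords)
    hit_t, hit_o = np.nonzero(D == 0.0)
    mean[hit_t] = H[hit_o]
    var[hit_t] = 0.0
    return mean, var


def fit_gp_mle(
    areas: Sequence[AreaRecord],
    phi_bounds: tuple[float, float] = (1e-3, 100.0),
) -> GPParams:
    """Maximum-likelihood GP parameters via the profile likelihood.

    For fixed ``phi`` the mean has the closed-form GLS solution and the
    variance its plug-in estimate, leaving a one-dimensional bounded search
    over ``phi`` (initialized, when possible, from the variogram curve fit).
    """
    coords, H = _observed(areas)
    n = len(H)
    if n < 3:
        raise ValueError("need >= 3 observed areas for MLE")

    def profile(phi: float) -> tuple[float, float, float]:
        cf = _chol(coords, 1.0, phi)  # correlation matrix factor
        one = np.ones(n)
        Rinv1 = cho_solve(cf, one)
        mu = float(H @ Rinv1 / (one @ Rinv1))
        r = H - mu
        s2 = float(r @ cho_solve(cf, r) / n)
        s2 = max(s2, 1e-12)
        logdetR = 2.0 * np.sum(np.log(np.diag(cf[0])))
        nll = 0.5 * (n * math.log(2 * math.pi * s2) + logdetR + n)
        return nll, mu, s2

    res = optimize.minimize_scalar(
        lambda p: profile(p)[0], bounds=phi_bounds, method="bounded",
        options={"xatol": 1e-6},
    )
    if not res.success:  # pragma: no cover - bounded search always returns
        raise RuntimeError(f"GP MLE failed: {res.message}")
    _, mu, s2 = profile(res.x)
    return GPParams(mu=mu, sigma2=s2, phi=float(res.x))


def loocv_imputation_mse(
    areas: Sequence[AreaRecord],
    method: Literal["kriging", "mean"] = "kriging",
) -> float:
    """Leave-one-out MSE of prevalence imputation (percent^2).

    Each observed area is held out in turn; the imputer is refit on the
    rest (full MLE for kriging, the arithmetic mean for mean imputation)
    and the held-out prevalence predicted.  Folds whose MLE fails are
    skipped with a warning.
    """
    obs = [a for a in areas if a.has_H]
    if len(obs) < 3:
        raise ValueError("need >= 3 observed areas for leave-one-out")
    errors = []
    for i, held in enumerate(obs):
        rest = obs[:i] + obs[i + 1 :]
        if method == "mean":
            pred = float(np.mean([a.H for a in rest]))
        elif method == "kriging":
            try:
                params = fit_gp_mle(rest)
            except (RuntimeError, ValueError) as exc:
                warnings.warn(
                    f"skipping fold {held.area_id!r}: MLE failed ({exc})",
                    stacklevel=2,
                )
                continue
            mean, _ = krige(params, rest, np.array([held.coords]))
            pred = float(mean[0])
        else:
            raise ValueError(f"unknown method {method!r}")
        errors.append((pred - held.H) ** 2)
    if not errors:
        raise RuntimeError("all leave-one-out folds failed")
    return float(np.mean(errors))
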