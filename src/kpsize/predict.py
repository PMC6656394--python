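"""Composition-sampling posterior prediction of per-area MSM counts.

For each retained MCMC draw m the predicted log fraction for area s is

    y(m) = beta0(m) + beta1(m) * log(max(N(s), threshold)) + beta2(m) * H(m)(s)

where H(m)(s) is the observed prevalence when available and otherwise a
draw from the kriging conditional under the GP parameters of draw m — so
imputation uncertainty flows into the count intervals.  The log-population
covariate is floored at the 10% population quantile (the fitted negative
population slope is not extrapolated below it); the back-conversion
fraction -> count always uses the true N(s).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist

from .bayes import PosteriorDraws
from .regression import AreaRecord
from .spatial import JITTER


@dataclass
class PredictionSummary:
    """Posterior-predictive summary for one area."""

    area_id: str
    name: str
    n_median: float
    n_low: float
    n_high: float
    pct_median: float
    relative_width: float
    hiv_was_imputed: bool
    leverage: float | None = None

    def __post_init__(self) -> None:
        if not self.n_low <= self.n_median <= self.n_high:
            raise ValueError(
                f"{self.area_id}: interval must bracket the median"
            )
        if self.relative_width < 0:
            raise ValueError("relative width must be >= 0")


def sample_missing_H(
    draws: PosteriorDraws,
    observed_areas: Sequence[AreaRecord],
    targets: np.ndarray,
    rng: np.random.Generator,
    joint: bool = False,
) -> np.ndarray:
    """Kriging-conditional prevalence draws at target coordinates.

    One draw per MCMC iteration per target, under that iteration's GP
    parameters.  ``joint=False`` (default) draws each target from its own
    univariate conditional given the observed areas only; ``joint=True``
    draws all targets jointly from the full conditional MVN.  Negative
    draws are truncated at 0 (prevalence is nonnegative).  Returns an
    (M, n_targets) array.
    """
    obs = [a for a in observed_areas if a.has_H]
    if not obs:
        raise ValueError(
            "cannot impute prevalence: no areas with observed prevalence"
        )
    coords = np.array([a.coords for a in obs], float)
    H = np.array([a.H for a in obs], float)
    targets = np.atleast_2d(np.asarray(targets, float))
    D = cdist(coords, coords)
    Dt = cdist(coords, targets)
    Dtt = cdist(targets, targets)
    M = len(draws)
    out = np.empty((M, len(targets)))
    for m in range(M):
        mu, s2, phi = draws.mu[m], draws.sigma2[m], draws.phi[m]
        R = np.exp(-phi * D)
        R[np.diag_indices_from(R)] += JITTER
        cf = cho_factor(R, lower=True)
        Vt = np.exp(-phi * Dt)  # correlation scale; s2 cancels in the mean
        alpha = cho_solve(cf, (H - mu))
        mean = mu + Vt.T @ alpha
        A = cho_solve(cf, Vt)
        if joint and len(targets) > 1:
            C = s2 * (np.exp(-phi * Dtt) - Vt.T @ A)
            C[np.diag_indices_from(C)] += JITTER * s2
            L = np.linalg.cholesky(C)
            out[m] = mean + L @ rng.standard_normal(len(targets))
        else:
            var = s2 * np.clip(1.0 - np.einsum("ij,ij->j", Vt, A), 0.0, None)
            out[m] = mean + np.sqrt(var) * rng.standard_normal(len(targets))
        # exact interpolation at coincident sites: observed value, no noise
        hit_t, hit_o = np.nonzero(Dt.T == 0.0)
        out[m, hit_t] = H[hit_o]
    return np.clip(out, 0.0, None)


def predict_area(
    area: AreaRecord,
    draws: PosteriorDraws,
    observed_areas: Sequence[AreaRecord],
    threshold: float,
    seed: int | np.random.Generator | None = None,
    joint: bool = False,
) -> np.ndarray:
    """Posterior-predictive count draws for one area (persons)."""
    if len(draws) == 0:
        raise ValueError("no posterior draws")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if area.has_H:
        Hdraws = np.full(len(draws), float(area.H))
    else:
        Hdraws = sample_missing_H(
            draws, observed_areas, np.array([area.coords]), rng, joint=joint
        )[:, 0]
    logN = np.log(max(area.N_male, threshold))
    y = draws.beta[:, 0] + draws.beta[:, 1] * logN + draws.beta[:, 2] * Hdraws
    return area.N_male * np.exp(y)


def predict_all(
    areas: Sequence[AreaRecord],
    draws: PosteriorDraws,
    observed_areas: Sequence[AreaRecord],
    threshold: float,
    seed: int | np.random.Generator | None = None,
    joint: bool = False,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Count draws for every area, sharing the per-draw GP factorizations.

    Returns ``(counts, prevalence)`` — per-area count draws and the
    prevalence draws used (constant arrays for observed-H areas).
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    missing = [a for a in areas if not a.has_H]
    Hdraws = {}
    if missing:
        tgt = np.array([a.coords for a in missing], float)
        block = sample_missing_H(draws, observed_areas, tgt, rng, joint=joint)
        Hdraws = {a.area_id: block[:, j] for j, a in enumerate(missing)}
    counts = {}
    for a in areas:
        if a.has_H:
            Hdraws[a.area_id] = np.full(len(draws), float(a.H))
        Hm = Hdraws[a.area_id]
        logN = np.log(max(a.N_male, threshold))
        y = draws.beta[:, 0] + draws.beta[:, 1] * logN + draws.beta[:, 2] * Hm
        counts[a.area_id] = a.N_male * np.exp(y)
    return counts, Hdraws


def leverage(X: np.ndarray, x: np.ndarray) -> float:
    """Leverage score x' (X'X)^{-1} x of a covariate vector against a design.

    For rows of ``X`` this is the hat-matrix diagonal, in (0, 1]; for a
    new area it measures covariate extremity relative to the training
    design.
    """
    X = np.asarray(X, float)
    x = np.asarray(x, float)
    XtX = X.T @ X
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return float(x @ np.linalg.solve(XtX, x))


def summarize_predictions(
    count_draws: Mapping[str, np.ndarray],
    areas: Sequence[AreaRecord],
    ci: float = 0.95,
    design: np.ndarray | None = None,
    threshold: float | None = None,
    prevalence_draws: Mapping[str, np.ndarray] | None = None,
) -> list[PredictionSummary]:
    """Per-area medians, central intervals, relative widths and leverages.

    ``relative_width = (n_high - n_low) / n_median`` — a scale-free
    uncertainty measure suited to the roughly log-normal count draws.
    When a training ``design`` is given, each area's leverage is computed
    with its (truncated) log population and its observed prevalence, or
    the median of ``prevalence_draws`` for imputed areas.
    """
    alpha = 1.0 - ci
    out = []
    for a in areas:
        d = np.asarray(count_draws[a.area_id], float)
        if len(d) < 100:
            raise ValueError(f"area {a.area_id!r}: need >= 100 draws")
        med, lo, hi = np.quantile(d, [0.5, alpha / 2, 1 - alpha / 2])
        lev = None
        if design is not None:
            N_eff = max(a.N_male, threshold) if threshold else a.N_male
            if a.has_H:
                H_eff = float(a.H)
            elif prevalence_draws is not None:
                H_eff = float(np.median(prevalence_draws[a.area_id]))
            else:
                raise ValueError(
                    f"area {a.area_id!r}: leverage needs prevalence_draws "
                    "for imputed areas"
                )
            lev = leverage(design, np.array([1.0, np.log(N_eff), H_eff]))
        out.append(
            PredictionSummary(
                area_id=a.area_id,
                name=a.name,
                n_median=float(med),
                n_low=float(lo),
                n_high=float(hi),
                pct_median=float(100.0 * med / a.N_male),
                relative_width=float((hi - lo) / med) if med > 0 else 0.0,
                hiv_was_imputed=not a.has_H,
                leverage=lev,
            )
        )
    return out
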