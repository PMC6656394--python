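"""Synthetic studies with the statistical structure the analysis assumes.

The real survey records and covariate tables behind the Côte d'Ivoire
analysis are not publicly deposited, so every pipeline stage is exercised
on data generated here.  A synthetic study mirrors the study design:
~61 areas on the national bounding box, log-normal male 18–29 populations,
HIV prevalence drawn jointly from the exponential-covariance GP (floored
at 0), roughly half of the non-training areas with prevalence masked, and
3–5 multiplier-method direct estimates with log-scale CI half-widths in
the range implied by the published intervals (CI ratios ~1.3–3.2) for each
of the 5 training areas.  Defaults for the generative parameters are the
published posterior medians, so simulated data live on the same scale as
the real study.

Training areas are, by default, the largest areas by male population —
deliberately reproducing the extrapolation pathology that motivates the
population-truncation rule (the training data only cover large areas).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .multiplier import SOURCE_LABELS, DirectEstimate, RDSRespondent, SourceCount
from .regression import AreaRecord
from .spatial import GPParams

#: Côte d'Ivoire bounding box (lon_min, lon_max, lat_min, lat_max), degrees.
CIV_BBOX = (-8.6, -2.5, 4.4, 10.7)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic-study generator.

    Defaults are the study conditions: 61 areas, 5 training areas,
    generative parameters at the published posterior medians, ~50% of
    areas missing prevalence.
    """

    n_areas: int = 61
    n_training_areas: int = 5
    methods_per_area: tuple[int, int] = (3, 5)
    beta: tuple[float, float, float] = (2.62, -0.79, 0.63)
    tau2: float = 0.65
    gp: GPParams = field(default_factory=lambda: GPParams(2.55, 0.86, 7.68))
    missing_H_fraction: float = 0.5
    pop_meanlog: float = 9.6
    pop_sdlog: float = 1.0
    bbox: tuple[float, float, float, float] = CIV_BBOX
    ci_halfwidth_range: tuple[float, float] = (0.15, 0.6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_training_areas > self.n_areas:
            raise ValueError("n_training_areas must be <= n_areas")
        if not 0 <= self.missing_H_fraction < 1:
            raise ValueError("missing_H_fraction must be in [0, 1)")
        if self.tau2 < 0 or self.pop_sdlog <= 0:
            raise ValueError("variances must be positive")
        lo, hi = self.methods_per_area
        if not 1 <= lo <= hi:
            raise ValueError("methods_per_area must be an increasing range")


@dataclass
class SyntheticStudy:
    """One complete generated study."""

    areas: list[AreaRecord]
    estimates: list[DirectEstimate]
    true_fractions: dict[str, float]  # latent exp(x' beta) per area
    true_H: dict[str, float]  # prevalence before masking
    training_ids: list[str]
    config: SimulationConfig


def training_areas(
    areas: Sequence[AreaRecord], config: SimulationConfig
) -> list[AreaRecord]:
    """The ``n_training_areas`` largest areas by male population."""
    return sorted(areas, key=lambda a: -a.N_male)[: config.n_training_areas]


def generate_areas(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[AreaRecord]:
    """Area table: coordinates, populations, spatially correlated prevalence.

    Coordinates are uniform on the bounding box; N_male is log-normal;
    prevalence is one joint draw from the exponential-covariance GP,
    floored at 0.  The missing-prevalence mask is applied to non-training
    areas only (training areas must keep observed prevalence).  Auxiliary
    covariates (pop_density, density_change, landscan_density) are
    population-correlated noise, present for model-selection exercises.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lon0, lon1, lat0, lat1 = config.bbox
    if not (lon0 < lon1 and lat0 < lat1):
        raise ValueError("degenerate bounding box")
    n = config.n_areas
    lon = rng.uniform(lon0, lon1, n)
    lat = rng.uniform(lat0, lat1, n)
    N = np.exp(rng.normal(config.pop_meanlog, config.pop_sdlog, n))
    coords = np.column_stack([lon, lat])
    K = config.gp.sigma2 * np.exp(-config.gp.phi * cdist(coords, coords))
    K[np.diag_indices_from(K)] += 1e-8 * config.gp.sigma2
    H = rng.multivariate_normal(np.full(n, config.gp.mu), K,
                                method="cholesky")
    H = np.clip(H, 0.0, None)
    logN = np.log(N)
    pop_density = np.exp(0.9 * logN - 4.0 + rng.normal(0, 0.5, n))
    density_change = rng.normal(0.02, 0.01, n)
    landscan = np.exp(0.85 * logN - 3.0 + rng.normal(0, 0.7, n))

    train_idx = set(np.argsort(-N)[: config.n_training_areas])
    eligible = [i for i in range(n) if i not in train_idx]
    n_missing = int(round(config.missing_H_fraction * n))
    n_missing = min(n_missing, len(eligible))
    missing = set(rng.choice(eligible, size=n_missing, replace=False)) \
        if n_missing else set()

    areas = []
    for i in range(n):
        areas.append(
            AreaRecord(
                area_id=f"A{i:03d}",
                name=f"Area {i:03d}",
                lon=float(lon[i]),
                lat=float(lat[i]),
                N_male=float(N[i]),
                H=None if i in missing else float(H[i]),
                extra={
                    "pop_density": float(pop_density[i]),
                    "density_change": float(density_change[i]),
                    "landscan_density": float(landscan[i]),
                    "_true_H": float(H[i]),
                },
            )
        )
    return areas


def generate_direct_estimates(
    areas: Sequence[AreaRecord],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[DirectEstimate], dict[str, float]]:
    """Direct estimates for the training areas under the generative model.

    For each training area and method, a log-scale CI half-width ``h`` is
    drawn from the configured range, the response is sampled as
    ``y ~ N(x' beta, tau2 * (2h)^2)`` and emitted as the estimate
    ``n = N * exp(y)`` with CI ``(N e^{y-h}, N e^{y+h})``.  Sampled
    fractions >= 1 are resampled (capped, with a warning).  Returns the
    estimates and the latent true fraction ``exp(x' beta)`` per area.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    b0, b1, b2 = config.beta
    lo_m, hi_m = config.methods_per_area
    h_lo, h_hi = config.ci_halfwidth_range
    estimates: list[DirectEstimate] = []
    true_fractions: dict[str, float] = {}
    for area in training_areas(areas, config):
        if not area.has_H:
            raise ValueError(
                f"training area {area.area_id!r} has no observed prevalence"
            )
        mean_y = b0 + b1 * np.log(area.N_male) + b2 * area.H
        true_fractions[area.area_id] = float(np.exp(mean_y))
        n_methods = int(rng.integers(lo_m, hi_m + 1))
        for j in range(n_methods):
            label = SOURCE_LABELS[j % len(SOURCE_LABELS)]
            if j >= len(SOURCE_LABELS):
                label = f"{label}_{j // len(SOURCE_LABELS) + 1}"
            h = float(rng.uniform(h_lo, h_hi))
            sd = np.sqrt(config.tau2) * 2.0 * h
            y = float(rng.normal(mean_y, sd))
            for _ in range(100):
                if np.exp(y) < 1.0:
                    break
                y = float(rng.normal(mean_y, sd))
            else:
                warnings.warn(
                    f"area {area.area_id!r}: capping generated fraction at "
                    "0.99 after 100 resamples",
                    stacklevel=2,
                )
                y = float(np.log(0.99))
            n_hat = area.N_male * float(np.exp(y))
            estimates.append(
                DirectEstimate(
                    area_id=area.area_id,
                    method_label=label,
                    n_hat=n_hat,
                    ci_low=area.N_male * float(np.exp(y - h)),
                    ci_high=area.N_male * float(np.exp(y + h)),
                )
            )
    return estimates, true_fractions


def generate_study(config: SimulationConfig | None = None) -> SyntheticStudy:
    """Generate a full study (areas + direct estimates) from one seed."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    areas = generate_areas(config, rng)
    estimates, fractions = generate_direct_estimates(areas, config, rng)
    true_H = {a.area_id: a.extra["_true_H"] for a in areas}
    return SyntheticStudy(
        areas=areas,
        estimates=estimates,
        true_fractions=fractions,
        true_H=true_H,
        training_ids=[a.area_id for a in training_areas(areas, config)],
        config=config,
    )


def generate_rds_population(
    M: int,
    source_totals: dict[str, int],
    n_respondents: int,
    seed: int | np.random.Generator | None = None,
    mean_degree: float = 8.0,
) -> tuple[list[RDSRespondent], list[SourceCount]]:
    """A hidden population plus a degree-biased RDS-style sample.

    Members get shifted-Poisson degrees (>= 1); each source's ``T``
    members are chosen uniformly at random (membership independent of
    degree); respondents are sampled without replacement with probability
    proportional to degree — the inclusion design the RDS-II estimator
    corrects for.
    """
    if n_respondents > M:
        raise ValueError("cannot sample more respondents than members")
    for label, total in source_totals.items():
        if not 0 <= total <= M:
            raise ValueError(f"source {label!r}: total must be in [0, M]")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    degrees = 1 + rng.poisson(mean_degree - 1.0, M)
    membership = {
        label: np.isin(np.arange(M),
                       rng.choice(M, size=total, replace=False))
        for label, total in source_totals.items()
    }
    p = degrees / degrees.sum()
    chosen = rng.choice(M, size=n_respondents, replace=False, p=p)
    respondents = [
        RDSRespondent(
            respondent_id=f"r{i}",
            degree=int(degrees[i]),
            memberships={lab: int(mem[i]) for lab, mem in membership.items()},
        )
        for i in chosen
    ]
    counts = [SourceCount(source_label=lab, total=tot)
              for lab, tot in source_totals.items()]
    return respondents, counts
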