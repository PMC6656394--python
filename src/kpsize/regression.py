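"""Log-fraction regression data preparation.

Direct size estimates ``n_ij`` (area i, multiplier method j) are converted
to responses ``y_ij = log(n_ij / N_i)`` — the natural log of the fraction of
the male 18–29 population that is MSM — and each observation receives a
heteroscedastic variance multiplier ``w_ij`` derived from its 95% CI.  If
the estimate were log-normal, the variance of ``y_ij`` would be
proportional to the squared width of the 95% interval on the log scale, so

    w_ij = (log(ci_high) - log(ci_low))**2

and the model variance is ``tau^2 * w_ij`` with a single free scale
``tau^2``.  Wide, imprecise direct estimates are thereby down-weighted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .multiplier import DirectEstimate

#: Design-matrix column names understood by :func:`build_design`.
COVARIATE_COLUMNS = (
    "log_male_pop",
    "hiv_prev_pct",
    "pop_density",
    "density_change",
    "landscan_density",
)

DEFAULT_COVARIATES = ("log_male_pop", "hiv_prev_pct")

#: Default fraction of the total male population assumed to fall in the
#: 18–29 age band when no age-stratified counts exist.
YOUNG_MALE_FRACTION = 0.55


@dataclass
class AreaRecord:
    """One prediction area (department / organizational unit).

    ``N_male`` is the male 18–29 population; ``H`` is HIV prevalence in
    percent (2.5 means 2.5%) and may be ``None`` when unobserved.  Optional
    auxiliary covariates (population density and its change, night-light
    derived density) live in ``extra``.
    """

    area_id: str
    name: str
    lon: float
    lat: float
    N_male: float
    H: float | None = None
    extra: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.N_male <= 0:
            raise ValueError(
                f"area {self.area_id!r}: N_male must be > 0, got {self.N_male}"
            )
        if self.H is not None and (not math.isfinite(self.H) or self.H < 0):
            raise ValueError(
                f"area {self.area_id!r}: H must be missing or >= 0, got {self.H}"
            )
        if not (math.isfinite(self.lon) and math.isfinite(self.lat)):
            raise ValueError(f"area {self.area_id!r}: non-finite coordinates")

    @property
    def has_H(self) -> bool:
        return self.H is not None

    @property
    def coords(self) -> tuple[float, float]:
        return (self.lon, self.lat)

    def covariate(self, name: str) -> float:
        """Look up a design covariate by column name."""
        if name == "log_male_pop":
            return math.log(self.N_male)
        if name == "hiv_prev_pct":
            if self.H is None:
                raise ValueError(
                    f"area {self.area_id!r}: HIV prevalence is missing"
                )
            return self.H
        try:
            return self.extra[name]
        except KeyError as exc:
            raise ValueError(
                f"area {self.area_id!r}: no covariate {name!r}"
            ) from exc


@dataclass(frozen=True)
class RegressionObservation:
    """One transformed direct estimate ready for the weighted regression."""

    area_id: str
    method_label: str
    y: float
    w: float
    x: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError(f"weight w must be > 0, got {self.w}")
        if self.x and self.x[0] != 1.0:
            raise ValueError("design vector must start with the intercept 1")


def derive_young_male_population(
    total_male: float, fraction: float = YOUNG_MALE_FRACTION
) -> int:
    """Male 18–29 count from a total male count via a constant age fraction.

    The default 55% reflects the assumption of an identical age structure
    in every area; the fraction is exposed because published commune-level
    pairs imply locally different values (e.g. 368,097 / 842,551 ≈ 0.44
    for the five central Abidjan communes).
    """
    if total_male <= 0:
        raise ValueError(f"total_male must be > 0, got {total_male}")
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    return round(fraction * total_male)


def to_log_fraction(estimate: DirectEstimate, N_male: float) -> float:
    """Response ``y = log(n_hat / N_male)``."""
    if estimate.n_hat <= 0:
        raise ValueError("n_hat must be > 0 to take a log fraction")
    if N_male <= 0:
        raise ValueError(f"N_male must be > 0, got {N_male}")
    return math.log(estimate.n_hat / N_male)


def ci_to_weight(estimate: DirectEstimate, N_male: float | None = None) -> float:
    """Variance multiplier ``w = (log ci_high - log ci_low)**2``.

    Depends only on the ratio of the CI bounds; ``N_male`` is accepted for
    interface symmetry with :func:`to_log_fraction` but cancels in the log
    difference.
    """
    if estimate.ci_low <= 0:
        raise ValueError("ci_low must be > 0")
    if estimate.ci_low >= estimate.ci_high:
        raise ValueError(
            "ci_low must be < ci_high; a zero-width CI would imply an "
            "infinitely precise observation"
        )
    return math.log(estimate.ci_high / estimate.ci_low) ** 2


def make_observation(
    estimate: DirectEstimate,
    area: AreaRecord,
    covariate_set: Sequence[str] = DEFAULT_COVARIATES,
) -> RegressionObservation:
    """Assemble response, weight and design row for one direct estimate."""
    x = (1.0,) + tuple(area.covariate(c) for c in covariate_set)
    return RegressionObservation(
        area_id=area.area_id,
        method_label=estimate.method_label,
        y=to_log_fraction(estimate, area.N_male),
        w=ci_to_weight(estimate),
        x=x,
    )


def build_design(
    areas: Sequence[AreaRecord],
    covariate_set: Sequence[str] = DEFAULT_COVARIATES,
    require_H: bool = True,
) -> np.ndarray:
    """Design matrix with an intercept column followed by the covariates.

    With the default covariate set each row is ``(1, log N_i, H_i)``.
    ``require_H=True`` (training time) raises on any missing prevalence;
    prediction-time callers impute first.
    """
    p = 1 + len(covariate_set)
    if not areas:
        return np.empty((0, p))
    rows = []
    for area in areas:
        if require_H and "hiv_prev_pct" in covariate_set and not area.has_H:
            raise ValueError(
                f"area {area.area_id!r}: training areas must have observed "
                "HIV prevalence"
            )
        rows.append([1.0] + [area.covariate(c) for c in covariate_set])
    return np.asarray(rows, float)


def population_truncation_threshold(
    areas: Sequence[AreaRecord], q: float = 0.10
) -> float:
    """Empirical q-quantile of N_male across all prediction areas.

    Used at prediction time to floor the log-population covariate: the
    fitted negative population slope is extrapolated no further down than
    this threshold, flattening predicted fractions for the smallest areas.
    Linear-interpolation quantile.
    """
    if not 0 < q < 1:
        raise ValueError(f"q must be in (0, 1), got {q}")
    if len(areas) < 2:
        raise ValueError("need at least 2 areas for an empirical quantile")
    return float(np.quantile([a.N_male for a in areas], q))
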