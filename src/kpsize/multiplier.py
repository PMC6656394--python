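"""Multiplier-method direct estimation of key-population size from RDS surveys.

The multiplier method combines a program-log total count ``T`` of
key-population members enrolled in some source (an NGO register, a clinic
log, a social-event attendance list, a unique-object distribution) with an
independently estimated proportion ``p_hat`` of the population covered by
that source: the population size estimate is ``N = T / p_hat``.

The proportion is estimated from a respondent-driven-sampling (RDS) survey
with the Volz–Heckathorn (RDS-II) estimator, which weights each respondent
inversely by their reported personal network size (degree) to correct for
the degree-biased inclusion probabilities of chain-referral sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

SOURCE_LABELS = ("ngo", "service", "social_event", "unique_object")

__all__ = [
    "SOURCE_LABELS",
    "RDSRespondent",
    "SourceCount",
    "DirectEstimate",
    "rds2_proportion",
    "rds2_proportion_ci",
    "multiplier_estimate",
]


@dataclass(frozen=True)
class RDSRespondent:
    """One RDS survey participant.

    Parameters
    ----------
    respondent_id : opaque identifier.
    degree : reported personal network size; must be a positive integer.
    memberships : mapping from source label (e.g. ``"ngo"``) to a binary
        indicator of whether the respondent is covered by that source.
        Sources the respondent was not asked about are simply absent.
    """

    respondent_id: str
    degree: int
    memberships: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise ValueError(
                f"respondent {self.respondent_id!r}: degree must be >= 1, "
                f"got {self.degree}"
            )
        for label, value in self.memberships.items():
            if value not in (0, 1):
                raise ValueError(
                    f"respondent {self.respondent_id!r}: membership "
                    f"indicator for {label!r} must be 0 or 1, got {value}"
                )


@dataclass(frozen=True)
class SourceCount:
    """Program-log total count of key-population members for one source."""

    source_label: str
    total: int
    area_id: str = ""

    def __post_init__(self) -> None:
        if self.total < 0:
            raise ValueError(f"source total must be >= 0, got {self.total}")


@dataclass(frozen=True)
class DirectEstimate:
    """A multiplier-method population-size estimate with its 95% CI."""

    area_id: str
    method_label: str
    n_hat: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if self.n_hat == self.ci_low == self.ci_high == 0:
            return  # degenerate zero-count source
        if not (0 < self.ci_low <= self.n_hat <= self.ci_high):
            raise ValueError(
                f"{self.area_id}/{self.method_label}: require "
                f"0 < ci_low <= n_hat <= ci_high, got "
                f"({self.ci_low}, {self.n_hat}, {self.ci_high})"
            )


def _membership_arrays(
    respondents: Sequence[RDSRespondent], source_label: str
) -> tuple[np.ndarray, np.ndarray]:
    if len(respondents) == 0:
        raise ValueError("cannot estimate a proportion from zero respondents")
    try:
        b = np.array([r.memberships[source_label] for r in respondents], float)
    except KeyError as exc:
        raise ValueError(
            f"some respondents have no membership record for {source_label!r}"
        ) from exc
    d = np.array([r.degree for r in respondents], float)
    return b, d


def rds2_proportion(
    respondents: Sequence[RDSRespondent], source_label: str
) -> float:
    """Volz–Heckathorn (RDS-II) estimate of a population proportion.

    Computes ``sum_i b_i / d_i  /  sum_i 1 / d_i`` where ``b_i`` is the
    binary source-membership indicator and ``d_i`` the degree.  With equal
    degrees this reduces to the plain sample proportion.  Invariant to
    rescaling all degrees by a common factor.

    Raises
    ------
    ValueError
        If the respondent list is empty, any respondent lacks the requested
        membership record, or all indicators are zero (the downstream
        multiplier ``T / p_hat`` would be undefined).
    """
    b, d = _membership_arrays(respondents, source_label)
    if b.sum() == 0:
        raise ValueError(
            f"all membership indicators for {source_label!r} are zero; "
            "the multiplier estimate would divide by zero"
        )
    return float(np.sum(b / d) / np.sum(1.0 / d))


def rds2_proportion_ci(
    respondents: Sequence[RDSRespondent],
    source_label: str,
    n_boot: int = 1000,
    confidence: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile-bootstrap confidence interval for the RDS-II proportion.

    Respondents are resampled with replacement ``n_boot`` times and the
    RDS-II estimator recomputed on each resample.  Degenerate resamples in
    which every indicator is zero are discarded (with a warning) and retried
    up to a cap, since the proportion downstream must stay positive.

    Parameters
    ----------
    n_boot : number of bootstrap resamples, at least 200.
    confidence : interval coverage level in (0, 1); default 0.95.
    seed : int seed or ``numpy.random.Generator`` for reproducibility.
    """
    if n_boot < 200:
        raise ValueError(f"n_boot must be >= 200, got {n_boot}")
    if not 0 < confidence < 1:
        raise ValueError(f"confidence must be in (0,1), got {confidence}")
    b, d = _membership_arrays(respondents, source_label)
    if b.sum() == 0:
        raise ValueError("all indicators zero; proportion CI undefined")
    rng = np.random.default_rng(seed)
    n = len(b)
    inv_d = 1.0 / d
    stats = np.empty(n_boot)
    filled = 0
    discarded = 0
    retry_cap = 10 * n_boot
    while filled < n_boot:
        if discarded >= retry_cap:
            raise RuntimeError(
                "bootstrap retry cap exceeded: nearly all resamples had "
                "zero indicators (prevalence of the source is too low)"
            )
        idx = rng.integers(0, n, size=n)
        num = np.sum(b[idx] * inv_d[idx])
        if num == 0:
            discarded += 1
            continue
        stats[filled] = num / np.sum(inv_d[idx])
        filled += 1
    if discarded:
        warnings.warn(
            f"discarded {discarded} degenerate bootstrap resamples with all "
            "indicators zero",
            stacklevel=2,
        )
    alpha = 1.0 - confidence
    low, high = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(low), float(high)


def multiplier_estimate(
    count: SourceCount,
    p_hat: float,
    p_ci: tuple[float, float],
    area_id: str | None = None,
) -> DirectEstimate:
    """Population-size estimate ``N = T / p_hat`` with inverted CI.

    The CI for the proportion inverts into a CI for the size with the
    bounds flipped: a higher covered proportion means a smaller population.
    """
    lo, hi = p_ci
    if p_hat <= 0:
        raise ValueError("p_hat must be > 0 (multiplier undefined at 0)")
    if not (0 < lo <= p_hat <= hi <= 1):
        raise ValueError(
            f"require 0 < ci_low <= p_hat <= ci_high <= 1, got "
            f"({lo}, {p_hat}, {hi})"
        )
    aid = area_id if area_id is not None else count.area_id
    if count.total == 0:
        warnings.warn(
            f"source {count.source_label!r} has total 0; estimate is 0",
            stacklevel=2,
        )
        return DirectEstimate(aid, count.source_label, 0.0, 0.0, 0.0)
    return DirectEstimate(
        area_id=aid,
        method_label=count.source_label,
        n_hat=count.total / p_hat,
        ci_low=count.total / hi,
        ci_high=count.total / lo,
    )
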