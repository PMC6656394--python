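"""Leave-one-area-out cross-validated covariate selection.

HIV prevalence is kept in every candidate model on epidemiological
grounds; candidates differ in the single additional covariate (log male
population, population density, density change, night-light density, or
none).  For each candidate, all direct estimates of one area are left out,
a weighted least-squares fit (weights 1/w_ij) is run on the rest, and the
held-out area's MSM *fraction* is predicted.  The score is the mean squared
error against the area's mean observed fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import statsmodels.api as sm

from .regression import AreaRecord, RegressionObservation


@dataclass(frozen=True)
class CandidateModel:
    """A label plus design covariate names (prevalence always included)."""

    label: str
    covariates: tuple[str, ...]

    def __post_init__(self) -> None:
        if "hiv_prev_pct" not in self.covariates:
            raise ValueError(
                f"candidate {self.label!r} must include hiv_prev_pct"
            )


#: The standard candidate set: prevalence alone, or prevalence plus one
#: population-derived covariate.
DEFAULT_CANDIDATES = (
    CandidateModel("log male population + HIV",
                   ("log_male_pop", "hiv_prev_pct")),
    CandidateModel("landscan density + HIV",
                   ("landscan_density", "hiv_prev_pct")),
    CandidateModel("population density + HIV",
                   ("pop_density", "hiv_prev_pct")),
    CandidateModel("density change + HIV",
                   ("density_change", "hiv_prev_pct")),
    CandidateModel("only HIV", ("hiv_prev_pct",)),
)


def loocv_mse(
    model: CandidateModel,
    observations: Sequence[RegressionObservation],
    areas: Sequence[AreaRecord],
    scale: Literal["fraction", "count"] = "fraction",
) -> float:
    """Leave-one-area-out cross-validated MSE for one candidate model.

    Per fold, WLS with weights 1/w_ij is fit on all other areas' log
    fractions; the held-out prediction is ``exp(x_i' beta_hat)``, compared
    to the mean of the held-out area's observed fractions ``n_ij / N_i``
    (or counts, with ``scale="count"``).
    """
    by_area = {a.area_id: a for a in areas}
    area_ids = sorted({o.area_id for o in observations})
    if len(area_ids) < 3:
        raise ValueError("need direct estimates from >= 3 areas")
    errors = []
    for held in area_ids:
        train = [o for o in observations if o.area_id != held]
        X = np.array(
            [[1.0] + [by_area[o.area_id].covariate(c) for c in model.covariates]
             for o in train]
        )
        y = np.array([o.y for o in train])
        w = np.array([o.w for o in train])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(
                f"fold {held!r}: design for {model.label!r} is rank deficient"
            )
        fit = sm.WLS(y, X, weights=1.0 / w).fit()
        ha = by_area[held]
        xh = np.array([1.0] + [ha.covariate(c) for c in model.covariates])
        # cap the exponent: a wildly extrapolating fold yields a huge but
        # finite penalty instead of a float overflow
        f_pred = float(np.exp(min(float(xh @ fit.params), 700.0)))
        f_true = float(np.mean([np.exp(o.y) for o in observations
                                if o.area_id == held]))
        if scale == "count":
            errors.append((ha.N_male * (f_true - f_pred)) ** 2)
        else:
            errors.append((f_true - f_pred) ** 2)
    return float(np.mean(errors))


def rank_models(
    candidates: Sequence[CandidateModel],
    observations: Sequence[RegressionObservation],
    areas: Sequence[AreaRecord],
    scale: Literal["fraction", "count"] = "fraction",
):
    """Candidates ordered by ascending LOOCV MSE (ties: fewer covariates)."""
    import pandas as pd

    if not candidates:
        raise ValueError("need at least one candidate model")
    rows = [
        {"label": c.label,
         "mse": loocv_mse(c, observations, areas, scale=scale),
         "n_covariates": len(c.covariates)}
        for c in candidates
    ]
    df = pd.DataFrame(rows).sort_values(
        ["mse", "n_covariates"], kind="stable"
    ).reset_index(drop=True)
    return df[["label", "mse"]]
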