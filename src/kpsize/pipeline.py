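"""End-to-end pipeline: prepare → fit → impute → predict, with artifacts.

``run_pipeline`` executes the full analysis the library implements —
transform direct estimates into weighted log-fraction observations, sample
the joint hierarchical posterior, impute missing prevalence inside the
composition-sampling step, and write predictions — persisting every stage
output plus a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as kio
from .bayes import MCMCConfig, posterior_summary, run_mcmc
from .multiplier import DirectEstimate
from .predict import predict_all, summarize_predictions
from .regression import (
    AreaRecord,
    DEFAULT_COVARIATES,
    RegressionObservation,
    build_design,
    make_observation,
    population_truncation_threshold,
)
from .spatial import fit_gp_mle, krige

logger = logging.getLogger("kpsize")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (mirrors the YAML config keys)."""

    area_csv: str
    estimates_csv: str
    output_dir: str
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    truncation_quantile: float = 0.10
    ci_level: float = 0.95
    seed: int = 0
    joint_missing_draws: bool = False
    loocv_scale: str = "fraction"
    truncate_N_in_count_conversion: bool = False
    covariates: tuple[str, ...] = DEFAULT_COVARIATES

    def __post_init__(self) -> None:
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if isinstance(self.mcmc, dict):
            self.mcmc = MCMCConfig(**self.mcmc)
        if isinstance(self.covariates, list):
            self.covariates = tuple(self.covariates)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def prepare_observations(
    estimates: Sequence[DirectEstimate],
    areas: Sequence[AreaRecord],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> list[RegressionObservation]:
    """Transform direct estimates into weighted regression observations."""
    by_area = {a.area_id: a for a in areas}
    obs = []
    for e in estimates:
        try:
            area = by_area[e.area_id]
        except KeyError as exc:
            raise ValueError(
                f"direct estimate references unknown area {e.area_id!r}"
            ) from exc
        obs.append(make_observation(e, area, covariates))
    return obs


def impute_hiv(areas: Sequence[AreaRecord]) -> pd.DataFrame:
    """Kriging imputation table for every area (MLE plug-in; the Bayesian
    pipeline instead integrates over the GP parameters)."""
    observed = [a for a in areas if a.has_H]
    params = fit_gp_mle(observed)
    rows = []
    for a in areas:
        if a.has_H:
            rows.append({"area_id": a.area_id,
                         "hiv_prev_pct_imputed": a.H, "sd": 0.0,
                         "q2.5": a.H, "q97.5": a.H, "was_observed": True})
        else:
            mean, var = krige(params, observed, np.array([a.coords]))
            sd = float(np.sqrt(var[0]))
            rows.append({"area_id": a.area_id,
                         "hiv_prev_pct_imputed": float(mean[0]), "sd": sd,
                         "q2.5": float(mean[0] - 1.96 * sd),
                         "q97.5": float(mean[0] + 1.96 * sd),
                         "was_observed": False})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the artifact directory.

    Writes ``draws.csv`` (one column per parameter), ``posterior_summary.csv``,
    ``predictions.csv``, ``imputed_hiv.csv``, ``diagnostics.csv`` and
    ``manifest.yaml``.  Deterministic given the config seed.  A failing
    stage raises with the stage name; artifacts written so far remain.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read-inputs"
    try:
        areas = kio.read_area_table(config.area_csv)
        estimates = kio.read_direct_estimates(config.estimates_csv)
        logger.info("read %d areas, %d direct estimates",
                    len(areas), len(estimates))

        stage = "prepare"
        obs = prepare_observations(estimates, areas, config.covariates)
        training_ids = {o.area_id for o in obs}
        training = [a for a in areas if a.area_id in training_ids]
        observed_H = [a for a in areas if a.has_H]
        threshold = population_truncation_threshold(
            areas, config.truncation_quantile)
        logger.info("prepared %d observations from %d training areas; "
                    "population truncation threshold %.1f",
                    len(obs), len(training), threshold)

        stage = "impute-hiv"
        kio.write_imputations(impute_hiv(areas), out / "imputed_hiv.csv")

        stage = "mcmc"
        draws = run_mcmc(obs, observed_H, config.mcmc)
        draws.to_frame().to_csv(out / "draws.csv", index=False)
        summary = posterior_summary(draws, ci=config.ci_level)
        summary.to_csv(out / "posterior_summary.csv")
        logger.info("retained %d posterior draws", len(draws))

        stage = "predict"
        counts, prevalence = predict_all(
            areas, draws, observed_H, threshold,
            seed=np.random.default_rng(config.seed),
            joint=config.joint_missing_draws,
        )
        if config.truncate_N_in_count_conversion:
            for a in areas:
                if a.N_male < threshold:
                    counts[a.area_id] = counts[a.area_id] \
                        * threshold / a.N_male
        design = build_design(training, config.covariates)
        summaries = summarize_predictions(
            counts, areas, ci=config.ci_level, design=design,
            threshold=threshold, prevalence_draws=prevalence,
        )
        kio.write_predictions(summaries, out / "predictions.csv")

        stage = "diagnostics"
        diag = pd.DataFrame({
            "parameter": list(draws.ess),
            "ess": [draws.ess[k] for k in draws.ess],
            "accept_rate": [draws.accept_rates.get(k, np.nan)
                            for k in draws.ess],
        })
        diag.to_csv(out / "diagnostics.csv", index=False)

        stage = "manifest"
        cfg_dict = asdict(config)
        cfg_hash = hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        versions = {}
        for mod in ("numpy", "scipy", "pandas", "statsmodels"):
            versions[mod] = __import__(mod).__version__
        from . import __version__
        versions["kpsize"] = __version__
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(
                {"seed": config.seed, "config": cfg_dict,
                 "config_sha256": cfg_hash, "versions": versions,
                 "accept_rates": draws.accept_rates},
                fh, sort_keys=True,
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    logger.info("pipeline artifacts written to %s", out)
    return out
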