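"""CSV readers and writers for every schema the pipeline exchanges.

All interchange is plain CSV with missing values as empty cells (never
sentinel numbers).  Readers return the typed records the library operates
on; writers are exact inverses, so write-then-read round-trips are
identity on the typed records (up to float formatting, which uses
``repr``-faithful precision).
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .multiplier import DirectEstimate, RDSRespondent, SourceCount, SOURCE_LABELS
from .predict import PredictionSummary
from .regression import AreaRecord

AREA_COLUMNS = ("area_id", "name", "lon", "lat", "male_pop_18_29",
                "hiv_prev_pct")
ESTIMATE_COLUMNS = ("area_id", "method_label", "n_hat", "ci_low", "ci_high")


def read_area_table(path: str | Path) -> list[AreaRecord]:
    """Read the area CSV into typed records.

    Empty ``hiv_prev_pct`` cells become missing prevalence.  Any extra
    columns are carried along as auxiliary covariates.  Duplicate area ids
    and nonpositive populations are rejected with the offending row named.
    """
    df = pd.read_csv(path)
    missing_cols = set(AREA_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing columns {sorted(missing_cols)}")
    dupes = df["area_id"][df["area_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"{path}: duplicate area_id {dupes.iloc[0]!r}")
    extra_cols = [c for c in df.columns if c not in AREA_COLUMNS]
    records = []
    for row_no, row in enumerate(df.to_dict("records"), start=2):
        if row["male_pop_18_29"] <= 0:
            raise ValueError(
                f"{path} row {row_no}: male_pop_18_29 must be > 0 "
                f"(area {row['area_id']!r})"
            )
        H = None if pd.isna(row["hiv_prev_pct"]) else float(row["hiv_prev_pct"])
        extra = {c: float(row[c]) for c in extra_cols if not pd.isna(row[c])}
        records.append(
            AreaRecord(
                area_id=str(row["area_id"]),
                name=str(row["name"]),
                lon=float(row["lon"]),
                lat=float(row["lat"]),
                N_male=float(row["male_pop_18_29"]),
                H=H,
                extra=extra,
            )
        )
    return records


def write_area_table(areas: Sequence[AreaRecord], path: str | Path) -> None:
    # underscore-prefixed extras are in-memory diagnostics, not schema
    extra_cols = sorted(
        {k for a in areas for k in a.extra if not k.startswith("_")}
    )
    rows = []
    for a in areas:
        row = {
            "area_id": a.area_id, "name": a.name, "lon": a.lon, "lat": a.lat,
            "male_pop_18_29": a.N_male,
            "hiv_prev_pct": a.H if a.has_H else np.nan,
        }
        for c in extra_cols:
            row[c] = a.extra.get(c, np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_direct_estimates(path: str | Path) -> list[DirectEstimate]:
    df = pd.read_csv(path)
    missing_cols = set(ESTIMATE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing columns {sorted(missing_cols)}")
    return [
        DirectEstimate(
            area_id=str(r.area_id), method_label=str(r.method_label),
            n_hat=float(r.n_hat), ci_low=float(r.ci_low),
            ci_high=float(r.ci_high),
        )
        for r in df.itertuples(index=False)
    ]


def write_direct_estimates(
    estimates: Sequence[DirectEstimate], path: str | Path
) -> None:
    pd.DataFrame(
        [{"area_id": e.area_id, "method_label": e.method_label,
          "n_hat": e.n_hat, "ci_low": e.ci_low, "ci_high": e.ci_high}
         for e in estimates]
    ).to_csv(path, index=False)


def load_reference_direct_estimates() -> list[DirectEstimate]:
    """The published multiplier-method direct estimates for the five
    Côte d'Ivoire departments with MSM survey data (19 estimates, persons,
    with 95% CIs), shipped as a packaged fixture."""
    ref = importlib.resources.files("kpsize.data") / "civ_direct_estimates.csv"
    with importlib.resources.as_file(ref) as path:
        return read_direct_estimates(path)


def read_rds_survey(path: str | Path) -> list[RDSRespondent]:
    """RDS survey CSV: respondent_id, degree, one binary column per source.

    Empty membership cells mean the respondent was not asked about that
    source; the indicator is simply absent from the record.
    """
    df = pd.read_csv(path)
    for col in ("respondent_id", "degree"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    source_cols = [c for c in df.columns if c in SOURCE_LABELS]
    records = []
    for row in df.itertuples(index=False):
        memberships = {}
        for c in source_cols:
            v = getattr(row, c)
            if not pd.isna(v):
                memberships[c] = int(v)
        records.append(
            RDSRespondent(
                respondent_id=str(row.respondent_id),
                degree=int(row.degree),
                memberships=memberships,
            )
        )
    return records


def read_source_counts(path: str | Path) -> list[SourceCount]:
    df = pd.read_csv(path)
    for col in ("area_id", "source_label", "total"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return [
        SourceCount(area_id=str(r.area_id), source_label=str(r.source_label),
                    total=int(r.total))
        for r in df.itertuples(index=False)
    ]


def write_predictions(
    summaries: Sequence[PredictionSummary], path: str | Path
) -> None:
    """Prediction CSV: one row per area with interval, relative width,
    imputation flag and leverage."""
    pd.DataFrame(
        [{"area_id": s.area_id, "name": s.name, "n_median": s.n_median,
          "n_low": s.n_low, "n_high": s.n_high, "pct_median": s.pct_median,
          "relative_width": s.relative_width,
          "hiv_was_imputed": s.hiv_was_imputed, "leverage": s.leverage}
         for s in summaries]
    ).to_csv(path, index=False)


def read_predictions(path: str | Path) -> list[PredictionSummary]:
    df = pd.read_csv(path)
    return [
        PredictionSummary(
            area_id=str(r.area_id), name=str(r.name),
            n_median=float(r.n_median), n_low=float(r.n_low),
            n_high=float(r.n_high), pct_median=float(r.pct_median),
            relative_width=float(r.relative_width),
            hiv_was_imputed=bool(r.hiv_was_imputed),
            leverage=None if pd.isna(r.leverage) else float(r.leverage),
        )
        for r in df.itertuples(index=False)
    ]


def write_imputations(
    df: pd.DataFrame, path: str | Path
) -> None:
    """Imputation CSV: area_id, imputed prevalence, sd, interval, flag."""
    expected = ["area_id", "hiv_prev_pct_imputed", "sd", "q2.5", "q97.5",
                "was_observed"]
    df[expected].to_csv(path, index=False)
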