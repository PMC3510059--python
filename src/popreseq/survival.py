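"""Left-truncated Cox regression of myocardial infarction on carrier
status, with age as the time scale.

Individuals enter the risk set at their entry age (delayed entry), so
age adjustment is structural rather than a covariate; sex is always a
covariate, and the multifactorial adjustment adds diabetes, hypertension
and smoking.  Individuals with an MI before entry are excluded before
fitting.  The partial likelihood is maximized by lifelines'
``CoxPHFitter`` (Breslow tie handling); the delayed-entry risk-set
contract is what this module owns and tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .containers import Genotypes

__all__ = ["build_survival_records", "fit_cox", "CoxFit"]

_BASE_COVARIATES = ["sex_female"]
_MULTIFACTORIAL = ["sex_female", "diabetes", "hypertension", "smoking"]


def build_survival_records(
    cohort: pd.DataFrame,
    genotypes: Genotypes,
    groupings: dict[str, list[str]],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Assemble the analysis table for the Cox fits.

    ``groupings`` maps a group label to the variant ids whose carriers
    define that group's exposure flag.  Prior-MI individuals are removed
    and counted; records whose exit age does not exceed their entry age
    are dropped with a warning and counted.

    Returns (records, exclusion report).
    """
    records = cohort.copy()
    exclusions = {"prior_mi": int(records["prior_mi"].sum())}
    keep = ~records["prior_mi"].astype(bool)

    bad = records["exit_age"] <= records["entry_age"]
    exclusions["nonpositive_followup"] = int((bad & keep).sum())
    if exclusions["nonpositive_followup"]:
        warnings.warn(
            f"dropping {exclusions['nonpositive_followup']} records with "
            "exit_age <= entry_age",
            stacklevel=2,
        )
    keep &= ~bad

    for label, vids in groupings.items():
        flag = np.zeros(len(records), dtype=bool)
        flag[genotypes.group_carriers(vids)] = True
        records[f"carrier_{label}"] = flag

    records = records.loc[keep].reset_index(drop=True)
    records["sex_female"] = (records["sex"] == "F").astype(int)
    cols = (
        ["id", "entry_age", "exit_age", "mi_event", "sex_female"]
        + ["diabetes", "hypertension", "smoking"]
        + [c for c in records.columns if c.startswith("carrier_")]
    )
    return records[cols], exclusions


@dataclass(frozen=True)
class CoxFit:
    group: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    beta: float
    se: float
    n: int
    n_events: int
    adjustment: str


def fit_cox(
    records: pd.DataFrame,
    group: str,
    adjustment: str = "age_sex",
) -> CoxFit:
    """Cox proportional-hazards fit for one carrier group.

    Age is the time scale: risk sets at each event age contain exactly
    those individuals with entry_age < t <= exit_age (left truncation).
    ``adjustment`` is ``"age_sex"`` (sex covariate only; age is the time
    scale) or ``"multifactorial"`` (adds diabetes, hypertension,
    smoking).  Ties are handled with the Breslow approximation.
    """
    flag_col = f"carrier_{group}"
    if flag_col not in records.columns:
        raise KeyError(f"no carrier flag for group {group!r}")
    n_events = int(records["mi_event"].sum())
    if n_events == 0:
        raise ValueError("no events among records; Cox fit undefined")
    if adjustment == "age_sex":
        covariates = _BASE_COVARIATES
    elif adjustment == "multifactorial":
        covariates = _MULTIFACTORIAL
    else:
        raise ValueError(f"unknown adjustment {adjustment!r}")

    carrier_events = int(records.loc[records[flag_col].astype(bool), "mi_event"].sum())
    noncarrier_events = n_events - carrier_events
    if carrier_events == 0 or noncarrier_events == 0:
        warnings.warn(
            f"group {group}: all events on one side of the carrier flag "
            "(complete separation); estimate unbounded",
            stacklevel=2,
        )

    df = records[["entry_age", "exit_age", "mi_event", flag_col] + list(covariates)].copy()
    df[flag_col] = df[flag_col].astype(int)
    for c in list(covariates):
        df[c] = df[c].astype(int)
        if df[c].var() == 0:  # constant covariates carry no information
            df = df.drop(columns=c)

    fitter = CoxPHFitter()
    try:
        fitter.fit(
            df,
            duration_col="exit_age",
            event_col="mi_event",
            entry_col="entry_age",
            fit_options={"precision": 1e-9},
        )
    except ConvergenceError as err:
        raise RuntimeError(
            f"Cox fit for group {group!r} did not converge: {err}"
        ) from err

    beta = float(fitter.params_[flag_col])
    se = float(fitter.standard_errors_[flag_col])
    return CoxFit(
        group=group,
        hazard_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.96 * se)),
        ci_high=float(np.exp(beta + 1.96 * se)),
        beta=beta,
        se=se,
        n=len(df),
        n_events=n_events,
        adjustment=adjustment,
    )


def cox_table(
    records: pd.DataFrame,
    groups: list[str],
    adjustment: str = "age_sex",
) -> pd.DataFrame:
    """CoxFit rows for several carrier groups, as a table."""
    rows = []
    for g in groups:
        fit = fit_cox(records, g, adjustment=adjustment)
        rows.append(
            {
                "group": fit.group,
                "hazard_ratio": fit.hazard_ratio,
                "ci_low": fit.ci_low,
                "ci_high": fit.ci_high,
                "beta": fit.beta,
                "se": fit.se,
                "n": fit.n,
                "n_events": fit.n_events,
                "adjustment": fit.adjustment,
            }
        )
    return pd.DataFrame(rows)
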