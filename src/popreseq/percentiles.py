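"""Percentile-normalized phenotype association for rare-variant carriers.

Raw trait values are converted to percentiles within sex x 10-year age
band x study strata, which removes sex, age and between-study level
differences without any parametric model.  Carrier groups are then
compared against the population median (the 50th percentile of the
normalized distribution) with a z-test whose null variance is that of a
continuous uniform on (0, 100):

    z = (xbar - 50) / sqrt((100^2 / 12) / k),   p = 2 (1 - Phi(|z|))

for k carriers with mean percentile xbar.  Supporting analyses: raw-scale
carrier/noncarrier contrasts (Mann-Whitney for continuous, Fisher's exact
for binary variables), burden collapsing over variant groups, and the
fraction of trait variance explained by allele-count regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import Genotypes

__all__ = [
    "age_band",
    "assign_percentiles",
    "heterozygote_ztest",
    "carrier_contrast",
    "burden_collapse",
    "variance_explained",
    "difference_record",
    "ZTestResult",
]

NULL_VARIANCE = 100.0**2 / 12.0  # variance of U(0, 100)


def age_band(age: float | np.ndarray) -> np.ndarray:
    """10-year age band label; ages 80 and above share the terminal band."""
    age = np.atleast_1d(np.asarray(age, dtype=float))
    lo = np.minimum(np.floor(age / 10.0) * 10, 80).astype(int)
    return np.where(lo >= 80, "80+", [f"{a}-{a + 9}" for a in lo])


def assign_percentiles(cohort: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Within-stratum percentiles for one trait.

    Strata are sex x 10-year age band x study.  Within a stratum of size
    n, the value of rank r (mid-rank for ties) gets percentile
    100 (r - 0.5) / n, so untied strata have mean exactly 50.  Strata
    with fewer than two members are assigned 50 with a warning.

    Returns a frame aligned with ``cohort`` rows: id, trait, stratum
    columns and ``percentile``.
    """
    if trait not in cohort.columns:
        raise KeyError(f"trait column {trait!r} not in cohort")
    out = cohort[["id", "sex", "study"]].copy()
    out["age_band"] = age_band(cohort["age_at_exam"].to_numpy())
    out["trait"] = trait
    values = cohort[trait]

    pct = np.empty(len(cohort))
    for _, idx in out.groupby(["sex", "age_band", "study"], observed=True).groups.items():
        v = values.loc[idx]
        if len(v) < 2:
            warnings.warn(
                f"stratum with n={len(v)} too small to rank; assigning the "
                "50th percentile",
                stacklevel=2,
            )
            pct[cohort.index.get_indexer(idx)] = 50.0
            continue
        ranks = stats.rankdata(v.to_numpy(), method="average")
        pct[cohort.index.get_indexer(idx)] = 100.0 * (ranks - 0.5) / len(v)
    out["percentile"] = pct
    return out


@dataclass(frozen=True)
class ZTestResult:
    group: str
    k: int
    mean_percentile: float
    median_percentile: float
    z: float
    p: float


def heterozygote_ztest(percentiles: np.ndarray, group: str = "") -> ZTestResult:
    """Test whether a carrier group's mean percentile differs from 50."""
    pct = np.asarray(percentiles, dtype=float)
    if pct.size == 0:
        raise ValueError("empty carrier set")
    xbar = float(pct.mean())
    z = (xbar - 50.0) / np.sqrt(NULL_VARIANCE / pct.size)
    p = 2.0 * stats.norm.sf(abs(z))
    return ZTestResult(
        group=group,
        k=int(pct.size),
        mean_percentile=xbar,
        median_percentile=float(np.median(pct)),
        z=float(z),
        p=float(p),
    )


def per_variant_ztests(
    assignments: pd.DataFrame, genotypes: Genotypes
) -> pd.DataFrame:
    """Heterozygote z-test for every polymorphic variant, one trait."""
    pct = assignments["percentile"].to_numpy()
    rows = []
    for vid in genotypes.variant_ids:
        carriers = genotypes.carriers(vid)
        if carriers.size == 0:
            continue
        r = heterozygote_ztest(pct[carriers], group=vid)
        rows.append(
            {
                "variant_id": vid,
                "trait": assignments["trait"].iloc[0],
                "k": r.k,
                "mean_percentile": r.mean_percentile,
                "median_percentile": r.median_percentile,
                "z": r.z,
                "p": r.p,
            }
        )
    return pd.DataFrame(rows)


def carrier_contrast(
    cohort: pd.DataFrame,
    carrier_idx: np.ndarray,
    continuous: list[str] = (),
    binary: list[str] = (),
) -> pd.DataFrame:
    """Raw-scale carrier vs noncarrier comparison table.

    Continuous variables get medians/IQRs and a two-sided Mann-Whitney U
    p-value; binary variables get proportions and a two-sided Fisher's
    exact p-value.  Carriers are excluded from the noncarrier group.
    """
    mask = np.zeros(len(cohort), dtype=bool)
    mask[np.asarray(carrier_idx, dtype=int)] = True
    if mask.sum() == 0 or mask.sum() == len(cohort):
        raise ValueError("both carrier and noncarrier groups must be nonempty")
    carriers = cohort.loc[mask]
    noncar = cohort.loc[~mask]

    rows = []
    for var in continuous:
        if var not in cohort.columns:
            raise KeyError(f"variable {var!r} not in cohort")
        a = carriers[var].to_numpy(dtype=float)
        b = noncar[var].to_numpy(dtype=float)
        p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        rows.append(
            {
                "variable": var,
                "kind": "continuous",
                "carrier_summary": _median_iqr(a),
                "noncarrier_summary": _median_iqr(b),
                "carrier_median": float(np.median(a)),
                "noncarrier_median": float(np.median(b)),
                "p": float(p),
            }
        )
    for var in binary:
        if var not in cohort.columns:
            raise KeyError(f"variable {var!r} not in cohort")
        a = carriers[var].astype(bool)
        b = noncar[var].astype(bool)
        table = [[int(a.sum()), int((~a).sum())], [int(b.sum()), int((~b).sum())]]
        p = stats.fisher_exact(table, alternative="two-sided")[1]
        rows.append(
            {
                "variable": var,
                "kind": "binary",
                "carrier_summary": f"{100 * a.mean():.0f}%",
                "noncarrier_summary": f"{100 * b.mean():.0f}%",
                "carrier_median": float(a.mean()),
                "noncarrier_median": float(b.mean()),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


def _median_iqr(x: np.ndarray) -> str:
    q1, q2, q3 = np.percentile(x, [25, 50, 75])
    return f"{q2:.1f} ({q1:.1f}-{q3:.1f})"


def between_study_contrast(
    assignments_a: pd.DataFrame,
    carriers_a: np.ndarray,
    assignments_b: pd.DataFrame,
    carriers_b: np.ndarray,
) -> float:
    """Compare one variant's carrier percentile distributions across two
    cohorts (rank-sum, two-sided) — the replication consistency check."""
    a = assignments_a["percentile"].to_numpy()[carriers_a]
    b = assignments_b["percentile"].to_numpy()[carriers_b]
    if a.size == 0 or b.size == 0:
        raise ValueError("carrier sets must be nonempty in both studies")
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def difference_record(
    noncarrier_median: float,
    carrier_median: float,
    carrier_median_percentile: float | None = None,
) -> dict:
    """Differences between noncarriers and carriers.

    ``delta_abs`` is on the raw measurement scale (noncarrier median minus
    carrier median); ``delta_rel`` is on the percentile scale (50 minus
    the carrier median percentile), when percentiles are supplied.
    """
    rec = {"delta_abs": float(noncarrier_median - carrier_median)}
    if carrier_median_percentile is not None:
        rec["delta_rel"] = float(50.0 - carrier_median_percentile)
    return rec


def burden_collapse(
    assignments: pd.DataFrame,
    genotypes: Genotypes,
    grouping: dict[str, list[str]],
    exclusions: list[str] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse carriers over variant groups and test each group.

    ``grouping`` maps group labels (e.g. "NS", "S") to variant-id lists;
    ``exclusions`` removes the named variants from every group before
    collapsing (e.g. to drop an amyloidosis-suspect variant).  An
    individual carrying variants from two groups contributes to both.

    Returns (per-group z-test table, pairwise between-group rank-sum
    table).
    """
    known = set(genotypes.variant_ids)
    unknown = [v for v in exclusions if v not in known]
    if unknown:
        raise KeyError(f"unknown variant ids in exclusions: {unknown}")
    pct = assignments["percentile"].to_numpy()

    group_pcts: dict[str, np.ndarray] = {}
    rows = []
    for label, vids in grouping.items():
        kept = [v for v in vids if v not in set(exclusions)]
        carriers = genotypes.group_carriers(kept)
        if carriers.size == 0:
            continue
        r = heterozygote_ztest(pct[carriers], group=label)
        group_pcts[label] = pct[carriers]
        rows.append(
            {
                "group": label,
                "n_variants": len(kept),
                "k": r.k,
                "mean_percentile": r.mean_percentile,
                "median_percentile": r.median_percentile,
                "z": r.z,
                "p": r.p,
            }
        )
    per_group = pd.DataFrame(rows)

    pair_rows = []
    labels = list(group_pcts)
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            p = stats.mannwhitneyu(
                group_pcts[la], group_pcts[lb], alternative="two-sided"
            ).pvalue
            pair_rows.append({"group_a": la, "group_b": lb, "p": float(p)})
    return per_group, pd.DataFrame(pair_rows)


def variance_explained(
    cohort: pd.DataFrame,
    trait: str,
    genotypes: Genotypes,
    groups: dict[str, list[str]],
) -> pd.DataFrame:
    """Fraction of trait variance explained by allele counts per group.

    Ordinary least squares of the raw trait on 0/1/2 allele-count
    predictors for every variant in the group; R^2 = 1 - RSS/TSS.
    Collinear predictors are dropped with a warning.
    """
    if trait not in cohort.columns:
        raise KeyError(f"trait column {trait!r} not in cohort")
    y = cohort[trait].to_numpy(dtype=float)
    rows = []
    for label, vids in groups.items():
        cols = []
        kept = []
        for v in vids:
            d = genotypes.dosage(v).astype(float)
            if d.std() == 0:
                warnings.warn(f"variant {v} is monomorphic; dropped", stacklevel=2)
                continue
            cols.append(d)
            kept.append(v)
        if not cols:
            rows.append({"group": label, "n_variants": 0, "r_squared": 0.0})
            continue
        X = np.column_stack(cols)
        rank = np.linalg.matrix_rank(X - X.mean(axis=0))
        if rank < X.shape[1]:
            warnings.warn(
                f"group {label}: collinear allele-count predictors", stacklevel=2
            )
        fit = sm.OLS(y, sm.add_constant(X)).fit()
        rows.append(
            {
                "group": label,
                "n_variants": len(kept),
                "r_squared": float(fit.rsquared),
            }
        )
    return pd.DataFrame(rows)
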