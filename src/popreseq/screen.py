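"""Extreme-phenotype screening design, compared with population-based
resequencing.

The screen resequences only individuals in the two tails of the
(normalized) trait distribution: percentile <= q or >= 100 - q.  A
variant is *detected* if at least one of its carriers falls in a screened
tail; detected variants are classified as exclusively-low,
exclusively-high or both depending on which tails contain carriers.  At
q = 50 the screen is the whole cohort and classification reduces to a
median split.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import Genotypes
from ._util import percent

__all__ = [
    "select_extreme_set",
    "classify_variant_tails",
    "screen_variants",
    "capture_statistics",
    "tail_asymmetry_test",
    "concordance_report",
]

TAIL_CLASSES = ("exclusively_low", "exclusively_high", "both", "undetected")


def _check_q(q: float) -> None:
    if not 0.0 < q <= 50.0:
        raise ValueError(f"cutoff q must lie in (0, 50], got {q}")


def select_extreme_set(assignments: pd.DataFrame, q: float) -> pd.DataFrame:
    """Individuals screened at cutoff q, with a ``tail`` label.

    Boundary percentiles are included in the tail (<= / >= comparisons).
    """
    _check_q(q)
    pct = assignments["percentile"].to_numpy()
    low = pct <= q
    high = pct >= 100.0 - q
    out = assignments.loc[low | high, ["id", "percentile"]].copy()
    out["tail"] = np.where(pct[low | high] <= q, "low", "high")
    # at q = 50 a percentile can satisfy both bounds only if it equals 50
    out.loc[(out["percentile"] <= q) & (out["percentile"] >= 100 - q), "tail"] = "low"
    return out


def classify_variant_tails(carrier_percentiles: np.ndarray, q: float) -> str:
    """Tail class of one variant from its carriers' percentiles."""
    _check_q(q)
    pct = np.asarray(carrier_percentiles, dtype=float)
    if pct.size == 0:
        raise ValueError("carrier percentile list must be nonempty")
    in_low = (pct <= q).any()
    in_high = (pct >= 100.0 - q).any()
    if in_low and in_high:
        return "both"
    if in_low:
        return "exclusively_low"
    if in_high:
        return "exclusively_high"
    return "undetected"


def screen_variants(
    assignments: pd.DataFrame, genotypes: Genotypes, q: float
) -> pd.DataFrame:
    """Per-variant tail classification at one cutoff.

    Returns variant_id, functional_class, carrier count, tail class and
    the cutoff; monomorphic variants are skipped.
    """
    _check_q(q)
    pct = assignments["percentile"].to_numpy()
    rows = []
    for vid in genotypes.variant_ids:
        carriers = genotypes.carriers(vid)
        if carriers.size == 0:
            continue
        rows.append(
            {
                "variant_id": vid,
                "functional_class": genotypes.variants.loc[vid, "functional_class"],
                "k": int(carriers.size),
                "tail_class": classify_variant_tails(pct[carriers], q),
                "q": q,
            }
        )
    return pd.DataFrame(rows)


def screen_counts(screen: pd.DataFrame) -> pd.DataFrame:
    """Counts by tail class x functional class for one cutoff's screen."""
    ct = (
        screen.groupby(["tail_class", "functional_class"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    return ct.reindex(TAIL_CLASSES, fill_value=0)


def capture_statistics(
    cutoffs: list[float],
    detected_counts: list[int],
    total_variants: int,
) -> pd.DataFrame:
    """Detected / missed counts and missed fraction per cutoff.

    ``detected_counts[i]`` is the number of variants with at least one
    carrier inside the tails at ``cutoffs[i]``.  Missed fractions are
    rounded half-up to whole percent, matching printed tables.
    """
    if list(cutoffs) != sorted(cutoffs):
        raise ValueError("cutoffs must be sorted ascending")
    rows = []
    for q, d in zip(cutoffs, detected_counts):
        if d > total_variants:
            raise ValueError("detected count exceeds total variants")
        rows.append(
            {
                "q": q,
                "detected": int(d),
                "missed": int(total_variants - d),
                "detected_pct": percent(d, total_variants),
                "missed_pct": percent(total_variants - d, total_variants),
            }
        )
    out = pd.DataFrame(rows)
    if not out["detected"].is_monotonic_increasing:
        raise ValueError("detection must be nondecreasing in q")
    return out


def tail_asymmetry_test(
    n_low: int,
    n_high: int,
    method: str = "sign_binomial",
    class_counts: tuple[int, int, int, int] | None = None,
) -> float:
    """Two-sided test of low/high tail asymmetry in exclusive detections.

    Default is the exact binomial sign test of ``n_low`` vs ``n_high``
    against a symmetric 0.5 split.  ``method="fisher"`` instead runs an
    exact 2x2 test on the nonsynonymous/synonymous breakdown, which must
    then be supplied as ``class_counts = (ns_low, s_low, ns_high,
    s_high)``; the two constructions can disagree on small tables.
    """
    if n_low < 0 or n_high < 0:
        raise ValueError("counts must be non-negative")
    if n_low + n_high == 0:
        raise ValueError("asymmetry test undefined with no exclusive detections")
    if method == "sign_binomial":
        return float(stats.binomtest(n_low, n_low + n_high, 0.5).pvalue)
    if method == "fisher":
        if class_counts is None:
            raise ValueError("fisher method needs class_counts (ns_low, s_low, ns_high, s_high)")
        ns_low, s_low, ns_high, s_high = class_counts
        table = [[ns_low, s_low], [ns_high, s_high]]
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    raise ValueError(f"unknown method {method!r}")


def run_screen(
    assignments: pd.DataFrame,
    genotypes: Genotypes,
    cutoffs: list[float],
    method: str = "sign_binomial",
) -> pd.DataFrame:
    """Full screening comparison across cutoffs: per-cutoff counts by tail
    class, capture fractions and the asymmetry test."""
    cutoffs = sorted(cutoffs)
    total = int((genotypes.variants["mac"] > 0).sum())
    rows = []
    for q in cutoffs:
        screen = screen_variants(assignments, genotypes, q)
        cls = screen["tail_class"]
        n_low = int((cls == "exclusively_low").sum())
        n_high = int((cls == "exclusively_high").sum())
        n_both = int((cls == "both").sum())
        detected = n_low + n_high + n_both
        p = (
            tail_asymmetry_test(n_low, n_high, method=method)
            if (n_low + n_high) > 0
            else float("nan")
        )
        rows.append(
            {
                "q": q,
                "exclusively_low": n_low,
                "exclusively_high": n_high,
                "both": n_both,
                "detected": detected,
                "missed": total - detected,
                "missed_pct": percent(total - detected, total) if total else 0.0,
                "asymmetry_p": p,
            }
        )
    return pd.DataFrame(rows)


def concordance_report(
    screen: pd.DataFrame,
    ztests: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Cross-tabulate tail-class predictions against population z-tests.

    Predicted class from the screen: ``low`` / ``high`` for exclusive
    tails, ``none`` for variants seen in both tails, ``not_screened`` for
    undetected variants.  Observed class from the whole-population
    heterozygote z-test at level ``alpha``: ``low`` (significant, mean
    percentile < 50), ``high`` (significant, > 50), else ``none``.
    """
    s = screen.set_index("variant_id")
    z = ztests.set_index("variant_id")
    only_screen = set(s.index) - set(z.index)
    only_z = set(z.index) - set(s.index)
    if only_screen or only_z:
        raise ValueError(
            f"variant sets differ between inputs: screen-only={sorted(only_screen)}, "
            f"ztest-only={sorted(only_z)}"
        )
    predicted = s["tail_class"].map(
        {
            "exclusively_low": "low",
            "exclusively_high": "high",
            "both": "none",
            "undetected": "not_screened",
        }
    )
    observed = pd.Series("none", index=z.index)
    sig = z["p"] < alpha
    observed[sig & (z["mean_percentile"] < 50)] = "low"
    observed[sig & (z["mean_percentile"] > 50)] = "high"
    table = pd.crosstab(predicted, observed, rownames=["predicted"], colnames=["observed"])
    return table
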