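"""Variant-spectrum analytics: MAF strata, site-frequency spectrum,
discovery saturation curves and Hardy-Weinberg tests.

The central object is the discovery curve: the expected cumulative number
of distinct variants found after resequencing n of N individuals, overall
and within MAF strata.  The exact curve uses the hypergeometric identity

    E[D(n)] = sum_v [ 1 - C(N - c_v, n) / C(N, n) ]

(c_v = number of carriers of variant v), which follows from linearity of
expectation under a uniformly random resequencing order; the Monte-Carlo
curve averages over random permutations and carries a standard error.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .containers import Genotypes
from ._util import percent

__all__ = [
    "classify_maf",
    "site_frequency_spectrum",
    "discovery_curve_exact",
    "discovery_curve_mc",
    "hwe_test",
    "DEFAULT_STRATA",
]

#: stratum labels in display order
DEFAULT_STRATA = ("common", "rare", "singleton")

_COMMON_MAF_PCT = 1.0  # "common" means MAF strictly above 1%


def classify_maf(
    mac: int, n_individuals: int, common_threshold_pct: float = _COMMON_MAF_PCT
) -> tuple[str, float]:
    """Assign a variant to a MAF stratum.

    Returns ``(stratum, maf_percent)`` where stratum is ``"common"`` for
    MAF strictly above the threshold (default 1%), ``"singleton"`` for
    MAC = 1 regardless of sample size, and ``"rare"`` otherwise; MAF
    exactly at the threshold is rare.
    """
    if mac < 1:
        raise ValueError("monomorphic variant (MAC = 0) has no stratum")
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    maf_pct = 100.0 * mac / (2.0 * n_individuals)
    if maf_pct > common_threshold_pct:
        return "common", maf_pct
    if mac == 1:
        return "singleton", maf_pct
    return "rare", maf_pct


def site_frequency_spectrum(variants: pd.DataFrame) -> tuple[pd.Series, float]:
    """Histogram of variants by carrier count, plus the share observed in
    at most two individuals (rounded half-up to a whole percent).

    ``variants`` must carry a ``carrier_count`` column (one row per
    polymorphic variant).
    """
    if len(variants) == 0:
        raise ValueError("empty variant table")
    counts = variants["carrier_count"].astype(int)
    if (counts < 1).any():
        raise ValueError("carrier counts must be >= 1 (drop monomorphic sites)")
    hist = counts.value_counts().sort_index()
    hist.index.name = "carrier_count"
    hist.name = "n_variants"
    share_le2 = percent(int((counts <= 2).sum()), len(counts))
    return hist, share_le2


def _strata_for_table(variants: pd.DataFrame, n_individuals: int) -> pd.Series:
    return pd.Series(
        [classify_maf(m, n_individuals)[0] for m in variants["mac"]],
        index=variants.index,
        name="stratum",
    )


def discovery_curve_exact(
    carrier_counts: np.ndarray,
    n_individuals: int,
    strata: np.ndarray | None = None,
) -> pd.DataFrame:
    """Exact expected discovery curve under random resequencing order.

    ``carrier_counts`` are the c_v per variant; ``strata`` optionally
    labels each variant so per-stratum curves are returned alongside the
    overall curve.  Computed with log-binomial coefficients for numerical
    safety at large N.
    """
    c = np.asarray(carrier_counts, dtype=int)
    N = int(n_individuals)
    if c.size and (c.min() < 1 or c.max() > N):
        raise ValueError("carrier counts must lie in [1, N]")

    n = np.arange(1, N + 1)

    def log_binom(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    # P(variant v undiscovered after n individuals) = C(N-c, n)/C(N, n)
    prob_hit = np.empty((c.size, N))
    for j, cv in enumerate(c):
        miss = np.zeros(N)
        valid = n <= N - cv
        nv = n[valid]
        miss[valid] = np.exp(log_binom(N - cv, nv) - log_binom(N, nv))
        prob_hit[j] = 1.0 - miss

    out = pd.DataFrame({"n": n, "overall": prob_hit.sum(axis=0)})
    if strata is not None:
        strata = np.asarray(strata)
        for label in dict.fromkeys(strata):
            out[label] = prob_hit[strata == label].sum(axis=0)
    out.attrs["method"] = "exact"
    return out


def discovery_curve_mc(
    genotypes_or_carriers: Genotypes | dict[str, np.ndarray],
    n_individuals: int,
    replicates: int = 1000,
    seed: int | None = None,
    strata: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Monte-Carlo discovery curve: mean cumulative distinct variants over
    random permutations of the resequencing order, with standard errors.

    Accepts a :class:`Genotypes` object or a mapping variant_id -> carrier
    row indices.  ``strata`` optionally maps variant ids to stratum
    labels for per-stratum curves.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if seed is None:
        raise ValueError("seed is mandatory")
    if isinstance(genotypes_or_carriers, Genotypes):
        carrier_map = genotypes_or_carriers.carrier_map()
    else:
        carrier_map = genotypes_or_carriers
    N = int(n_individuals)
    vids = list(carrier_map)
    rng = np.random.default_rng(seed)

    labels = None
    if strata is not None:
        labels = np.array([strata[v] for v in vids])

    overall = np.zeros((replicates, N))
    per_stratum: dict[str, np.ndarray] = {}
    if labels is not None:
        per_stratum = {lab: np.zeros((replicates, N)) for lab in dict.fromkeys(labels)}

    for m in range(replicates):
        order = rng.permutation(N)
        position = np.empty(N, dtype=int)
        position[order] = np.arange(N)  # position[i] = step at which i is sequenced
        first_hit = np.array(
            [position[carrier_map[v]].min() for v in vids], dtype=int
        )
        overall[m] = np.cumsum(np.bincount(first_hit, minlength=N))
        if labels is not None:
            for lab, curve in per_stratum.items():
                hits = first_hit[labels == lab]
                curve[m] = np.cumsum(np.bincount(hits, minlength=N))

    out = pd.DataFrame({"n": np.arange(1, N + 1), "overall": overall.mean(axis=0)})
    out["overall_se"] = overall.std(axis=0, ddof=1) / np.sqrt(replicates) if replicates > 1 else 0.0
    for lab, curve in per_stratum.items():
        out[lab] = curve.mean(axis=0)
    out.attrs["method"] = "monte-carlo"
    out.attrs["replicates"] = replicates
    out.attrs["seed"] = seed
    return out


def observed_order_curve(
    genotypes: Genotypes, order: np.ndarray | None = None
) -> pd.DataFrame:
    """Discovery curve for one fixed resequencing order (default: cohort
    row order) — the curve a single sequencing campaign would draw."""
    N = genotypes.n_individuals
    if order is None:
        order = np.arange(N)
    position = np.empty(N, dtype=int)
    position[order] = np.arange(N)
    first_hit = np.array(
        [position[genotypes.carriers(v)].min() for v in genotypes.variant_ids]
    )
    d = np.cumsum(np.bincount(first_hit, minlength=N))
    out = pd.DataFrame({"n": np.arange(1, N + 1), "overall": d})
    out.attrs["method"] = "observed-order"
    return out


def spectrum_tables(genotypes: Genotypes) -> dict[str, pd.DataFrame]:
    """Convenience: MAF strata, SFS and HWE results for one cohort."""
    n = genotypes.n_individuals
    poly, _ = genotypes.drop_monomorphic()
    table = poly.variants.copy()
    table["stratum"] = _strata_for_table(table, n)
    table["maf_pct"] = 100.0 * table["maf"]
    hwe = np.array(
        [
            hwe_test((row.n_hom_ref, row.n_het, row.n_hom_alt))
            for row in table.itertuples()
        ]
    )
    table["hwe_chi2"] = hwe[:, 0]
    table["hwe_p"] = hwe[:, 1]
    sfs, share_le2 = site_frequency_spectrum(table)
    sfs_df = sfs.reset_index()
    sfs_df.attrs["share_le2_pct"] = share_le2
    return {"variants": table.reset_index(), "sfs": sfs_df}


def hwe_test(genotype_counts: tuple[int, int, int]) -> tuple[float, float]:
    """One-degree-of-freedom chi-square test of Hardy-Weinberg equilibrium.

    ``genotype_counts`` is (hom-ref, het, hom-alt); expectation is formed
    from the sample allele frequency.
    """
    counts = np.asarray(genotype_counts, dtype=float)
    if counts.shape != (3,) or (counts < 0).any():
        raise ValueError("genotype_counts must be three non-negative counts")
    n = counts.sum()
    if n == 0:
        raise ValueError("no genotypes")
    p = (counts[1] + 2 * counts[2]) / (2 * n)
    expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    chi2 = float(terms.sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))
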