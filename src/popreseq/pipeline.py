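"""End-to-end pipeline driver: generate or read a cohort, then run the
enabled analysis stages in order (spectrum -> percentiles -> extremes ->
survival) and collect every stage table into a ResultBundle."""

from __future__ import annotations

import logging
import time
from importlib.metadata import PackageNotFoundError, version

import numpy as np
import pandas as pd

from . import io, percentiles, screen, spectrum, survival, synthetic
from .config import PipelineConfig
from .containers import Genotypes, ResultBundle

log = logging.getLogger("popreseq")

__all__ = ["run_pipeline"]


def _package_version() -> str:
    try:
        return version("popreseq")
    except PackageNotFoundError:
        return "unknown"


class _StageTimer:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, *exc):
        log.info("stage %s: done in %.2fs", self.name, time.perf_counter() - self.t0)
        return False


def _load_inputs(config: PipelineConfig) -> tuple[pd.DataFrame, Genotypes]:
    if config.generator is not None:
        return synthetic.generate_cohort(config.generator)
    cohort = io.read_cohort(config.cohort_path)
    genotypes = io.read_genotypes(config.vcf_path, cohort)
    return cohort, genotypes


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    """Execute the enabled stages and return all result tables.

    The bundle's metadata records the seed, the config hash and the
    package version, which is sufficient to re-run the identical
    analysis; with a generator config the whole run is a pure function of
    the config.
    """
    bundle = ResultBundle(
        metadata={
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "popreseq_version": _package_version(),
        }
    )
    with _StageTimer("inputs"):
        cohort, genotypes = _load_inputs(config)
    poly, dropped = genotypes.drop_monomorphic()
    if dropped:
        log.info("excluding %d monomorphic variants", len(dropped))
    bundle.metadata["n_individuals"] = len(cohort)
    bundle.metadata["n_variants"] = len(poly.variant_ids)

    n = len(cohort)

    if config.run_spectrum and poly.variant_ids:
        with _StageTimer("spectrum"):
            tables = spectrum.spectrum_tables(poly)
            bundle.add("spectrum", "variants", tables["variants"])
            bundle.add("spectrum", "sfs", tables["sfs"])
            strata = {
                row.variant_id: spectrum.classify_maf(row.mac, n)[0]
                for row in tables["variants"].itertuples()
            }
            exact = spectrum.discovery_curve_exact(
                tables["variants"]["carrier_count"].to_numpy(),
                n,
                strata=np.array([strata[v] for v in tables["variants"]["variant_id"]]),
            )
            bundle.add("spectrum", "discovery_exact", exact)
            mc = spectrum.discovery_curve_mc(
                poly, n, replicates=config.mc_replicates, seed=config.seed, strata=strata
            )
            bundle.add("spectrum", "discovery_mc", mc)

    assignments = {}
    if config.run_percentiles or config.run_extremes:
        with _StageTimer("percentiles"):
            for trait in config.traits:
                assignments[trait] = percentiles.assign_percentiles(cohort, trait)

    if config.run_percentiles and poly.variant_ids:
        with _StageTimer("ztests"):
            for trait, asn in assignments.items():
                ztab = percentiles.per_variant_ztests(asn, poly)
                bundle.add("percentiles", f"ztests_{trait}", ztab)
            grouping = {
                label: [
                    v
                    for v in poly.variant_ids
                    if poly.variants.loc[v, "functional_class"] == label
                ]
                for label in ("NS", "S")
            }
            grouping = {k: v for k, v in grouping.items() if v}
            if grouping:
                per_group, pairwise = percentiles.burden_collapse(
                    assignments[config.traits[0]], poly, grouping
                )
                bundle.add("percentiles", "burden", per_group)
                if len(pairwise):
                    bundle.add("percentiles", "burden_pairwise", pairwise)
                var_groups = dict(grouping)
                var_groups["all"] = sum(grouping.values(), [])
                for trait in config.traits:
                    vtab = percentiles.variance_explained(cohort, trait, poly, var_groups)
                    bundle.add("percentiles", f"variance_{trait}", vtab)

    if config.run_extremes and config.extreme_cutoffs and poly.variant_ids:
        with _StageTimer("extremes"):
            trait = config.traits[0]
            asn = assignments[trait]
            table = screen.run_screen(asn, poly, list(config.extreme_cutoffs))
            bundle.add("extremes", "screen", table)
            ztab = percentiles.per_variant_ztests(asn, poly)
            q_ref = max(q for q in config.extreme_cutoffs)
            per_variant = screen.screen_variants(asn, poly, min(20.0, q_ref))
            conc = screen.concordance_report(per_variant, ztab)
            bundle.add("extremes", "concordance", conc.reset_index())

    if config.run_survival and poly.variant_ids:
        with _StageTimer("survival"):
            groupings = {}
            for label in config.survival_groups:
                vids = [
                    v
                    for v in poly.variant_ids
                    if poly.variants.loc[v, "functional_class"] == label
                ]
                if vids:
                    groupings[label] = vids
            if config.survival_exclusions and "NS" in groupings:
                groupings["NS_excl"] = [
                    v
                    for v in groupings["NS"]
                    if v not in set(config.survival_exclusions)
                ]
            if groupings:
                records, exclusions = survival.build_survival_records(
                    cohort, poly, groupings
                )
                bundle.metadata["survival_exclusions"] = exclusions
                fits = []
                for label in groupings:
                    try:
                        fits.append(survival.fit_cox(records, label))
                    except (ValueError, RuntimeError) as err:
                        log.warning("survival fit for %s skipped: %s", label, err)
                if fits:
                    bundle.add(
                        "survival",
                        "cox",
                        pd.DataFrame([f.__dict__ for f in fits]),
                    )
    return bundle
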