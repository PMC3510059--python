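"""Configuration objects for cohort simulation and the analysis pipeline.

The generator emulates two Danish-style general-population cohorts: a
10,330-person discovery study and a 45,239-person
validation study, with nonfasting lipid panels, binary cardiovascular
covariates and registry-style myocardial-infarction follow-up.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

FUNCTIONAL_CLASSES = ("NS", "S", "promoter", "intronic", "UTR")


@dataclass(frozen=True)
class VariantSpec:
    """A variant to plant in a simulated cohort.

    Effects are additive per minor allele on the measurement scale; a
    variant may carry a myocardial-infarction hazard without any lipid
    effect (the amyloidosis-like channel).
    """

    variant_id: str
    functional_class: str
    allele_freq: float
    apoa1_effect: float = 0.0  # mg/dL per allele
    hdl_effect: float = 0.0  # mmol/L per allele
    log_hr_mi: float = 0.0  # log hazard ratio per allele

    def __post_init__(self) -> None:
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise ValueError(
                f"functional_class must be one of {FUNCTIONAL_CLASSES}, "
                f"got {self.functional_class!r}"
            )
        if not 0.0 < self.allele_freq <= 0.5:
            raise ValueError(
                f"allele_freq must lie in (0, 0.5], got {self.allele_freq}"
            )
        for name in ("apoa1_effect", "hdl_effect", "log_hr_mi"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class GompertzHazard:
    """Gompertz baseline hazard for MI on the age axis.

    ``rate_at_20`` is the hazard per year at age 20; the hazard doubles
    every ``doubling_years`` thereafter.  Any parametric baseline would do
    for a semi-parametric Cox analysis; Gompertz gives the exponential age
    climb seen in registry MI incidence.
    """

    rate_at_20: float = 5e-5
    doubling_years: float = 8.0

    def __post_init__(self) -> None:
        if self.rate_at_20 <= 0 or self.doubling_years <= 0:
            raise ValueError("hazard parameters must be positive")

    @property
    def shape(self) -> float:
        return math.log(2.0) / self.doubling_years


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one simulated cohort.

    ``seed`` is mandatory: every draw in the generator is derived from it,
    so a config fixes every output byte.
    """

    n_individuals: int
    seed: int
    study_label: str = "DISCOVERY"
    age_range: tuple[float, float] = (20.0, 82.0)
    sex_ratio: float = 0.56  # fraction female
    apoa1_median: float = 140.0  # mg/dL
    apoa1_log_sd: float = 0.20
    hdl_median: float = 1.5  # mmol/L
    hdl_sd: float = 0.45
    hdl_target_corr: float = 0.83
    variant_specs: tuple[VariantSpec, ...] = ()
    followup_years: float = 24.0
    baseline_hazard: GompertzHazard = field(default_factory=GompertzHazard)
    prior_mi_prob: float = 0.005

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")
        if not abs(self.hdl_target_corr) <= 1.0:
            raise ValueError("|hdl_target_corr| must be <= 1")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be (min, max) with min < max")
        if self.seed is None:  # guards dict-built configs
            raise ValueError("seed is mandatory")
        object.__setattr__(self, "variant_specs", tuple(self.variant_specs))


@dataclass
class PipelineConfig:
    """Inputs, stage toggles and output location for a pipeline run."""

    seed: int
    out_dir: str = "results"
    cohort_path: str | None = None
    vcf_path: str | None = None
    generator: GeneratorConfig | None = None
    run_spectrum: bool = True
    run_percentiles: bool = True
    run_extremes: bool = True
    run_survival: bool = True
    extreme_cutoffs: tuple[float, ...] = (1.0, 5.0, 10.0, 20.0, 50.0)
    traits: tuple[str, ...] = ("apoa1", "hdl")
    survival_groups: tuple[str, ...] = ("NS", "S")
    survival_exclusions: tuple[str, ...] = ()
    mc_replicates: int = 1000

    def __post_init__(self) -> None:
        if self.generator is None and (self.cohort_path is None or self.vcf_path is None):
            raise ValueError(
                "either a generator config or both cohort_path and vcf_path "
                "must be provided"
            )
        for q in self.extreme_cutoffs:
            if not 0.0 < q <= 50.0:
                raise ValueError(f"extreme cutoff {q} outside (0, 50]")

    def config_hash(self) -> str:
        payload = json.dumps(_to_jsonable(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _to_jsonable(cfg) -> dict:
    return asdict(cfg)


def _generator_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    specs = tuple(VariantSpec(**v) for v in d.pop("variant_specs", []))
    hazard = d.pop("baseline_hazard", None)
    kwargs = dict(d, variant_specs=specs)
    if hazard is not None:
        kwargs["baseline_hazard"] = GompertzHazard(**hazard)
    if "age_range" in kwargs:
        kwargs["age_range"] = tuple(kwargs["age_range"])
    return GeneratorConfig(**kwargs)


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline config from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    gen = raw.pop("generator", None)
    kwargs = dict(raw)
    if gen is not None:
        kwargs["generator"] = _generator_from_dict(gen)
    for key in ("extreme_cutoffs", "traits", "survival_groups", "survival_exclusions"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    return PipelineConfig(**kwargs)


def save_pipeline_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_jsonable(cfg), fh, sort_keys=False)
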