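import numpy as np
import pytest

from popreseq import synthetic as syn
from popreseq.config import GeneratorConfig, VariantSpec


@pytest.fixture(scope="session")
def discovery_config() -> GeneratorConfig:
    """A discovery-scale study: 10,330 individuals, 40-variant panel."""
    return GeneratorConfig(
        n_individuals=10330,
        seed=20123,
        study_label="DISCOVERY",
        variant_specs=syn.default_variant_panel(seed=77),
    )


@pytest.fixture(scope="session")
def discovery_study(discovery_config):
    """(cohort, genotypes) for the discovery-scale study."""
    return syn.generate_cohort(discovery_config)


@pytest.fixture(scope="session")
def null_cohort():
    """An effect-free cohort for calibration checks."""
    cfg = GeneratorConfig(n_individuals=10330, seed=999, study_label="NULL")
    cohort, geno = syn.generate_cohort(cfg)
    return cohort, geno


@pytest.fixture(scope="session")
def mini_config() -> GeneratorConfig:
    specs = (
        VariantSpec("big_ns", "NS", 0.004, apoa1_effect=-39.0, hdl_effect=-0.9),
        VariantSpec("null_ns", "NS", 0.01),
        VariantSpec("null_s", "S", 0.02),
        VariantSpec("risk_ns", "NS", 0.01, log_hr_mi=float(np.log(1.7))),
        VariantSpec("common_prom", "promoter", 0.16),
    )
    return GeneratorConfig(
        n_individuals=600, seed=42, study_label="MINI", variant_specs=specs
    )


@pytest.fixture(scope="session")
def mini(mini_config):
    return syn.generate_cohort(mini_config)
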