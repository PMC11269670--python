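"""Shared fixtures: synthetic plates and cohorts reused across test modules.

Session scope keeps the expensive cohort analyses to a single run each.
"""

from dataclasses import replace

import pytest

from burdenkit.pipeline import analyze_cohort
from burdenkit.synthdata import SyntheticConfig, generate_cohort, generate_plate


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig()


@pytest.fixture(scope="session")
def default_plate(default_config):
    """One default-noise plate with its truth table (seed frozen)."""
    return generate_plate(default_config, seed=42)


@pytest.fixture(scope="session")
def noise_free_plate(default_config):
    return generate_plate(default_config.noise_free(), seed=43)


# Cohort used for ordering/recovery checks: composition from the detection
# example (about 20% of parts in the >= 10% burden tail), parts measured on
# 3 plates (n = 9 replicates).
@pytest.fixture(scope="session")
def ordering_cohort(default_config):
    cfg = replace(
        default_config,
        burden_zero_weight=0.40,
        burden_shoulder_weight=0.40,
    )
    return generate_cohort(cfg, n_parts=46, seed=7, plates_per_part=3)


@pytest.fixture(scope="session")
def ordering_analysis(ordering_cohort):
    return analyze_cohort(ordering_cohort, seed=17)


@pytest.fixture(scope="session")
def null_cohort(default_config):
    """All-zero-burden cohort for type-I checks."""
    cfg = replace(default_config, burden_zero_weight=1.0, burden_shoulder_weight=0.0)
    return generate_cohort(cfg, n_parts=46, seed=3)


@pytest.fixture(scope="session")
def null_analysis(null_cohort):
    return analyze_cohort(null_cohort, run_capacity=False)
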