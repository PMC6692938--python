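"""Shared fixtures: synthetic cohorts at the sizes the analyses assume."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cptmethsig.diffmeth import (differential_methylation, extract_signature,
                                 labels_from_diagnosis)
from cptmethsig.filtering import filter_probes
from cptmethsig.simulate import PlantedTier, SimulationConfig, simulate_cohort


def recovery_config(seed: int = 101) -> SimulationConfig:
    """Benchmark cohort: 2000 probes, 200 planted at delta-beta 0.4,
    20 carcinomas (7 hom / 9 het / 4 wt) vs 20 papillomas, kappa 50."""
    return SimulationConfig(
        n_probes=2000, planted=(PlantedTier(200, 0.40),),
        n_cpc_hom=7, n_cpc_het=9, n_cpc_wt=4, n_acpp=5, n_cpp=15,
        kappa=50.0, seed=seed)


def null_config(n_probes: int = 1000, seed: int = 0) -> SimulationConfig:
    """No planted probes, equal hazards: the type-I-error condition."""
    return SimulationConfig(
        n_probes=n_probes, planted=(),
        n_promoter_linked=0, n_body_linked=0,
        hazard_cpc_hom=0.01, hazard_cpc_other=0.01, hazard_papilloma=0.01,
        seed=seed)


@pytest.fixture(scope="session")
def recovery_cohort():
    return simulate_cohort(recovery_config())


@pytest.fixture(scope="session")
def recovery_filtered(recovery_cohort):
    filtered, _ = filter_probes(recovery_cohort.beta, recovery_cohort.annotation)
    return filtered


@pytest.fixture(scope="session")
def recovery_labels(recovery_cohort):
    return labels_from_diagnosis(recovery_cohort.metadata["diagnosis"])


@pytest.fixture(scope="session")
def recovery_diffmeth(recovery_filtered, recovery_labels):
    return differential_methylation(recovery_filtered, recovery_labels)


@pytest.fixture(scope="session")
def recovery_tier1(recovery_diffmeth, recovery_cohort):
    return extract_signature(recovery_diffmeth, "tier1",
                             recovery_cohort.annotation)


@pytest.fixture(scope="session")
def recovery_tier2(recovery_diffmeth, recovery_cohort):
    return extract_signature(recovery_diffmeth, "tier2",
                             recovery_cohort.annotation)


@pytest.fixture(scope="session")
def small_cohort():
    """Cheap cohort for IO/round-trip and smoke tests."""
    cfg = SimulationConfig(n_probes=120, planted=(PlantedTier(12, 0.4),),
                           n_cpc_hom=2, n_cpc_het=2, n_cpc_wt=1,
                           n_acpp=2, n_cpp=4,
                           n_promoter_linked=3, n_body_linked=2, seed=5)
    return simulate_cohort(cfg)
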