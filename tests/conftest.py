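from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from offtarget_burden.cohortsim import CallerProfile, SimConfig, simulate

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_noise_free_config(seed: int, capture_bp: int = 200_000) -> SimConfig:
    """F1-only study conditions with perfect callers and no artifact
    substrate: the parameter-recovery setting (all true AFs are 0.5)."""
    return SimConfig(
        seed=seed,
        capture_bp=capture_bp,
        include_f0=False,
        denovo_indel_fraction=0.0,
        founder_indel_fraction=0.0,
        dbsnp_extra_density=0.0,
        repeat_tracts_per_chrom=0,
        segdup_tracts_per_chrom=0,
        profiles=[
            CallerProfile.noise_free("germline"),
            CallerProfile.noise_free("somatic"),
        ],
    )


@pytest.fixture(scope="session")
def default_sim():
    """Full 70-sample cohort with default caller noise at reduced capture."""
    return simulate(SimConfig(seed=11, capture_bp=150_000))


@pytest.fixture(scope="session")
def noise_free_sim():
    return simulate(make_noise_free_config(seed=5))
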