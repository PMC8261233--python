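import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from flowmod import CohortConfig, EventTable, GatingParams, SerumSample, SimParams

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def gparams() -> GatingParams:
    return GatingParams()


@pytest.fixture(scope="session")
def small_params() -> SimParams:
    """Reduced event count for fast unit tests; defaults otherwise."""
    return SimParams(n_events_per_well=8_000, seed=11)


@pytest.fixture(scope="session")
def healthy_sample() -> SerumSample:
    return SerumSample(sample_id="HC01", category="healthy")


@pytest.fixture(scope="session")
def positive_sample() -> SerumSample:
    return SerumSample(
        sample_id="POS01",
        category="seropositive_AAG",
        true_conc_pM=1500.0,
        ria_pM=1500.0,
    )


@pytest.fixture(scope="session")
def tiny_cohort() -> CohortConfig:
    """18-serum cohort for end-to-end tests."""
    return CohortConfig(
        group_sizes={
            "seropositive_AAG": 2,
            "blinded": 2,
            "probable_AAG": 1,
            "seronegative_AAG": 1,
            "healthy": 6,
            "autonomic_not_AAG": 2,
            "other_neuro": 2,
            "SLE": 2,
        },
        blinded_positive=1,
        plate_capacity=10,
        seed=11,
    )


def make_table(n: int, *, fsc_a=50_000.0, fsc_h=None, ssc_a=30_000.0,
               apc=20.0, pe=50.0, rng=None) -> EventTable:
    """Synthetic hand-built event table; scalar args broadcast, arrays pass
    through."""
    def col(v):
        arr = np.broadcast_to(np.asarray(v, dtype=float), (n,)).copy()
        return arr

    data = {
        "FSC-A": col(fsc_a),
        "FSC-H": col(fsc_a if fsc_h is None else fsc_h),
        "SSC-A": col(ssc_a),
        "APC-A": col(apc),
        "PE-A": col(pe),
    }
    return EventTable(events=pd.DataFrame(data))
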