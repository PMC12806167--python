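import numpy as np
import pytest

from dfncstates import (
    CohortConfig,
    ComponentTimecourse,
    FNCConfig,
    WindowedFNC,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250925)


@pytest.fixture(scope="session")
def tiny_cohort_config():
    """Small, fast cohort used by pipeline-level tests."""
    return CohortConfig(
        n_per_cell={
            ("MDD", "active"): 3,
            ("MDD", "sham"): 3,
            ("HC", "active"): 2,
            ("HC", "sham"): 2,
        },
        n_components=8,
        n_timepoints=80,
        self_transition=0.95,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_cohort_config):
    return simulate_cohort(tiny_cohort_config, seed=11)


@pytest.fixture(scope="session")
def tiny_fnc_config():
    return FNCConfig(width=10, sigma=1.5)


def make_wfnc(z, subject="sub-001", condition="rest_pre", width=10, sigma=1.5):
    """Build a WindowedFNC directly from a stack of symmetric z matrices."""
    z = np.asarray(z, dtype=float)
    return WindowedFNC(
        z=z,
        offsets=np.arange(z.shape[0]),
        lambda_used=0.1,
        subject_id=subject,
        condition=condition,
        width=width,
        sigma=sigma,
    )


def smooth_timecourse(t_len=120, n_comp=3, tr=2.0, freq=0.02, seed=0):
    """Low-frequency multi-component signal for filter-identity style checks."""
    rng = np.random.default_rng(seed)
    t = np.arange(t_len) * tr
    phases = rng.uniform(0, 2 * np.pi, n_comp)
    amps = rng.uniform(0.5, 2.0, n_comp)
    data = np.sin(2 * np.pi * freq * t[:, None] + phases[None, :]) * amps[None, :]
    return ComponentTimecourse(data=data, tr_seconds=tr)
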