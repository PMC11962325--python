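import numpy as np
import pandas as pd
import pytest

from wardaki import SimConfig, make_fixture_cohort, simulate_cohort

T0 = pd.Timestamp("2021-06-01 08:00")


def random_trajectories(n: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random irregular SCr trajectories (hours, values) with occasional
    jumps and dips so both detectors fire on a sizable minority."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        k = int(rng.integers(4, 11))
        hours = np.sort(rng.uniform(0, 24 * 12, k)) + np.arange(k) * 1e-3
        base = rng.uniform(0.4, 1.3)
        vals = base + rng.normal(0, 0.12, k)
        for j in range(k):
            u = rng.random()
            if u < 0.12:
                vals[j] += rng.uniform(0.2, 1.0)
            elif u < 0.20:
                vals[j] -= rng.uniform(0.2, 0.4)
        out.append((hours, np.round(np.clip(vals, 0.15, None), 2)))
    return out


def hours_to_times(hours) -> np.ndarray:
    return (T0 + pd.to_timedelta(hours, "h")).values


@pytest.fixture(scope="session")
def fixture_cohort():
    return make_fixture_cohort()


@pytest.fixture(scope="session")
def dense_cohort():
    """Small cohort with daily sampling: every planted label recoverable."""
    cfg = SimConfig(n_patients=150, seed=42, sampling_prob=1.0)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def sparse_cohort():
    """Default (sparse) sampling: exercises indeterminate/excluded branches."""
    cfg = SimConfig(n_patients=200, seed=7, event_sampling_prob=0.6)
    return simulate_cohort(cfg)
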