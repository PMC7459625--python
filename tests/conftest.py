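import numpy as np
import pandas as pd
import pytest

from locomix import (
    OPTIMAL_NLMM,
    FixedEffects,
    SimulationDesign,
    VarianceComponents,
    fit,
    simulate_panel,
)

# Optimal-mixed-model point estimates of the reference rat study; used as
# generating truth throughout the suite.
REF_THETA = FixedEffects(xi0=4.319, beta1=0.066, beta2=-0.006, omega1=9.063)
REF_DELTA = VarianceComponents(psi2=0.0018, phi2=0.0019, sigma2=0.0015)


@pytest.fixture(scope="session")
def ref_theta():
    return REF_THETA


@pytest.fixture(scope="session")
def ref_delta():
    return REF_DELTA


@pytest.fixture(scope="session")
def default_truth():
    """One full-design simulated panel with known ground truth."""
    return simulate_panel(SimulationDesign(seed=20140416))


@pytest.fixture(scope="session")
def default_panel(default_truth):
    return default_truth.panel


@pytest.fixture(scope="session")
def optimal_fit(default_panel):
    """Optimal-spec mixed fit of the default simulated panel (shared)."""
    result = fit(default_panel, OPTIMAL_NLMM)
    assert result.converged
    return result


def small_panel(n_animals=3, n_days=4, seed=0, sigma=0.05):
    """Tiny synthetic panel for oracle comparisons (not from the generator)."""
    rng = np.random.default_rng(seed)
    rows = []
    doses = [0.0, 2.0, 5.0, 3.5]
    for i in range(n_animals):
        for t in range(-1, n_days - 1):
            rows.append(
                {
                    "animal_id": f"A{i}",
                    "dose_gy": doses[i % len(doses)],
                    "day": t,
                    "log_activity": 4.3 + sigma * rng.standard_normal(),
                }
            )
    return pd.DataFrame(rows)
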