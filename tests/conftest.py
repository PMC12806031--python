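import numpy as np
import pandas as pd
import pytest

from glucoflux.network import load_curated_network
from glucoflux.simulate import SimConfig, simulate_cohort, simulate_network


@pytest.fixture(scope="session")
def curated_net():
    return load_curated_network()


@pytest.fixture(scope="session")
def small_network():
    """4 internal metabolites, 8 sinks, planted truth."""
    return simulate_network(4, 8, seed=1)


@pytest.fixture(scope="session")
def cohort():
    """Default 50/50 synthetic cohort on the 10-internal/8-sink network."""
    network, truth = simulate_network(10, 8, seed=1)
    expr, meta, truth, sets = simulate_cohort(network, SimConfig(seed=1), truth)
    return network, expr, meta, truth, sets


@pytest.fixture(scope="session")
def cohort_priors(cohort):
    _, _, _, truth, _ = cohort
    return pd.DataFrame(
        {
            "reaction_id": truth.true_eff.index,
            "eff0": truth.true_eff.to_numpy(),
            "source": "curated",
        }
    )


def two_sink_kkt(w1, w2, B1, B2, V, lam):
    """Analytic optimum of the two-variable allocation QP (test oracle).

    Substituting v2 = V - v1 makes the objective concave in v1 with
    unconstrained maximizer V/2 + (w1 - w2)/(4 lam); the constrained
    optimum clips it to the feasible interval [max(0, V-B2), min(B1, V)].
    """
    lo = max(0.0, V - B2)
    hi = min(B1, V)
    if lo > hi + 1e-12:
        raise ValueError("infeasible")
    v1 = np.clip(V / 2 + (w1 - w2) / (4 * lam), lo, hi)
    return float(v1), float(V - v1)
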