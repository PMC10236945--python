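"""Shared fixtures: small synthetic patients and graph oracles."""

import warnings

import numpy as np
import pytest

from spikevcr.pipeline import run_pipeline
from spikevcr.synthetic import SimScenario, simulate_patient


@pytest.fixture(scope="session")
def tiny_patient():
    """Small but complete synthetic patient (121 sources, 10 spikes)."""
    scn = SimScenario(n_per_side=7, cluster_size=8, n_spikes=10, seed=3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundle, truth = simulate_patient(scn)
    return scn, bundle, truth


@pytest.fixture(scope="session")
def tiny_result(tiny_patient):
    """Pipeline output on the small patient, shared across tests."""
    _, bundle, _ = tiny_patient
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(bundle)


def oracle_synchronizability(a: np.ndarray) -> float:
    """Independent eigenratio computation (scipy dense solver)."""
    from scipy.linalg import eigh

    lap = np.diag(a.sum(axis=1)) - a
    w = eigh(lap, eigvals_only=True)
    if w[-1] < 1e-12 or w[1] < 1e-12 * max(1.0, w[-1]):
        return 0.0
    return float(w[1] / w[-1])


def oracle_control_centrality(a: np.ndarray) -> np.ndarray:
    """Exhaustive-deletion oracle built on the scipy eigensolver."""
    s = oracle_synchronizability(a)
    n = len(a)
    out = np.empty(n)
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        out[i] = (oracle_synchronizability(a[np.ix_(keep, keep)]) - s) / s
    return out


def random_connected_graph(rng: np.random.Generator, n: int) -> np.ndarray:
    """Seeded dense weighted graph (connected by construction)."""
    a = rng.uniform(0.1, 1.0, size=(n, n))
    a = 0.5 * (a + a.T)
    np.fill_diagonal(a, 0.0)
    return a
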