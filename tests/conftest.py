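import numpy as np
import pytest

import thalnet as tn
from thalnet.experiments import HIGH_NOISE, LOW_NOISE, Condition, derive_seed, g_sweep
from thalnet.synthetic import (
    ConnectomeGenSpec,
    ReferenceRun,
    generate_cohort,
    generate_pseudo_empirical,
)


@pytest.fixture(scope="session")
def jr():
    return tn.JRParameters()


@pytest.fixture(scope="session")
def single_node():
    """One uncoupled region (empty weight matrix)."""
    return tn.StructuralConnectome(["roi"], ["cortical"], np.zeros((1, 1)), np.zeros((1, 1)))


@pytest.fixture(scope="session")
def random_sc():
    """Factory for small random valid connectomes."""

    def make(n=8, n_driver=2, seed=0, driver_role="thalamic"):
        rng = np.random.default_rng(seed)
        w = rng.uniform(0.5, 10.0, size=(n, n))
        w = np.triu(w, k=1)
        w = w + w.T
        d = rng.uniform(20.0, 150.0, size=(n, n))
        d = np.triu(d, k=1)
        d = d + d.T
        roles = ["cortical"] * (n - n_driver) + [driver_role] * n_driver
        labels = [f"r{i}" for i in range(n)]
        return tn.StructuralConnectome(labels, roles, w, d, subject_id=f"toy-{seed}")

    return make


@pytest.fixture(scope="session")
def toy_sc(random_sc):
    return random_sc(n=8, n_driver=2, seed=3)


@pytest.fixture(scope="session")
def cohort5():
    """Five synthetic subjects at the generator's default study conditions."""
    return generate_cohort(5, ConnectomeGenSpec(), seed=7)


@pytest.fixture(scope="session")
def targets5(cohort5):
    """Pseudo-empirical FC/dFC targets from hidden high-driver-noise runs at g*=4."""
    return [
        generate_pseudo_empirical(
            sc, ReferenceRun(g=4.0), noise_sd=0.02, seed=derive_seed(7, 0xEE, k)
        )
        for k, sc in enumerate(cohort5)
    ]


@pytest.fixture(scope="session")
def main_sweep(cohort5, targets5):
    """Coupling sweep over the noise-condition factorial on the cohort.

    Parceled driver variant under three drive parametrizations: high
    driver noise, low driver noise, and high noise on driver AND cortex
    (the whole-cortex noise control). 10-s simulations, prebifurcation
    coupling grid.
    """
    conditions = [
        Condition(sc_variant="parceled", driver_eta=HIGH_NOISE),
        Condition(sc_variant="parceled", driver_eta=LOW_NOISE),
        Condition(sc_variant="parceled", driver_eta=HIGH_NOISE, cortical_eta=HIGH_NOISE),
    ]
    cfg = tn.SimulationConfig(duration=10_000.0, transient=2_000.0, seed=7)
    return g_sweep(cohort5, conditions, np.arange(0.0, 7.0), 1, cfg, targets5)
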