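import time

import numpy as np
import pytest

from vasoloop import scoring
from vasoloop.config import load_config
from vasoloop.controllers import anfis as anfis_mod


@pytest.fixture(scope="session")
def default_config():
    return load_config()


@pytest.fixture(scope="session")
def battery(default_config):
    """One full 10-configuration x 3-scenario battery plus its wall time."""
    from vasoloop.runner import run_battery
    t0 = time.perf_counter()
    result = run_battery(default_config, seed=0)
    return result, time.perf_counter() - t0


@pytest.fixture(scope="session")
def reference_panels():
    return {s: scoring.load_reference_panel(s) for s in scoring.SCENARIOS}


@pytest.fixture(scope="session")
def reference_terms():
    return scoring.load_reference_terms()


def make_synthetic_anfis(seed: int = 42):
    """A known 9-rule generating model plus samples drawn from it.

    Used as the simulate-then-fit oracle for hybrid training: the fitted
    network must reproduce this model's input-output map on held-out data.
    """
    rng = np.random.default_rng(seed)
    premises = np.array([
        [[10.0, 2.0, -10.0], [10.0, 2.0, 10.0], [10.0, 2.0, 30.0]],
        [[0.1, 2.0, -0.15], [0.1, 2.0, 0.0], [0.1, 2.0, 0.15]],
    ])
    consequents = np.stack([
        rng.uniform(-0.05, 0.05, 9),
        rng.uniform(-2.0, 2.0, 9),
        rng.uniform(0.0, 3.0, 9),
    ], axis=1)
    truth = anfis_mod.AnfisModel(premises=premises, consequents=consequents)
    X = np.column_stack([rng.uniform(-20, 40, 600), rng.uniform(-0.3, 0.3, 600)])
    y = anfis_mod.anfis_forward(truth, X[:, 0], X[:, 1])
    return truth, np.column_stack([X, y])
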