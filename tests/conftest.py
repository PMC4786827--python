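"""Shared fixtures.

The baseline replicate batch is expensive (replicates of the full
5000-generation reference configuration) and is shared session-wide by the
tests that probe long-run behavior.
"""

from __future__ import annotations

import numpy as np
import pytest

from mlsel_pgg import SimConfig
from mlsel_pgg.experiments import run_replicates

BASELINE_RUNS = 50
BASELINE_SEED = 42


@pytest.fixture(scope="session")
def baseline_batch():
    """Replicates of the reference configuration (random init, T=5000)."""
    return run_replicates(SimConfig(), runs=BASELINE_RUNS, base_seed=BASELINE_SEED)


@pytest.fixture(scope="session")
def weak_selection_batch():
    """Replicates at weak intra-group selection (w0 = 5)."""
    return run_replicates(SimConfig(w0=5.0), runs=3, base_seed=2042)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
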