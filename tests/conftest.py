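"""Shared fixtures: the heavy learning runs are session-scoped so several
tests (acceptance checks and engine invariants) reuse one simulation."""

import pytest

from burstnet import experiments
from burstnet.experiments import population_metrics  # re-export for tests

__all__ = ["population_metrics"]


@pytest.fixture(scope="session")
def fig1_run():
    """Scaled feedforward burst-homeostasis run (strong dendritic drive)."""
    return experiments.burst_homeostasis(seed=11)


@pytest.fixture(scope="session")
def fig3_run():
    """Scaled recurrent noise-free microcircuit learned to its doubly-AI state."""
    return experiments.doubly_ai_state(seed=11)
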