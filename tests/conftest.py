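"""Shared fixtures: the default multi-batch simulation and its MASI chain.

The heavy objects (4500-cell fixture, discovered markers, scores, serial
consensus annotation) are built once per session and shared between the
unit and acceptance tests.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from masi import (
    annotate,
    discover_markers,
    log_normalize,
    score_cells,
    simulate_multibatch,
)

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_default():
    """Default study conditions: 5 types x 3 batches x 300 cells/type/batch."""
    return simulate_multibatch()


@pytest.fixture(scope="session")
def lognorm_default(sim_default):
    expr, _ = sim_default
    return log_normalize(expr)


@pytest.fixture(scope="session")
def markers_default(sim_default, lognorm_default):
    _, truth = sim_default
    return discover_markers(lognorm_default, truth.cell_types)


@pytest.fixture(scope="session")
def scores_default(lognorm_default, markers_default):
    return score_cells(lognorm_default, markers_default)


@pytest.fixture(scope="session")
def annotation_default(sim_default, markers_default):
    expr, _ = sim_default
    return annotate(expr, markers_default)


@pytest.fixture
def small_lognorm():
    """Tiny deterministic log-normalized matrix for hand-checkable tests."""
    from masi import ExpressionMatrix

    rng = np.random.default_rng(7)
    values = rng.gamma(2.0, 1.0, size=(12, 6))
    return ExpressionMatrix(
        values,
        [f"c{i}" for i in range(12)],
        [f"g{j}" for j in range(6)],
        layer="lognorm",
    )
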