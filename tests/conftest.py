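"""Shared fixtures.

The expensive steady-state FDTD validation runs (six piston cases, the
seeded skull-phantom focusing comparison) are computed once per session and
shared between the tests that grade different aspects of the same runs.
"""

from __future__ import annotations

import numpy as np
import pytest


@pytest.fixture(scope="session")
def piston_results():
    """All six piston validation cases at the desk-scale grid, 60 periods.

    The lossless circular simulation is kept alive so the steady-state
    (60 → 90 period) criterion can extend it without a rerun.
    """
    from tcfus.runs import PISTON_VALIDATION_CASES, run_piston_case

    out = {}
    for kind, lossy in PISTON_VALIDATION_CASES:
        out[(kind, lossy)] = run_piston_case(
            kind, lossy, keep_simulation=(kind == "circular" and not lossy))
    return out


@pytest.fixture(scope="session")
def steady_state_delta_percent(piston_results):
    """Max on-axis |Δp| (percent of peak) between 60- and 90-period runs."""
    from tcfus.runs import steady_state_change

    return steady_state_change(
        piston_results[("circular", False)], extra_periods=30)


@pytest.fixture(scope="session")
def focus_comparison():
    """Seeded skull-shell focusing study: all four correction strategies."""
    from tcfus.runs import make_focus_scenario, run_focus_comparison

    scenario = make_focus_scenario(seed=1)
    results = run_focus_comparison(scenario)
    return scenario, results


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
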