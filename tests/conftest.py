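"""Shared fixtures: solved cases are expensive enough to cache per session."""

from __future__ import annotations

import pytest

from perisim.scenarios import Scenario, SolverSettings, run_case

GEOMETRY_LABELS = ("LS", "LE", "LT", "SS", "SE", "ST")


@pytest.fixture(scope="session")
def baseline_cases():
    """Six baseline cisplatin cases (transient to 3600 s + steady)."""
    return {g: run_case(Scenario(g)) for g in GEOMETRY_LABELS}


@pytest.fixture(scope="session")
def paclitaxel_cases():
    """Six paclitaxel cases at the shared boundary concentration."""
    return {g: run_case(Scenario(g, "paclitaxel")) for g in GEOMETRY_LABELS}


@pytest.fixture(scope="session")
def ls_case(baseline_cases):
    return baseline_cases["LS"]


@pytest.fixture(scope="session")
def ss_step_case():
    """Small sphere stored every step (for budget/monotonicity checks)."""
    return run_case(Scenario("SS"),
                    SolverSettings(store_every=1, compute_steady=False))
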