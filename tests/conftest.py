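"""Shared fixtures: the packaged network and the expensive scenario sweeps.

The sweep fixtures are session-scoped because the acceptance tests and the
behavioural unit tests interrogate the same simulations.
"""

from __future__ import annotations

import pytest

from clotsim.model_build import build_full_model, default_model
from clotsim.scenarios import (
    Scenario,
    run_dose_sweep,
    run_knockout_panel,
    run_tpa_upa_balance,
)


@pytest.fixture(scope="session")
def full_network():
    return build_full_model()


@pytest.fixture(scope="session")
def packaged_network():
    return default_model()


@pytest.fixture(scope="session")
def fig4_sweep(full_network):
    """TXA dose sweep in the tPA regime (TF 5 pM, tPA 2.5 nM, physiological
    inhibitors)."""
    return run_dose_sweep(Scenario(tpa=2.5e-9), network=full_network,
                          keep_timecourses=True)


@pytest.fixture(scope="session")
def fig5_panels(full_network):
    """Inhibitor-knockout panels under uPA 5 nM."""
    return run_knockout_panel(Scenario(upa=5e-9), network=full_network,
                              keep_timecourses=True)


@pytest.fixture(scope="session")
def fig6_balance(full_network):
    """tPA:uPA balance sweep at uPA 5 nM with A2M = A1AT = 0."""
    return run_tpa_upa_balance(Scenario(upa=5e-9, a2m=0.0, a1at=0.0),
                               network=full_network, keep_timecourses=True)
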