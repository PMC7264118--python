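"""Shared fixtures.

The expensive objects (limit-cycle branches, the Hopf curve in delta_k) are
session-scoped so that module tests and the acceptance checks reuse one
computation.
"""

import numpy as np
import pytest

from thetanet import (ModelParams, continue_equilibria, continue_hopf_curve,
                      limit_cycle_branch, pulse_coefficients)

# the two reference configurations studied throughout: Case 1 (excitable
# neurons, excitatory coupling) swept in k0, and Case 2 (spiking neurons,
# inhibitory coupling) swept in eta0
CASE1 = dict(eta0=-0.3, delta_eta=0.08, n=2)
CASE1_SWEEP = ("k0", (0.0, 3.0))
CASE2 = dict(delta_eta=0.5, k0=-9.0, n=2)
CASE2_SWEEP = ("eta0", (0.0, 15.0))


@pytest.fixture(scope="session")
def pulse2():
    return pulse_coefficients(2)


@pytest.fixture(scope="session")
def pulse9():
    return pulse_coefficients(9)


def case1_params(delta_k=0.0):
    return ModelParams(eta0=CASE1["eta0"], delta_eta=CASE1["delta_eta"],
                       k0=0.0, delta_k=delta_k, n=2)


def case2_params(delta_k=0.0):
    return ModelParams(eta0=0.0, delta_eta=CASE2["delta_eta"],
                       k0=CASE2["k0"], delta_k=delta_k, n=2)


@pytest.fixture(scope="session")
def case1_branches():
    """Equilibrium branches along the Case 1 line for delta_k in {0, 0.2}."""
    return {dk: continue_equilibria(case1_params(dk), *CASE1_SWEEP)
            for dk in (0.0, 0.2)}


@pytest.fixture(scope="session")
def case2_branches():
    """Equilibrium branches along the Case 2 line for delta_k in {0, 1.3, 1.7}."""
    return {dk: continue_equilibria(case2_params(dk), *CASE2_SWEEP)
            for dk in (0.0, 1.3, 1.7)}


def hopf_events(branches):
    return [e for b in branches for e in b.events_of("hopf")]


def sn_events(branches):
    return [e for b in branches for e in b.events_of("saddle-node")]


def nf_events(branches):
    return [e for b in branches for e in b.events_of("node-focus")]


@pytest.fixture(scope="session")
def case2_cycle_branch(case2_branches):
    """The stable cycle born at the Case 2 supercritical Hopf, followed to
    its homoclinic termination."""
    hopf = hopf_events(case2_branches[0.0])[0]
    return limit_cycle_branch(case2_params(0.0), "eta0", (0.0, 15.0),
                              init=hopf)


@pytest.fixture(scope="session")
def subcritical_cycle_branch():
    """Cycle branch from the subcritical Hopf at eta0 = 6: unstable cycle,
    SNPO fold, stable cycle, homoclinic termination."""
    params = ModelParams(6.0, 0.4, 0.0, 0.0, 2)
    brs = continue_equilibria(params, "k0", (-25.0, 0.0), direction=-1.0)
    hopf = hopf_events(brs)[0]
    return limit_cycle_branch(params, "k0", (-25.0, 0.0), init=hopf,
                              hopf_offset=0.05)


@pytest.fixture(scope="session")
def hopf_curve_eta6():
    """The Hopf curve in delta_k for eta0 = 6, delta_eta = 0.4 (carries the
    Bautin point and the fold where the Hopf disappears)."""
    return continue_hopf_curve(ModelParams(6.0, 0.4, 0.0, 0.0, 2),
                               "k0", (-25.0, 0.0), (0.0, 2.0))


@pytest.fixture()
def rng():
    # function-scoped: every test sees the same deterministic stream
    # regardless of execution order
    return np.random.default_rng(20260930)
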