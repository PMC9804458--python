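"""Shared fixtures: parameter sets, predation rates, and independent
root-finding oracles for the closed-form thresholds."""

from __future__ import annotations

import pytest
from scipy.optimize import brentq

import mesothresh as mt


@pytest.fixture(scope="session")
def pset() -> mt.ParameterSet:
    """Packaged defaults, printed cat-diet convention."""
    return mt.load_parameters()


@pytest.fixture(scope="session")
def pset_split() -> mt.ParameterSet:
    """Packaged defaults with the bird fraction of cat diet split between
    adults and hatchlings."""
    return mt.load_parameters(catdiet_mode="split")


@pytest.fixture(scope="session")
def rates(pset) -> mt.PredationRates:
    return mt.compute_rates(pset.energetics)


@pytest.fixture(scope="session")
def rates_split(pset_split) -> mt.PredationRates:
    return mt.compute_rates(pset_split.energetics)


@pytest.fixture(scope="session")
def fixture_sets() -> list[dict]:
    """1000 jittered-but-valid parameter configurations."""
    return mt.generate_parameter_sets(seed=7, n_sets=1000)


def _eta(d, r, cats, rats, eta_target):
    return mt.reproduction_ratio(d, r, mt.PredatorScenario(cats, rats)) - eta_target


def bisect_critical_rats(d, r, eta_target=1.0):
    """Root of eta(0, x) = eta_target by bracketed bisection, independent of
    the closed form.  The upper bracket is the egg-exhaustion point, where
    eta = 0."""
    hi = d.beta * d.N_A0 / (r.p_E_R * d.T_I)
    return brentq(lambda x: _eta(d, r, 0.0, x, eta_target), 0.0, hi,
                  xtol=1e-10, rtol=1e-13)


def bisect_critical_cats(d, r, eta_target=1.0):
    """Root of eta(x, 0) = eta_target; upper bracket is the adult-exhaustion
    point."""
    hi = (1.0 - d.mu_A) * d.N_A0 / (r.p_A_C * d.T_B)
    return brentq(lambda x: _eta(d, r, x, 0.0, eta_target), 0.0, hi,
                  xtol=1e-10, rtol=1e-13)


def bisect_cat_equivalence(d, r, eta_target=1.0):
    """Slope magnitude of the eta = eta_target level set, measured as the
    drop in tolerable rats per cat added.  The level set is linear where no
    clamp binds, so any cat step inside the triangle gives the slope; half
    the (bisected) critical cat abundance always is."""
    cr = bisect_critical_rats(d, r, eta_target)
    step = 0.5 * bisect_critical_cats(d, r, eta_target)
    hi = d.beta * d.N_A0 / (r.p_E_R * d.T_I)
    at_step = brentq(lambda x: _eta(d, r, step, x, eta_target), 0.0, hi,
                     xtol=1e-10, rtol=1e-13)
    return (cr - at_step) / step
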