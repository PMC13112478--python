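"""Shared fixtures: phantoms are generated once per session and reused."""

from __future__ import annotations

import warnings

import pytest

from cardiac4d import phantom


@pytest.fixture(scope="session")
def default_phantom():
    """The default 20-phase phantom with its analytic truth."""
    params = phantom.PhantomParams()
    cine, truth = phantom.generate_phantom(params)
    return params, cine, truth


@pytest.fixture(scope="session")
def small_phantom():
    """A 4-phase phantom for cheaper tests that do not need the full cycle."""
    params = phantom.PhantomParams(n_phases=4, seed=7)
    cine, truth = phantom.generate_phantom(params)
    return params, cine, truth


@pytest.fixture(autouse=True)
def _quiet_demons():
    """Registration convergence warnings are expected noise in tests."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="demons metric increased")
        yield
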