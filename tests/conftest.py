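"""Shared fixtures: small hand-checkable models and landscapes."""

import numpy as np
import pytest

from energyscape import MEMParams, boltzmann_distribution


@pytest.fixture
def double_well():
    """N=2 symmetric double well: h=0, J12=1.

    Energies are E(++) = E(--) = -1 and E(+-) = E(-+) = +1, so the
    all-active and all-inactive patterns are the two local minima.
    """
    params = MEMParams(h=np.zeros(2), J=np.array([[0.0, 1.0], [1.0, 0.0]]))
    return params, boltzmann_distribution(params)


@pytest.fixture
def single_well():
    """N=3 independent model with all h > 0: unique minimum at all-active."""
    params = MEMParams(h=np.array([0.4, 0.7, 1.1]), J=np.zeros((3, 3)))
    return params, boltzmann_distribution(params)


def random_params(n, seed, field_scale=0.4, coupling_scale=0.4):
    rng = np.random.default_rng(seed)
    h = rng.normal(0, field_scale, n)
    J = rng.normal(0, coupling_scale, (n, n))
    J = np.triu(J, 1)
    J = J + J.T
    return MEMParams(h=h, J=J)
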