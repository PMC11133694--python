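"""Metropolis-Hastings random walk on the energy landscape.

Brain-activity dynamics are emulated as a Markov chain over the ``2**N``
patterns: from the current pattern one of its N single-flip neighbours is
proposed uniformly and accepted with probability
``min(1, exp(E_current - E_proposed))``; a rejection keeps the current
pattern and still consumes one time step.  The chain satisfies detailed
balance with the Boltzmann distribution, so long trajectories sample
``P(V_k)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dynamics import subject_measures
from .landscape import BasinMap, StateDefinition
from .mem import LandscapeTable

__all__ = [
    "SimTrajectory",
    "metropolis_walk",
    "transition_matrix",
    "simulated_measures",
]


@dataclass(frozen=True)
class SimTrajectory:
    """Time-ordered pattern indices produced by a Metropolis walk."""

    steps: np.ndarray
    seed: int
    n_networks: int

    @property
    def n_steps(self) -> int:
        return self.steps.size


def _acceptance_table(table: LandscapeTable) -> tuple[np.ndarray, np.ndarray]:
    """Neighbour indices and acceptance probabilities for every pattern."""
    n = table.n_networks
    k = np.arange(table.n_patterns)
    nbr = k[:, None] ^ (1 << np.arange(n))
    acc = np.minimum(1.0, np.exp(table.energies[:, None] - table.energies[nbr]))
    return nbr, acc


def metropolis_walk(
    table: LandscapeTable,
    n_steps: int = 100_000,
    seed: int = 0,
    start: Optional[int] = None,
    persistence: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> SimTrajectory:
    """Run a Metropolis-Hastings walk of ``n_steps`` time points.

    The initial pattern is drawn uniformly from all ``2**N`` patterns unless
    ``start`` is given.  ``persistence`` mixes in a lazy self-repeat: with
    that probability a step simply repeats the previous pattern before any
    proposal is made, which leaves the stationary distribution unchanged
    while lengthening dwell times.  Deterministic given ``seed`` (or an
    explicit ``rng``).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if not 0.0 <= persistence < 1.0:
        raise ValueError("persistence must lie in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = table.n_networks
    nbr, acc = _acceptance_table(table)
    if start is None:
        state = int(rng.integers(table.n_patterns))
    else:
        state = int(start)

    proposals = rng.integers(0, n, size=n_steps)
    u = rng.random(n_steps)
    lazy = rng.random(n_steps) < persistence if persistence > 0 else None

    steps = np.empty(n_steps, dtype=np.int64)
    nbr_l = nbr.tolist()
    acc_l = acc.tolist()
    prop_l = proposals.tolist()
    u_l = u.tolist()
    lazy_l = lazy.tolist() if lazy is not None else None
    for t in range(n_steps):
        if lazy_l is None or not lazy_l[t]:
            i = prop_l[t]
            if u_l[t] < acc_l[state][i]:
                state = nbr_l[state][i]
        steps[t] = state
    return SimTrajectory(steps=steps, seed=seed, n_networks=n)


def transition_matrix(table: LandscapeTable) -> np.ndarray:
    """Explicit one-step transition matrix of the Metropolis kernel.

    ``T[i, j] = (1/N) min(1, exp(E_i - E_j))`` for neighbours, with the
    rejection mass on the diagonal.  Intended for small N (the matrix is
    ``2**N`` square); used to verify detailed balance exactly.
    """
    n = table.n_networks
    if n > 12:
        raise ValueError("explicit transition matrix only supported for N <= 12")
    nbr, acc = _acceptance_table(table)
    size = table.n_patterns
    T = np.zeros((size, size))
    for k in range(size):
        for i in range(n):
            T[k, nbr[k, i]] += acc[k, i] / n
        T[k, k] += 1.0 - acc[k].sum() / n
    return T


def simulated_measures(
    traj: SimTrajectory,
    table: LandscapeTable,
    basins: BasinMap,
    states: StateDefinition,
    d_max: int = 1,
) -> dict[str, float]:
    """Dynamics measures of a simulated trajectory.

    The trajectory is treated as a single subject: each step's pattern is
    labelled through its basin's minimum, and the same occupancy and
    transition statistics as for empirical data are applied.
    """
    if traj.n_networks != basins.n_networks:
        raise ValueError("trajectory and basins disagree on N")
    pattern_state = states.state_of_pattern(basins)
    labels = pattern_state[traj.steps]
    energies = table.energies[traj.steps]
    return subject_measures(labels, energies, states.n_states, d_max=d_max)
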