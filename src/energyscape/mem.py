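"""Pairwise maximum-entropy (Ising) model over binary network-activity patterns.

The model assigns each joint activity pattern ``V_k`` of ``N`` binary
(+1/-1) networks a statistical energy

    E(V_k) = - sum_i h_i sigma_i  -  1/2 sum_{i != j} J_ij sigma_i sigma_j

and the Boltzmann probability ``P(V_k) = exp(-E(V_k)) / Z``.  ``h_i`` is the
activation tendency (baseline activity) of network ``i`` and ``J_ij`` the
pairwise interaction between networks ``i`` and ``j``.  The energy is
dimensionless: it indexes how often a pattern occurs, not metabolic cost.

Fitting matches the model's first and second moments to empirical moments by
gradient ascent on the log-likelihood, with the model moments recomputed
exactly by enumerating all ``2**N`` patterns at every step.  This exact
treatment is feasible for the intended regime of N around 9 networks and is
capped at N = 20.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "MEMParams",
    "LandscapeTable",
    "MomentSet",
    "FitDiagnostics",
    "ConvergenceError",
    "all_patterns",
    "pattern_energy",
    "enumerate_energies",
    "boltzmann_distribution",
    "empirical_moments",
    "empirical_pattern_frequencies",
    "model_moments",
    "fit_independent_mem",
    "fit_pairwise_mem",
    "fit_accuracy",
]

#: hard cap on the number of networks for exact enumeration (2**20 patterns)
N_MAX = 20


class ConvergenceError(RuntimeError):
    """Raised when the gradient-ascent fit diverges."""


@dataclass(frozen=True)
class MEMParams:
    """Parameters of a pairwise maximum-entropy model.

    Attributes
    ----------
    h : ndarray, shape (N,)
        Baseline activation tendency of each network.
    J : ndarray, shape (N, N)
        Symmetric pairwise couplings with a zero diagonal.
    """

    h: np.ndarray
    J: np.ndarray

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=float)
        J = np.asarray(self.J, dtype=float)
        object.__setattr__(self, "h", h)
        object.__setattr__(self, "J", J)
        if h.ndim != 1 or J.shape != (h.size, h.size):
            raise ValueError(f"inconsistent shapes: h {h.shape}, J {J.shape}")
        if not (np.all(np.isfinite(h)) and np.all(np.isfinite(J))):
            raise ValueError("MEM parameters must be finite")
        if not np.allclose(J, J.T, atol=1e-12):
            raise ValueError("J must be symmetric")
        if np.any(np.diag(J) != 0.0):
            raise ValueError("J must have a zero diagonal")

    @property
    def n_networks(self) -> int:
        return self.h.size


@dataclass(frozen=True)
class LandscapeTable:
    """Energies and Boltzmann probabilities of all ``2**N`` activity patterns.

    Row ``k`` describes pattern index ``k`` under the codec of
    :mod:`energyscape.binarize` (network ``i`` active iff bit ``i`` of ``k``
    is set).
    """

    energies: np.ndarray
    probabilities: np.ndarray
    n_networks: int

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "probabilities", p)
        n_patterns = 2 ** self.n_networks
        if e.shape != (n_patterns,) or p.shape != (n_patterns,):
            raise ValueError("energies/probabilities must have length 2**N")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")
        if np.any(p <= 0):
            raise ValueError("probabilities must be strictly positive")

    @property
    def n_patterns(self) -> int:
        return 2 ** self.n_networks


@dataclass(frozen=True)
class MomentSet:
    """First and second moments of the +/-1 network activities.

    ``mean_activity[i]`` is <sigma_i>, ``pairwise[i, j]`` is <sigma_i sigma_j>.
    ``source`` records whether the moments were measured from data
    ("empirical") or computed under the model ("model").
    """

    mean_activity: np.ndarray
    pairwise: np.ndarray
    source: str = "empirical"

    def __post_init__(self) -> None:
        m = np.asarray(self.mean_activity, dtype=float)
        c = np.asarray(self.pairwise, dtype=float)
        object.__setattr__(self, "mean_activity", m)
        object.__setattr__(self, "pairwise", c)
        if m.ndim != 1 or c.shape != (m.size, m.size):
            raise ValueError("inconsistent moment shapes")
        if np.any(np.abs(m) > 1 + 1e-12) or np.any(np.abs(c) > 1 + 1e-12):
            raise ValueError("moments of +/-1 variables must lie in [-1, 1]")

    @property
    def n_networks(self) -> int:
        return self.mean_activity.size


@dataclass
class FitDiagnostics:
    """Goodness-of-fit summary of a pairwise MEM.

    ``D1``/``D2`` are Kullback-Leibler divergences in bits from the empirical
    pattern distribution to the independent (J = 0) and pairwise models.
    ``R = (D1 - D2) / D1`` is the fraction of the independent model's
    shortfall removed by the couplings: 1 means the pairwise model reproduces
    the empirical distribution exactly, 0 means the couplings add nothing.
    """

    R: Optional[float] = None
    D1: Optional[float] = None
    D2: Optional[float] = None
    pearson_r: Optional[float] = None
    iterations: int = 0
    converged: bool = False
    max_moment_gap: float = np.inf
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# pattern enumeration and energies


def all_patterns(n_networks: int) -> np.ndarray:
    """Return the (2**N, N) matrix of all +/-1 patterns in index order.

    Row ``k`` is the pattern with index ``k``: entry ``i`` is +1 iff bit ``i``
    of ``k`` is set (network 1 = least-significant bit).
    """
    if not 1 <= n_networks <= N_MAX:
        raise ValueError(f"n_networks must be in [1, {N_MAX}], got {n_networks}")
    k = np.arange(2 ** n_networks)
    bits = (k[:, None] >> np.arange(n_networks)) & 1
    return (2 * bits - 1).astype(np.int8)


def pattern_energy(params: MEMParams, sigma: np.ndarray) -> float:
    """Energy of a single +/-1 activity pattern under the model."""
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != (params.n_networks,):
        raise ValueError(
            f"pattern length {sigma.shape} does not match N={params.n_networks}"
        )
    return float(-sigma @ params.h - 0.5 * sigma @ params.J @ sigma)


def enumerate_energies(params: MEMParams) -> np.ndarray:
    """Energies of all ``2**N`` patterns (vectorised enumeration)."""
    S = all_patterns(params.n_networks).astype(float)
    return -S @ params.h - 0.5 * np.einsum("ki,ki->k", S @ params.J, S)


def boltzmann_distribution(params: MEMParams) -> LandscapeTable:
    """Enumerate the Boltzmann distribution ``P(V_k) ∝ exp(-E(V_k))``.

    Probabilities are computed with a max-shifted softmax so that adding any
    constant to all energies leaves them unchanged and no overflow occurs.
    """
    if params.n_networks > N_MAX:
        raise ValueError(f"N={params.n_networks} exceeds enumeration cap {N_MAX}")
    e = enumerate_energies(params)
    w = np.exp(-(e - e.min()))
    p = w / w.sum()
    return LandscapeTable(energies=e, probabilities=p, n_networks=params.n_networks)


# ---------------------------------------------------------------------------
# moments


def empirical_moments(values: np.ndarray) -> MomentSet:
    """Empirical moments of +/-1 data.

    Parameters
    ----------
    values : ndarray
        Either an (N, T) matrix of concatenated +/-1 activities or an
        (S, N, T) per-subject stack, which is concatenated along time.
    """
    values = np.asarray(values)
    if values.ndim == 3:
        values = np.concatenate(list(values), axis=1)
    if values.ndim != 2 or values.size == 0:
        raise ValueError("expected nonempty (N, T) or (S, N, T) data")
    if not np.all(np.isin(values, (-1, 1))):
        raise ValueError("data must be +/-1")
    v = values.astype(float)
    mean = v.mean(axis=1)
    pair = (v @ v.T) / v.shape[1]
    return MomentSet(mean_activity=mean, pairwise=pair, source="empirical")


def empirical_pattern_frequencies(pattern_index: np.ndarray, n_networks: int) -> np.ndarray:
    """Relative frequency of each of the ``2**N`` patterns in the data."""
    idx = np.asarray(pattern_index).ravel()
    if idx.size == 0:
        raise ValueError("empty pattern index")
    counts = np.bincount(idx, minlength=2 ** n_networks)
    return counts / idx.size


def model_moments(table: LandscapeTable) -> MomentSet:
    """Exact model moments under the enumerated distribution."""
    S = all_patterns(table.n_networks).astype(float)
    p = table.probabilities
    mean = p @ S
    pair = S.T @ (p[:, None] * S)
    return MomentSet(mean_activity=mean, pairwise=pair, source="model")


# ---------------------------------------------------------------------------
# fitting


def fit_independent_mem(mean_activity: np.ndarray) -> MEMParams:
    """Closed-form fit of the independent model (J = 0).

    ``h_i = atanh(<sigma_i>)`` makes the model means match exactly.  Means at
    +/-1 (a network constantly on or off) are clamped just inside the open
    interval, with a warning, to keep h finite.
    """
    m = np.asarray(mean_activity, dtype=float).copy()
    clip = 1.0 - 1e-9
    if np.any(np.abs(m) >= 1.0):
        warnings.warn(
            "mean activity at +/-1 clamped to +/-(1 - 1e-9) for the "
            "independent fit",
            stacklevel=2,
        )
        m = np.clip(m, -clip, clip)
    h = np.arctanh(m)
    return MEMParams(h=h, J=np.zeros((m.size, m.size)))


def fit_pairwise_mem(
    empirical: MomentSet,
    learning_rate: float = 0.1,
    tol: float = 1e-5,
    max_iter: int = 50_000,
    adapt_lr: bool = True,
    init: Optional[MEMParams] = None,
) -> tuple[MEMParams, FitDiagnostics]:
    """Fit h and J by gradient ascent on the moment mismatch.

    Each iteration updates ``h_i += lr * (<sigma_i> - <sigma_i>_m)`` and
    ``J_ij += lr * (<sigma_i sigma_j> - <sigma_i sigma_j>_m)`` with the model
    moments recomputed exactly by enumeration; the fixed point is the
    maximum-likelihood pairwise MEM.  Iteration stops when the largest
    absolute moment gap falls below ``tol``.

    Parameters
    ----------
    empirical : MomentSet
        Target first and second moments.
    learning_rate : float
        Gradient step size.
    tol : float
        Convergence threshold on the max absolute moment gap.
    max_iter : int
        Iteration cap; the fit returns unconverged beyond it.
    adapt_lr : bool
        Halve the step size when the gap oscillates upward.
    init : MEMParams, optional
        Starting point; defaults to the independent closed form with J = 0.

    Raises
    ------
    ConvergenceError
        If the moment gap grows tenfold over a 100-iteration window.
    """
    if learning_rate <= 0 or tol <= 0:
        raise ValueError("learning_rate and tol must be positive")
    n = empirical.n_networks
    S = all_patterns(n).astype(float)
    target_m = empirical.mean_activity
    # symmetrise the target and ignore its diagonal (always 1 for +/-1 data)
    target_c = 0.5 * (empirical.pairwise + empirical.pairwise.T)

    if init is None:
        init = fit_independent_mem(target_m)
    h = init.h.copy()
    J = init.J.copy()
    off = ~np.eye(n, dtype=bool)

    lr = learning_rate
    gap = np.inf
    prev_gap = np.inf
    rising = 0
    window_start_gap = None
    it = 0
    for it in range(1, max_iter + 1):
        e = -S @ h - 0.5 * np.einsum("ki,ki->k", S @ J, S)
        w = np.exp(-(e - e.min()))
        p = w / w.sum()
        model_m = p @ S
        model_c = S.T * p @ S

        dh = target_m - model_m
        dJ = np.where(off, target_c - model_c, 0.0)
        gap = max(np.abs(dh).max(), np.abs(dJ).max())
        if gap < tol:
            break
        if it % 100 == 1:
            if window_start_gap is not None and gap > 10 * window_start_gap:
                raise ConvergenceError(
                    f"moment gap grew from {window_start_gap:.3g} to {gap:.3g} "
                    f"over 100 iterations; learning_rate={lr} is too large"
                )
            window_start_gap = gap
        if adapt_lr:
            # halve only on sustained growth: transient wobble is normal
            rising = rising + 1 if gap > prev_gap * (1 + 1e-12) else 0
            if rising >= 25:
                lr *= 0.5
                rising = 0
        prev_gap = gap

        h += lr * dh
        J += lr * dJ

    params = MEMParams(h=h, J=0.5 * (J + J.T))
    diag = FitDiagnostics(
        iterations=it, converged=bool(gap < tol), max_moment_gap=float(gap)
    )
    return params, diag


def _kl_bits(freq: np.ndarray, model_p: np.ndarray) -> float:
    """KL divergence in bits; empirical-zero terms contribute 0."""
    mask = freq > 0
    return float(np.sum(freq[mask] * np.log2(freq[mask] / model_p[mask])))


def fit_accuracy(
    empirical_frequencies: np.ndarray,
    independent: LandscapeTable,
    pairwise: LandscapeTable,
) -> FitDiagnostics:
    """Accuracy of the pairwise fit relative to the independent baseline.

    ``D1`` and ``D2`` are the KL divergences (bits) from the empirical
    pattern distribution to the independent and pairwise models;
    ``R = (D1 - D2)/D1``; ``pearson_r`` correlates pairwise-model
    probabilities with empirical frequencies across all patterns.
    """
    freq = np.asarray(empirical_frequencies, dtype=float)
    if abs(freq.sum() - 1.0) > 1e-9:
        raise ValueError("empirical frequencies must sum to 1")
    if freq.shape != (independent.n_patterns,) or freq.shape != (pairwise.n_patterns,):
        raise ValueError("frequency vector length must be 2**N of both models")
    d1 = _kl_bits(freq, independent.probabilities)
    d2 = _kl_bits(freq, pairwise.probabilities)
    diag = FitDiagnostics(D1=d1, D2=d2)
    if d1 > 0:
        diag.R = (d1 - d2) / d1
    else:
        diag.warnings.append("D1 = 0: empirical data match the independent model; R undefined")
        warnings.warn(diag.warnings[-1], stacklevel=2)
    # Pearson r between model and empirical probabilities over all patterns
    from scipy import stats as _stats

    if np.ptp(freq) > 0:
        diag.pearson_r = float(_stats.pearsonr(pairwise.probabilities, freq)[0])
    else:
        diag.warnings.append("constant empirical frequencies: pearson_r undefined")
    return diag
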