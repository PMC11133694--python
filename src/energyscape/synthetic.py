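"""Synthetic two-cohort generator with known ground truth.

The generator emulates the statistical structure the analysis assumes for a
resting-state cohort: per group, S subjects x N networks x T time points,
with binary activity patterns governed by a group-specific Boltzmann
distribution, temporal persistence producing realistic dwell times, a
continuous signal (pattern x snr + unit Gaussian noise, zero baseline) whose
mean-threshold binarization approximately recovers the patterns, and
behavior scores linearly coupled to a planted dynamics measure plus noise.

Defaults mirror the emulated study design: 30 subjects per group, 9
networks, 140 time points.  Group differences are planted by perturbing a
chosen subset of pairwise couplings in one group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .binarize import BinaryPatternData
from .dynamics import subject_measures
from .landscape import (
    StateDefinition,
    assign_basins,
    build_disconnectivity_tree,
    group_minima_into_states,
)
from .mem import MEMParams, LandscapeTable, all_patterns, boltzmann_distribution
from .simulate import metropolis_walk

__all__ = [
    "BehaviorModel",
    "GroundTruth",
    "Cohort",
    "make_ground_truth_mem",
    "make_three_well_params",
    "make_planted_truth",
    "PLANTED_PAIR_MEASURE",
    "perturb_couplings",
    "make_two_group_truth",
    "sample_patterns",
    "make_cohort",
    "generate_state_measures",
]

#: study-scale defaults for the emulated cohort
DEFAULT_N_NETWORKS = 9
DEFAULT_N_SUBJECTS = 30
DEFAULT_T = 140
DEFAULT_SNR = 1.0
DEFAULT_PERSISTENCE = 0.0
DEFAULT_FIELD_SCALE = 0.2
DEFAULT_COUPLING_SCALE = 0.4
DEFAULT_THIN = 40


@dataclass(frozen=True)
class BehaviorModel:
    """Linear link from one planted dynamics measure to a behavior score.

    ``score = intercept + slope * measure + Normal(0, noise_sd)``, with the
    measure computed per subject from the generating (noise-free) state
    sequence under the subject's group ground-truth landscape.
    """

    measure: str = "appearance_frequency_s1"
    slope: float = 1.0
    intercept: float = 0.0
    noise_sd: float = 1.0
    score_name: str = "score"


@dataclass(frozen=True)
class GroundTruth:
    """Ground-truth generative description of a two-group cohort."""

    params_per_group: Mapping[str, MEMParams]
    persistence: float = DEFAULT_PERSISTENCE
    behavior_model: BehaviorModel = field(default_factory=BehaviorModel)
    seed: int = 0
    n_states: int = 3
    d_max: int = 1
    thin: int = DEFAULT_THIN

    def __post_init__(self) -> None:
        object.__setattr__(self, "params_per_group", dict(self.params_per_group))
        if not 0.0 <= self.persistence < 1.0:
            raise ValueError("persistence must lie in [0, 1)")
        ns = {p.n_networks for p in self.params_per_group.values()}
        if len(ns) != 1:
            raise ValueError("all groups must share the same N")

    @property
    def n_networks(self) -> int:
        return next(iter(self.params_per_group.values())).n_networks

    @property
    def groups(self) -> list[str]:
        return list(self.params_per_group)


@dataclass(frozen=True)
class Cohort:
    """A generated cohort: continuous series, behavior table, ground truth."""

    series: Mapping[str, list[np.ndarray]]
    behavior: pd.DataFrame
    true_patterns: Mapping[str, np.ndarray]
    truth: GroundTruth
    snr: float

    @property
    def subject_ids(self) -> list[str]:
        return list(self.behavior["subject_id"])


def make_ground_truth_mem(
    n_networks: int,
    field_scale: float,
    coupling_scale: float,
    seed: int,
) -> MEMParams:
    """Draw a random ground-truth model.

    ``h`` is i.i.d. Normal(0, field_scale); the off-diagonal upper triangle
    of ``J`` is i.i.d. Normal(0, coupling_scale) and mirrored to keep ``J``
    symmetric with a zero diagonal.  Deterministic given ``seed``.
    """
    if not 2 <= n_networks <= 14:
        raise ValueError("n_networks must be in [2, 14] for exact enumeration")
    if not (np.isfinite(field_scale) and np.isfinite(coupling_scale)):
        raise ValueError("scales must be finite")
    rng = np.random.default_rng(seed)
    h = rng.normal(0.0, 1.0, n_networks) * field_scale
    upper = rng.normal(0.0, 1.0, (n_networks, n_networks)) * coupling_scale
    J = np.triu(upper, k=1)
    J = J + J.T
    return MEMParams(h=h, J=J)


def make_three_well_params(
    intra: float = 0.3,
    inter: float = 0.3,
    inactivation: float = 0.7,
    tilt: float = 0.01,
) -> MEMParams:
    """Structured ground truth with three balanced attractor wells.

    Nine networks form three blocks of three; couplings are ``+intra``
    within a block and ``-inter`` between blocks, and every network carries
    a baseline ``h = -inactivation`` (plus a tiny per-block ``tilt`` that
    breaks the three-fold symmetry so energies are generic).  The landscape
    has exactly three local minima - one per block, that block active and
    the rest inactive - with near-equal basin sizes, occupancies and
    pairwise transition rates.  This balanced geometry is the base
    condition for planting group differences in specific transitions.
    """
    n, block = 9, 3
    h = np.full(n, -inactivation)
    for blk in range(3):
        h[blk * block : (blk + 1) * block] += tilt * blk
    J = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            J[i, j] = intra if i // block == j // block else -inter
            J[j, i] = J[i, j]
    return MEMParams(h=h, J=J)


#: measure column that the planted bridge of :func:`make_planted_truth`
#: shifts most strongly (wells 1 and 2 are states 2 and 3 by energy order)
PLANTED_PAIR_MEASURE = "transition_frequency_s2s3"


def make_planted_truth(
    bridge_delta: float = 0.6,
    bridge_pairs: Sequence[tuple[int, int]] = ((0, 3), (1, 4)),
    group_labels: tuple[str, str] = ("control", "patient"),
    persistence: float = DEFAULT_PERSISTENCE,
    thin: int = DEFAULT_THIN,
    seed: int = 0,
) -> GroundTruth:
    """Three-well truth with a planted transition-rate group difference.

    Both groups share the balanced three-well model; the second group gets
    ``bridge_delta`` added to two couplings bridging blocks 1 and 2, which
    reshapes the saddle between those wells and shifts the relative
    transition frequency of the corresponding state pair
    (:data:`PLANTED_PAIR_MEASURE`) while leaving the three minima intact.
    """
    base = make_three_well_params()
    planted = perturb_couplings(base, bridge_pairs, bridge_delta)
    return GroundTruth(
        params_per_group={group_labels[0]: base, group_labels[1]: planted},
        persistence=persistence,
        seed=seed,
        n_states=3,
        thin=thin,
    )


def perturb_couplings(
    params: MEMParams, pairs: Sequence[tuple[int, int]], delta: float
) -> MEMParams:
    """Return a copy of ``params`` with ``delta`` added to selected couplings."""
    J = params.J.copy()
    for i, j in pairs:
        if i == j:
            raise ValueError("cannot perturb a diagonal coupling")
        J[i, j] += delta
        J[j, i] += delta
    return MEMParams(h=params.h.copy(), J=J)


def make_two_group_truth(
    n_networks: int = DEFAULT_N_NETWORKS,
    field_scale: float = DEFAULT_FIELD_SCALE,
    coupling_scale: float = DEFAULT_COUPLING_SCALE,
    seed: int = 0,
    group_labels: tuple[str, str] = ("control", "patient"),
    perturbed_pairs: Sequence[tuple[int, int]] = (),
    coupling_delta: float = 0.0,
    persistence: float = DEFAULT_PERSISTENCE,
    behavior_model: Optional[BehaviorModel] = None,
    n_states: int = 3,
    thin: int = DEFAULT_THIN,
) -> GroundTruth:
    """Two-group ground truth sharing one base model.

    The second group's couplings are shifted by ``coupling_delta`` on
    ``perturbed_pairs``; with an empty perturbation the groups are
    identical (a null cohort).
    """
    base = make_ground_truth_mem(n_networks, field_scale, coupling_scale, seed)
    second = (
        perturb_couplings(base, perturbed_pairs, coupling_delta)
        if perturbed_pairs
        else base
    )
    return GroundTruth(
        params_per_group={group_labels[0]: base, group_labels[1]: second},
        persistence=persistence,
        behavior_model=behavior_model or BehaviorModel(),
        seed=seed,
        n_states=n_states,
        thin=thin,
    )


def sample_patterns(
    params: MEMParams,
    n_samples: int,
    mode: str = "markov",
    persistence: float = 0.0,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
    thin: int = 1,
) -> BinaryPatternData:
    """Sample +/-1 activity patterns from the model's Boltzmann law.

    ``iid`` mode draws independent patterns from the exactly enumerated
    distribution.  ``markov`` mode runs the Metropolis kernel started from a
    stationary draw, with an extra self-repeat probability ``persistence``,
    so samples are temporally correlated but marginally still Boltzmann.
    ``thin`` records every ``thin``-th state of the kernel: one observed
    time point then spans several elementary pattern moves, which emulates
    a sampling interval (TR) long relative to the underlying dynamics.
    Returned as a single-subject :class:`BinaryPatternData` with zero
    thresholds.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    table = boltzmann_distribution(params)
    if mode == "iid":
        idx = rng.choice(table.n_patterns, size=n_samples, p=table.probabilities)
    elif mode == "markov":
        start = int(rng.choice(table.n_patterns, p=table.probabilities))
        traj = metropolis_walk(
            table,
            n_steps=n_samples * thin,
            start=start,
            persistence=persistence,
            rng=rng,
        )
        idx = traj.steps[thin - 1 :: thin]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    values = all_patterns(params.n_networks)[idx].T  # (N, T)
    return BinaryPatternData(
        values=values[None, :, :],
        pattern_index=idx[None, :],
        thresholds=np.zeros(params.n_networks),
    )


def generate_state_measures(
    truth: GroundTruth,
    n_subjects_per_group: int = DEFAULT_N_SUBJECTS,
    t_per_subject: int = DEFAULT_T,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-subject dynamics measures computed from generating sequences.

    Samples each subject's pattern sequence from the subject's group model
    (markov mode, the truth's persistence and thinning) and evaluates the
    dynamics measures through the ground-truth landscape, bypassing the
    noise/binarization layer.  This isolates the sampling and statistics
    stages: it is the natural input for calibration and power experiments
    on the group-comparison machinery.
    """
    rows = []
    root = np.random.SeedSequence(seed)
    for group, params in truth.params_per_group.items():
        table, states, pattern_state = _truth_states(params, truth.n_states)
        rng = np.random.default_rng(root.spawn(1)[0])
        for s_i in range(n_subjects_per_group):
            sample = sample_patterns(
                params,
                t_per_subject,
                mode="markov",
                persistence=truth.persistence,
                rng=rng,
                thin=truth.thin,
            )
            idx = sample.pattern_index[0]
            row = subject_measures(
                pattern_state[idx], table.energies[idx], states.n_states,
                d_max=truth.d_max,
            )
            row["subject_id"] = f"{group}-{s_i + 1:03d}"
            row["group"] = group
            rows.append(row)
    return pd.DataFrame(rows)


def _truth_states(
    params: MEMParams, n_states: int
) -> tuple[LandscapeTable, StateDefinition, "np.ndarray"]:
    """Landscape, state definition and per-pattern state codes of a model."""
    table = boltzmann_distribution(params)
    basins = assign_basins(table)
    tree = build_disconnectivity_tree(table, list(basins.minima))
    k = min(n_states, len(basins.minima))
    states = group_minima_into_states(tree, k=k)
    return table, states, states.state_of_pattern(basins)


def make_cohort(
    truth: GroundTruth,
    n_subjects_per_group: int = DEFAULT_N_SUBJECTS,
    t_per_subject: int = DEFAULT_T,
    snr: float = DEFAULT_SNR,
    seed: Optional[int] = None,
) -> Cohort:
    """Generate a full two-group cohort of continuous network time series.

    Per subject a markov-mode +/-1 pattern sequence is drawn from the
    subject's group model and mapped to continuous values
    ``pattern * snr + Normal(0, 1)`` per network and time point (zero
    baseline), so that group-mean thresholding approximately recovers the
    generating patterns.  Behavior scores follow the ground truth's linear
    model on the planted measure.  Deterministic given ``seed`` (defaults to
    ``truth.seed``).
    """
    if n_subjects_per_group < 1 or t_per_subject < 1:
        raise ValueError("counts must be >= 1")
    if snr <= 0:
        raise ValueError("snr must be positive")
    if seed is None:
        seed = truth.seed
    root = np.random.SeedSequence(seed)
    patterns_mat = all_patterns(truth.n_networks).astype(float)

    series: dict[str, list[np.ndarray]] = {}
    true_idx: dict[str, np.ndarray] = {}
    rows = []
    bm = truth.behavior_model
    for group, params in truth.params_per_group.items():
        table, states, pattern_state = _truth_states(params, truth.n_states)
        group_seq = root.spawn(1)[0]
        subject_seeds = group_seq.spawn(n_subjects_per_group)
        series[group] = []
        idx_all = np.empty((n_subjects_per_group, t_per_subject), dtype=np.int64)
        for s_i, ss in enumerate(subject_seeds):
            rng = np.random.default_rng(ss)
            sample = sample_patterns(
                params,
                t_per_subject,
                mode="markov",
                persistence=truth.persistence,
                rng=rng,
                thin=truth.thin,
            )
            idx = sample.pattern_index[0]
            idx_all[s_i] = idx
            sigma = patterns_mat[idx].T  # (N, T)
            noise = rng.normal(0.0, 1.0, sigma.shape)
            series[group].append(sigma * snr + noise)

            labels = pattern_state[idx]
            m = subject_measures(
                labels, table.energies[idx], states.n_states, d_max=truth.d_max
            )
            planted = m.get(bm.measure, np.nan)
            score = bm.intercept + bm.slope * planted + rng.normal(0.0, bm.noise_sd)
            rows.append({
                "subject_id": f"{group}-{s_i + 1:03d}",
                "group": group,
                bm.score_name: score,
                f"true_{bm.measure}": planted,
            })
        true_idx[group] = idx_all
    behavior = pd.DataFrame(rows)
    return Cohort(
        series=series, behavior=behavior, true_patterns=true_idx,
        truth=truth, snr=snr,
    )
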