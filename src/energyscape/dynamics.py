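"""Per-subject brain-state dynamics measures.

Each time point's activity pattern is mapped through its basin of attraction
to a brain state, and seven measures are computed per subject: appearance
frequency, mean duration and mean energy per state, and total / direct /
indirect transition frequencies per unordered state pair plus an in/out
transition frequency per state.

A transition is read off the run-length-compressed state sequence.  A run
triple (A, C, B) with A != B, C distinct from both, and dwell(C) <= d_max
counts as ONE indirect transition A -> B (a brief excursion through C); its
two constituent direct steps are suppressed.  Every remaining adjacent run
pair counts as a direct transition.  With this bookkeeping the direct and
indirect counts sum to the total transition count, so the reported
frequencies (count / total transitions) are exhaustive and sum to 1.

Durations are in time points; the repetition time (TR, seconds per time
point) is carried as metadata for conversion to seconds.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Hashable, Optional, Sequence

import numpy as np
import pandas as pd

from .binarize import BinaryPatternData
from .landscape import BasinMap, StateDefinition
from .mem import LandscapeTable

__all__ = [
    "StateSequence",
    "DEFAULT_TR_SECONDS",
    "label_state_sequence",
    "run_length_encode",
    "occupancy_statistics",
    "transition_statistics",
    "subject_measures",
    "measures_table",
]

#: repetition time of the emulated acquisition, seconds per time point
DEFAULT_TR_SECONDS = 3.0


@dataclass(frozen=True)
class StateSequence:
    """Time-ordered state labels per subject, with the underlying patterns.

    ``labels`` and ``energies`` have shape (S, T); ``state_names`` maps the
    integer codes used in ``labels`` back to the caller's state labels.
    """

    labels: np.ndarray
    pattern_index: np.ndarray
    energies: np.ndarray
    state_names: tuple[Hashable, ...]
    tr_seconds: float = DEFAULT_TR_SECONDS

    @property
    def n_subjects(self) -> int:
        return self.labels.shape[0]

    @property
    def n_states(self) -> int:
        return len(self.state_names)


def label_state_sequence(
    data: BinaryPatternData,
    table: LandscapeTable,
    basins: BasinMap,
    states: StateDefinition,
    tr_seconds: float = DEFAULT_TR_SECONDS,
) -> StateSequence:
    """Classify every time point of every subject into a brain state.

    Each pattern index is sent to its basin's local minimum and from there to
    that minimum's state.  Energies are looked up per visited pattern.
    """
    if data.n_networks != basins.n_networks:
        raise ValueError("data and basins disagree on N")
    idx = data.pattern_index
    if idx.min() < 0 or idx.max() >= 2 ** basins.n_networks:
        raise ValueError("pattern index out of range")
    pattern_state = states.state_of_pattern(basins)
    return StateSequence(
        labels=pattern_state[idx],
        pattern_index=idx,
        energies=table.energies[idx],
        state_names=tuple(states.states),
        tr_seconds=tr_seconds,
    )


def run_length_encode(labels: Sequence[int]) -> list[tuple[int, int]]:
    """Compress a label sequence into (label, run length) pairs."""
    out: list[tuple[int, int]] = []
    for lab, grp in itertools.groupby(labels):
        out.append((int(lab), sum(1 for _ in grp)))
    return out


def occupancy_statistics(
    labels: np.ndarray, energies: np.ndarray, n_states: int
) -> dict[str, np.ndarray]:
    """Appearance frequency, mean duration and mean energy per state.

    Appearance frequency is the fraction of time points spent in the state;
    mean duration is the average length of its maximal runs (in time
    points); mean energy averages the visited patterns' energies over the
    state's time points.  Unvisited states get frequency 0 and NaN for
    duration and energy.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty state sequence")
    t = labels.size
    freq = np.array([(labels == s).sum() / t for s in range(n_states)])
    runs = run_length_encode(labels)
    duration = np.full(n_states, np.nan)
    energy = np.full(n_states, np.nan)
    for s in range(n_states):
        lens = [ln for lab, ln in runs if lab == s]
        if lens:
            duration[s] = float(np.mean(lens))
            energy[s] = float(energies[labels == s].mean())
    return {"appearance_frequency": freq, "mean_duration": duration, "mean_energy": energy}


def transition_statistics(
    labels: np.ndarray, n_states: int, d_max: int = 1
) -> dict[str, np.ndarray]:
    """Direct/indirect/total transition frequencies from one state sequence.

    Returns per-unordered-pair matrices (symmetric, zero diagonal) of total,
    direct and indirect transition frequencies, and a per-state in/out
    frequency; all are counts divided by the total number of transitions.
    A sequence with no state change reports all-zero frequencies with a
    warning.
    """
    if d_max < 1:
        raise ValueError("d_max must be >= 1")
    runs = run_length_encode(np.asarray(labels))
    direct = np.zeros((n_states, n_states))
    indirect = np.zeros((n_states, n_states))
    i = 0
    while i < len(runs) - 1:
        a, _ = runs[i]
        c, dwell_c = runs[i + 1]
        if i + 2 < len(runs):
            b, _ = runs[i + 2]
            if a != b and c != a and c != b and dwell_c <= d_max:
                indirect[a, b] += 1
                i += 2
                continue
        direct[a, c] += 1
        i += 1
    total = direct.sum() + indirect.sum()
    if total == 0:
        warnings.warn("no state transitions observed; frequencies set to 0", stacklevel=2)
        scale = np.inf
    else:
        scale = total
    # direction-summed unordered-pair frequencies
    sym = lambda M: (M + M.T) / scale  # noqa: E731
    direct_f = sym(direct)
    indirect_f = sym(indirect)
    counts = direct + indirect
    inout = (counts.sum(axis=0) + counts.sum(axis=1)) / scale
    return {
        "transition_frequency": direct_f + indirect_f,
        "direct_transition_frequency": direct_f,
        "indirect_transition_frequency": indirect_f,
        "inout_frequency": inout,
        "n_transitions": total,
    }


def subject_measures(
    labels: np.ndarray,
    energies: np.ndarray,
    n_states: int,
    d_max: int = 1,
) -> dict[str, float]:
    """Flat measure dictionary for a single subject (or trajectory).

    Keys follow ``<measure>_s<state>`` for per-state measures and
    ``<measure>_s<a>s<b>`` (a < b) for per-pair measures, states numbered
    from 1.
    """
    occ = occupancy_statistics(labels, energies, n_states)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        trans = transition_statistics(labels, n_states, d_max=d_max)
    out: dict[str, float] = {}
    for name in ("appearance_frequency", "mean_duration", "mean_energy"):
        for s in range(n_states):
            out[f"{name}_s{s + 1}"] = float(occ[name][s])
    for name in (
        "transition_frequency",
        "direct_transition_frequency",
        "indirect_transition_frequency",
    ):
        mat = trans[name]
        for a in range(n_states):
            for b in range(a + 1, n_states):
                out[f"{name}_s{a + 1}s{b + 1}"] = float(mat[a, b])
    for s in range(n_states):
        out[f"inout_frequency_s{s + 1}"] = float(trans["inout_frequency"][s])
    out["n_transitions"] = float(trans["n_transitions"])
    return out


def measures_table(
    seq: StateSequence,
    d_max: int = 1,
    subject_ids: Optional[Sequence[str]] = None,
    group: Optional[str] = None,
) -> pd.DataFrame:
    """Per-subject dynamics measures as a tidy table, one row per subject.

    Runs never cross subject boundaries: every subject's sequence is
    compressed and counted separately.
    """
    rows = []
    for s in range(seq.n_subjects):
        row = subject_measures(seq.labels[s], seq.energies[s], seq.n_states, d_max=d_max)
        row["subject_id"] = (
            subject_ids[s] if subject_ids is not None else f"sub-{s + 1:03d}"
        )
        if group is not None:
            row["group"] = group
        rows.append(row)
    df = pd.DataFrame(rows)
    front = ["subject_id"] + (["group"] if group is not None else [])
    return df[front + [c for c in df.columns if c not in front]]
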