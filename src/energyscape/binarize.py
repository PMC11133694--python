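"""Binarization of network time series and pattern-index encoding.

Per group, the continuous network-by-time matrices of all subjects are
concatenated into one ``N x S*T`` matrix ``Z``; each network (row) is then
thresholded at its own mean over the concatenation, giving +1 (active) above
the mean and -1 (inactive) otherwise.  Each time point's joint +/-1 vector is
encoded as an integer pattern index.

Bit order: network ``i`` (0-based) maps to bit ``i`` of the index, so
network 1 is the least-significant bit.  The all-inactive pattern is index 0.
This convention is shared by every module that enumerates patterns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "BinaryPatternData",
    "ConcatenatedSeries",
    "concatenate_subjects",
    "binarize_by_mean",
    "encode_pattern",
    "decode_pattern",
    "encode_pattern_array",
]


class ConcatenatedSeries(NamedTuple):
    """Group-level concatenation of subject time series.

    ``Z`` has shape (N, S*T) with columns subject-major (subject 1's time
    points first); ``n_subjects`` and ``t_per_subject`` record the subject
    boundaries so that later run-based statistics never span subjects.
    """

    Z: np.ndarray
    n_subjects: int
    t_per_subject: int


@dataclass(frozen=True)
class BinaryPatternData:
    """Binarized +/-1 activity of S subjects, N networks, T time points.

    Attributes
    ----------
    values : ndarray, shape (S, N, T), entries exactly -1 or +1
    pattern_index : ndarray, shape (S, T), integer pattern codes in [0, 2**N)
    thresholds : ndarray, shape (N,)
        Per-network means of the concatenated continuous matrix used as
        binarization thresholds.
    """

    values: np.ndarray
    pattern_index: np.ndarray
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise ValueError("values must be (S, N, T)")
        if not np.all(np.isin(v, (-1, 1))):
            raise ValueError("values must be exactly -1 or +1")
        object.__setattr__(self, "values", v.astype(np.int8))
        idx = np.asarray(self.pattern_index)
        if idx.shape != (v.shape[0], v.shape[2]):
            raise ValueError("pattern_index must be (S, T)")
        object.__setattr__(self, "pattern_index", idx.astype(np.int64))

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_networks(self) -> int:
        return self.values.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[2]


def concatenate_subjects(cohort: Sequence[np.ndarray]) -> ConcatenatedSeries:
    """Concatenate per-subject (N, T) matrices along time, subject-major."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    mats = [np.asarray(m, dtype=float) for m in cohort]
    n, t = mats[0].shape
    if n < 2:
        raise ValueError("need at least 2 networks")
    for i, m in enumerate(mats):
        if m.shape != (n, t):
            raise ValueError(
                f"subject {i} has shape {m.shape}, expected {(n, t)}"
            )
    return ConcatenatedSeries(np.concatenate(mats, axis=1), len(mats), t)


def binarize_by_mean(concat: ConcatenatedSeries) -> BinaryPatternData:
    """Threshold each network at its mean over the group concatenation.

    Entries strictly above the row mean map to +1; entries equal to or below
    it map to -1.  The result is reshaped back to (S, N, T).
    """
    Z, s, t = concat
    if not np.all(np.isfinite(Z)):
        raise ValueError("non-finite entries in the data matrix")
    m = Z.mean(axis=1)
    binary = np.where(Z > m[:, None], 1, -1).astype(np.int8)
    values = binary.reshape(Z.shape[0], s, t).transpose(1, 0, 2)
    idx = encode_pattern_array(values)
    return BinaryPatternData(values=values, pattern_index=idx, thresholds=m)


# ---------------------------------------------------------------------------
# pattern index codec: bit i of k set  <=>  network i active (+1)


def encode_pattern(sigma: Sequence[int]) -> int:
    """Encode one +/-1 pattern as its integer index."""
    sigma = np.asarray(sigma)
    if not np.all(np.isin(sigma, (-1, 1))):
        raise ValueError("pattern entries must be -1 or +1")
    bits = (sigma > 0).astype(np.int64)
    return int(bits @ (1 << np.arange(sigma.size)))

def decode_pattern(k: int, n_networks: int) -> np.ndarray:
    """Decode an integer index back to its +/-1 pattern."""
    if not 0 <= k < 2 ** n_networks:
        raise ValueError(f"index {k} out of range for N={n_networks}")
    bits = (k >> np.arange(n_networks)) & 1
    return (2 * bits - 1).astype(np.int8)


def encode_pattern_array(values: np.ndarray) -> np.ndarray:
    """Encode (S, N, T) or (N, T) +/-1 arrays to pattern indices over N."""
    v = np.asarray(values)
    net_axis = 0 if v.ndim == 2 else 1
    n = v.shape[net_axis]
    weights = 1 << np.arange(n, dtype=np.int64)
    bits = (v > 0).astype(np.int64)
    return np.tensordot(bits, weights, axes=([net_axis], [0]))
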