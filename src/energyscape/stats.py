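"""Group comparisons and behavior correlations.

Implements the statistical stage of the pipeline: pooled-variance two-sample
t tests with Bonferroni correction over explicitly declared measure
families, chi-square tests with post-hoc adjusted standardized residuals for
count tables (used for basin-size and simulated-dynamics comparisons), and
per-group Pearson correlations between behavior scores and the dynamics
measures that showed significant group differences.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "ChiSquareResult",
    "two_sample_t",
    "t_from_summary",
    "bonferroni_adjust",
    "chi_square_posthoc",
    "compare_measures",
    "behavior_correlations",
    "DEFAULT_FAMILIES",
]


@dataclass
class ComparisonResult:
    """One group comparison: statistic, p values, family bookkeeping."""

    statistic: float
    p: float
    df: float
    corrected_p: Optional[float] = None
    family: Optional[str] = None
    family_size: Optional[int] = None
    mean1: Optional[float] = None
    sd1: Optional[float] = None
    n1: Optional[int] = None
    mean2: Optional[float] = None
    sd2: Optional[float] = None
    n2: Optional[int] = None
    overflow: bool = False


@dataclass
class ChiSquareResult:
    """Pearson chi-square with per-cell post-hoc adjusted residuals."""

    chi2: float
    p: float
    df: int
    observed: np.ndarray = field(repr=False, default=None)
    expected: np.ndarray = field(repr=False, default=None)
    adjusted_residuals: np.ndarray = field(repr=False, default=None)
    residual_p: np.ndarray = field(repr=False, default=None)
    residual_p_corrected: np.ndarray = field(repr=False, default=None)


def _pooled_t(m1, s1, n1, m2, s2, n2) -> tuple[float, float, bool]:
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / df
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        if m1 == m2:
            return 0.0, float(df), False
        return math.inf if m1 > m2 else -math.inf, float(df), True
    return (m1 - m2) / se, float(df), False


def two_sample_t(
    group1: Sequence[float],
    group2: Sequence[float],
    equal_var: bool = True,
) -> ComparisonResult:
    """Two-sample t test (pooled-variance Student form by default).

    NaNs are dropped per group.  With ``equal_var=False`` the Welch form
    (Satterthwaite degrees of freedom) is used instead.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 non-missing values")
    m1, m2 = x.mean(), y.mean()
    s1, s2 = x.std(ddof=1), y.std(ddof=1)
    if equal_var:
        t, df, overflow = _pooled_t(m1, s1, n1, m2, s2, n2)
    else:
        v1, v2 = s1 ** 2 / n1, s2 ** 2 / n2
        se = math.sqrt(v1 + v2)
        if se == 0:
            t, df, overflow = (0.0, float(n1 + n2 - 2), False) if m1 == m2 else (
                math.copysign(math.inf, m1 - m2), float(n1 + n2 - 2), True)
        else:
            t = (m1 - m2) / se
            df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
            overflow = False
    p = 0.0 if overflow else 2 * sps.t.sf(abs(t), df)
    return ComparisonResult(
        statistic=float(t), p=float(p), df=df,
        mean1=float(m1), sd1=float(s1), n1=n1,
        mean2=float(m2), sd2=float(s2), n2=n2,
        overflow=overflow,
    )


def t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> ComparisonResult:
    """Pooled-variance Student t from printed summary statistics.

    t = (m1 - m2) / sqrt(s_p^2 (1/n1 + 1/n2)) with
    s_p^2 = ((n1-1)s1^2 + (n2-1)s2^2) / (n1 + n2 - 2).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    t, df, overflow = _pooled_t(mean1, sd1, n1, mean2, sd2, n2)
    p = 0.0 if overflow else 2 * sps.t.sf(abs(t), df)
    return ComparisonResult(
        statistic=float(t), p=float(p), df=df,
        mean1=mean1, sd1=sd1, n1=n1, mean2=mean2, sd2=sd2, n2=n2,
        overflow=overflow,
    )


def bonferroni_adjust(p_values: Sequence[float], family_size: Optional[int] = None) -> np.ndarray:
    """Bonferroni correction: ``min(1, p * family size)``.

    ``family_size`` defaults to the number of p values passed; pass it
    explicitly when correcting a subset of a declared family.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = family_size if family_size is not None else p.size
    return np.minimum(1.0, p * m)


def chi_square_posthoc(table: np.ndarray) -> ChiSquareResult:
    """Pearson chi-square test of independence with post-hoc residuals.

    The adjusted standardized residual of cell (i, j) is
    ``(O - E) / sqrt(E (1 - row_i/n) (1 - col_j/n))``, approximately standard
    normal under independence; its two-sided normal p values are Bonferroni
    corrected across cells.  Cells with expected count 0 are flagged NaN and
    excluded with a warning.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or np.any(obs < 0):
        raise ValueError("need a 2-D table of non-negative counts")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row <= 0) or np.any(col <= 0):
        raise ValueError("all row and column sums must be positive")
    n = obs.sum()
    expected = np.outer(row, col) / n
    ok = expected > 0
    if not ok.all():
        warnings.warn("cells with expected count 0 excluded", stacklevel=2)
    chi2 = float(np.sum((obs[ok] - expected[ok]) ** 2 / expected[ok]))
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(chi2, df))
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(expected * (1 - row[:, None] / n) * (1 - col[None, :] / n))
        adj = np.where(ok & (denom > 0), (obs - expected) / denom, np.nan)
    res_p = 2 * sps.norm.sf(np.abs(adj))
    n_cells = int(np.isfinite(adj).sum())
    res_p_corr = np.minimum(1.0, res_p * n_cells)
    return ChiSquareResult(
        chi2=chi2, p=p, df=df, observed=obs, expected=expected,
        adjusted_residuals=adj, residual_p=res_p, residual_p_corrected=res_p_corr,
    )


# ---------------------------------------------------------------------------
# measure-table comparisons

#: Bonferroni families over the per-subject measure columns, for 3 states.
#: Occupancy-type measures form one family per measure across the 3 states;
#: pair-transition measures across the 3 unordered pairs.
DEFAULT_FAMILIES: dict[str, list[str]] = {
    "appearance_frequency": ["appearance_frequency_s1", "appearance_frequency_s2", "appearance_frequency_s3"],
    "mean_duration": ["mean_duration_s1", "mean_duration_s2", "mean_duration_s3"],
    "mean_energy": ["mean_energy_s1", "mean_energy_s2", "mean_energy_s3"],
    "transition_frequency": ["transition_frequency_s1s2", "transition_frequency_s1s3", "transition_frequency_s2s3"],
    "direct_transition_frequency": ["direct_transition_frequency_s1s2", "direct_transition_frequency_s1s3", "direct_transition_frequency_s2s3"],
    "indirect_transition_frequency": ["indirect_transition_frequency_s1s2", "indirect_transition_frequency_s1s3", "indirect_transition_frequency_s2s3"],
    "inout_frequency": ["inout_frequency_s1", "inout_frequency_s2", "inout_frequency_s3"],
}


def families_for_states(n_states: int) -> dict[str, list[str]]:
    """Measure families (for Bonferroni correction) for ``n_states`` states."""
    states = [f"s{i + 1}" for i in range(n_states)]
    pairs = [f"s{a + 1}s{b + 1}" for a in range(n_states) for b in range(a + 1, n_states)]
    fams = {}
    for name in ("appearance_frequency", "mean_duration", "mean_energy", "inout_frequency"):
        fams[name] = [f"{name}_{s}" for s in states]
    for name in ("transition_frequency", "direct_transition_frequency", "indirect_transition_frequency"):
        fams[name] = [f"{name}_{p}" for p in pairs]
    return fams


def compare_measures(
    measures: pd.DataFrame,
    group_col: str = "group",
    families: Optional[Mapping[str, Sequence[str]]] = None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sample t tests over all measure columns, Bonferroni per family.

    ``measures`` holds one row per subject with a group label column; the
    two groups are compared column by column, and each raw p value is
    multiplied by its declared family size (capped at 1).  Returns a tidy
    table sorted as given, one row per measure.
    """
    groups = list(dict.fromkeys(measures[group_col]))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    g1 = measures[measures[group_col] == groups[0]]
    g2 = measures[measures[group_col] == groups[1]]
    if families is None:
        families = DEFAULT_FAMILIES
    rows = []
    for fam_name, cols in families.items():
        present = [c for c in cols if c in measures.columns]
        if not present:
            continue
        fam_size = len(present)
        for c in present:
            if (g1[c].notna().sum() < 2) or (g2[c].notna().sum() < 2):
                warnings.warn(
                    f"measure {c} has fewer than 2 values in a group; skipped",
                    stacklevel=2,
                )
                continue
            res = two_sample_t(g1[c], g2[c], equal_var=equal_var)
            rows.append({
                "measure": c,
                "family": fam_name,
                "family_size": fam_size,
                f"mean_{groups[0]}": res.mean1,
                f"sd_{groups[0]}": res.sd1,
                f"mean_{groups[1]}": res.mean2,
                f"sd_{groups[1]}": res.sd2,
                "t": res.statistic,
                "df": res.df,
                "p": res.p,
                "p_bonferroni": float(bonferroni_adjust([res.p], fam_size)[0]),
            })
    return pd.DataFrame(rows)


def behavior_correlations(
    measures: pd.DataFrame,
    behavior: pd.DataFrame,
    selected_measures: Sequence[str],
    score_cols: Sequence[str],
    group_col: str = "group",
    subject_col: str = "subject_id",
) -> pd.DataFrame:
    """Pearson correlations between behavior scores and selected measures.

    Correlations are computed within each group separately, restricted to
    the measures previously flagged as showing a significant group
    difference.  Zero-variance columns yield missing r with a warning.
    """
    if len(selected_measures) == 0:
        raise ValueError("no measures selected for behavior correlation")
    merged = measures.merge(behavior, on=[subject_col, group_col], how="inner")
    rows = []
    for grp, sub in merged.groupby(group_col, sort=False):
        for m in selected_measures:
            for score in score_cols:
                x = sub[m].to_numpy(dtype=float)
                y = sub[score].to_numpy(dtype=float)
                keep = ~(np.isnan(x) | np.isnan(y))
                x, y = x[keep], y[keep]
                if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                    warnings.warn(
                        f"correlation undefined for {m} vs {score} in group {grp}",
                        stacklevel=2,
                    )
                    r, p = np.nan, np.nan
                else:
                    r, p = sps.pearsonr(x, y)
                rows.append({
                    "group": grp, "measure": m, "score": score,
                    "n": int(x.size), "r": float(r), "p": float(p),
                })
    return pd.DataFrame(rows)
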