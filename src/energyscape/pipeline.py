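"""End-to-end orchestration of the per-group energy-landscape analysis.

For each group: concatenate subjects, binarize at the group mean, fit the
pairwise MEM, enumerate the landscape, find minima/basins, build the
disconnectivity tree, group minima into brain states, and compute the
per-subject dynamics measures.  Across groups: t tests with Bonferroni
correction over declared families, a chi-square comparison of state sizes,
behavior correlations restricted to significant measures, and a
Metropolis-Hastings simulation per group compared by chi-square tests on
count tables.

States are labelled per group by cutting that group's tree into
``n_states`` subtrees and numbering the states by their deepest minimum's
energy, so labels are comparable across groups when the landscapes are
similar (as for cohorts drawn from a shared ground truth).
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as esio
from .binarize import BinaryPatternData, binarize_by_mean, concatenate_subjects
from .dynamics import DEFAULT_TR_SECONDS, label_state_sequence, measures_table
from .landscape import (
    BasinMap,
    DisconnectivityTree,
    StateDefinition,
    assign_basins,
    build_disconnectivity_tree,
    group_minima_into_states,
)
from .mem import (
    FitDiagnostics,
    LandscapeTable,
    MEMParams,
    boltzmann_distribution,
    empirical_moments,
    empirical_pattern_frequencies,
    fit_accuracy,
    fit_independent_mem,
    fit_pairwise_mem,
)
from .simulate import metropolis_walk, simulated_measures
from .stats import (
    ChiSquareResult,
    behavior_correlations,
    chi_square_posthoc,
    compare_measures,
    families_for_states,
)

logger = logging.getLogger("energyscape")

__all__ = ["RunConfig", "GroupResult", "AnalysisBundle", "analyze_cohort", "run_group_analysis"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    manifest: str = ""
    outdir: str = "results"
    n_states: int = 3
    state_mapping: Optional[dict] = None
    learning_rate: float = 0.1
    tol: float = 1e-5
    max_iter: int = 50_000
    d_max: int = 1
    mcmc_steps: int = 100_000
    seed: int = 0
    equal_var: bool = True
    tr_seconds: float = DEFAULT_TR_SECONDS
    score_cols: list[str] = field(default_factory=lambda: ["score"])
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroupResult:
    """All per-group artifacts of the analysis."""

    group: str
    data: BinaryPatternData
    params: MEMParams
    fit_diagnostics: "FitDiagnostics"
    accuracy: "FitDiagnostics"
    table: LandscapeTable
    empirical_freq: np.ndarray
    basins: BasinMap
    tree: DisconnectivityTree
    states: StateDefinition
    measures: pd.DataFrame
    simulated: Optional[dict] = None
    sim_labels: Optional[np.ndarray] = None


@dataclass
class AnalysisBundle:
    """Whole-cohort result bundle."""

    groups: dict[str, GroupResult]
    measures: pd.DataFrame
    comparisons: pd.DataFrame
    state_size_chi2: "ChiSquareResult"
    behavior: Optional[pd.DataFrame] = None
    behavior_corr: Optional[pd.DataFrame] = None
    simulated_chi2: Optional[dict] = None
    config: Optional[RunConfig] = None


def analyze_group(
    series: Sequence[np.ndarray],
    group: str,
    config: RunConfig,
    subject_ids: Optional[Sequence[str]] = None,
) -> GroupResult:
    """Run the single-group stages: binarize, fit, landscape, measures."""
    concat = concatenate_subjects(list(series))
    data = binarize_by_mean(concat)
    moments = empirical_moments(data.values)
    params, diag = fit_pairwise_mem(
        moments,
        learning_rate=config.learning_rate,
        tol=config.tol,
        max_iter=config.max_iter,
    )
    table = boltzmann_distribution(params)
    freq = empirical_pattern_frequencies(data.pattern_index, data.n_networks)
    independent = boltzmann_distribution(fit_independent_mem(moments.mean_activity))
    acc = fit_accuracy(freq, independent, table)
    acc.iterations = diag.iterations
    acc.converged = diag.converged
    acc.max_moment_gap = diag.max_moment_gap

    basins = assign_basins(table)
    tree = build_disconnectivity_tree(table, list(basins.minima))
    if config.state_mapping is not None:
        states = group_minima_into_states(tree, mapping=config.state_mapping)
    else:
        k = min(config.n_states, len(basins.minima))
        states = group_minima_into_states(tree, k=k)
    seq = label_state_sequence(data, table, basins, states, tr_seconds=config.tr_seconds)
    measures = measures_table(seq, d_max=config.d_max, subject_ids=subject_ids, group=group)
    logger.info(
        "group %s: fit %s in %d iterations (gap %.2e), %d minima, %d states",
        group, "converged" if diag.converged else "NOT converged",
        diag.iterations, diag.max_moment_gap, len(basins.minima), states.n_states,
    )
    return GroupResult(
        group=group, data=data, params=params, fit_diagnostics=diag,
        accuracy=acc, table=table, empirical_freq=freq, basins=basins,
        tree=tree, states=states, measures=measures,
    )


def _state_pattern_counts(result: GroupResult, n_states: int) -> np.ndarray:
    """Number of the 2**N patterns assigned to each state (basin sizes as counts)."""
    codes = result.states.state_of_pattern(result.basins)
    return np.bincount(codes, minlength=n_states)


def _simulate_group(result: GroupResult, config: RunConfig, seed: int) -> None:
    traj = metropolis_walk(result.table, n_steps=config.mcmc_steps, seed=seed)
    result.simulated = simulated_measures(
        traj, result.table, result.basins, result.states, d_max=config.d_max
    )
    result.sim_labels = result.states.state_of_pattern(result.basins)[traj.steps]


def _sim_count_tables(groups: dict[str, GroupResult], n_states: int, d_max: int) -> dict[str, np.ndarray]:
    """Count tables (group x category) for chi-square comparison of simulations."""
    from .dynamics import run_length_encode, transition_statistics
    import warnings as _w

    occupancy, n_runs, trans, direct, indirect, inout = [], [], [], [], [], []
    for res in groups.values():
        labels = res.sim_labels
        occupancy.append(np.bincount(labels, minlength=n_states))
        runs = run_length_encode(labels)
        n_runs.append(np.bincount([lab for lab, _ in runs], minlength=n_states))
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            ts = transition_statistics(labels, n_states, d_max=d_max)
        tot = ts["n_transitions"]
        pairs = [(a, b) for a in range(n_states) for b in range(a + 1, n_states)]
        trans.append([round(ts["transition_frequency"][a, b] * tot) for a, b in pairs])
        direct.append([round(ts["direct_transition_frequency"][a, b] * tot) for a, b in pairs])
        indirect.append([round(ts["indirect_transition_frequency"][a, b] * tot) for a, b in pairs])
        inout.append([round(ts["inout_frequency"][s] * tot) for s in range(n_states)])
    return {
        "occupancy": np.array(occupancy),
        "state_runs": np.array(n_runs),
        "transition": np.array(trans),
        "direct_transition": np.array(direct),
        "indirect_transition": np.array(indirect),
        "inout": np.array(inout),
    }


def analyze_cohort(
    series: Mapping[str, Sequence[np.ndarray]],
    config: Optional[RunConfig] = None,
    behavior: Optional[pd.DataFrame] = None,
    subject_ids: Optional[Mapping[str, Sequence[str]]] = None,
    simulate: bool = True,
) -> AnalysisBundle:
    """Run the full two-group analysis on in-memory time series.

    ``series`` maps each group label to its list of (N, T) matrices;
    ``behavior`` optionally carries subject_id, group and score columns for
    the correlation stage.
    """
    config = config or RunConfig()
    groups: dict[str, GroupResult] = {}
    for group, mats in series.items():
        sids = subject_ids.get(group) if subject_ids else None
        groups[group] = analyze_group(mats, group, config, subject_ids=sids)

    measures = pd.concat([g.measures for g in groups.values()], ignore_index=True)
    n_states = max(g.states.n_states for g in groups.values())
    families = families_for_states(n_states)
    comparisons = compare_measures(measures, families=families, equal_var=config.equal_var)
    comparisons = comparisons.sort_values("p", kind="stable").reset_index(drop=True)

    counts = np.array([_state_pattern_counts(g, n_states) for g in groups.values()])
    # a state absent from one group would zero a column; drop empty columns
    keep = counts.sum(axis=0) > 0
    state_size_chi2 = chi_square_posthoc(counts[:, keep]) if keep.sum() >= 2 else None

    behavior_corr = None
    if behavior is not None:
        sig = comparisons.loc[comparisons["p_bonferroni"] < config.alpha, "measure"]
        if len(sig) > 0:
            score_cols = [c for c in config.score_cols if c in behavior.columns]
            behavior_corr = behavior_correlations(
                measures, behavior, list(sig), score_cols
            )
        else:
            logger.info("no measure survived Bonferroni; behavior correlations skipped")

    simulated_chi2 = None
    if simulate:
        ss = np.random.SeedSequence(config.seed)
        for child, res in zip(ss.spawn(len(groups)), groups.values()):
            _simulate_group(res, config, seed=child.generate_state(1)[0] % (2**31))
        tables = _sim_count_tables(groups, n_states, config.d_max)
        simulated_chi2 = {
            name: chi_square_posthoc(tab)
            for name, tab in tables.items()
            if min(np.asarray(tab).shape) >= 2
            and np.asarray(tab).sum(axis=0).min() > 0
            and np.asarray(tab).sum(axis=1).min() > 0
        }

    return AnalysisBundle(
        groups=groups, measures=measures, comparisons=comparisons,
        state_size_chi2=state_size_chi2, behavior=behavior,
        behavior_corr=behavior_corr, simulated_chi2=simulated_chi2,
        config=config,
    )


def run_group_analysis(config: RunConfig) -> AnalysisBundle:
    """File-based pipeline entry point: read manifest, analyze, persist."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        series, manifest = esio.read_cohort(config.manifest)
        sids = {
            g: list(manifest.loc[manifest["group"] == g, "subject_id"])
            for g in series
        }
        behavior = None
        score_cols = [c for c in config.score_cols if c in manifest.columns]
        if score_cols:
            behavior = manifest[["subject_id", "group"] + score_cols]
        bundle = analyze_cohort(series, config, behavior=behavior, subject_ids=sids)
        _persist(bundle, outdir, config)
        logger.info("pipeline finished in %.1f s", time.time() - t0)
        return bundle
    finally:
        logger.removeHandler(handler)
        handler.close()


def _persist(bundle: AnalysisBundle, outdir: Path, config: RunConfig) -> None:
    # hash only analysis parameters, not filesystem locations
    params = {k: v for k, v in config.to_dict().items() if k not in ("manifest", "outdir")}
    chash = esio.config_hash(params)
    provenance = {"config_hash": chash, "seed": config.seed}
    for name, res in bundle.groups.items():
        gdir = outdir / f"group-{name}"
        gdir.mkdir(exist_ok=True)
        esio.write_mem_params(res.params, gdir / "mem_params.tsv")
        esio.write_landscape_table(
            res.table, gdir / "landscape.tsv",
            empirical_freq=res.empirical_freq, basins=res.basins, states=res.states,
        )
        (gdir / "tree.newick").write_text(res.tree.to_newick() + "\n")
        res.measures.to_csv(gdir / "measures.csv", index=False)
        if res.simulated is not None:
            esio.write_json({**provenance, **res.simulated}, gdir / "simulated_measures.json")
    bundle.measures.to_csv(outdir / "measures.csv", index=False)
    bundle.comparisons.to_csv(outdir / "comparisons.csv", index=False)
    if bundle.behavior_corr is not None:
        bundle.behavior_corr.to_csv(outdir / "behavior_correlations.csv", index=False)

    summary = {
        **provenance,
        "groups": {
            name: {
                "n_subjects": int(res.data.n_subjects),
                "n_networks": int(res.data.n_networks),
                "R": res.accuracy.R,
                "pearson_r": res.accuracy.pearson_r,
                "converged": bool(res.fit_diagnostics.converged),
                "iterations": int(res.fit_diagnostics.iterations),
                "n_minima": len(res.basins.minima),
                "basin_sizes": res.basins.basin_sizes.tolist(),
                "minima": [list(m) for m in res.basins.minima],
            }
            for name, res in bundle.groups.items()
        },
        "state_size_chi2": {
            "chi2": bundle.state_size_chi2.chi2,
            "p": bundle.state_size_chi2.p,
            "df": bundle.state_size_chi2.df,
        },
        "top_comparison": (
            bundle.comparisons.iloc[0][["measure", "t", "p", "p_bonferroni"]].to_dict()
            if len(bundle.comparisons)
            else None
        ),
        "simulated_chi2": (
            {k: {"chi2": v.chi2, "p": v.p, "df": v.df} for k, v in bundle.simulated_chi2.items()}
            if bundle.simulated_chi2
            else None
        ),
    }
    esio.write_json(summary, outdir / "summary.json")
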