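"""Delimited-text input/output for cohorts, models and results.

Everything is plain text: per-subject network-by-time matrices as TSV, a
cohort manifest as CSV (subject ID, group, behavior columns, file path),
fitted parameters and landscape tables as TSV, trees as Newick.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .binarize import decode_pattern
from .landscape import BasinMap, StateDefinition
from .mem import LandscapeTable, MEMParams
from .synthetic import Cohort

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_mem_params",
    "read_mem_params",
    "write_landscape_table",
    "config_hash",
    "write_json",
]

MANIFEST_NAME = "manifest.csv"


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write per-subject TSV matrices, a manifest, and a ground-truth sidecar.

    Returns the manifest path.  The sidecar records each group's h, J and
    the generator seed so that downstream recovery can be checked.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    behavior = cohort.behavior.set_index("subject_id")
    for group, mats in cohort.series.items():
        sub_ids = [i for i in behavior.index if behavior.loc[i, "group"] == group]
        for sid, mat in zip(sub_ids, mats):
            fname = f"{sid}.tsv"
            np.savetxt(outdir / fname, mat, delimiter="\t", fmt="%.6f")
            row = {"subject_id": sid, "group": group, "file": fname}
            for col in behavior.columns:
                if col != "group":
                    row[col] = behavior.loc[sid, col]
            rows.append(row)
    manifest = outdir / MANIFEST_NAME
    pd.DataFrame(rows).to_csv(manifest, index=False)

    sidecar = {
        "seed": cohort.truth.seed,
        "snr": cohort.snr,
        "persistence": cohort.truth.persistence,
        "groups": {
            g: {"h": p.h.tolist(), "J": p.J.tolist()}
            for g, p in cohort.truth.params_per_group.items()
        },
    }
    (outdir / "ground_truth.json").write_text(json.dumps(sidecar, indent=1))
    return manifest


def read_cohort(manifest: str | Path) -> tuple[dict[str, list[np.ndarray]], pd.DataFrame]:
    """Read a cohort manifest; returns per-group matrices and the manifest table."""
    manifest = Path(manifest)
    table = pd.read_csv(manifest)
    series: dict[str, list[np.ndarray]] = {}
    for _, row in table.iterrows():
        mat = np.loadtxt(manifest.parent / row["file"], delimiter="\t")
        series.setdefault(row["group"], []).append(mat)
    return series, table


def write_mem_params(params: MEMParams, path: str | Path) -> None:
    """Write h and J as a single TSV: first row h, then the J matrix."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# pairwise MEM parameters: row 1 = h, rows 2..N+1 = J\n")
        np.savetxt(fh, params.h[None, :], delimiter="\t", fmt="%.12g")
        np.savetxt(fh, params.J, delimiter="\t", fmt="%.12g")


def read_mem_params(path: str | Path) -> MEMParams:
    raw = np.loadtxt(path, delimiter="\t", comments="#")
    return MEMParams(h=raw[0], J=raw[1:])


def write_landscape_table(
    table: LandscapeTable,
    path: str | Path,
    empirical_freq: Optional[np.ndarray] = None,
    basins: Optional[BasinMap] = None,
    states: Optional[StateDefinition] = None,
) -> pd.DataFrame:
    """Full per-pattern landscape table as TSV (one row per pattern).

    Columns: pattern index, +/-1 pattern string (network 1 first), energy,
    probability, and optionally empirical frequency, basin minimum and
    state label.
    """
    n = table.n_networks
    df = pd.DataFrame({
        "pattern_index": np.arange(table.n_patterns),
        "pattern": [
            "".join("+" if v > 0 else "-" for v in decode_pattern(k, n))
            for k in range(table.n_patterns)
        ],
        "energy": table.energies,
        "probability": table.probabilities,
    })
    if empirical_freq is not None:
        df["empirical_frequency"] = empirical_freq
    if basins is not None:
        df["basin_minimum"] = basins.basin_of
        if states is not None:
            codes = states.state_of_pattern(basins)
            names = states.states
            df["state"] = [names[c] for c in codes]
    df.to_csv(path, sep="\t", index=False)
    return df


def config_hash(config: Mapping) -> str:
    """Stable short hash of a configuration mapping, for provenance stamps."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, default=default, allow_nan=True))
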