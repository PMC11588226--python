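"""CSV/JSON interchange for curves, labels, scores and run provenance.

Curve matrices travel as plain CSV, one curve per row, with the grid
values as the header row.  A JSON sidecar (``<name>.json`` next to the
CSV) records the basis family, domain and variable blocks so a sample
can be reconstructed faithfully.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .basis import BasisSystem, FunctionalSample, make_discrete_basis


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(".json")


def write_curves(path, sample: FunctionalSample) -> None:
    """Write a sample's coefficient/value matrix plus its JSON sidecar."""
    path = Path(path)
    if sample.basis.family == "discrete" and sample.n_vars == 1:
        header = [f"{t:.10g}" for t in sample.grid]
    else:
        header = [f"c{j}" for j in range(sample.m)]
    pd.DataFrame(sample.coefficients, columns=header).to_csv(path, index=False)
    meta = {
        "family": sample.basis.family,
        "m": sample.basis.m,
        "domain": list(sample.basis.domain),
        "var_blocks": [list(b) for b in sample.var_blocks],
    }
    if sample.basis.family == "discrete":
        meta["grid"] = list(map(float, sample.grid))
    sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_curves(path) -> FunctionalSample:
    """Read a curve CSV (and sidecar, if present) back into a sample.

    Without a sidecar the file is interpreted as grid values: the header
    must parse as a strictly increasing grid, which then defines a
    discrete basis on its span.
    """
    path = Path(path)
    df = pd.read_csv(path)
    values = df.to_numpy(dtype=float)
    side = sidecar_path(path)
    if side.exists():
        meta = json.loads(side.read_text())
        fam = meta["family"]
        a, b = meta["domain"]
        if fam == "discrete":
            grid = np.asarray(meta["grid"], dtype=float)
            basis = make_discrete_basis(grid.size, a, b)
            blocks = tuple(tuple(x) for x in meta["var_blocks"])
            if len(blocks) > 1:
                W = basis.W
                # stacked discrete variables share the grid; metric repeats
                from scipy.linalg import block_diag

                W = block_diag(*[np.eye(b2 - a2) * W[0, 0] for a2, b2 in blocks])
                basis = BasisSystem(fam, values.shape[1], (a, b), W, grid=grid)
            return FunctionalSample(values, basis, grid=grid, var_blocks=blocks)
        raise ValueError(
            "only discrete-family sidecars are round-tripped; refit basis "
            "coefficients from grid values instead"
        )
    try:
        grid = np.asarray([float(c) for c in df.columns], dtype=float)
    except ValueError as exc:
        raise ValueError("curve CSV without sidecar needs a numeric grid header") from exc
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid header must be strictly increasing")
    basis = make_discrete_basis(grid.size, float(grid[0]), float(grid[-1]))
    return FunctionalSample(values, basis, grid=grid)


def write_labels(path, labels, cluster_ids) -> None:
    pd.DataFrame(
        {
            "curve_id": np.arange(len(labels)),
            "is_outlier": np.asarray(labels, dtype=int),
            "cluster_id": np.asarray(cluster_ids, dtype=int),
        }
    ).to_csv(path, index=False)


def read_labels(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["is_outlier"].to_numpy(bool), df["cluster_id"].to_numpy(int)


def write_scores(path, scores, labels=None) -> None:
    df = pd.DataFrame({"curve_id": np.arange(len(scores)), "score": scores})
    if labels is not None:
        df["label"] = np.asarray(labels, dtype=int)
    df.to_csv(path, index=False)


def write_provenance(path, config: dict, seed: int | None) -> None:
    """Record what produced an output: settings, seed and versions."""
    record = {
        "config": config,
        "seed": seed,
        "faaknn_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
    }
    Path(path).write_text(json.dumps(record, indent=2, default=str))
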