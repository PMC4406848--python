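"""Serialization: matrices, tensors, projections and decompositions.

Delimited-text matrices travel with a one-line JSON sidecar (``<path>.json``)
carrying the block metadata (q, n, N_T, block_order) so that any file on disk
can be rebuilt into a :class:`~rprpca.matrix.DataMatrix` without guessing the
species/time layout.  ``.npz`` archives embed the same metadata directly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .linalg import Decomposition
from .matrix import DataMatrix, TrialTensor
from .projection import ProjectionOperator

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_tensor_csv",
    "write_tensor_csv",
    "write_decomposition",
    "read_decomposition",
    "write_projection",
    "read_projection",
]

_FORMATS = ("csv", "tsv", "npz")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in _FORMATS:
            raise ValueError(f"unknown format {format!r}; choose from {_FORMATS}")
        return format
    suffix = path.suffix.lstrip(".").lower()
    if suffix in _FORMATS:
        return suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def write_matrix(X: DataMatrix, path, format: str | None = None) -> None:
    """Write a data matrix with its block-metadata sidecar.

    CSV/TSV values are written with 17 significant digits so the text round
    trip is exact for doubles; ``npz`` is a lossless binary round trip.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    meta = {
        "q": X.n_trials,
        "n": X.n_species,
        "N_T": X.n_timepoints,
        "block_order": X.block_order,
        "row_labels": list(X.row_labels),
        "column_labels": list(X.column_labels),
    }
    if fmt == "npz":
        np.savez(path, values=X.values, meta=json.dumps(meta))
        return
    sep = "," if fmt == "csv" else "\t"
    df = pd.DataFrame(X.values, index=X.row_labels, columns=X.column_labels)
    df.to_csv(path, sep=sep, float_format="%.17g")
    _sidecar_path(path).write_text(json.dumps(meta) + "\n")


def read_matrix(path, format: str | None = None) -> DataMatrix:
    """Read a matrix written by :func:`write_matrix`."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "npz":
        with np.load(path, allow_pickle=False) as archive:
            values = archive["values"]
            meta = json.loads(str(archive["meta"]))
    else:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FileNotFoundError(
                f"missing metadata sidecar {sidecar.name}; matrices must be "
                "written with write_matrix (or provide the JSON sidecar with "
                "q, n, N_T and block_order)")
        meta = json.loads(sidecar.read_text())
        sep = "," if fmt == "csv" else "\t"
        # round_trip parsing so 17-significant-digit text is bit-exact
        df = pd.read_csv(path, sep=sep, index_col=0,
                         float_precision="round_trip")
        values = df.to_numpy(dtype=float)
    expected = meta["n"] * meta["N_T"]
    if values.shape[1] != expected:
        raise ValueError(
            f"{path.name}: {values.shape[1]} columns but sidecar declares "
            f"n*N_T = {expected}")
    return DataMatrix(
        values,
        n_species=meta["n"],
        n_timepoints=meta["N_T"],
        row_labels=list(meta.get("row_labels") or []),
        column_labels=list(meta.get("column_labels") or []),
        block_order=meta.get("block_order", "species-major"),
    )


def write_tensor_csv(T: TrialTensor, path) -> None:
    """Long-format CSV export: one (trial, species, time, value) row each."""
    q, n, nt = T.data.shape
    trial = np.repeat(np.arange(q), n * nt)
    species = np.tile(np.repeat(np.arange(n), nt), q)
    time = np.tile(np.arange(nt), q * n)
    df = pd.DataFrame({
        "trial": [T.trial_labels[i] for i in trial],
        "species": [T.species_labels[i] for i in species],
        "time": T.time_labels[time],
        "value": T.data.ravel(),
    })
    df.to_csv(path, index=False, float_format="%.17g")


def read_tensor_csv(path) -> TrialTensor:
    """Read a long-format (trial, species, time, value) CSV into a tensor."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"trial", "species", "time", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"long-format CSV needs columns {sorted(required)}")
    trials = list(dict.fromkeys(df["trial"]))
    species = list(dict.fromkeys(df["species"]))
    times = np.sort(df["time"].unique())
    pivot = df.set_index(["trial", "species", "time"])["value"]
    data = np.empty((len(trials), len(species), len(times)))
    for a, tr in enumerate(trials):
        for b, sp in enumerate(species):
            data[a, b] = pivot.loc[tr, sp].reindex(times).to_numpy()
    if np.isnan(data).any():
        raise ValueError("long-format CSV is not a complete trial grid")
    return TrialTensor(data, trial_labels=[str(t) for t in trials],
                       species_labels=[str(s) for s in species],
                       time_labels=times.astype(float))


def write_decomposition(dec: Decomposition, directory, stem: str = "decomp",
                        format: str = "csv",
                        template: DataMatrix | None = None) -> None:
    """Write L, S and a JSON diagnostics record into ``directory``.

    ``template`` supplies the block metadata for the component matrices; when
    omitted a single-species layout is assumed.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if template is None:
        template = DataMatrix(dec.L, n_species=1, n_timepoints=dec.L.shape[1])
    write_matrix(template.with_values(dec.L),
                 directory / f"{stem}_L.{format}", format)
    write_matrix(template.with_values(dec.S),
                 directory / f"{stem}_S.{format}", format)
    record = {
        "lam": dec.lam,
        "iterations": dec.iterations,
        "residual": dec.residual,
        "converged": dec.converged,
        "back_projected": dec.back_projected,
    }
    (directory / f"{stem}_diagnostics.json").write_text(
        json.dumps(record, indent=2) + "\n")


def read_decomposition(directory, stem: str = "decomp",
                       format: str = "csv") -> Decomposition:
    directory = Path(directory)
    L = read_matrix(directory / f"{stem}_L.{format}", format)
    S = read_matrix(directory / f"{stem}_S.{format}", format)
    record = json.loads((directory / f"{stem}_diagnostics.json").read_text())
    return Decomposition(L.values, S.values, record["lam"],
                         iterations=record["iterations"],
                         residual=record["residual"],
                         converged=record["converged"],
                         back_projected=record.get("back_projected", False))


def write_projection(P: ProjectionOperator, path) -> None:
    """Matrix file plus JSON metadata so a run is exactly replayable."""
    path = Path(path)
    np.savetxt(path, P.psi, delimiter=",", fmt="%.17g")
    meta = {"m": P.m, "n": P.n, "N_T": P.N_T, "seed": P.seed,
            "distribution": P.distribution}
    _sidecar_path(path).write_text(json.dumps(meta) + "\n")


def read_projection(path) -> ProjectionOperator:
    path = Path(path)
    psi = np.atleast_2d(np.loadtxt(path, delimiter=","))
    meta = json.loads(_sidecar_path(path).read_text())
    if psi.shape != (meta["m"], meta["n"]):
        raise ValueError("projection matrix shape disagrees with its sidecar")
    return ProjectionOperator(psi, meta["N_T"], seed=meta.get("seed"),
                              distribution=meta.get("distribution", "gaussian"))
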