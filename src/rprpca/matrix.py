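"""Trial tensors and the stacked trial-by-feature data matrix.

A recording session (or perturbation panel) is a set of ``q`` aligned trials,
each an ``n`` species × ``N_T`` time-point array.  The stacked data matrix
``X`` places one trial per row, vectorized *species-major*: columns are grouped
per species, each group holding that species' full time course in temporal
order.  This layout is what the Kronecker-structured projection operator
``Ψᵀ ⊗ I_{N_T}`` acts on, so it is enforced everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger("rprpca")

__all__ = [
    "DataMatrix",
    "TrialTensor",
    "build_data_matrix",
    "unbuild_data_matrix",
    "align_trials",
]


def _default_labels(prefix: str, k: int) -> list[str]:
    return [f"{prefix}{i}" for i in range(k)]


@dataclass
class DataMatrix:
    """A ``q × (n·N_T)`` matrix of vectorized trials with block metadata.

    Parameters
    ----------
    values
        Real matrix, one row per trial, species-major column blocks.
    n_species
        Number of species (neurons, proteins, genes) ``n``.
    n_timepoints
        Time points per species block ``N_T``.
    row_labels, column_labels
        Optional identifiers; generated when omitted.
    block_order
        Column-block convention; only ``"species-major"`` is supported.
    """

    values: np.ndarray
    n_species: int
    n_timepoints: int
    row_labels: list[str] = field(default_factory=list)
    column_labels: list[str] = field(default_factory=list)
    block_order: str = "species-major"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.block_order != "species-major":
            raise ValueError(f"unsupported block order: {self.block_order!r}")
        if self.n_species < 1 or self.n_timepoints < 1:
            raise ValueError("n_species and n_timepoints must be positive")
        q, cols = self.values.shape
        if cols != self.n_species * self.n_timepoints:
            raise ValueError(
                f"column count {cols} != n_species*n_timepoints "
                f"({self.n_species}*{self.n_timepoints})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if not self.row_labels:
            self.row_labels = _default_labels("trial", q)
        if not self.column_labels:
            self.column_labels = [
                f"s{i}_t{t}"
                for i in range(self.n_species)
                for t in range(self.n_timepoints)
            ]
        if len(self.row_labels) != q:
            raise ValueError("row_labels length mismatch")
        if len(self.column_labels) != cols:
            raise ValueError("column_labels length mismatch")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def block(self, i: int) -> np.ndarray:
        """Time-course block of species ``i``: a ``q × N_T`` slice."""
        if not 0 <= i < self.n_species:
            raise IndexError(f"species index {i} out of range")
        nt = self.n_timepoints
        return self.values[:, i * nt : (i + 1) * nt]

    def as_tensor(self) -> np.ndarray:
        """Reshape to ``(q, n, N_T)`` without copying metadata."""
        q = self.n_trials
        return self.values.reshape(q, self.n_species, self.n_timepoints)

    def with_values(self, values: np.ndarray, **overrides) -> "DataMatrix":
        """A copy sharing metadata but holding different values."""
        kwargs = dict(
            n_species=self.n_species,
            n_timepoints=self.n_timepoints,
            row_labels=list(self.row_labels),
            column_labels=list(self.column_labels),
            block_order=self.block_order,
        )
        kwargs.update(overrides)
        return DataMatrix(np.asarray(values, dtype=float), **kwargs)


@dataclass
class TrialTensor:
    """``q`` aligned trials of an ``n × N_T`` spatio-temporal recording."""

    data: np.ndarray  # (q, n, N_T)
    trial_labels: list[str] = field(default_factory=list)
    species_labels: list[str] = field(default_factory=list)
    time_labels: np.ndarray | None = None
    alignment_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be a (trials, species, time) array")
        q, n, nt = self.data.shape
        if not self.trial_labels:
            self.trial_labels = _default_labels("trial", q)
        if not self.species_labels:
            self.species_labels = _default_labels("s", n)
        if self.time_labels is None:
            self.time_labels = np.arange(nt, dtype=float)
        else:
            self.time_labels = np.asarray(self.time_labels, dtype=float)
        if len(self.trial_labels) != q or len(self.species_labels) != n:
            raise ValueError("label length mismatch")
        if self.time_labels.shape != (nt,):
            raise ValueError("time_labels length mismatch")
        if nt > 1 and not np.all(np.diff(self.time_labels) > 0):
            raise ValueError("time_labels must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_species(self) -> int:
        return self.data.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[2]


def build_data_matrix(tensor: TrialTensor) -> DataMatrix:
    """Stack a trial tensor into the ``q × n·N_T`` species-major matrix.

    Row ``i`` is the species-major vectorization of trial ``i``: the time
    courses of species 0, 1, …, n−1 concatenated in order.
    """
    q, n, nt = tensor.data.shape
    values = tensor.data.reshape(q, n * nt)
    columns = [
        f"{tensor.species_labels[i]}_t{t}" for i in range(n) for t in range(nt)
    ]
    return DataMatrix(
        values.copy(),
        n_species=n,
        n_timepoints=nt,
        row_labels=list(tensor.trial_labels),
        column_labels=columns,
    )


def unbuild_data_matrix(X: DataMatrix) -> TrialTensor:
    """Exact inverse of :func:`build_data_matrix`."""
    q, cols = X.shape
    n, nt = X.n_species, X.n_timepoints
    if cols != n * nt:  # defensive; DataMatrix enforces this already
        raise ValueError("column count inconsistent with block metadata")
    species = [lbl.rsplit("_t", 1)[0] for lbl in X.column_labels[::nt]]
    return TrialTensor(
        X.values.reshape(q, n, nt).copy(),
        trial_labels=list(X.row_labels),
        species_labels=species,
    )


def align_trials(
    raw: Sequence[np.ndarray],
    onsets: Sequence[int],
    window: tuple[int, int],
    trial_labels: Sequence[str] | None = None,
) -> TrialTensor:
    """Cut equal-length windows around each trial's event index.

    Each raw trial is an ``n × T_i`` series (a 1-D series is treated as a
    single species).  The window ``(pre, post)`` keeps samples with 0-based
    indices in the half-open range ``[onset−pre, onset+post)``, so
    ``N_T = pre + post``.  Trials whose window falls outside the recording are
    dropped and counted in the log.
    """
    pre, post = window
    if pre < 0 or post < 0 or pre + post == 0:
        raise ValueError("window (pre, post) must be nonnegative with pre+post > 0")
    if len(raw) != len(onsets):
        raise ValueError("raw and onsets must have equal length")

    segments: list[np.ndarray] = []
    kept: list[int] = []
    for idx, (series, onset) in enumerate(zip(raw, onsets)):
        arr = np.atleast_2d(np.asarray(series, dtype=float))
        start, stop = onset - pre, onset + post
        if start < 0 or stop > arr.shape[1]:
            continue
        segments.append(arr[:, start:stop])
        kept.append(idx)

    n_dropped = len(raw) - len(segments)
    if n_dropped:
        logger.info("align_trials: dropped %d trial(s) too short for the window",
                    n_dropped)
    if not segments:
        raise ValueError("no trial covers the requested alignment window")
    shapes = {s.shape for s in segments}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent trial shapes after alignment: {shapes}")

    labels = (
        [trial_labels[i] for i in kept]
        if trial_labels is not None
        else _default_labels("trial", len(kept))
    )
    return TrialTensor(np.stack(segments), trial_labels=labels,
                       alignment_index=pre)
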