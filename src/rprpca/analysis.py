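"""Downstream consumers of the decomposition.

Two applications are built on the low-rank/sparse split:

* **event detection** — the common response ``L`` summarizes the stereotyped
  population signature around an event (e.g. submovement onset); correlating
  a template extracted from ``L`` against a held-out stream and thresholding
  the score detects event onsets, evaluated with an ROC curve;
* **clustering** — rows (perturbation experiments, cell lines) are compared
  either on the raw matrix with the correlation distance d_xy = 1 − corr, or
  on the disentangled pair [L S] with d_φψ, a γ-weighted combination of the
  correlation distances of the common and aberrant parts, fed to
  agglomerative clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .linalg import Decomposition
from .matrix import DataMatrix

logger = logging.getLogger("rprpca")

__all__ = [
    "DetectionResult",
    "DissimilarityMatrix",
    "extract_template",
    "correlation_score",
    "detect_onsets",
    "roc_curve",
    "roc_auc",
    "dissimilarity_raw",
    "dissimilarity_disentangled",
    "hierarchical_cluster",
    "dendrogram_newick",
]


# -- event detection ---------------------------------------------------------

@dataclass
class DetectionResult:
    """Correlation-score trace, threshold, and the detected rising edges."""

    score_trace: np.ndarray
    threshold: float
    detected_onsets: np.ndarray
    match_window: int = 5


def extract_template(L: np.ndarray, method: str = "svd") -> np.ndarray:
    """Reduce the common component to a single feature template.

    ``method="svd"`` (default) returns the leading right singular vector of
    ``L`` — the best rank-1 temporal summary — unit-normalized with its
    largest-magnitude entry made positive.  ``method="mean"`` returns the row
    mean.
    """
    L = np.asarray(L, dtype=float)
    if not np.any(L):
        raise ValueError("cannot extract a template from an all-zero matrix")
    if method == "svd":
        _, _, Vt = np.linalg.svd(L, full_matrices=False)
        v = Vt[0]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        return v
    if method == "mean":
        return L.mean(axis=0)
    raise ValueError(f"unknown template method {method!r}")


def correlation_score(
    signal: np.ndarray,
    template: np.ndarray,
    stride: int = 1,
) -> np.ndarray:
    """Sliding Pearson correlation between a stream and a feature template.

    ``signal`` is a ``n_species × T`` stream; each window of ``N_T``
    consecutive samples is vectorized species-major (matching the template's
    layout) and correlated with the template.  One score per window start, at
    the given stride.  Zero-variance windows score 0 (counted in the log).
    """
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    template = np.asarray(template, dtype=float).ravel()
    n = signal.shape[0]
    if template.size % n:
        raise ValueError("template length not divisible by stream species count")
    nt = template.size // n
    T = signal.shape[1]
    if T < nt:
        raise ValueError("stream shorter than the template window")
    if stride < 1:
        raise ValueError("stride must be >= 1")

    tc = template - template.mean()
    t_norm = np.linalg.norm(tc)
    if t_norm == 0:
        raise ValueError("template has zero variance")

    starts = np.arange(0, T - nt + 1, stride)
    scores = np.zeros(starts.size)
    n_flat = 0
    for k, s in enumerate(starts):
        w = signal[:, s:s + nt].ravel()
        wc = w - w.mean()
        w_norm = np.linalg.norm(wc)
        if w_norm == 0:
            n_flat += 1
            continue
        scores[k] = float(np.dot(wc, tc) / (w_norm * t_norm))
    if n_flat:
        logger.info("correlation_score: %d zero-variance window(s) scored 0",
                    n_flat)
    return scores


def _rising_edges(scores: np.ndarray, threshold: float) -> np.ndarray:
    above = scores >= threshold
    edges = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    return edges


def detect_onsets(scores: np.ndarray, threshold: float,
                  match_window: int = 5) -> DetectionResult:
    """Label rising-edge threshold crossings of the score trace as onsets."""
    scores = np.asarray(scores, dtype=float)
    return DetectionResult(scores, threshold, _rising_edges(scores, threshold),
                           match_window=match_window)


def roc_curve(
    scores: np.ndarray,
    true_onsets: np.ndarray,
    thresholds: np.ndarray | None = None,
    match_window: int = 5,
) -> np.ndarray:
    """Receiver operating characteristic over correlation thresholds.

    At each threshold, detection events are rising-edge crossings (so one
    sustained excursion counts once); a true onset counts as detected (TP)
    if a crossing lies within ``±match_window`` samples of it or if the
    score at the onset itself is above threshold (the onset sits inside a
    suprathreshold excursion).  Each crossing matched to no onset is a false
    positive.  Eligible negatives are the score indices farther than
    ``match_window`` from every true onset.  Returns rows
    ``(threshold, FPR, TPR)`` sorted by descending threshold (so FPR is
    nondecreasing along the curve).
    """
    scores = np.asarray(scores, dtype=float)
    true_onsets = np.asarray(true_onsets, dtype=int)
    if true_onsets.size == 0:
        raise ValueError("at least one true onset is required")
    if thresholds is None:
        thresholds = np.linspace(-1.0, 1.0, 201)
    thresholds = np.sort(np.asarray(thresholds, dtype=float))[::-1]

    near_onset = np.zeros(scores.size, dtype=bool)
    for onset in true_onsets:
        lo = max(0, onset - match_window)
        near_onset[lo:onset + match_window + 1] = True
    n_neg = int((~near_onset).sum())

    rows = np.empty((thresholds.size, 3))
    for i, thr in enumerate(thresholds):
        det = _rising_edges(scores, thr)
        tp = sum(
            bool(det.size and np.min(np.abs(det - onset)) <= match_window)
            or bool(scores[min(onset, scores.size - 1)] >= thr)
            for onset in true_onsets
        )
        fp = int(np.sum(~near_onset[det])) if det.size else 0
        tpr = tp / true_onsets.size
        fpr = fp / n_neg if n_neg else 0.0
        rows[i] = (thr, fpr, tpr)
    return rows


def roc_auc(curve: np.ndarray) -> float:
    """Trapezoidal area under a ``(threshold, FPR, TPR)`` ROC curve,
    anchored at (0,0) and (1,1)."""
    fpr = np.concatenate(([0.0], curve[:, 1], [1.0]))
    tpr = np.concatenate(([0.0], curve[:, 2], [1.0]))
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(tpr[order], fpr[order]))


# -- dissimilarities and clustering -----------------------------------------

@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise distances among experiment rows."""

    d: np.ndarray
    measure: str = "raw"
    gamma: float | None = None
    row_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.ndim != 2 or self.d.shape[0] != self.d.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        np.fill_diagonal(self.d, 0.0)
        self.d = np.clip(self.d, 0.0, None)
        if not self.row_labels:
            self.row_labels = [f"row{i}" for i in range(self.d.shape[0])]

    @property
    def n(self) -> int:
        return self.d.shape[0]


def _row_corr_dist(A: np.ndarray) -> np.ndarray:
    """1 − Pearson correlation between all row pairs.

    Zero-variance rows are assigned distance 1 to every other row (their
    correlation is undefined); this is logged.
    """
    A = np.asarray(A, dtype=float)
    centred = A - A.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1)
    flat = norms == 0
    if flat.any():
        logger.info("correlation distance: %d zero-variance row(s) at "
                    "distance 1 to all others", int(flat.sum()))
    safe = np.where(flat, 1.0, norms)
    C = (centred / safe[:, None]) @ (centred / safe[:, None]).T
    D = 1.0 - np.clip(C, -1.0, 1.0)
    D[flat, :] = 1.0
    D[:, flat] = 1.0
    np.fill_diagonal(D, 0.0)
    return D


def dissimilarity_raw(X) -> DissimilarityMatrix:
    """Correlation distance d_xy = 1 − corr between raw rows.

    Being correlation-based, d_xy ignores per-row offsets and positive
    rescalings — differences in average measurement level or range drop out.
    """
    if isinstance(X, DataMatrix):
        values, labels = X.values, list(X.row_labels)
    else:
        values, labels = np.asarray(X, dtype=float), []
    return DissimilarityMatrix(_row_corr_dist(values), measure="raw",
                               row_labels=labels)


def dissimilarity_disentangled(
    dec: Decomposition,
    gamma: float = 0.5,
    row_labels: list[str] | None = None,
) -> DissimilarityMatrix:
    """Distance on the disentangled pair [L S] with weighting factor γ.

    d_φψ(i,j) = (1−γ)·(1 − corr(L_i, L_j)) + γ·(1 − corr(S_i, S_j)).

    γ = 0 compares common responses only; γ = 1 compares aberrant responses
    only.  Sparse rows that are entirely zero have no defined correlation:
    two all-zero sparse rows are treated as identical (sparse term 0), a zero
    row against a nonzero one as maximally different (sparse term 1).
    """
    if not 0 <= gamma <= 1:
        raise ValueError("gamma must lie in [0, 1]")
    if dec.L.shape != dec.S.shape:
        raise ValueError("L and S must be row-aligned")
    DL = _row_corr_dist(dec.L)

    S = dec.S
    zero_rows = ~np.any(S, axis=1)
    DS = _row_corr_dist(S)
    if zero_rows.any():
        both_zero = np.outer(zero_rows, zero_rows)
        one_zero = np.logical_xor.outer(zero_rows, zero_rows)
        DS[both_zero] = 0.0
        DS[one_zero] = 1.0
        np.fill_diagonal(DS, 0.0)

    D = (1.0 - gamma) * DL + gamma * DS
    return DissimilarityMatrix(D, measure="disentangled", gamma=gamma,
                               row_labels=row_labels or [])


def hierarchical_cluster(
    D: DissimilarityMatrix,
    k: int,
    linkage: str = "average",
) -> np.ndarray:
    """Agglomerative clustering of a dissimilarity matrix cut at k clusters."""
    if k < 1 or k > D.n:
        raise ValueError(f"k={k} must lie in [1, {D.n}]")
    if D.n == 1:
        return np.zeros(1, dtype=int)
    Z = hierarchy.linkage(squareform(D.d, checks=False), method=linkage)
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return labels - 1


def dendrogram_newick(D: DissimilarityMatrix, linkage: str = "average") -> str:
    """Newick text export of the agglomerative dendrogram."""
    Z = hierarchy.linkage(squareform(D.d, checks=False), method=linkage)
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0) if parent_height else 0.0
        if node.is_leaf():
            return f"{D.row_labels[node.id]}:{parent_height:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    left = walk(tree.left, tree.dist)
    right = walk(tree.right, tree.dist)
    return f"({left},{right});"
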