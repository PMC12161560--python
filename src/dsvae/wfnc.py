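"""Windowed functional network connectivity (wFNC).

The classical sliding-window representation of fMRI dynamics: for each
window, the Pearson correlation matrix between component timecourses. This
module computes per-window wFNC matrices, their upper-triangle
vectorization, a PCA reduction used as the linear baseline embedding, and
cluster-level averaging for connectivity maps.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from .io_windows import Window


@dataclass(frozen=True)
class WfncMatrix:
    """Symmetric unit-diagonal correlation matrix with window provenance."""

    matrix: np.ndarray
    subject_id: str = ""
    window_start: int = 0

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"wFNC matrix must be square, got {m.shape}")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("wFNC matrix must be symmetric")
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def compute_wfnc(window: Window) -> WfncMatrix:
    """Pearson correlation of every component pair across the window.

    A component with zero variance inside the window is an error (naming the
    component and the window) rather than a silent NaN, since NaNs would
    corrupt downstream PCA and distance computations.
    """
    data = window.data
    if window.width < 2:
        raise ValueError("need window width >= 2 to correlate")
    std = data.std(axis=1)
    zero = np.flatnonzero(std == 0)
    if zero.size:
        raise ValueError(
            f"component {int(zero[0])} has zero variance in window "
            f"(subject {window.subject_id!r}, start {window.start})"
        )
    m = np.corrcoef(data)
    m = np.clip((m + m.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(m, 1.0)
    return WfncMatrix(m, window.subject_id, window.start)


def vectorize_upper(m: WfncMatrix | np.ndarray) -> np.ndarray:
    """Row-major upper triangle (i < j), diagonal excluded; length
    N(N-1)/2. Invertible up to the unit diagonal."""
    a = m.matrix if isinstance(m, WfncMatrix) else np.asarray(m, dtype=float)
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    iu = np.triu_indices(a.shape[0], k=1)
    return a[iu]


def matrix_from_upper(v: np.ndarray, diagonal: float = 1.0) -> np.ndarray:
    """Reassemble a symmetric matrix from its upper-triangle vectorization."""
    v = np.asarray(v, dtype=float)
    L = v.shape[0]
    n = int(round((1 + np.sqrt(1 + 8 * L)) / 2))
    if n * (n - 1) // 2 != L:
        raise ValueError(f"length {L} is not a triangular number")
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    m[iu] = v
    m = m + m.T
    np.fill_diagonal(m, diagonal)
    return m


def wfnc_vectors(windows: Sequence[Window]) -> np.ndarray:
    """Stacked upper-triangle wFNC vectors, one row per window."""
    return np.stack([vectorize_upper(compute_wfnc(w)) for w in windows])


def pca_reduce(
    train_vectors: np.ndarray,
    val_vectors: np.ndarray,
    test_vectors: np.ndarray,
    dim: int,
    standardize: bool = False,
):
    """PCA fit on train+val only; the test set is projected with the fitted
    transform.

    Component signs follow the convention that the largest-magnitude loading
    of each component is positive. ``standardize`` optionally z-scores each
    input coordinate (train+val statistics) before the PCA; default is
    centering only, which PCA itself performs.

    Returns (train_reduced, val_reduced, test_reduced, pca).
    """
    train_vectors = np.asarray(train_vectors, dtype=float)
    val_vectors = np.asarray(val_vectors, dtype=float)
    test_vectors = np.asarray(test_vectors, dtype=float)
    fit = np.vstack([train_vectors, val_vectors])
    if dim > min(fit.shape):
        raise ValueError(
            f"dim={dim} exceeds min(n_samples={fit.shape[0]}, "
            f"n_features={fit.shape[1]}) of the fitting set"
        )
    mu = fit.mean(axis=0)
    sd = np.ones_like(mu)
    if standardize:
        sd = fit.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
    sets = [(v - mu) / sd for v in (train_vectors, val_vectors, test_vectors)]
    pca = PCA(n_components=dim, svd_solver="full")
    pca.fit((fit - mu) / sd)
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(
        pca.components_[np.arange(dim), np.argmax(np.abs(pca.components_), axis=1)]
    )
    flip[flip == 0] = 1.0
    pca.components_ = pca.components_ * flip[:, None]
    reduced = [s @ pca.components_.T for s in sets]
    return reduced[0], reduced[1], reduced[2], pca


def average_wfnc(windows: Sequence[Window]) -> WfncMatrix:
    """Elementwise mean of per-window wFNC matrices; symmetric with unit
    diagonal by construction."""
    if not windows:
        raise ValueError("cannot average an empty window list")
    mats = [compute_wfnc(w).matrix for w in windows]
    if len({m.shape for m in mats}) != 1:
        raise ValueError("windows must share the component count")
    return WfncMatrix(np.mean(mats, axis=0))
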