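"""Dynamic cross-correlation matrix and essential-dynamics PCA.

The cross-correlation coefficient between residues i and j is the normalized
covariance of their 3-D displacement vectors,

    X_ij = ⟨Δr_i · Δr_j⟩ / sqrt(⟨Δr_i²⟩ ⟨Δr_j²⟩),   Δr_i = r_i − ⟨r_i⟩,

computed over superposed frames: +1 is fully correlated motion, −1 exact
antiphase.  PCA diagonalizes the 3N×3N Cartesian covariance of the same
superposed Cα coordinates; projections of frames onto the leading
eigenvectors give the essential-dynamics subspace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import Selection, Trajectory
from .fluctuations import mean_structure_coords

__all__ = ["DCCMatrix", "PCAResult", "dccm", "threshold_dccm", "pca", "project"]


@dataclass
class DCCMatrix:
    """N×N residue cross-correlation matrix with residue labels."""

    values: np.ndarray
    residue_labels: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("DCCM must be square")
        if len(self.residue_labels) != v.shape[0]:
            raise ValueError("label count must match matrix dimension")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class PCAResult:
    """Cartesian covariance eigendecomposition over a Cα selection."""

    covariance: np.ndarray        # (3N, 3N)
    mean_coords: np.ndarray       # (N, 3)
    eigenvalues: np.ndarray       # nonincreasing
    eigenvectors: np.ndarray      # orthonormal columns, (3N, 3N)


def _displacements(
    traj: Trajectory,
    selection: Selection,
    window: tuple[int, int] | None,
    superpose: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """(mean (N,3), displacements (F,N,3)) over superposed window frames."""
    start, end = window if window is not None else (0, traj.n_frames)
    if end - start < 2:
        raise ValueError("at least 2 frames required")
    mean, fitted = mean_structure_coords(traj, selection, (start, end), superpose)
    return mean, fitted - mean


def dccm(
    traj: Trajectory,
    selection: Selection,
    window: tuple[int, int] | None = None,
    superpose: bool = True,
) -> DCCMatrix:
    """Dynamic cross-correlation matrix over a frame window.

    The numerator is the 3-D displacement dot product, not a per-component
    correlation.  Zero-variance residues get 0 off-diagonal and 1 on the
    diagonal, with a warning, instead of NaN.
    """
    _, dev = _displacements(traj, selection, window, superpose)
    # inner products of displacement vectors, averaged over frames
    inner = np.einsum("fid,fjd->ij", dev, dev) / dev.shape[0]
    var = np.diag(inner).copy()
    # rounding in the mean subtraction leaves ~1e-32 Å² on constant residues
    degenerate = var <= 1e-12 * max(float(var.max()), 1.0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance residue(s) in DCCM; "
            "rows/columns set to 0 off-diagonal",
            stacklevel=2,
        )
        var[degenerate] = 1.0  # placeholder; rows zeroed below
    norm = np.sqrt(np.outer(var, var))
    values = inner / norm
    values[degenerate, :] = 0.0
    values[:, degenerate] = 0.0
    np.fill_diagonal(values, 1.0)
    values = np.clip(values, -1.0, 1.0)
    return DCCMatrix(values=values, residue_labels=selection.labels(traj.topology))


def threshold_dccm(m: DCCMatrix, cutoff: float) -> DCCMatrix:
    """Zero entries with ``|X| < cutoff``; the diagonal is untouched."""
    if not (0.0 <= cutoff <= 1.0):
        raise ValueError("cutoff must be in [0, 1]")
    values = np.where(np.abs(m.values) < cutoff, 0.0, m.values)
    np.fill_diagonal(values, np.diag(m.values))
    return DCCMatrix(values=values, residue_labels=list(m.residue_labels))


def pca(
    traj: Trajectory,
    selection: Selection,
    window: tuple[int, int] | None = None,
    superpose: bool = True,
) -> PCAResult:
    """Essential-dynamics PCA of the Cα Cartesian covariance.

    The covariance is ``Z_ij = ⟨(x_i−⟨x_i⟩)(x_j−⟨x_j⟩)⟩`` over the 3N
    coordinates of the selection; eigenvalues are sorted descending with
    orthonormal eigenvector columns.
    """
    mean, dev = _displacements(traj, selection, window, superpose)
    flat = dev.reshape(dev.shape[0], -1)  # (F, 3N)
    covariance = flat.T @ flat / flat.shape[0]
    eigvals, eigvecs = np.linalg.eigh(covariance)
    order = np.argsort(eigvals)[::-1]
    return PCAResult(
        covariance=covariance,
        mean_coords=mean,
        eigenvalues=eigvals[order],
        eigenvectors=eigvecs[:, order],
    )


def project(
    traj: Trajectory,
    selection: Selection,
    pca_result: PCAResult,
    k: int = 2,
    window: tuple[int, int] | None = None,
    superpose: bool = True,
) -> np.ndarray:
    """Project frames onto the first ``k`` principal components.

    Frames are superposed onto the PCA mean structure, centered, and dotted
    with the leading eigenvectors; returns an (F, k) score array.
    """
    if k > pca_result.eigenvectors.shape[1]:
        raise ValueError("k exceeds the number of available modes")
    if pca_result.mean_coords.shape[0] != len(selection):
        raise ValueError("selection does not match PCA dimension")
    start, end = window if window is not None else (0, traj.n_frames)
    coords = selection.apply(traj.frames[start:end])
    if superpose:
        from .core import kabsch_superpose

        coords = np.stack(
            [kabsch_superpose(frame, pca_result.mean_coords)[0] for frame in coords]
        )
    flat = (coords - pca_result.mean_coords).reshape(coords.shape[0], -1)
    return flat @ pca_result.eigenvectors[:, :k]
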