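"""Cartesian principal component analysis, porcupine vectors, and 2D
free-energy landscapes of a conformational ensemble.

PCA diagonalises the 3n×3n covariance of the superposed Cartesian
coordinates; eigenvalues are in Å² and the variance of the projection
onto mode k equals eigenvalue k.  The landscape converts a 2D histogram
of projections into ΔG = -k_B T ln(P / P_max), so the global minimum is
exactly zero and empty bins are undefined (NaN).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .superpose_fluct import superpose_frames
from .traj_io import Ensemble, Selection, resolve_selection

KB_KCAL = 0.0019872041  # Boltzmann constant, kcal/(mol*K)

__all__ = ["PCAModel", "cartesian_pca", "porcupine_vectors", "free_energy_surface", "KB_KCAL"]


@dataclass
class PCAModel:
    mean_structure: np.ndarray  # (N, 3), Å
    eigenvectors: np.ndarray  # (modes, 3N), orthonormal rows
    eigenvalues: np.ndarray  # (modes,), Å², descending
    projections: np.ndarray  # (frames, modes), centered
    atom_indices: np.ndarray  # selection used, into the source ensemble

    def __post_init__(self) -> None:
        if np.any(self.eigenvalues < -1e-10):
            raise ValueError("negative eigenvalue")
        gram = self.eigenvectors @ self.eigenvectors.T
        if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8):
            raise ValueError("eigenvectors not orthonormal")

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.size

    def explained_variance_ratio(self) -> np.ndarray:
        tot = self.eigenvalues.sum()
        return self.eigenvalues / tot if tot > 0 else np.zeros_like(self.eigenvalues)


def cartesian_pca(
    ensemble: Ensemble,
    selection: Selection | None = None,
    n_modes: int | None = None,
) -> PCAModel:
    """PCA of superposed Cartesian coordinates.

    Frames are superposed onto the mean structure (align to frame 0,
    average, re-align to the mean), then the centered coordinate matrix
    is decomposed by SVD; eigenvalue k is the variance along mode k.
    """
    if ensemble.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    idx = resolve_selection(ensemble, selection)
    sub = ensemble.coordinates[:, idx, :]
    sub = superpose_frames(sub, sub[0])
    mean = sub.mean(axis=0)
    sub = superpose_frames(sub, mean)
    mean = sub.mean(axis=0)
    F = sub.shape[0]
    X = (sub - mean).reshape(F, -1)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    eigvals = s**2 / F
    if n_modes is not None:
        eigvals = eigvals[:n_modes]
        Vt = Vt[:n_modes]
        U = U[:, :n_modes]
        s = s[:n_modes]
    projections = U * s
    return PCAModel(
        mean_structure=mean,
        eigenvectors=Vt,
        eigenvalues=eigvals,
        projections=projections,
        atom_indices=idx,
    )


def porcupine_vectors(model: PCAModel, mode: int = 0, scale: float = 1.0) -> np.ndarray:
    """Per-atom displacement vectors of one PCA mode, anchored at the mean
    structure: rows of ``(N, 3)`` equal to scale × eigenvector components.
    Exported alongside the mean structure for porcupine-style rendering."""
    if not (0 <= mode < model.n_modes):
        raise IndexError(f"mode {mode} out of range (model has {model.n_modes})")
    return scale * model.eigenvectors[mode].reshape(-1, 3)


def free_energy_surface(
    projections: np.ndarray,
    bins: int = 60,
    temperature: float = 300.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2D free-energy landscape from projections onto two modes.

    Returns ``(dG, x_edges, y_edges)`` with ΔG(bin) = -k_B T ln(P/P_max)
    in kcal/mol; empty bins are NaN and the minimum of the surface is 0.
    """
    proj = np.asarray(projections, dtype=np.float64)
    if proj.ndim != 2 or proj.shape[1] != 2:
        raise ValueError("projections must be (frames, 2)")
    if proj.shape[0] < 1:
        raise ValueError("need at least one frame")
    if np.isscalar(bins) and bins < 2:
        raise ValueError("need at least 2 bins per axis")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    H, xe, ye = np.histogram2d(proj[:, 0], proj[:, 1], bins=bins)
    P = H / H.sum()
    pmax = P.max()
    with np.errstate(divide="ignore"):
        dG = -KB_KCAL * temperature * np.log(P / pmax)
    dG[P == 0] = np.nan
    return dG, xe, ye
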