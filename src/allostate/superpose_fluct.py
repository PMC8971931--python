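"""Rigid-body superposition (Kabsch) and RMSD/RMSF descriptors.

The Kabsch algorithm returns the least-squares optimal *proper* rotation:
the reflection branch of the SVD is sign-corrected, so improper rotations
are never produced even for near-planar inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traj_io import Ensemble, Selection, resolve_selection

__all__ = [
    "SuperpositionResult",
    "kabsch_superpose",
    "superpose_frames",
    "rmsd_series",
    "rmsf_per_residue",
]


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # 3-vector, Å
    rmsd: float  # Å

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _check_cloud(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"{name} must be (n, 3)")
    if x.shape[0] < 3:
        raise ValueError("superposition needs at least 3 particles")
    centered = x - x.mean(axis=0)
    # collinear clouds leave a free rotation about the line
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 2:
        raise ValueError(f"{name} is degenerate (collinear points)")
    return x


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Optimal rigid-body fit of ``mobile`` onto ``reference``.

    Returns rotation R and translation t minimising
    ``sum_i w_i |R x_i + t - y_i|^2``, with the RMSD evaluated after the fit.
    """
    mobile = _check_cloud(mobile, "mobile")
    reference = _check_cloud(reference, "reference")
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have equal particle counts")
    if weights is None:
        w = np.full(mobile.shape[0], 1.0 / mobile.shape[0])
    else:
        w = np.asarray(weights, dtype=np.float64)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
        w = w / w.sum()
    mu_m = w @ mobile
    mu_r = w @ reference
    H = (mobile - mu_m).T @ ((reference - mu_r) * w[:, None])
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_r - R @ mu_m
    fitted = mobile @ R.T + t
    rmsd = float(np.sqrt(np.sum(w * np.sum((fitted - reference) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def superpose_frames(
    coords: np.ndarray, reference: np.ndarray, fit_indices: np.ndarray | None = None
) -> np.ndarray:
    """Batched Kabsch: superpose every frame of ``coords`` (F, N, 3) onto
    ``reference`` (N, 3), fitting on ``fit_indices`` (default all atoms).

    All frames are rotated/translated as rigid bodies; returns a new array.
    """
    coords = np.asarray(coords, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    idx = np.arange(coords.shape[1]) if fit_indices is None else fit_indices
    sub = coords[:, idx, :]
    ref = reference[idx]
    mu_m = sub.mean(axis=1, keepdims=True)  # (F,1,3)
    mu_r = ref.mean(axis=0)
    H = np.einsum("fni,nj->fij", sub - mu_m, ref - mu_r)
    U, _, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("fij,fjk->fik", np.swapaxes(Vt, 1, 2), np.swapaxes(U, 1, 2)))
    D = np.zeros_like(H)
    D[:, 0, 0] = 1.0
    D[:, 1, 1] = 1.0
    D[:, 2, 2] = np.sign(det)
    R = np.einsum("fij,fjk,fkl->fil", np.swapaxes(Vt, 1, 2), D, np.swapaxes(U, 1, 2))
    t = mu_r - np.einsum("fij,fj->fi", R, mu_m[:, 0, :])
    return np.einsum("fij,fnj->fni", R, coords) + t[:, None, :]


def rmsd_series(
    ensemble: Ensemble,
    reference_frame: int = 0,
    selection: Selection | None = None,
    fit: bool = True,
) -> np.ndarray:
    """Per-frame RMSD (Å) of the selected atoms versus a reference frame.

    With ``fit=True`` (default) every frame is Kabsch-superposed onto the
    reference before measuring; ``fit=False`` measures raw coordinate
    deviation, useful when frames are already aligned.
    """
    if not (0 <= reference_frame < ensemble.n_frames):
        raise IndexError(f"reference_frame {reference_frame} out of range")
    idx = resolve_selection(ensemble, selection)
    sub = ensemble.coordinates[:, idx, :]
    ref = sub[reference_frame]
    if fit:
        sub = superpose_frames(sub, ref)
    dev = sub - ref
    out = np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=1))
    out[reference_frame] = 0.0  # identical to itself by definition
    return out


def rmsf_per_residue(
    ensemble: Ensemble,
    selection: Selection | None = None,
    reference_mode: str = "mean",
) -> np.ndarray:
    """Per-residue RMSF (Å) of the selected atoms.

    Frames are superposed onto the reference structure, then
    ``RMSF_i = sqrt(mean_f |r_i(f) - r_ref,i|^2)`` where the reference
    position is the time mean (``reference_mode="mean"``, default) or the
    initial-frame position (``reference_mode="initial"``).  Residues with
    several selected atoms report the atom-averaged RMSF.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    if reference_mode not in ("mean", "initial"):
        raise ValueError("reference_mode must be 'mean' or 'initial'")
    idx = resolve_selection(ensemble, selection)
    sub = ensemble.coordinates[:, idx, :]
    if reference_mode == "mean":
        # iterate once: align to frame 0, take the mean, re-align to the mean
        sub = superpose_frames(sub, sub[0])
        mean = sub.mean(axis=0)
        sub = superpose_frames(sub, mean)
        ref = sub.mean(axis=0)
    else:
        sub = superpose_frames(sub, sub[0])
        ref = sub[0]
    msf = np.mean(np.sum((sub - ref) ** 2, axis=2), axis=0)  # per selected atom
    res_of_atom = ensemble.residue_index[idx]
    residues = np.unique(res_of_atom)
    out = np.empty(residues.size)
    for k, r in enumerate(residues):
        out[k] = np.sqrt(np.mean(msf[res_of_atom == r]))
    return out
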