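"""Dynamic cross-correlation matrices (DCCM).

The correlation between residues i and j is the normalized equal-time
scalar covariance of their Cα displacement vectors,

    C_ij = <Δr_i · Δr_j> / sqrt(<|Δr_i|²> <|Δr_j|²>),

with Δr measured from the time-mean structure after rigid-body
superposition onto that mean (align to frame 0, compute the mean,
re-align to the mean — iterated once).  C is symmetric with unit
diagonal and |C| ≤ 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .superpose_fluct import superpose_frames
from .traj_io import Ensemble, Selection, resolve_selection

__all__ = [
    "CorrelationMatrix",
    "cross_correlation_matrix",
    "mask_weak_correlations",
    "analytic_dccm_from_covariance",
]

_ZERO_FLUCT_TOL = 1e-12


@dataclass
class CorrelationMatrix:
    """Symmetric n×n matrix of residue cross-correlations in [-1, 1].

    Rows/columns of residues with zero fluctuation are NaN and listed in
    :attr:`undefined_residues`.
    """

    values: np.ndarray
    residue_ids: np.ndarray
    mask_threshold: float | None = None
    undefined_residues: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("correlation matrix must be square")
        finite = np.isfinite(self.values)
        if not np.allclose(
            np.where(finite, self.values, 0.0),
            np.where(finite.T, self.values.T, 0.0),
            atol=1e-10,
        ):
            raise ValueError("correlation matrix must be symmetric")
        if finite.any() and np.max(np.abs(self.values[finite])) > 1 + 1e-10:
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]


def cross_correlation_matrix(
    ensemble: Ensemble, selection: Selection | None = None
) -> CorrelationMatrix:
    """DCCM of an ensemble over one selected particle per residue (Cα)."""
    if ensemble.n_frames < 2:
        raise ValueError("DCCM needs at least 2 frames")
    idx = resolve_selection(ensemble, selection)
    res = ensemble.residue_index[idx]
    uniq, counts = np.unique(res, return_counts=True)
    if np.any(counts != 1):
        bad = uniq[counts != 1].tolist()
        raise ValueError(
            f"DCCM requires exactly one selected particle per residue; "
            f"residues {bad} have multiple"
        )
    sub = ensemble.coordinates[:, idx, :]
    sub = superpose_frames(sub, sub[0])
    mean = sub.mean(axis=0)
    sub = superpose_frames(sub, mean)
    delta = sub - sub.mean(axis=0)
    c = np.einsum("fia,fja->ij", delta, delta) / delta.shape[0]
    var = np.diag(c).copy()
    dead = np.nonzero(var <= _ZERO_FLUCT_TOL * max(var.max(), 1.0))[0]
    safe_var = var.copy()
    safe_var[dead] = 1.0
    denom = np.sqrt(np.outer(safe_var, safe_var))
    C = c / denom
    C[dead, :] = np.nan
    C[:, dead] = np.nan
    np.fill_diagonal(C, np.where(np.isin(np.arange(C.shape[0]), dead), np.nan, 1.0))
    C = np.clip(C, -1.0, 1.0)  # NaN passes through
    if dead.size:
        warnings.warn(
            f"residues {uniq[dead].tolist()} have zero fluctuation; "
            "their correlations are undefined (NaN)",
            stacklevel=2,
        )
    return CorrelationMatrix(
        values=C, residue_ids=uniq, undefined_residues=uniq[dead].tolist()
    )


def mask_weak_correlations(
    C: CorrelationMatrix, threshold: float = 0.3
) -> CorrelationMatrix:
    """Zero out entries with |C| < threshold (boundary inclusive keep);
    the diagonal is untouched.  Mirrors the display convention of DCCM
    heat maps where weak correlations are blanked."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("mask threshold must lie in [0, 1]")
    vals = C.values.copy()
    weak = np.abs(vals) < threshold
    np.fill_diagonal(weak, False)
    vals[weak] = 0.0
    return CorrelationMatrix(
        values=vals,
        residue_ids=C.residue_ids,
        mask_threshold=threshold,
        undefined_residues=list(C.undefined_residues),
    )


def analytic_dccm_from_covariance(covariance: np.ndarray) -> CorrelationMatrix:
    """Exact DCCM from a 3n×3n positional covariance:
    C_ij = tr(Σ_ij) / sqrt(tr(Σ_ii) tr(Σ_jj)) over the 3×3 blocks."""
    cov = np.asarray(covariance, dtype=np.float64)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1] or cov.shape[0] % 3:
        raise ValueError("covariance must be square with size divisible by 3")
    if not np.allclose(cov, cov.T, atol=1e-8 * max(1.0, np.abs(cov).max())):
        raise ValueError("covariance must be symmetric")
    n = cov.shape[0] // 3
    blocks = cov.reshape(n, 3, n, 3)
    traces = np.einsum("iaja->ij", blocks)
    var = np.diag(traces).copy()
    dead = np.nonzero(var <= _ZERO_FLUCT_TOL * max(var.max(), 1.0))[0]
    safe = var.copy()
    safe[dead] = 1.0
    C = traces / np.sqrt(np.outer(safe, safe))
    C[dead, :] = np.nan
    C[:, dead] = np.nan
    np.fill_diagonal(C, np.where(np.isin(np.arange(n), dead), np.nan, 1.0))
    C = np.clip(C, -1.0, 1.0)  # NaN passes through
    return CorrelationMatrix(
        values=C, residue_ids=np.arange(n), undefined_residues=dead.tolist()
    )
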