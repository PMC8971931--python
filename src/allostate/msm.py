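"""Markov state models: microstate clustering, transition-matrix
estimation, implied timescales, Chapman–Kolmogorov validation, PCCA+
macrostate coarse-graining, and representative-conformation selection.

Estimation is reversible by default: transition counts are symmetrized,
(C + Cᵀ)/2, before row normalization, which enforces detailed balance
exactly (a deterministic approximation to the reversible maximum-
likelihood estimator, adequate for the sample sizes this package
targets).  States without observed transitions are trimmed to the
largest connected set before estimation.

Macrostates come from PCCA+ (Perron cluster cluster analysis): the
leading right eigenvectors of the reversible transition matrix span a
simplex whose vertices are the metastable sets; memberships are the
barycentric coordinates from the inner-simplex vertex search.

The representative conformation of a macrostate maximises the summed
structural similarity  S_ij = exp(-d_ij / d_scale)  over the frame pool,
where d_ij is the pairwise Kabsch RMSD and d_scale the standard
deviation of all pairwise RMSDs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components

from .superpose_fluct import superpose_frames

logger = logging.getLogger(__name__)

__all__ = [
    "DiscreteTrajectory",
    "MarkovModel",
    "RepresentativeSelection",
    "kmeans_microstates",
    "count_matrix",
    "transition_matrix",
    "estimate_msm",
    "implied_timescales",
    "ck_test",
    "pcca_macrostates",
    "extract_macrostate_frames",
    "representative_frame",
]


@dataclass
class DiscreteTrajectory:
    """Per-frame microstate indices for one trajectory."""

    states: np.ndarray
    frame_stride_time: float | None = None  # ns per frame

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.intp)
        if self.states.ndim != 1 or self.states.size < 1:
            raise ValueError("discrete trajectory must be a non-empty 1D sequence")
        if self.states.min() < 0:
            raise ValueError("negative state index")

    def __len__(self) -> int:
        return self.states.size


@dataclass
class MarkovModel:
    counts: np.ndarray  # k×k raw (unsymmetrized) counts on the active set
    transition_matrix: np.ndarray  # k×k row-stochastic
    lag: int  # frames
    stationary: np.ndarray  # π, sums to 1
    active_states: np.ndarray  # original microstate labels of rows
    reversible: bool = True
    memberships: np.ndarray | None = None  # k×m PCCA+ memberships
    macrostate_of: np.ndarray | None = None  # crisp argmax assignment

    def __post_init__(self) -> None:
        T = self.transition_matrix
        if not np.allclose(T.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(T < -1e-12):
            raise ValueError("negative transition probability")
        if not np.allclose(self.stationary @ T, self.stationary, atol=1e-8):
            raise ValueError("stationary vector is not a fixed point")

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    def eigenvalues(self) -> np.ndarray:
        """Real spectrum (descending).  For reversible models uses the
        symmetric similarity transform, guaranteeing real eigenvalues."""
        if self.reversible:
            d = np.sqrt(self.stationary)
            sym = d[:, None] * self.transition_matrix / d[None, :]
            vals = np.linalg.eigvalsh((sym + sym.T) / 2)
            return vals[::-1]
        vals = np.linalg.eigvals(self.transition_matrix)
        return np.sort(vals.real)[::-1]

    def timescales(self, n: int | None = None) -> np.ndarray:
        """Implied timescales t_i = -lag / ln λ_i (λ₁ = 1 excluded), in
        frames; non-positive eigenvalues give NaN."""
        lam = self.eigenvalues()[1:]
        if n is not None:
            lam = lam[:n]
        out = np.full(lam.shape, np.nan)
        ok = lam > 0
        with np.errstate(divide="ignore"):
            out[ok] = -self.lag / np.log(lam[ok])
        return out


@dataclass
class RepresentativeSelection:
    macrostate: int
    frame: int  # index into the pool
    scores: np.ndarray  # summed similarity per pool frame
    similarity: np.ndarray  # full S_ij matrix
    d_scale: float  # Å
    degenerate: bool = False


# --- microstates ----------------------------------------------------------


def kmeans_microstates(
    projections: np.ndarray,
    k: int = 100,
    max_iter: int = 100,
    seed: int = 0,
) -> tuple[DiscreteTrajectory, np.ndarray]:
    """k-means microstate clustering of (frames × features) projections
    with k-means++ seeding under a fixed seed."""
    from sklearn.cluster import KMeans

    X = np.asarray(projections, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    n_distinct = np.unique(X, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds {n_distinct} distinct points")
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=1, max_iter=max_iter, random_state=seed
    ).fit(X)
    return DiscreteTrajectory(states=km.labels_), km.cluster_centers_


# --- estimation -----------------------------------------------------------


def count_matrix(
    dtrajs: "list[DiscreteTrajectory] | DiscreteTrajectory", lag: int
) -> np.ndarray:
    """Sliding-window transition counts at the given lag (frames).  Counts
    never cross trajectory boundaries."""
    if isinstance(dtrajs, DiscreteTrajectory):
        dtrajs = [dtrajs]
    if lag < 1:
        raise ValueError("lag must be >= 1")
    n_states = 1 + max(int(d.states.max()) for d in dtrajs)
    C = np.zeros((n_states, n_states), dtype=np.float64)
    any_counts = False
    for d in dtrajs:
        s = d.states
        if s.size <= lag:
            continue
        any_counts = True
        np.add.at(C, (s[:-lag], s[lag:]), 1.0)
    if not any_counts:
        raise ValueError(f"lag {lag} leaves no transition pairs in any trajectory")
    return C


def _largest_connected(C: np.ndarray) -> np.ndarray:
    sym = ((C + C.T) > 0).astype(np.int8)
    n_comp, labels = connected_components(sym, directed=False)
    if n_comp == 1:
        return np.arange(C.shape[0])
    # weight components by total counts, keep the heaviest
    best = max(range(n_comp), key=lambda c: C[np.ix_(labels == c, labels == c)].sum())
    return np.nonzero(labels == best)[0]


def transition_matrix(
    counts: np.ndarray, reversible: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Estimate T and the stationary distribution π from counts.

    Reversible mode symmetrizes counts, (C + Cᵀ)/2, then row-normalizes;
    detailed balance π_i T_ij = π_j T_ji then holds by construction with
    π proportional to the symmetrized row sums.  Returns
    ``(T, pi, active_states)`` after trimming to the largest connected
    set (reported via logging when states are dropped).
    """
    C = np.asarray(counts, dtype=np.float64)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("counts must be square")
    if np.any(C < 0):
        raise ValueError("negative counts")
    active = _largest_connected(C)
    rows = C[np.ix_(active, active)]
    if rows.sum() == 0:
        raise ValueError("no transitions in the connected set")
    if active.size < C.shape[0]:
        logger.info(
            "trimmed %d disconnected states; %d active remain",
            C.shape[0] - active.size,
            active.size,
        )
    if reversible:
        S = (rows + rows.T) / 2.0
        row_sums = S.sum(axis=1)
        T = S / row_sums[:, None]
        pi = row_sums / row_sums.sum()
    else:
        row_sums = rows.sum(axis=1)
        if np.any(row_sums == 0):
            raise ValueError("state with no outgoing counts in connected set")
        T = rows / row_sums[:, None]
        vals, vecs = np.linalg.eig(T.T)
        lead = np.argmax(vals.real)
        pi = np.abs(vecs[:, lead].real)
        pi = pi / pi.sum()
    return T, pi, active


def estimate_msm(
    dtrajs: "list[DiscreteTrajectory] | DiscreteTrajectory",
    lag: int,
    reversible: bool = True,
) -> MarkovModel:
    """Count, trim, and estimate a Markov model at the given lag."""
    C = count_matrix(dtrajs, lag)
    T, pi, active = transition_matrix(C, reversible=reversible)
    return MarkovModel(
        counts=C[np.ix_(active, active)],
        transition_matrix=T,
        lag=lag,
        stationary=pi,
        active_states=active,
        reversible=reversible,
    )


def implied_timescales(
    dtrajs: "list[DiscreteTrajectory] | DiscreteTrajectory",
    lags: "list[int]",
    n_timescales: int | None = None,
    reversible: bool = True,
) -> dict[int, np.ndarray]:
    """Implied-timescale curves t_i(τ) = -τ / ln λ_i(τ) across lags, in
    frames.  Lag-independent curves indicate Markovian behaviour."""
    out: dict[int, np.ndarray] = {}
    for lag in lags:
        if lag < 1:
            raise ValueError("lags must be >= 1")
        model = estimate_msm(dtrajs, lag, reversible=reversible)
        out[lag] = model.timescales(n_timescales)
    return out


# --- PCCA+ ----------------------------------------------------------------


def _right_eigenvectors(model: MarkovModel, n: int) -> np.ndarray:
    d = np.sqrt(model.stationary)
    sym = d[:, None] * model.transition_matrix / d[None, :]
    vals, vecs = np.linalg.eigh((sym + sym.T) / 2)
    order = np.argsort(vals)[::-1][:n]
    # right eigenvectors of T: ψ = D^{-1/2} v
    psi = vecs[:, order] / d[:, None]
    # normalize sign/scale of the stationary eigenvector to 1
    psi[:, 0] = 1.0
    return psi


def _inner_simplex_vertices(X: np.ndarray, m: int) -> np.ndarray:
    """Indices of m rows of X spanning the largest simplex (classic PCCA+
    vertex search by successive orthogonalization)."""
    work = X.copy()
    vertices = np.empty(m, dtype=np.intp)
    # first vertex: farthest row from the centroid
    norms = np.linalg.norm(work - work.mean(axis=0), axis=1)
    vertices[0] = int(np.argmax(norms))
    work = work - work[vertices[0]]
    for i in range(1, m):
        norms = np.linalg.norm(work, axis=1)
        vertices[i] = int(np.argmax(norms))
        v = work[vertices[i]]
        nv = norms[vertices[i]]
        if nv == 0:
            raise ValueError("degenerate eigenvector geometry in PCCA+")
        v = v / nv
        work = work - np.outer(work @ v, v)
    return vertices


def pcca_macrostates(model: MarkovModel, n_macro: int) -> tuple[np.ndarray, np.ndarray]:
    """PCCA+ fuzzy memberships and crisp assignments.

    Returns ``(memberships, assignment)``: a (k × m) row-stochastic
    membership matrix and the argmax macrostate per microstate.  Requires
    a reversible model; n_macro must not exceed the number of states.
    """
    if not model.reversible:
        raise ValueError("PCCA+ requires a reversible transition matrix")
    k = model.n_states
    if not (1 < n_macro <= k):
        raise ValueError(f"n_macro must be in (1, {k}]")
    X = _right_eigenvectors(model, n_macro)
    vertices = _inner_simplex_vertices(X, n_macro)
    A = np.linalg.inv(X[vertices])
    chi = X @ A
    chi = np.clip(chi, 0.0, None)
    chi = chi / chi.sum(axis=1, keepdims=True)
    assignment = np.argmax(chi, axis=1)
    return chi, assignment


def macrostate_populations(
    model: MarkovModel, memberships: np.ndarray, assignment: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Crisp (sum of π over members) and membership-weighted macrostate
    populations."""
    m = memberships.shape[1]
    crisp = np.array(
        [model.stationary[assignment == a].sum() for a in range(m)]
    )
    fuzzy = memberships.T @ model.stationary
    return crisp, fuzzy


# --- Chapman–Kolmogorov ---------------------------------------------------


def _project_to_macro(
    T: np.ndarray, pi: np.ndarray, sets: "list[np.ndarray]"
) -> np.ndarray:
    m = len(sets)
    P = np.zeros((m, m))
    for a, A in enumerate(sets):
        wa = pi[A]
        if wa.sum() == 0:
            continue
        for b, B in enumerate(sets):
            P[a, b] = wa @ T[np.ix_(A, B)].sum(axis=1) / wa.sum()
    return P


def ck_test(
    dtrajs: "list[DiscreteTrajectory] | DiscreteTrajectory",
    lag: int,
    n_macrostates: int,
    factors: "tuple[int, ...]" = (2, 3, 4),
) -> dict[int, dict[str, np.ndarray | float]]:
    """Chapman–Kolmogorov test on macrostates.

    Compares the model estimated at ``lag`` propagated f steps,
    T(lag)^f, against a model re-estimated at f·lag, both projected onto
    the PCCA+ macrostate sets of the base model.  Returns per factor the
    predicted and estimated macrostate transition matrices and their
    maximum absolute deviation.
    """
    if isinstance(dtrajs, DiscreteTrajectory):
        dtrajs = [dtrajs]
    base = estimate_msm(dtrajs, lag)
    if n_macrostates < base.n_states:
        _, assignment = pcca_macrostates(base, n_macrostates)
    else:
        assignment = np.arange(base.n_states)
    sets_active = [np.nonzero(assignment == a)[0] for a in range(assignment.max() + 1)]
    # map microstate labels to base-model active rows
    label_of = {s: i for i, s in enumerate(base.active_states)}
    out: dict[int, dict[str, np.ndarray | float]] = {}
    for f in factors:
        if f < 1:
            raise ValueError("factors must be >= 1")
        pred = _project_to_macro(
            np.linalg.matrix_power(base.transition_matrix, f),
            base.stationary,
            sets_active,
        )
        est_model = estimate_msm(dtrajs, lag * f)
        # align the re-estimated model onto the base active set
        k = base.n_states
        T_est = np.eye(k)
        row_of = {s: i for i, s in enumerate(est_model.active_states)}
        for s_i in base.active_states:
            for s_j in base.active_states:
                if s_i in row_of and s_j in row_of:
                    T_est[label_of[s_i], label_of[s_j]] = est_model.transition_matrix[
                        row_of[s_i], row_of[s_j]
                    ]
        T_est = T_est / T_est.sum(axis=1, keepdims=True)
        est = _project_to_macro(T_est, base.stationary, sets_active)
        out[f] = {
            "predicted": pred,
            "estimated": est,
            "max_deviation": float(np.max(np.abs(pred - est))),
        }
    return out


# --- representatives ------------------------------------------------------


def extract_macrostate_frames(
    dtrajs: "list[DiscreteTrajectory] | DiscreteTrajectory",
    assignment: np.ndarray,
    macrostate: int,
    active_states: np.ndarray | None = None,
) -> list[tuple[int, np.ndarray]]:
    """Frame pool of one macrostate.

    Only trajectories with strictly more than 50% of their frames in the
    macrostate qualify; from each qualifying trajectory the frames
    assigned to the macrostate are pooled.  Returns
    ``[(trajectory index, frame indices), ...]``; an empty pool is
    flagged with a warning.
    """
    if isinstance(dtrajs, DiscreteTrajectory):
        dtrajs = [dtrajs]
    assignment = np.asarray(assignment)
    k = assignment.size
    macro_of_state = np.full(
        1 + max(int(d.states.max()) for d in dtrajs), -1, dtype=np.intp
    )
    states = np.arange(k) if active_states is None else np.asarray(active_states)
    macro_of_state[states] = assignment
    pools: list[tuple[int, np.ndarray]] = []
    for t, d in enumerate(dtrajs):
        macro = macro_of_state[d.states]
        frac = np.mean(macro == macrostate)
        if frac > 0.5:
            pools.append((t, np.nonzero(macro == macrostate)[0]))
    if not pools:
        warnings.warn(
            f"no trajectory has >50% of frames in macrostate {macrostate}",
            stacklevel=2,
        )
    return pools


def representative_frame(
    pool_coordinates: np.ndarray, macrostate: int = 0
) -> RepresentativeSelection:
    """Most representative conformation of a frame pool.

    Computes the pairwise Kabsch RMSD matrix d over the pool, sets
    d_scale to the standard deviation of all pairwise values, scores
    each frame by Σ_{j≠i} exp(-d_ij / d_scale), and returns the frame
    with the maximal summed similarity.  A pool whose frames are all
    identical (d_scale = 0) degenerately returns the first frame.
    """
    coords = np.asarray(pool_coordinates, dtype=np.float64)
    if coords.ndim != 3 or coords.shape[0] < 1:
        raise ValueError("pool must be (frames, atoms, 3) with >= 1 frame")
    P = coords.shape[0]
    if P == 1:
        return RepresentativeSelection(
            macrostate=macrostate,
            frame=0,
            scores=np.array([1.0]),
            similarity=np.ones((1, 1)),
            d_scale=0.0,
            degenerate=True,
        )
    d = np.zeros((P, P))
    for i in range(P):
        fitted = superpose_frames(coords[i + 1 :], coords[i])
        dev = fitted - coords[i]
        d[i, i + 1 :] = np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=1))
    d = d + d.T
    iu = np.triu_indices(P, k=1)
    d_scale = float(np.std(d[iu]))
    if d_scale == 0.0:
        logger.info("degenerate pool: all pairwise RMSDs identical")
        return RepresentativeSelection(
            macrostate=macrostate,
            frame=0,
            scores=np.ones(P),
            similarity=np.ones((P, P)),
            d_scale=0.0,
            degenerate=True,
        )
    S = np.exp(-d / d_scale)
    scores = S.sum(axis=1) - 1.0  # exclude self-similarity
    best = int(np.argmax(scores))
    return RepresentativeSelection(
        macrostate=macrostate,
        frame=best,
        scores=scores,
        similarity=S,
        d_scale=d_scale,
    )
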