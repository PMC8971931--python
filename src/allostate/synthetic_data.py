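"""Synthetic ensembles, Markov chains, and energy tables with known
ground truth.

Three generators provide oracles for every downstream stage:

* **Elastic-network ensembles** — frames drawn i.i.d. from the Gaussian
  whose 3n×3n covariance is k_B·T times the pseudoinverse of the
  anisotropic-network Hessian built from harmonic springs.  The analytic
  covariance is returned alongside the samples, so correlation matrices,
  fluctuations, and PCA modes all have closed-form references.  Sampling
  is i.i.d. rather than Langevin time-stepping: the equal-time covariance
  (all that DCCM, networks, and PCA consume) is then exact by
  construction; time correlation for MSM testing comes from the discrete
  Markov-chain generator instead.

* **Discrete Markov chains** — state sequences from a known row-
  stochastic transition matrix with planted metastable blocks, the
  ground truth for MSM estimation, implied timescales, PCCA+, and the
  Chapman–Kolmogorov test.

* **Apo/holo pair-energy tables** — a Gaussian background of
  interaction-energy shifts with planted large-shift outlier pairs; the
  returned group labels are computed from the *realized* shift
  distribution by the same 1σ/3σ band rule the classifier applies, so
  recovery can be checked exactly.

Units: coordinates in Å, energies in kcal/mol, temperature in Kelvin,
k_B = 0.0019872041 kcal/(mol·K).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energy_coupling import EnergyTable, classify_shifts_by_sd
from .traj_io import Ensemble

KB_KCAL = 0.0019872041  # kcal/(mol*K)
NULL_MODE_RTOL = 1e-8  # eigenvalues below this fraction of the largest are null

__all__ = [
    "ElasticNetworkSpec",
    "MarkovChainSpec",
    "EnergyTableSpec",
    "enm_hessian",
    "enm_covariance",
    "enm_softest_mode",
    "generate_enm_ensemble",
    "generate_markov_trajectory",
    "generate_energy_tables",
    "two_domain_spec",
    "metastable_chain_spec",
    "lumped_chain_example",
    "KB_KCAL",
]


# --- elastic network ------------------------------------------------------


@dataclass
class ElasticNetworkSpec:
    """Bead-spring network defining a Gaussian conformational ensemble.

    ``spring_pairs`` lists (i, j, force constant in kcal/mol/Å²) with
    0 ≤ i < j < n; the spring graph must be connected.  ``domain_labels``
    records the planted community ground truth per bead.
    """

    n_residues: int
    positions0: np.ndarray  # (n, 3), Å
    spring_pairs: list[tuple[int, int, float]]
    temperature: float = 300.0
    domain_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions0 = np.asarray(self.positions0, dtype=np.float64)
        if self.positions0.shape != (self.n_residues, 3):
            raise ValueError("positions0 must be (n_residues, 3)")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        parent = list(range(self.n_residues))

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i, j, k in self.spring_pairs:
            if not (0 <= i < j < self.n_residues):
                raise ValueError(f"spring ({i},{j}) violates 0 <= i < j < n")
            if k <= 0:
                raise ValueError(f"spring ({i},{j}) has non-positive force constant")
            parent[find(i)] = find(j)
        roots = {find(a) for a in range(self.n_residues)}
        if len(roots) > 1:
            raise ValueError(
                f"spring graph is disconnected ({len(roots)} components); "
                "a disconnected network has more than six rigid-body null modes"
            )
        if self.domain_labels is None:
            self.domain_labels = np.zeros(self.n_residues, dtype=np.intp)
        else:
            self.domain_labels = np.asarray(self.domain_labels, dtype=np.intp)
            if self.domain_labels.shape != (self.n_residues,):
                raise ValueError("domain_labels must have one entry per residue")


def enm_hessian(spec: ElasticNetworkSpec) -> np.ndarray:
    """3n×3n anisotropic-network Hessian: each spring (i, j, k)
    contributes k·(û ûᵀ) along the unit bond vector û."""
    n = spec.n_residues
    H = np.zeros((3 * n, 3 * n))
    for i, j, k in spec.spring_pairs:
        d = spec.positions0[j] - spec.positions0[i]
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ValueError(f"spring ({i},{j}) joins coincident beads")
        u = d / norm
        block = k * np.outer(u, u)
        sl_i, sl_j = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        H[sl_i, sl_i] += block
        H[sl_j, sl_j] += block
        H[sl_i, sl_j] -= block
        H[sl_j, sl_i] -= block
    return H


def _hessian_modes(spec: ElasticNetworkSpec) -> tuple[np.ndarray, np.ndarray]:
    H = enm_hessian(spec)
    vals, vecs = np.linalg.eigh(H)
    keep = vals > NULL_MODE_RTOL * vals.max()
    return vals[keep], vecs[:, keep]


def enm_covariance(spec: ElasticNetworkSpec) -> np.ndarray:
    """Analytic 3n×3n fluctuation covariance k_B·T·H⁺ with the rigid-body
    null space excluded by relative eigenvalue thresholding."""
    vals, vecs = _hessian_modes(spec)
    return KB_KCAL * spec.temperature * (vecs / vals) @ vecs.T


def enm_softest_mode(spec: ElasticNetworkSpec) -> np.ndarray:
    """Unit 3n-vector of the lowest non-null Hessian mode (the dominant
    PCA direction of the ensemble)."""
    vals, vecs = _hessian_modes(spec)
    return vecs[:, np.argmin(vals)]


def generate_enm_ensemble(
    spec: ElasticNetworkSpec, n_frames: int, seed: int
) -> tuple[Ensemble, np.ndarray]:
    """Sample i.i.d. frames from the elastic-network Gaussian.

    Returns the ensemble (frames centered on the reference coordinates)
    and the analytic covariance used for sampling.  Bit-reproducible for
    a fixed seed.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    vals, vecs = _hessian_modes(spec)
    sd = np.sqrt(KB_KCAL * spec.temperature / vals)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_frames, vals.size))
    disp = (z * sd) @ vecs.T
    coords = spec.positions0[None, :, :] + disp.reshape(n_frames, spec.n_residues, 3)
    cov = KB_KCAL * spec.temperature * (vecs / vals) @ vecs.T
    ens = Ensemble(
        coordinates=coords,
        residue_index=np.arange(spec.n_residues),
        atom_names=["CA"] * spec.n_residues,
    )
    return ens, cov


def two_domain_spec(
    n_per_domain: int = 10,
    k_intra: float = 10.0,
    k_bridge: float = 0.5,
    temperature: float = 300.0,
    separation: float = 10.0,
    radius: float = 3.2,
    spring_cutoff: float = 6.5,
    geometry_seed: int = 2024,
) -> ElasticNetworkSpec:
    """Two compact spring-dense domains joined by a single weak spring.

    Beads of each domain are placed pseudo-randomly in a ball of the
    given radius (with a minimum inter-bead spacing), the domains offset
    along x by ``separation``; all intra-domain pairs within
    ``spring_cutoff`` receive stiff springs and one inter-domain bead
    pair, pulled to the interface ~4 Å apart, carries the weak bridge.
    Downstream this yields a block-diagonal |C| and a contact network
    whose community structure matches ``domain_labels``.
    """
    rng = np.random.default_rng(geometry_seed)

    def blob(center: np.ndarray) -> np.ndarray:
        pts: list[np.ndarray] = []
        while len(pts) < n_per_domain:
            p = center + rng.uniform(-radius, radius, size=3)
            if np.linalg.norm(p - center) > radius:
                continue
            if pts and min(np.linalg.norm(p - q) for q in pts) < 2.4:
                continue
            pts.append(p)
        return np.array(pts)

    a = blob(np.zeros(3))
    b = blob(np.array([separation, 0.0, 0.0]))
    # pull one bead of each domain to the interface, ~4 Å apart
    bridge_a, bridge_b = n_per_domain // 2, n_per_domain // 2
    a[bridge_a] = np.array([separation / 2 - 2.0, 0.0, 0.0])
    b[bridge_b] = np.array([separation / 2 + 2.0, 0.0, 0.0])
    pos = np.vstack([a, b])
    n = 2 * n_per_domain
    springs: list[tuple[int, int, float]] = []
    for i in range(n):
        for j in range(i + 1, n):
            same = (i < n_per_domain) == (j < n_per_domain)
            if same and np.linalg.norm(pos[i] - pos[j]) <= spring_cutoff:
                springs.append((i, j, k_intra))
    springs.append((bridge_a, n_per_domain + bridge_b, k_bridge))
    labels = np.repeat([0, 1], n_per_domain)
    return ElasticNetworkSpec(
        n_residues=n,
        positions0=pos,
        spring_pairs=springs,
        temperature=temperature,
        domain_labels=labels,
    )


# --- discrete Markov chains -----------------------------------------------


@dataclass
class MarkovChainSpec:
    """A known row-stochastic chain with planted macrostate blocks."""

    transition_matrix: np.ndarray
    initial_state: int = 0
    block_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        T = np.asarray(self.transition_matrix, dtype=np.float64)
        if T.ndim != 2 or T.shape[0] != T.shape[1]:
            raise ValueError("transition matrix must be square")
        if np.any(T < 0):
            raise ValueError("transition probabilities must be >= 0")
        if not np.allclose(T.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1 (within 1e-12)")
        self.transition_matrix = T
        if not (0 <= self.initial_state < T.shape[0]):
            raise ValueError("initial_state out of range")
        if self.block_labels is None:
            self.block_labels = np.zeros(T.shape[0], dtype=np.intp)
        else:
            self.block_labels = np.asarray(self.block_labels, dtype=np.intp)
            if self.block_labels.shape != (T.shape[0],):
                raise ValueError("block_labels must have one entry per state")

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]


def generate_markov_trajectory(
    spec: MarkovChainSpec, n_steps: int, seed: int
) -> np.ndarray:
    """Sample a state sequence of length ``n_steps`` from the chain."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    cdf = np.cumsum(spec.transition_matrix, axis=1)
    cdf[:, -1] = 1.0  # guard against rounding
    rng = np.random.default_rng(seed)
    u = rng.random(n_steps - 1)
    seq = np.empty(n_steps, dtype=np.intp)
    seq[0] = spec.initial_state
    s = spec.initial_state
    for t in range(1, n_steps):
        s = int(np.searchsorted(cdf[s], u[t - 1], side="right"))
        seq[t] = s
    return seq


def metastable_chain_spec(
    n_blocks: int = 3,
    states_per_block: int = 2,
    p_intra: float = 0.98,
    p_inter: float = 0.02,
) -> MarkovChainSpec:
    """Planted-metastable chain: from any state the total probability of
    staying in its block is ``p_intra`` (split uniformly over the block),
    of leaving ``p_inter`` (split uniformly over the other states)."""
    k = n_blocks * states_per_block
    labels = np.repeat(np.arange(n_blocks), states_per_block)
    T = np.empty((k, k))
    for s in range(k):
        same = labels == labels[s]
        T[s, same] = p_intra / same.sum()
        T[s, ~same] = p_inter / (~same).sum()
    return MarkovChainSpec(transition_matrix=T, initial_state=0, block_labels=labels)


def lumped_chain_example() -> tuple[MarkovChainSpec, np.ndarray]:
    """A 3-state hidden chain whose projection onto 2 observed states is
    strongly non-Markovian (a constructed Chapman–Kolmogorov
    counterexample).  Returns the hidden chain and the per-state observed
    label (state 0 → 0, states 1, 2 → 1): the near-deterministic cycle
    through the hidden states gives the lumped state 1 a sharply
    non-geometric dwell time."""
    T = np.array(
        [
            [0.50, 0.50, 0.00],
            [0.02, 0.08, 0.90],
            [0.50, 0.00, 0.50],
        ]
    )
    lump = np.array([0, 1, 1], dtype=np.intp)
    return MarkovChainSpec(transition_matrix=T), lump


# --- energy tables --------------------------------------------------------


@dataclass
class EnergyTableSpec:
    """Gaussian background of apo→holo interaction-energy shifts with
    planted outlier pairs shifted by a prescribed number of SDs."""

    n_pairs: int
    background_mean: float = -1.0
    background_sd: float = 1.0
    planted_outliers: list[tuple[int, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 10:
            raise ValueError("need at least 10 pairs")
        if self.background_sd < 0:
            raise ValueError("background_sd must be >= 0")
        for idx, shift in self.planted_outliers:
            if not (0 <= idx < self.n_pairs):
                raise ValueError(f"planted pair index {idx} out of range")
            if not np.isfinite(shift):
                raise ValueError("planted shifts must be finite")


def generate_energy_tables(
    spec: EnergyTableSpec,
) -> tuple[EnergyTable, EnergyTable, np.ndarray]:
    """Apo/holo tables plus exact group labels.

    Apo energies are drawn from the background N(mean, sd²); holo adds
    N(0, sd²) noise per pair, plus shift·sd for planted pairs.  The
    returned labels are recomputed from the realized ΔE distribution by
    the 1σ/3σ band rule, so downstream classification can be compared
    exactly rather than approximately.
    """
    rng = np.random.default_rng(spec.seed)
    apo_e = rng.normal(spec.background_mean, spec.background_sd, size=spec.n_pairs)
    holo_e = apo_e + rng.normal(0.0, spec.background_sd, size=spec.n_pairs)
    for idx, shift in spec.planted_outliers:
        holo_e[idx] = apo_e[idx] + shift * spec.background_sd
    res_i = np.arange(spec.n_pairs)
    res_j = res_i + 3  # minimum sequence separation of the estimator
    zeros = np.zeros(spec.n_pairs)

    def table(e: np.ndarray, condition: str) -> EnergyTable:
        return EnergyTable(
            frame=pd.DataFrame(
                {
                    "res_i": res_i,
                    "res_j": res_j,
                    "e_eel": e,
                    "e_vdw": zeros,
                    "g_pol": zeros,
                    "g_sas": zeros,
                }
            ),
            condition=condition,
        )

    labels, _, _ = classify_shifts_by_sd(holo_e - apo_e)
    return table(apo_e, "apo"), table(holo_e, "holo"), labels
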