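"""Residue-pair interaction energies and the energy-coupling fraction.

The coupling statistic asks whether ligand binding at one site
(orthosteric) redistributes interaction energies at a distant site
(allosteric).  For every residue pair p in the site, the apo→holo shift
ΔE_p = E_holo,p − E_apo,p is classified by how far it sits from the mean
shift μ in units of the standard deviation σ of {ΔE_p}:

    group a (minor):     |ΔE_p − μ| ≤ σ
    group b (moderate):  σ < |ΔE_p − μ| ≤ 3σ
    group c (major):     |ΔE_p − μ| > 3σ

The energy coupling fraction is N_c / (N_b + N_c); a fraction strictly
above the threshold (0.25 by default) flags orthosteric–allosteric
coupling.

Pair energies can be supplied directly as tables (e.g. from an MM-GBSA
decomposition) or estimated from an ensemble with a simple nonbonded
model: Coulomb electrostatics with a uniform dielectric plus
Lennard-Jones with Lorentz–Berthelot combination, averaged over frames.
Polar-solvation (g_pol) and surface-area (g_sas) terms are accepted as
precomputed per-pair columns; the internal (bonded) energy between
distinct residues is zero by definition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .traj_io import Ensemble

COULOMB_KCAL = 332.0637  # kcal*Å/(mol*e^2)

ENERGY_COLUMNS = ["res_i", "res_j", "e_eel", "e_vdw", "g_pol", "g_sas"]

__all__ = [
    "PairEnergyTopology",
    "EnergyTable",
    "CouplingReport",
    "pairwise_interaction_energy",
    "classify_energy_shifts",
    "coupling_fraction",
    "export_coupling_scatter",
    "read_energy_table",
    "write_energy_table",
    "COULOMB_KCAL",
]


@dataclass
class PairEnergyTopology:
    """Per-particle nonbonded parameters for the toy pair-energy estimator."""

    charges: np.ndarray  # e
    sigma: np.ndarray  # Å
    epsilon: np.ndarray  # kcal/mol
    dielectric: float = 1.0

    def __post_init__(self) -> None:
        self.charges = np.asarray(self.charges, dtype=np.float64)
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        self.epsilon = np.asarray(self.epsilon, dtype=np.float64)
        if np.any(self.epsilon < 0):
            raise ValueError("epsilon must be >= 0")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be > 0")
        if self.dielectric <= 0:
            raise ValueError("dielectric must be > 0")


@dataclass
class EnergyTable:
    """Ensemble-averaged per-residue-pair interaction energies (kcal/mol)."""

    frame: pd.DataFrame  # columns ENERGY_COLUMNS (+ derived e_total)
    condition: str = "apo"

    def __post_init__(self) -> None:
        df = self.frame.copy()
        missing = [c for c in ENERGY_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"energy table missing columns {missing}")
        if np.any(df["res_i"] >= df["res_j"]):
            raise ValueError("pairs must satisfy res_i < res_j")
        df["e_total"] = df[["e_eel", "e_vdw", "g_pol", "g_sas"]].sum(axis=1)
        self.frame = df.reset_index(drop=True)

    @property
    def pairs(self) -> pd.DataFrame:
        return self.frame[["res_i", "res_j"]]

    def totals(self) -> np.ndarray:
        return self.frame["e_total"].to_numpy()


@dataclass
class CouplingReport:
    pairs: pd.DataFrame  # res_i, res_j, delta_e, group
    mean: float  # μ of ΔE
    sd: float  # σ of ΔE
    counts: dict[str, int] = field(default_factory=dict)
    fraction: float | None = None
    coupled: bool | None = None
    threshold: float | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        n = len(self.pairs)
        if sum(self.counts.get(g, 0) for g in "abc") != n:
            raise ValueError("group counts must partition the pair set")


def read_energy_table(path: str, condition: str = "apo") -> EnergyTable:
    df = pd.read_csv(path, sep=r"\s+")
    return EnergyTable(frame=df, condition=condition)


def write_energy_table(table: EnergyTable, path: str) -> None:
    table.frame[ENERGY_COLUMNS].to_csv(path, sep="\t", index=False)


def pairwise_interaction_energy(
    ensemble: Ensemble,
    topology: PairEnergyTopology,
    min_separation: int = 3,
    g_pol: "dict[tuple[int, int], float] | None" = None,
    g_sas: "dict[tuple[int, int], float] | None" = None,
    condition: str = "apo",
) -> EnergyTable:
    """Frame-averaged nonbonded pair energies for residue pairs separated
    by at least ``min_separation`` in sequence (|i−j| ≥ min_separation).

    E_eel = Σ_ab 332.0637 q_a q_b / (ε r_ab);
    E_vdw = Σ_ab 4 ε_ab [(σ_ab/r)¹² − (σ_ab/r)⁶], σ_ab = (σ_a+σ_b)/2,
    ε_ab = sqrt(ε_a ε_b).  g_pol/g_sas default to 0 when not supplied.
    """
    n_atoms = ensemble.n_particles
    for arr, name in (
        (topology.charges, "charges"),
        (topology.sigma, "sigma"),
        (topology.epsilon, "epsilon"),
    ):
        if arr.shape != (n_atoms,):
            raise ValueError(f"topology {name} must cover all {n_atoms} particles")
    n_res = ensemble.n_residues
    atoms = [ensemble.residue_atoms(r) for r in range(n_res)]
    rows = []
    for i in range(n_res):
        for j in range(i + 1, n_res):
            if j - i < min_separation:
                continue
            ai, aj = atoms[i], atoms[j]
            xi = ensemble.coordinates[:, ai, :]
            xj = ensemble.coordinates[:, aj, :]
            diff = xi[:, :, None, :] - xj[:, None, :, :]
            r = np.sqrt(np.einsum("fabx,fabx->fab", diff, diff))
            if np.any(r == 0):
                raise ValueError(
                    f"zero interatomic distance between residues {i} and {j}"
                )
            qq = np.outer(topology.charges[ai], topology.charges[aj])
            eel = COULOMB_KCAL * (qq / (topology.dielectric * r)).sum(axis=(1, 2))
            sig = 0.5 * (topology.sigma[ai][:, None] + topology.sigma[aj][None, :])
            eps = np.sqrt(
                np.outer(topology.epsilon[ai], topology.epsilon[aj])
            )
            sr6 = (sig / r) ** 6
            vdw = (4.0 * eps * (sr6**2 - sr6)).sum(axis=(1, 2))
            rows.append(
                {
                    "res_i": i,
                    "res_j": j,
                    "e_eel": float(eel.mean()),
                    "e_vdw": float(vdw.mean()),
                    "g_pol": float((g_pol or {}).get((i, j), 0.0)),
                    "g_sas": float((g_sas or {}).get((i, j), 0.0)),
                }
            )
    return EnergyTable(frame=pd.DataFrame(rows), condition=condition)


def classify_shifts_by_sd(delta: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Label shifts a/b/c by distance from the mean in SD units.

    The 1σ band is closed (a includes |ΔE−μ| = σ), the 3σ band is closed
    for b, and c lies strictly beyond 3σ.  With σ = 0 every pair is a.
    Returns ``(labels, mean, sd)``; the SD is the population value
    (ddof = 0).
    """
    delta = np.asarray(delta, dtype=np.float64)
    mu = float(delta.mean())
    sd = float(delta.std())
    dev = np.abs(delta - mu)
    labels = np.full(delta.shape, "a", dtype="<U1")
    if sd > 0:
        labels[(dev > sd) & (dev <= 3 * sd)] = "b"
        labels[dev > 3 * sd] = "c"
    return labels, mu, sd


def classify_energy_shifts(apo: EnergyTable, holo: EnergyTable) -> CouplingReport:
    """Classify each pair's apo→holo total-energy shift into the a/b/c
    SD bands.  Both tables must list the identical pair set in order."""
    if not apo.pairs.equals(holo.pairs):
        raise ValueError("apo and holo tables must share an identical pair set")
    n = len(apo.frame)
    if n < 10:
        warnings.warn(
            f"only {n} pairs: the SD of the shift distribution is unstable",
            stacklevel=2,
        )
    delta = holo.totals() - apo.totals()
    labels, mu, sd = classify_shifts_by_sd(delta)
    pairs = apo.pairs.copy()
    pairs["delta_e"] = delta
    pairs["group"] = labels
    counts = {g: int(np.sum(labels == g)) for g in "abc"}
    return CouplingReport(pairs=pairs, mean=mu, sd=sd, counts=counts)


def coupling_fraction(
    report: CouplingReport, threshold: float = 0.25
) -> CouplingReport:
    """Energy coupling fraction N_c / (N_b + N_c) with a strict coupled
    flag at the threshold.  An empty b∪c set gives fraction 0, flagged
    degenerate (no coupling signal to measure)."""
    nb, nc = report.counts.get("b", 0), report.counts.get("c", 0)
    if nb + nc == 0:
        fraction, degenerate = 0.0, True
    else:
        fraction, degenerate = nc / (nb + nc), False
    report.fraction = fraction
    report.coupled = fraction > threshold
    report.threshold = threshold
    report.degenerate = degenerate
    return report


def export_coupling_scatter(
    apo: EnergyTable, holo: EnergyTable, report: CouplingReport
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-pair (E_apo, E_holo, group) rows plus the μ±σ / μ±3σ band
    boundaries in ΔE space, for scatter rendering."""
    df = pd.DataFrame(
        {
            "res_i": apo.frame["res_i"],
            "res_j": apo.frame["res_j"],
            "e_apo": apo.totals(),
            "e_holo": holo.totals(),
            "group": report.pairs["group"],
        }
    )
    bands = {
        "mu": report.mean,
        "mu_minus_sd": report.mean - report.sd,
        "mu_plus_sd": report.mean + report.sd,
        "mu_minus_3sd": report.mean - 3 * report.sd,
        "mu_plus_3sd": report.mean + 3 * report.sd,
    }
    return df, bands
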