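"""Conformational-ensemble container and file I/O.

All coordinates are stored in Ångström as float64 arrays of shape
``(n_frames, n_particles, 3)``.  Residues are indexed 0-based internally;
file formats that carry 1-based (or arbitrary) residue numbering keep the
original numbers in :attr:`Ensemble.residue_numbers` so reports and
round-trips can map back.

Supported formats:

``pdb``
    Multi-model PDB via :mod:`mdtraj` (one MODEL per frame).
``dcd`` / ``xtc``
    Binary trajectory plus a single-frame PDB topology, via :mod:`mdtraj`.
``plain``
    A self-contained text container (header line, JSON metadata line, one
    whitespace-separated ``x y z`` row per particle per frame).  Coordinates
    are written with shortest round-trip ``repr`` so the format is lossless
    for float64.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable

import numpy as np

PLAIN_MAGIC = "#allostate-plain-v1"

__all__ = [
    "Ensemble",
    "Selection",
    "read_ensemble",
    "write_ensemble",
    "PLAIN_MAGIC",
]


@dataclass
class Ensemble:
    """A conformational ensemble with a particle-to-residue map.

    Parameters
    ----------
    coordinates
        ``(n_frames, n_particles, 3)`` float64 array, Å.
    residue_index
        Per-particle 0-based residue id, non-decreasing.
    residue_names
        Optional per-residue labels (length = number of residues).
    residue_numbers
        Original file residue numbers per residue (for round-trips and
        user-facing reports); defaults to 1-based sequential numbering.
    atom_names
        Optional per-particle atom names (``"CA"`` etc.).
    frame_stride_time
        Optional nanoseconds between consecutive frames.
    """

    coordinates: np.ndarray
    residue_index: np.ndarray
    residue_names: list[str] | None = None
    residue_numbers: np.ndarray | None = None
    atom_names: list[str] | None = None
    frame_stride_time: float | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError(
                f"coordinates must have shape (frames, particles, 3), "
                f"got {self.coordinates.shape}"
            )
        if self.coordinates.shape[0] < 1 or self.coordinates.shape[1] < 1:
            raise ValueError("ensemble needs at least one frame and one particle")
        if not np.isfinite(self.coordinates).all():
            raise ValueError("coordinates contain NaN or Inf")
        self.residue_index = np.asarray(self.residue_index, dtype=np.intp)
        if self.residue_index.shape != (self.coordinates.shape[1],):
            raise ValueError("residue_index must have one entry per particle")
        if np.any(np.diff(self.residue_index) < 0):
            raise ValueError("residue_index must be non-decreasing")
        if self.residue_numbers is None:
            self.residue_numbers = np.arange(1, self.n_residues + 1)
        else:
            self.residue_numbers = np.asarray(self.residue_numbers, dtype=np.intp)
            if self.residue_numbers.shape != (self.n_residues,):
                raise ValueError("residue_numbers must have one entry per residue")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_particles(self) -> int:
        return self.coordinates.shape[1]

    @property
    def n_residues(self) -> int:
        return int(self.residue_index.max()) + 1

    def residue_atoms(self, residue: int) -> np.ndarray:
        """Particle indices belonging to ``residue`` (0-based)."""
        return np.nonzero(self.residue_index == residue)[0]


@dataclass
class Selection:
    """A predicate over particles resolving to an ordered index list."""

    predicate: Callable[[Ensemble, int], bool]
    label: str = "custom"

    @classmethod
    def all(cls) -> "Selection":
        return cls(lambda ens, i: True, label="all")

    @classmethod
    def atoms_named(cls, name: str) -> "Selection":
        """Particles whose atom name matches; falls back to all particles
        when the ensemble carries no atom names (bead models)."""

        def pred(ens: Ensemble, i: int) -> bool:
            if ens.atom_names is None:
                return True
            return ens.atom_names[i] == name

        return cls(pred, label=f"name {name}")

    @classmethod
    def residue_range(cls, first: int, last: int) -> "Selection":
        """1-based inclusive residue-number range (PDB convention)."""

        def pred(ens: Ensemble, i: int) -> bool:
            num = ens.residue_numbers[ens.residue_index[i]]
            return first <= num <= last

        return cls(pred, label=f"resid {first}-{last}")

    def resolve(self, ensemble: Ensemble) -> np.ndarray:
        idx = np.array(
            [i for i in range(ensemble.n_particles) if self.predicate(ensemble, i)],
            dtype=np.intp,
        )
        if idx.size == 0:
            raise ValueError(f"selection '{self.label}' matches no particles")
        return idx


def resolve_selection(ensemble: Ensemble, selection: "Selection | None") -> np.ndarray:
    if selection is None:
        return np.arange(ensemble.n_particles, dtype=np.intp)
    return selection.resolve(ensemble)


# --- plain text container -------------------------------------------------


def _write_plain(ensemble: Ensemble, path: str) -> None:
    meta = {
        "n_frames": ensemble.n_frames,
        "n_particles": ensemble.n_particles,
        "residue_index": ensemble.residue_index.tolist(),
        "residue_numbers": ensemble.residue_numbers.tolist(),
        "residue_names": ensemble.residue_names,
        "atom_names": ensemble.atom_names,
        "frame_stride_time": ensemble.frame_stride_time,
    }
    with open(path, "w") as fh:
        fh.write(PLAIN_MAGIC + "\n")
        fh.write(json.dumps(meta) + "\n")
        for frame in ensemble.coordinates:
            for x, y, z in frame:
                # shortest round-trip repr of the Python float is lossless
                fh.write(f"{float(x)!r} {float(y)!r} {float(z)!r}\n")


def _read_plain(path: str) -> Ensemble:
    with open(path) as fh:
        magic = fh.readline().strip()
        if magic != PLAIN_MAGIC:
            raise ValueError(f"{path}: not a plain ensemble file (bad magic {magic!r})")
        meta = json.loads(fh.readline())
        n_frames, n_particles = meta["n_frames"], meta["n_particles"]
        coords = np.empty((n_frames * n_particles, 3), dtype=np.float64)
        for row in range(n_frames * n_particles):
            parts = fh.readline().split()
            if len(parts) != 3:
                raise ValueError(f"{path}: truncated at coordinate row {row}")
            coords[row] = [float(p) for p in parts]
    return Ensemble(
        coordinates=coords.reshape(n_frames, n_particles, 3),
        residue_index=np.asarray(meta["residue_index"]),
        residue_names=meta["residue_names"],
        residue_numbers=np.asarray(meta["residue_numbers"]),
        atom_names=meta["atom_names"],
        frame_stride_time=meta["frame_stride_time"],
    )


# --- mdtraj-backed standard formats ---------------------------------------


def _mdtraj_topology(ensemble: Ensemble):
    import mdtraj as md

    top = md.Topology()
    chain = top.add_chain()
    residues = {}
    carbon = md.element.carbon
    for i in range(ensemble.n_particles):
        r = int(ensemble.residue_index[i])
        if r not in residues:
            name = ensemble.residue_names[r] if ensemble.residue_names else "GLY"
            residues[r] = top.add_residue(
                name, chain, resSeq=int(ensemble.residue_numbers[r])
            )
        atom_name = ensemble.atom_names[i] if ensemble.atom_names else "CA"
        top.add_atom(atom_name, carbon, residues[r])
    return top


def _to_mdtraj(ensemble: Ensemble):
    import mdtraj as md

    return md.Trajectory(
        xyz=(ensemble.coordinates / 10.0).astype(np.float32),
        topology=_mdtraj_topology(ensemble),
    )


def _from_mdtraj(traj) -> Ensemble:
    atoms = list(traj.topology.atoms)
    residue_index = np.array([a.residue.index for a in atoms], dtype=np.intp)
    residues = list(traj.topology.residues)
    return Ensemble(
        coordinates=np.asarray(traj.xyz, dtype=np.float64) * 10.0,
        residue_index=residue_index,
        residue_names=[r.name for r in residues],
        residue_numbers=np.array([r.resSeq for r in residues], dtype=np.intp),
        atom_names=[a.name for a in atoms],
    )


def read_ensemble(path: str, format: str, topology: str | None = None) -> Ensemble:
    """Read an ensemble.

    ``format`` is one of ``pdb`` (multi-model), ``dcd``/``xtc`` (requires
    ``topology``, a single-frame PDB), or ``plain``.
    """
    if format == "plain":
        return _read_plain(path)
    import mdtraj as md

    if format == "pdb":
        return _from_mdtraj(md.load_pdb(path, standard_names=False))
    if format in ("dcd", "xtc"):
        if topology is None:
            raise ValueError(f"{format} input requires a PDB topology file")
        try:
            traj = md.load(path, top=topology)
        except Exception as exc:  # surface atom-count mismatches with context
            raise ValueError(
                f"failed to read {path} with topology {topology}: {exc}"
            ) from exc
        return _from_mdtraj(traj)
    raise ValueError(f"unsupported ensemble format: {format!r}")


def write_ensemble(ensemble: Ensemble, path: str, format: str) -> None:
    """Write an ensemble; the plain format round-trips losslessly, PDB at
    the 3-decimal coordinate precision of the format."""
    if format == "plain":
        _write_plain(ensemble, path)
        return
    if format == "pdb":
        _to_mdtraj(ensemble).save_pdb(path)
        return
    if format == "dcd":
        _to_mdtraj(ensemble).save_dcd(path)
        return
    if format == "xtc":
        _to_mdtraj(ensemble).save_xtc(path)
        return
    raise ValueError(f"unsupported ensemble format: {format!r}")
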