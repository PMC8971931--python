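"""End-to-end orchestration of the analysis from one configuration.

Stages run in dependency order — ensemble → RMSD/RMSF → DCCM →
network/communities → PCA → MSM → energy coupling — each writing
delimited-text outputs into the output directory, plus a JSON manifest
recording package/library versions, the seed, all stage parameters, and
checksums of inputs and outputs so a run can be reproduced and verified
bit-for-bit.

The input section of the config either points at ensemble files
(``ensemble: {path, format, topology}``) or requests synthetic data
(``synthetic: {kind: two_domain, ...}``); an MSM stage over a planted
discrete chain is requested with ``markov: {...}``, and the coupling
stage with either apo/holo table paths or ``coupling: {synthetic: ...}``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .dccm import cross_correlation_matrix, mask_weak_correlations
from .energy_coupling import (
    classify_energy_shifts,
    coupling_fraction,
    read_energy_table,
    write_energy_table,
)
from .msm import (
    ck_test,
    estimate_msm,
    implied_timescales,
    macrostate_populations,
    pcca_macrostates,
    DiscreteTrajectory,
)
from .network_communities import (
    contact_occupancy_edges,
    edge_distances,
    girvan_newman_communities,
)
from .pca_landscape import cartesian_pca, free_energy_surface, porcupine_vectors
from .superpose_fluct import rmsd_series, rmsf_per_residue
from .synthetic_data import (
    EnergyTableSpec,
    generate_energy_tables,
    generate_enm_ensemble,
    generate_markov_trajectory,
    metastable_chain_spec,
    two_domain_spec,
)
from .traj_io import Ensemble, read_ensemble, write_ensemble

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    output_dir: str
    seed: int = 0
    ensemble: dict | None = None  # {path, format, topology?}
    synthetic: dict | None = None  # {kind: two_domain, n_frames, ...}
    markov: dict | None = None  # {n_steps, lag, macrostates, ...}
    coupling: dict | None = None  # {apo, holo} or {synthetic: {...}}
    contact_cutoff: float = 4.5
    contact_occupancy: float = 0.75
    exclude_neighbors: int = 1
    mask_threshold: float = 0.3
    min_community_size: int = 3
    pca_modes: int = 2
    landscape_bins: int = 40
    temperature: float = 300.0
    coupling_threshold: float = 0.25

    def __post_init__(self) -> None:
        if self.ensemble is None and self.synthetic is None:
            raise ValueError("config needs an 'ensemble' or 'synthetic' section")
        if self.contact_cutoff <= 0:
            raise ValueError("contact_cutoff must be positive")
        if not (0.0 < self.contact_occupancy <= 1.0):
            raise ValueError("contact_occupancy must lie in (0, 1]")
        if not (0.0 <= self.mask_threshold <= 1.0):
            raise ValueError("mask_threshold must lie in [0, 1]")
        if self.min_community_size < 1:
            raise ValueError("min_community_size must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not (0.0 <= self.coupling_threshold <= 1.0):
            raise ValueError("coupling_threshold must lie in [0, 1]")
        if self.pca_modes < 2:
            raise ValueError("pca_modes must be >= 2 (landscape needs two)")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_matrix(path: Path, M: np.ndarray, fmt: str = "%.10g") -> None:
    np.savetxt(path, M, fmt=fmt, delimiter="\t")


def _load_or_generate_ensemble(cfg: PipelineConfig) -> tuple[Ensemble, dict]:
    if cfg.ensemble is not None:
        ens = read_ensemble(
            cfg.ensemble["path"],
            cfg.ensemble.get("format", "plain"),
            topology=cfg.ensemble.get("topology"),
        )
        return ens, {"source": "file", **cfg.ensemble}
    syn = dict(cfg.synthetic)
    kind = syn.pop("kind", "two_domain")
    n_frames = int(syn.pop("n_frames", 20000))
    if kind != "two_domain":
        raise ValueError(f"unknown synthetic ensemble kind {kind!r}")
    spec = two_domain_spec(temperature=cfg.temperature, **syn)
    ens, _ = generate_enm_ensemble(spec, n_frames=n_frames, seed=cfg.seed)
    return ens, {
        "source": "synthetic",
        "kind": kind,
        "n_frames": n_frames,
        "domain_labels": spec.domain_labels.tolist(),
        **{k: v for k, v in syn.items()},
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns a result dict and writes
    outputs plus ``manifest.json`` into the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage_params: dict = {}
    t0 = time.perf_counter()

    def log_stage(name: str, start: float) -> None:
        logger.info("stage %-12s done in %.2f s", name, time.perf_counter() - start)

    # --- ensemble
    t = time.perf_counter()
    ensemble, source_meta = _load_or_generate_ensemble(config)
    write_ensemble(ensemble, str(out / "ensemble.coords.txt"), "plain")
    stage_params["ensemble"] = source_meta
    log_stage("ensemble", t)

    # --- RMSD / RMSF
    t = time.perf_counter()
    rmsd = rmsd_series(ensemble, reference_frame=0)
    np.savetxt(
        out / "rmsd.tsv",
        np.column_stack([np.arange(rmsd.size), rmsd]),
        fmt=("%d", "%.10g"),
        delimiter="\t",
        header="frame\trmsd_A",
        comments="",
    )
    rmsf = rmsf_per_residue(ensemble, reference_mode="mean")
    np.savetxt(
        out / "rmsf.tsv",
        np.column_stack([np.arange(rmsf.size), rmsf]),
        fmt=("%d", "%.10g"),
        delimiter="\t",
        header="residue\trmsf_A",
        comments="",
    )
    results["rmsd_mean"] = float(rmsd.mean())
    results["rmsf"] = rmsf
    log_stage("fluctuation", t)

    # --- DCCM
    t = time.perf_counter()
    C = cross_correlation_matrix(ensemble)
    masked = mask_weak_correlations(C, threshold=config.mask_threshold)
    _write_matrix(out / "dccm.tsv", C.values)
    _write_matrix(out / "dccm_masked.tsv", masked.values)
    results["dccm"] = C
    log_stage("dccm", t)

    # --- network / communities
    t = time.perf_counter()
    edges = contact_occupancy_edges(
        ensemble,
        cutoff=config.contact_cutoff,
        min_occupancy=config.contact_occupancy,
        exclude_neighbors=config.exclude_neighbors,
    )
    graph = edge_distances(C, edges)
    partition = girvan_newman_communities(graph, min_size=config.min_community_size)
    with open(out / "communities.tsv", "w") as fh:
        fh.write("residue\tcommunity\n")
        for res, cid in sorted(partition.labels().items()):
            fh.write(f"{res}\t{cid}\n")
    with open(out / "community_connectivity.tsv", "w") as fh:
        fh.write("community_a\tcommunity_b\tbetweenness\n")
        for (a, b), w in sorted(partition.connectivity.items()):
            fh.write(f"{a}\t{b}\t{w:.10g}\n")
    with open(out / "edges.tsv", "w") as fh:
        fh.write("res_i\tres_j\toccupancy\tabs_correlation\tdistance\n")
        for u, v, data in sorted(graph.graph.edges(data=True)):
            fh.write(
                f"{u}\t{v}\t{data['occupancy']:.10g}\t"
                f"{data['correlation']:.10g}\t{data['distance']:.10g}\n"
            )
    results["partition"] = partition
    results["n_communities"] = len(partition.communities)
    results["modularity"] = partition.modularity
    log_stage("network", t)

    # --- PCA / landscape
    t = time.perf_counter()
    pca = cartesian_pca(ensemble, n_modes=config.pca_modes)
    np.savetxt(
        out / "pca_eigenvalues.tsv", pca.eigenvalues, fmt="%.10g", delimiter="\t"
    )
    _write_matrix(out / "pca_projections.tsv", pca.projections)
    _write_matrix(out / "porcupine_pc1.tsv", porcupine_vectors(pca, mode=0, scale=1.0))
    dG, xe, ye = free_energy_surface(
        pca.projections[:, :2],
        bins=config.landscape_bins,
        temperature=config.temperature,
    )
    _write_matrix(out / "landscape_dG.tsv", dG)
    results["pca"] = pca
    log_stage("pca", t)

    # --- MSM (planted discrete chain)
    if config.markov is not None:
        t = time.perf_counter()
        mk = dict(config.markov)
        n_steps = int(mk.pop("n_steps", 100000))
        lag = int(mk.pop("lag", 1))
        n_macro = int(mk.pop("macrostates", 3))
        spec = metastable_chain_spec(**mk)
        seq = generate_markov_trajectory(spec, n_steps=n_steps, seed=config.seed + 1)
        dtraj = DiscreteTrajectory(states=seq)
        model = estimate_msm(dtraj, lag=lag)
        its = implied_timescales(dtraj, lags=[lag, 2 * lag, 4 * lag])
        chi, assignment = pcca_macrostates(model, n_macro)
        crisp_pop, fuzzy_pop = macrostate_populations(model, chi, assignment)
        ck = ck_test(dtraj, lag=lag, n_macrostates=n_macro)
        _write_matrix(out / "msm_transition_matrix.tsv", model.transition_matrix)
        _write_matrix(out / "msm_memberships.tsv", chi)
        np.savetxt(out / "msm_dtraj.tsv", seq, fmt="%d")
        with open(out / "msm_summary.json", "w") as fh:
            json.dump(
                {
                    "lag": lag,
                    "stationary": model.stationary.tolist(),
                    "implied_timescales": {
                        str(k): [None if np.isnan(x) else x for x in v]
                        for k, v in its.items()
                    },
                    "macrostate_assignment": assignment.tolist(),
                    "populations_crisp": crisp_pop.tolist(),
                    "populations_fuzzy": fuzzy_pop.tolist(),
                    "ck_max_deviation": {
                        str(f): r["max_deviation"] for f, r in ck.items()
                    },
                },
                fh,
                indent=1,
                sort_keys=True,
            )
        results["msm"] = model
        results["msm_assignment"] = assignment
        stage_params["markov"] = {
            "n_steps": n_steps,
            "lag": lag,
            "macrostates": n_macro,
            **mk,
        }
        log_stage("msm", t)

    # --- energy coupling
    if config.coupling is not None:
        t = time.perf_counter()
        cp = dict(config.coupling)
        if "synthetic" in cp:
            syn = dict(cp["synthetic"])
            syn.setdefault("seed", config.seed + 2)
            spec = EnergyTableSpec(**syn)
            apo, holo, _ = generate_energy_tables(spec)
            write_energy_table(apo, str(out / "energies_apo.tsv"))
            write_energy_table(holo, str(out / "energies_holo.tsv"))
        else:
            apo = read_energy_table(cp["apo"], condition="apo")
            holo = read_energy_table(cp["holo"], condition="holo")
        report = coupling_fraction(
            classify_energy_shifts(apo, holo), threshold=config.coupling_threshold
        )
        report.pairs.to_csv(out / "coupling_groups.tsv", sep="\t", index=False)
        with open(out / "coupling_summary.json", "w") as fh:
            json.dump(
                {
                    "counts": report.counts,
                    "fraction": report.fraction,
                    "coupled": report.coupled,
                    "threshold": report.threshold,
                    "mean_shift": report.mean,
                    "sd_shift": report.sd,
                },
                fh,
                indent=1,
                sort_keys=True,
            )
        results["coupling"] = report
        stage_params["coupling"] = cp
        log_stage("coupling", t)

    # --- manifest (no timestamps: runs must be byte-reproducible)
    import networkx
    import pandas
    import scipy
    import sklearn

    outputs = sorted(p for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "package": {"allostate": __version__},
        "libraries": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "networkx": networkx.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "seed": config.seed,
        "parameters": {
            "contact_cutoff": config.contact_cutoff,
            "contact_occupancy": config.contact_occupancy,
            "exclude_neighbors": config.exclude_neighbors,
            "mask_threshold": config.mask_threshold,
            "min_community_size": config.min_community_size,
            "pca_modes": config.pca_modes,
            "landscape_bins": config.landscape_bins,
            "temperature": config.temperature,
            "coupling_threshold": config.coupling_threshold,
            **stage_params,
        },
        "inputs": {
            k: _sha256(Path(v))
            for k, v in (
                ("ensemble", (config.ensemble or {}).get("path")),
                ("apo", (config.coupling or {}).get("apo")),
                ("holo", (config.coupling or {}).get("holo")),
            )
            if v
        },
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("pipeline finished in %.2f s", time.perf_counter() - t0)
    results["manifest"] = manifest
    return results
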