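"""End-to-end orchestration: equilibration discard through morph export.

A single :class:`RunConfig` drives the full stage sequence —

    discard equilibration -> LOVO core fit -> RMSD mask-mode table ->
    RMSF + apo/holo difference map -> crossbridge frame + angle series +
    densities -> residue contacts + differentials -> ligand occupancy +
    conformer clustering (holo) -> elevation morphs

— writing CSV/JSON/PDB outputs plus a manifest that suffices to reproduce
any output (config, seed, package versions).  Inputs are either the shipped
synthetic scenario (default) or user-supplied multi-model PDB trajectories.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment import lovo_fit, rmsd_series, rmsf_profile, superpose_frames
from .cluster import cluster_report, nmrclust, pose_rmsd_matrix
from .contacts import differential_contacts, ligand_occupancy, residue_contact_tables
from .geometry import (
    angle_density,
    angle_summary,
    angle_timeseries,
    build_crossbridge_frame,
    superpose_to_reference,
)
from .model_io import (
    MolecularModel,
    Selection,
    Trajectory,
    read_structure,
    read_trajectory,
    select,
    write_trajectory,
)
from .morph import bin_by_elevation, interpolate_morph
from .stats import rmsd_summary_table, rmsf_difference_map
from .synthetic import apo_spec, holo_spec, make_hinged_system, simulate_trajectories

log = logging.getLogger("myolever")

__all__ = ["RunConfig", "ConfigError", "StageError", "run_full_analysis"]


class ConfigError(ValueError):
    """Configuration failed pre-flight validation; no stage has run."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""


@dataclass
class RunConfig:
    """All knobs of the full analysis.

    Defaults follow the study conventions: 100 ns equilibration discard for
    file inputs (the synthetic generator emulates post-equilibration
    production, so its discard defaults to zero), 100 ps contact stride,
    LOVO fraction 0.35 with 1 ns subsampling, 5 Å contact cutoff, α = 0.05,
    10% occupancy-difference threshold, 2° angle bins and 5° morph bins.
    """

    output_dir: str = "results"
    seed: int = 0
    # synthetic scenario (used when no input trajectories are given)
    frames: int = 4000
    replicates: int = 3
    # file inputs: {"apo": [paths...], "holo": [paths...]}, multi-model PDB
    trajectories: dict | None = None
    topology_path: str | None = None
    reference_complex_path: str | None = None
    timestep_ps: float = 100.0
    # selections
    hlh_expression: str = "chain A and resid 200-230"
    junction_expression: str = "chain A and resid 704-723"
    actin_expression: str = "chain F"
    anchor_expression: str = "chain A and resid 712-766"
    ligand_expression: str = "chain L"
    ca_expression: str = "name CA and chain A E"
    tail_proximal: tuple = (769, 771)
    tail_distal: tuple = (784, 787)
    # parameters
    equilibration_discard_ps: float | None = None  # auto: 0 synthetic, 1e5 files
    contact_stride_ps: float = 100.0
    lovo_stride_ps: float = 1000.0
    lovo_fraction: float = 0.35
    cutoff: float = 5.0
    alpha: float = 0.05
    delta_threshold: float = 0.10
    angle_bin_width: float = 2.0
    morph_bin_width: float = 5.0
    morph_steps: int = 5

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)

    @property
    def is_synthetic(self) -> bool:
        return self.trajectories is None

    @property
    def discard_ps(self) -> float:
        if self.equilibration_discard_ps is not None:
            return self.equilibration_discard_ps
        return 0.0 if self.is_synthetic else 100_000.0


def _load_inputs(config: RunConfig):
    """Return (trajectories by condition, topology, reference complex)."""
    if config.is_synthetic:
        a_spec = apo_spec(n_frames=config.frames, n_replicates=config.replicates,
                          seed=config.seed, timestep=config.timestep_ps)
        h_spec = holo_spec(n_frames=config.frames, n_replicates=config.replicates,
                           seed=config.seed + 1, timestep=config.timestep_ps)
        a_sys = make_hinged_system(a_spec)
        h_sys = make_hinged_system(h_spec)
        apo, _ = simulate_trajectories(a_spec, a_sys)
        holo, _ = simulate_trajectories(h_spec, h_sys)
        # holo topology carries the ligand; the reference complex is shared geometry
        return {"apo": apo, "holo": holo}, h_sys.model, h_sys.reference_complex
    if not (config.topology_path and config.reference_complex_path):
        raise ConfigError("file inputs need topology_path and reference_complex_path")
    topology = read_structure(config.topology_path, heavy_only=True)
    reference = read_structure(config.reference_complex_path, heavy_only=True)
    trajs: dict[str, list[Trajectory]] = {}
    for cond, paths in config.trajectories.items():
        trajs[cond] = [
            read_trajectory(p, topology, timestep=config.timestep_ps,
                            replicate=str(i + 1), condition=cond)
            for i, p in enumerate(paths)
        ]
    return trajs, topology, reference


def _validate_selections(config: RunConfig, topology: MolecularModel,
                         reference: MolecularModel) -> dict[str, Selection]:
    """Pre-flight: every configured selection must resolve (non-empty)."""
    out = {}
    checks = [
        ("hlh", config.hlh_expression, topology),
        ("junction", config.junction_expression, topology),
        ("ca", config.ca_expression, topology),
        ("actin", config.actin_expression, reference),
        ("anchor", config.anchor_expression, reference),
        ("hlh_reference", config.hlh_expression, reference),
    ]
    import warnings as _w

    for label, expr, model in checks:
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            sel = select(model, expr)
        if len(sel) == 0:
            raise ConfigError(f"selection '{label}' ({expr!r}) matches no atoms")
        out[label] = sel
    return out


def run_full_analysis(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle.

    Any stage failure aborts with the stage name and cause; outputs written
    so far are retained next to a ``FAILED`` marker file.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    written: list[str] = []

    def _save_csv(df: pd.DataFrame, name: str, **kw) -> None:
        path = out_dir / name
        df.to_csv(path, index=kw.pop("index", False), **kw)
        written.append(name)

    trajs, topology, reference = _load_inputs(config)
    sels = _validate_selections(config, topology, reference)

    stage = "setup"
    try:
        # ligand-free heavy-atom selection for protein contact work
        lig_sel = None
        try:
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                lig_sel = select(topology, config.ligand_expression)
        except Exception:
            lig_sel = None
        protein_mask = np.ones(topology.n_atoms, dtype=bool)
        if lig_sel is not None and len(lig_sel):
            protein_mask[lig_sel.indices] = False
        protein_sel = Selection(np.where(protein_mask & (topology.element != "H"))[0],
                                provenance="protein heavy atoms")

        stage = "equilibration_discard"
        if config.discard_ps > 0:
            trajs = {
                c: [t.discard_equilibration(config.discard_ps) for t in ts]
                for c, ts in trajs.items()
            }

        # trajectories may carry different topologies per condition (ligand);
        # per-condition Cα selections are resolved against each topology
        def _cond_sel(expr: str, cond: str) -> Selection:
            return select(trajs[cond][0].topology, expr)

        stage = "lovo_fit"
        lovo_stride = max(1, int(round(config.lovo_stride_ps / config.timestep_ps)))
        lovo_results = {}
        for cond, ts in trajs.items():
            ca_sel = _cond_sel(config.ca_expression, cond)
            combined = np.concatenate([t.frames[::lovo_stride] for t in ts])
            ens = Trajectory(topology=ts[0].topology, frames=combined,
                             timestep=config.timestep_ps * lovo_stride,
                             replicate="ensemble", condition=cond)
            lovo_results[cond] = lovo_fit(ens, fraction=config.lovo_fraction,
                                          ca_selection=ca_sel)
        subset_resid = {
            cond: sorted(
                trajs[cond][0].topology.resid[r.subset.indices].tolist()
            )
            for cond, r in lovo_results.items()
        }
        pd.DataFrame(
            [(c, r) for c, rs in subset_resid.items() for r in rs],
            columns=["condition", "resid"],
        ).pipe(_save_csv, "lovo_subset.csv")
        results["lovo"] = lovo_results

        stage = "rmsd_table"
        mask_modes = {
            "all_ca": (config.ca_expression, config.ca_expression),
            "converter": ("name CA and chain A and resid 712-766",
                          "name CA and chain A and resid 712-766"),
            "tail": ("name CA and chain A and resid 768-810",
                     "name CA and chain A and resid 768-810"),
            "elc": ("name CA and chain E", "name CA and chain E"),
        }
        series: dict[str, dict[str, dict[str, np.ndarray]]] = {"apo": {}, "holo": {}}
        for cond, ts in trajs.items():
            ref_model = ts[0].topology  # initial structure as RMSD reference
            for mode, (a_expr, m_expr) in mask_modes.items():
                a_sel = _cond_sel(a_expr, cond)
                m_sel = _cond_sel(m_expr, cond)
                series[cond].setdefault(mode, {})
                for t in ts:
                    series[cond][mode][t.replicate] = rmsd_series(t, a_sel, m_sel, ref_model)
            lovo = lovo_results[cond]
            ca_sel = _cond_sel(config.ca_expression, cond)
            for mode, m_sel in (("lovo_subset", lovo.subset), ("lovo_all", ca_sel)):
                series[cond].setdefault(mode, {})
                for t in ts:
                    series[cond][mode][t.replicate] = rmsd_series(
                        t, lovo.subset, m_sel, ref_model
                    )
        rmsd_table = rmsd_summary_table(series["apo"], series["holo"])
        _save_csv(rmsd_table.reset_index(), "rmsd_table.csv")
        results["rmsd_table"] = rmsd_table

        stage = "rmsf"
        profiles: dict[str, list] = {}
        for cond, ts in trajs.items():
            lovo = lovo_results[cond]
            ca_sel = _cond_sel(config.ca_expression, cond)
            ref_sub = lovo.average[lovo._subset_pos]
            profiles[cond] = []
            for t in ts:
                aligned_frames, _, _ = superpose_frames(
                    t.frames, lovo.subset.indices, ref_sub
                )
                aligned = dataclasses.replace(t, frames=aligned_frames)
                profiles[cond].append(rmsf_profile(aligned, ca_sel))
        diff_map = rmsf_difference_map(profiles["apo"], profiles["holo"],
                                       alpha=config.alpha)
        _save_csv(diff_map.table, "rmsf_difference.csv")
        results["rmsf_difference"] = diff_map

        stage = "crossbridge_angles"
        frame = build_crossbridge_frame(reference, sels["actin"], sels["anchor"])
        all_angles = []
        for cond, ts in trajs.items():
            hlh_mobile = _cond_sel(config.hlh_expression, cond)
            for t in ts:
                placed = superpose_to_reference(t, hlh_mobile, reference,
                                                sels["hlh_reference"])
                all_angles.append(
                    angle_timeseries(placed, frame,
                                     proximal=tuple(config.tail_proximal),
                                     distal=tuple(config.tail_distal))
                )
        angles = pd.concat(all_angles, ignore_index=True)
        _save_csv(angles, "angles.csv")
        summary = angle_summary(angles)
        _save_csv(summary.reset_index(), "angle_summary.csv")
        results["angles"] = angles
        results["angle_summary"] = summary
        for cond in trajs:
            sub = angles[angles.condition == cond]
            dens = angle_density(sub["elevation"], bin_width=config.angle_bin_width)
            pd.DataFrame(
                {"bin_left": dens.edges[:-1], "bin_right": dens.edges[1:],
                 "density": dens.density}
            ).pipe(_save_csv, f"elevation_density_{cond}.csv")

        stage = "contacts"
        tables: dict[str, list[pd.DataFrame]] = {}
        for cond, ts in trajs.items():
            top = ts[0].topology
            mask = np.ones(top.n_atoms, dtype=bool)
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                ls = select(top, config.ligand_expression)
            if len(ls):
                mask[ls.indices] = False
            psel = Selection(np.where(mask & (top.element != "H"))[0],
                             provenance="protein heavy atoms")
            tables[cond] = [
                residue_contact_tables(t, stride_ps=config.contact_stride_ps,
                                       selection=psel, cutoff=config.cutoff)
                for t in ts
            ]
        for cond, tabs in tables.items():
            pd.concat(tabs, ignore_index=True).pipe(
                _save_csv, f"contacts_{cond}.csv"
            )
        diff = differential_contacts(tables["apo"], tables["holo"],
                                     alpha=config.alpha,
                                     delta_threshold=config.delta_threshold)
        _save_csv(diff, "differential_contacts.csv")
        # pseudo-bond export: residue_i residue_j radius (|Δ| scaled)
        with open(out_dir / "differential_contacts.pseudobonds.txt", "w") as fh:
            for r in diff.itertuples():
                fh.write(
                    f"{r.chain_i}{r.resid_i} {r.chain_j}{r.resid_j} "
                    f"{abs(r.delta):.3f}\n"
                )
        written.append("differential_contacts.pseudobonds.txt")
        results["differential_contacts"] = diff

        stage = "ligand"
        if "holo" in trajs:
            holo_top = trajs["holo"][0].topology
            lig = select(holo_top, config.ligand_expression)
            if len(lig):
                occ = ligand_occupancy(trajs["holo"], lig, cutoff=config.cutoff)
                occ.average.rename("occupancy").reset_index().pipe(
                    _save_csv, "ligand_occupancy.csv"
                )
                results["ligand_occupancy"] = occ
                stage = "cluster"
                poses = np.concatenate(
                    [t.frames[:, lig.indices, :] for t in trajs["holo"]]
                )
                # subsample poses for tractable all-pair RMSD
                step = max(1, len(poses) // 400)
                poses = poses[::step]
                ring = [i for i, nm in enumerate(holo_top.name[lig.indices])
                        if nm in ("C1", "C2", "C3", "C4", "C5", "C6", "F1")]
                dist = pose_rmsd_matrix(poses, np.array(ring))
                clusters = nmrclust(dist)
                report = cluster_report(clusters, top_k=4)
                _save_csv(report, "ligand_clusters.csv")
                results["ligand_clusters"] = clusters
                results["ligand_cluster_report"] = report

        stage = "morph"
        morphs = {}
        for cond, ts in trajs.items():
            t = ts[0]
            junction = _cond_sel(config.junction_expression, cond)
            hlh_mobile = _cond_sel(config.hlh_expression, cond)
            placed = superpose_to_reference(t, hlh_mobile, reference,
                                            sels["hlh_reference"])
            ang = angle_timeseries(placed, frame,
                                   proximal=tuple(config.tail_proximal),
                                   distal=tuple(config.tail_distal))
            binned = bin_by_elevation(placed, ang, junction,
                                      bin_width=config.morph_bin_width)
            if len(binned.occupied) >= 2:
                morph_traj = interpolate_morph(binned, config.morph_steps)
                write_trajectory(morph_traj, str(out_dir / f"morph_{cond}.pdb"))
                written.append(f"morph_{cond}.pdb")
                morphs[cond] = morph_traj
        results["morphs"] = morphs

        stage = "manifest"
        cfg_dict = dataclasses.asdict(config)
        cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
        manifest = {
            "config": cfg_dict,
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "seed": config.seed,
            "versions": {
                "myolever": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "outputs": written,
        }
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        results["manifest"] = manifest
    except Exception as exc:
        (out_dir / "FAILED").write_text(f"stage: {stage}\ncause: {exc}\n")
        raise StageError(f"stage '{stage}' failed: {exc}") from exc
    return results
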