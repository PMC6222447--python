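"""End-to-end workflow: structure -> interface -> vectors -> configs -> stats.

A single :class:`RunConfig` drives the full pipeline for one complex: read
(or generate) the structure, detect the interface, compute the RDM and COM
pulling vectors, emit the pulling configuration files for an external MD
engine and, optionally, run the Brownian toy simulator along the chosen
direction and an orthogonal control and compare their rupture statistics.
Every run writes its resolved configuration and a manifest with SHA-256
checksums of all artifacts, so identical configs yield identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np

from . import interface_detection, pull_vectors, rupture_analysis, smd_config
from . import structure_io, toy_pull_simulator
from .structure_io import StructureError

__all__ = ["RunConfig", "WorkflowError", "run_workflow"]

logger = logging.getLogger(__name__)


class WorkflowError(RuntimeError):
    """A stage failure, carrying the stage name for context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration of one workflow run (JSON-serialisable)."""

    output_dir: str
    pdb_path: str | None = None
    toy_spec: structure_io.ToyComplexSpec | None = None
    receptor_chains: tuple[str, ...] = ("A",)
    ligand_chain: str = "B"
    model_index: int = 1
    cutoff_nm: float = interface_detection.DEFAULT_CUTOFF_NM
    direction_kind: str = "rdm"  # or "com"
    orient: str = "toward-ligand"
    spring_constant_k: float = smd_config.DEFAULT_SPRING_K
    pull_speed_v: float = smd_config.DEFAULT_PULL_SPEED
    temperature: float = smd_config.DEFAULT_TEMPERATURE
    n_trajectories: int = 50
    base_seed: int = 1
    run_toy_sim: bool = False
    toy_sim_speed: float = 1e-3  # nm/ps; desk-scale, not the engine speed
    toy_sim_spring_k: float = 100.0
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.pdb_path is None) == (self.toy_spec is None):
            raise ValueError("exactly one of pdb_path / toy_spec must be set")
        if self.direction_kind not in ("rdm", "com"):
            raise ValueError(f"unknown direction kind {self.direction_kind!r}")
        if self.n_trajectories < 1:
            raise ValueError("n_trajectories must be >= 1")
        if self.cutoff_nm <= 0:
            raise ValueError("cutoff must be positive")

    def to_dict(self, portable: bool = False) -> dict:
        """JSON form; ``portable`` replaces output_dir with "." so copies
        stored inside the output directory don't differ across runs."""
        d = dataclasses.asdict(self)
        if self.toy_spec is not None:
            d["toy_spec"] = dataclasses.asdict(self.toy_spec)
        if portable:
            d["output_dir"] = "."
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("toy_spec") is not None:
            spec = dict(d["toy_spec"])
            if "placed_dipole_direction" in spec:
                spec["placed_dipole_direction"] = tuple(
                    spec["placed_dipole_direction"]
                )
            d["toy_spec"] = structure_io.ToyComplexSpec(**spec)
        if "receptor_chains" in d:
            d["receptor_chains"] = tuple(d["receptor_chains"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _orthogonal_unit(v: np.ndarray) -> np.ndarray:
    """A deterministic unit vector orthogonal to v."""
    trial = np.array([1.0, 0.0, 0.0])
    if abs(v @ trial) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    w = trial - (trial @ v) * v
    return w / np.linalg.norm(w)


def run_workflow(config: RunConfig) -> dict:
    """Run the configured pipeline; returns the manifest (also written).

    Stages: structure, interface, vectors, smd_config and (optionally)
    toy_sim + analysis.  Errors are re-raised with the failing stage named.
    """
    try:
        config.validate()
    except ValueError as exc:
        raise WorkflowError("validate", str(exc)) from exc
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    summary: dict = {}

    def emit(path: Path) -> Path:
        files.append(path)
        return path

    cfg_path = out / "config.json"
    cfg_path.write_text(
        json.dumps(config.to_dict(portable=True), indent=2, sort_keys=True) + "\n"
    )
    emit(cfg_path)

    # --- structure ---------------------------------------------------------
    try:
        if config.toy_spec is not None:
            structure, truth = structure_io.generate_toy_complex(
                config.toy_spec, contact_cutoff_nm=config.cutoff_nm
            )
            pdb_path = structure_io.write_structure(structure, out / "complex.pdb")
            emit(pdb_path)
            truth_path = out / "toy_ground_truth.json"
            truth_path.write_text(
                json.dumps(dataclasses.asdict(truth), indent=2) + "\n"
            )
            emit(truth_path)
        else:
            structure = structure_io.read_structure(
                config.pdb_path, model_index=config.model_index
            )
    except (StructureError, FileNotFoundError) as exc:
        raise WorkflowError("structure", str(exc)) from exc
    summary["chain_lengths"] = structure_io.chain_lengths(structure)

    # --- interface ---------------------------------------------------------
    try:
        iface = interface_detection.find_interface(
            structure,
            config.receptor_chains,
            config.ligand_chain,
            cutoff_nm=config.cutoff_nm,
        )
    except StructureError as exc:
        raise WorkflowError("interface", str(exc)) from exc
    iface_path = out / "interface.tsv"
    with iface_path.open("w") as fh:
        fh.write("residue\n")
        for r in iface.receptor_residues:
            fh.write(f"{r}\n")
        fh.write(
            "# ranges: "
            + interface_detection.format_residue_ranges(iface.receptor_residues)
            + "\n"
        )
    emit(iface_path)
    summary["interface_residues"] = interface_detection.format_residue_ranges(
        iface.receptor_residues
    )

    # --- pulling vectors ---------------------------------------------------
    try:
        rdm_vec, dipole, _ = pull_vectors.rdm_vector(
            structure,
            config.receptor_chains,
            config.ligand_chain,
            cutoff_nm=config.cutoff_nm,
            orient=config.orient,
        )
        com_vec = pull_vectors.com_vector(
            structure, config.receptor_chains, config.ligand_chain
        )
    except (StructureError, pull_vectors.ZeroDipoleError) as exc:
        raise WorkflowError("vectors", str(exc)) from exc
    angle = pull_vectors.angle_between(rdm_vec.direction, com_vec.direction)
    vectors_path = out / "vectors.json"
    vectors_path.write_text(
        json.dumps(
            {
                "rdm": list(rdm_vec.direction),
                "com": list(com_vec.direction),
                "angle_rdm_com_deg": angle,
                "dipole_e_nm": list(dipole.dipole),
                "dipole_debye": dipole.dipole_debye,
                "net_charge_e": dipole.net_charge,
                "residues": list(iface.receptor_residues),
                "cutoff_nm": config.cutoff_nm,
            },
            indent=2,
        )
        + "\n"
    )
    emit(vectors_path)
    summary["angle_rdm_com_deg"] = angle

    # --- SMD configuration files ------------------------------------------
    direction = rdm_vec if config.direction_kind == "rdm" else com_vec
    smd = smd_config.SMDConfig(
        direction=direction,
        spring_constant_k=config.spring_constant_k,
        pull_speed_v=config.pull_speed_v,
        temperature=config.temperature,
        n_trajectories=config.n_trajectories,
        base_seed=config.base_seed,
    )
    mdp_dir = out / "mdp"
    mdp_dir.mkdir(exist_ok=True)
    for i in range(config.n_trajectories):
        p = mdp_dir / f"pull_{i:03d}.mdp"
        p.write_text(smd_config.emit_pull_mdp(smd, trajectory_index=i))
        emit(p)
    ndx_path = out / "index.ndx"
    ndx_path.write_text(
        smd_config.emit_index_groups(
            structure, [config.ligand_chain], list(config.receptor_chains)
        )
    )
    emit(ndx_path)

    # --- toy pulling simulation -------------------------------------------
    if config.run_toy_sim:
        d_pull = np.asarray(direction.direction, dtype=float)
        landscape = toy_pull_simulator.dipole_stabilized_landscape(d_pull)
        settings = toy_pull_simulator.PullSettings(gamma=50.0)
        dt = 0.05 * settings.gamma / (
            config.toy_sim_spring_k + landscape.max_curvature
        )
        stats = {}
        for label, d in (
            ("pull", d_pull),
            ("orthogonal", _orthogonal_unit(d_pull)),
        ):
            res = toy_pull_simulator.simulate_fmax_batch(
                landscape,
                d,
                v=config.toy_sim_speed,
                k=config.toy_sim_spring_k,
                temperature=config.temperature,
                dt=dt,
                seeds=[config.base_seed + i for i in range(config.n_trajectories)],
                max_time=toy_pull_simulator.rupture_anchor_travel(
                    landscape, d, config.toy_sim_spring_k
                )
                / config.toy_sim_speed,
                settings=settings,
            )
            st = rupture_analysis.aggregate_ruptures(res["f_max"], label=label)
            emit(st.save(out / f"rupture_stats_{label}.json"))
            tsv = out / f"fmax_{label}.tsv"
            with tsv.open("w") as fh:
                fh.write("trajectory\tf_max_kj_mol_nm\n")
                for i, fm in enumerate(res["f_max"]):
                    fh.write(f"{i}\t{fm:.6g}\n")
            emit(tsv)
            stats[label] = st
        comparison = rupture_analysis.compare_directions(
            stats["pull"], stats["orthogonal"]
        )
        cmp_path = out / "direction_comparison.json"
        cmp_path.write_text(json.dumps(comparison.to_dict(), indent=2) + "\n")
        emit(cmp_path)
        summary["mean_f_max_pull"] = stats["pull"].mean
        summary["mean_f_max_orthogonal"] = stats["orthogonal"].mean
        summary["mean_difference"] = comparison.mean_difference

    manifest = {
        "config": config.to_dict(portable=True),
        "summary": summary,
        "files": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(set(files))
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
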