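"""Emission of constant-velocity pulling configurations (GROMACS dialect).

The artifact emits the pull-code section of an mdp file plus ndx index
groups for an external MD engine; it never runs the engine itself.  The
protocol emitted matches common steered-MD practice for complex unbinding:
a harmonic spring of stiffness k (default 1000 kJ/mol/nm^2, about the upper
stiffness of an AFM cantilever) whose anchor moves at constant speed v
(default 1e-5 nm/ps = 10^7 nm/s) along a fixed unit vector, with the ligand
as the pulled group and the receptor as reference, at 310 K, repeated over
n_trajectories with per-trajectory velocity seeds.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .constants import PN_PER_NM_PER_KJ_MOL_NM2
from .pull_vectors import PullVector
from .structure_io import Structure, StructureError

__all__ = [
    "SMDConfig",
    "emit_pull_mdp",
    "parse_pull_mdp",
    "emit_index_groups",
    "spring_constant_pn_per_nm",
]

DEFAULT_SPRING_K = 1000.0  # kJ/(mol nm^2)
DEFAULT_PULL_SPEED = 1e-5  # nm/ps (= 10^7 nm/s)
DEFAULT_TEMPERATURE = 310.0  # K


@dataclasses.dataclass(frozen=True)
class SMDConfig:
    direction: PullVector
    spring_constant_k: float = DEFAULT_SPRING_K
    pull_speed_v: float = DEFAULT_PULL_SPEED
    pull_group: str = "ligand"
    reference_group: str = "receptor"
    temperature: float = DEFAULT_TEMPERATURE
    n_trajectories: int = 50
    base_seed: int = 1

    def __post_init__(self) -> None:
        if self.spring_constant_k <= 0:
            raise ValueError("spring constant must be positive")
        if self.pull_speed_v <= 0:
            raise ValueError("pulling speed must be positive")
        if self.n_trajectories < 1:
            raise ValueError("need at least one trajectory")
        norm = float(np.linalg.norm(self.direction.direction))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("pulling direction must be a unit vector")


_MDP_HEADER = """\
; Constant-velocity pulling (umbrella spring along a fixed vector).
; Companion run settings used with this protocol (not regenerated here):
;   integrator md, dt 0.002 ps, LINCS on all bonds, PME electrostatics,
;   1.4 nm non-bonded cutoff, v-rescale thermostat at the ref-t below,
;   initial velocities from a Maxwell distribution (gen-vel, gen-seed).
"""


def emit_pull_mdp(config: SMDConfig, trajectory_index: int = 0) -> str:
    """Render the pull-code mdp text for one trajectory; byte-deterministic.

    The per-trajectory velocity seed is ``base_seed + trajectory_index`` so a
    50-trajectory protocol is scriptable and reproducible.  Fields that the
    pull code itself does not carry (trajectory count, base seed) are stored
    in machine-readable meta comments so that :func:`parse_pull_mdp` is a
    full inverse.
    """
    if not 0 <= trajectory_index < config.n_trajectories:
        raise ValueError(
            f"trajectory index {trajectory_index} outside "
            f"[0, {config.n_trajectories})"
        )
    d = config.direction.direction
    seed = config.base_seed + trajectory_index
    lines = [
        _MDP_HEADER,
        f"; rdmpull-meta direction-kind = {config.direction.kind}",
        f"; rdmpull-meta n-trajectories = {config.n_trajectories}",
        f"; rdmpull-meta base-seed = {config.base_seed}",
        f"; rdmpull-meta trajectory-index = {trajectory_index}",
        "",
        f"ref-t                    = {config.temperature:g}",
        "gen-vel                  = yes",
        f"gen-temp                 = {config.temperature:g}",
        f"gen-seed                 = {seed}",
        "",
        "pull                     = yes",
        "pull-ngroups             = 2",
        "pull-ncoords             = 1",
        f"pull-group1-name         = {config.reference_group}",
        f"pull-group2-name         = {config.pull_group}",
        "pull-coord1-type         = umbrella",
        "pull-coord1-geometry     = direction",
        "pull-coord1-groups       = 1 2",
        f"pull-coord1-vec          = {d[0]:.17g} {d[1]:.17g} {d[2]:.17g}",
        f"pull-coord1-rate         = {config.pull_speed_v:g}",
        f"pull-coord1-k            = {config.spring_constant_k:g}",
        "pull-coord1-start        = yes",
        "",
    ]
    return "\n".join(lines)


def parse_pull_mdp(text: str) -> tuple[SMDConfig, int]:
    """Parse mdp text produced by :func:`emit_pull_mdp`.

    Returns the config and the trajectory index.  Round-trip identity with
    the emitter holds on all fields.
    """
    keys: dict[str, str] = {}
    meta: dict[str, str] = {}
    for raw in text.splitlines():
        line = raw.strip()
        if line.startswith("; rdmpull-meta"):
            k, _, v = line[len("; rdmpull-meta"):].partition("=")
            meta[k.strip()] = v.strip()
        elif line.startswith(";") or not line:
            continue
        else:
            k, _, v = line.partition("=")
            keys[k.strip()] = v.strip()
    try:
        vec = tuple(float(x) for x in keys["pull-coord1-vec"].split())
        direction = PullVector(
            direction=tuple(np.asarray(vec) / np.linalg.norm(vec)),
            kind=meta.get("direction-kind", "COM"),
        )
        config = SMDConfig(
            direction=direction,
            spring_constant_k=float(keys["pull-coord1-k"]),
            pull_speed_v=float(keys["pull-coord1-rate"]),
            pull_group=keys["pull-group2-name"],
            reference_group=keys["pull-group1-name"],
            temperature=float(keys["ref-t"]),
            n_trajectories=int(meta["n-trajectories"]),
            base_seed=int(meta["base-seed"]),
        )
        return config, int(meta["trajectory-index"])
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"mdp text lacks required key {exc}") from exc


def emit_index_groups(
    structure: Structure,
    pull_group: Sequence[str] | str,
    reference_group: Sequence[str] | str,
    pull_name: str = "ligand",
    reference_name: str = "receptor",
) -> str:
    """GROMACS ndx text with 1-based atom indices in file order, 15 per line."""
    if isinstance(pull_group, str):
        pull_group = [pull_group]
    if isinstance(reference_group, str):
        reference_group = [reference_group]
    if set(pull_group) & set(reference_group):
        raise StructureError("pull and reference groups overlap")

    def indices(chains: Sequence[str]) -> list[int]:
        chains = set(chains)
        unknown = chains - set(structure.chain_ids)
        if unknown:
            raise StructureError(f"unknown chain id(s) {sorted(unknown)}")
        out = [
            i + 1 for i, a in enumerate(structure.atoms) if a.chain_id in chains
        ]
        if not out:
            raise StructureError(f"empty index group for chains {sorted(chains)}")
        return out

    def block(name: str, idx: list[int]) -> str:
        rows = [
            " ".join(f"{i}" for i in idx[k : k + 15])
            for k in range(0, len(idx), 15)
        ]
        return f"[ {name} ]\n" + "\n".join(rows) + "\n"

    return block(reference_name, indices(reference_group)) + block(
        pull_name, indices(pull_group)
    )


def spring_constant_pn_per_nm(k: float) -> float:
    """Convert a spring constant from kJ/(mol nm^2) to pN/nm.

    1 kJ/(mol nm^2) = 1e24/N_A pN/nm ~= 1.660539, so the AFM-style default
    of 1000 kJ/(mol nm^2) is ~1660.5 pN/nm (1700 at two significant figures).
    """
    if k < 0:
        raise ValueError("spring constant must be non-negative")
    return k * PN_PER_NM_PER_KJ_MOL_NM2
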