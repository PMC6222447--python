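"""Pulling-direction vectors: resultant backbone dipole (RDM) and COM vector.

The resultant dipole moment is the net dipole of the backbone atoms
(N, H, CA, C, O) of the receptor residues that contact the bound peptide,

    mu = sum_i q_i (r_i - r0),

with united-atom backbone partial charges and r0 the centre of geometry of
the selection.  Because every backbone charge group is neutral the dipole is
origin independent; a non-neutral selection (clipped charge group) is flagged
instead of silently reported.  The dipole sign follows the physical
convention, pointing from net negative towards net positive charge.

The conventional alternative pulling direction is the unit vector from the
receptor centre of mass to the ligand centre of mass (the unbinding sense).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
from biotite.structure.info import mass as _biotite_mass

from .constants import DEBYE_PER_E_NM
from .structure_io import Atom, Structure, StructureError

__all__ = [
    "ChargeTable",
    "ChargedAtomSet",
    "DipoleResult",
    "PullVector",
    "ZeroDipoleError",
    "load_backbone_charges",
    "assign_backbone_charges",
    "resultant_dipole",
    "com_vector",
    "angle_between",
]

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "H", "CA", "C", "O")
NH_BOND_NM = 0.100  # ideal amide N-H bond length


class ZeroDipoleError(ValueError):
    """The selection has an exactly vanishing dipole; no direction exists."""


@dataclasses.dataclass(frozen=True)
class ChargeTable:
    """Per-residue-context backbone charges and charge-group definitions."""

    charges: Mapping[str, Mapping[str, float]]  # context -> atom_name -> e
    groups: Mapping[str, tuple[tuple[str, ...], ...]]

    def context_for(self, residue_name: str) -> str:
        return residue_name if residue_name in self.charges else "default"

    def charge(self, residue_name: str, atom_name: str) -> float:
        return self.charges[self.context_for(residue_name)][atom_name]

    def backbone_atoms(self, residue_name: str) -> tuple[str, ...]:
        return tuple(self.charges[self.context_for(residue_name)].keys())

    def validate_group_neutrality(self, tol: float = 1e-6) -> None:
        for ctx, groups in self.groups.items():
            for group in groups:
                total = sum(self.charges[ctx][a] for a in group)
                if abs(total) > tol:
                    raise ValueError(
                        f"charge group {group} of {ctx} not neutral ({total} e)"
                    )


def load_backbone_charges() -> ChargeTable:
    """Load the bundled GROMOS 43A1 backbone charge table."""
    raw = json.loads(
        resources.files("rdmpull.data")
        .joinpath("gromos43a1_backbone_charges.json")
        .read_text()
    )
    charges = {k: dict(v["charges"]) for k, v in raw.items() if k != "comment"}
    groups = {
        k: tuple(tuple(g) for g in v["groups"])
        for k, v in raw.items()
        if k != "comment"
    }
    table = ChargeTable(charges=charges, groups=groups)
    table.validate_group_neutrality()
    return table


@dataclasses.dataclass
class ChargedAtomSet:
    atoms: list[tuple[Atom, float]]
    net_charge: float
    origin: np.ndarray  # centre of geometry, nm

    def positions(self) -> np.ndarray:
        return np.array([a.position for a, _ in self.atoms])

    def charges(self) -> np.ndarray:
        return np.array([q for _, q in self.atoms])


@dataclasses.dataclass(frozen=True)
class DipoleResult:
    dipole: tuple[float, float, float]  # e nm
    dipole_debye: float
    unit_vector: tuple[float, float, float]
    net_charge: float
    origin_dependent: bool


@dataclasses.dataclass(frozen=True)
class PullVector:
    direction: tuple[float, float, float]
    kind: str  # "RDM" or "COM"
    source: Mapping[str, object] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        norm = float(np.linalg.norm(self.direction))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"pull vector not unit norm ({norm})")
        if self.kind not in ("RDM", "COM"):
            raise ValueError(f"unknown pull vector kind {self.kind!r}")


def _reconstruct_amide_h(
    n_pos: np.ndarray,
    ca_pos: np.ndarray,
    prev_c_pos: np.ndarray | None,
) -> np.ndarray:
    """Ideal amide H: 0.1 nm from N, in the peptide plane, anti to the
    preceding carbonyl (bisector of the C(prev)-N and CA-N directions)."""
    if prev_c_pos is not None:
        d = (n_pos - prev_c_pos) / np.linalg.norm(n_pos - prev_c_pos) + (
            n_pos - ca_pos
        ) / np.linalg.norm(n_pos - ca_pos)
    else:  # chain start: no preceding carbonyl to orient against
        d = n_pos - ca_pos
    norm = np.linalg.norm(d)
    if norm < 1e-9:
        raise StructureError("degenerate geometry while reconstructing amide H")
    return n_pos + NH_BOND_NM * d / norm


def assign_backbone_charges(
    structure: Structure,
    residues: Iterable[int],
    charge_table: ChargeTable | None = None,
    chains: Sequence[str] | None = None,
) -> ChargedAtomSet:
    """Select backbone atoms N, H, CA, C, O of ``residues`` and attach charges.

    Missing amide hydrogens (typical for X-ray / heavy-atom-only files) are
    reconstructed at the ideal geometry; proline contributes no amide H.
    Chain-terminal residues get interior-backbone charges with a logged
    warning (the table has no termini variants).
    """
    if charge_table is None:
        charge_table = load_backbone_charges()
    wanted = set(int(r) for r in residues)
    if not wanted:
        raise StructureError("empty residue selection")

    pool = structure.atoms
    if chains is not None:
        pool = [a for a in pool if a.chain_id in set(chains)]
    by_res: dict[tuple[str, int], dict[str, Atom]] = {}
    order: list[tuple[str, int]] = []
    for a in pool:
        key = (a.chain_id, a.residue_number)
        if key not in by_res:
            by_res[key] = {}
            order.append(key)
        by_res[key].setdefault(a.atom_name, a)

    missing = wanted - {r for _, r in by_res}
    if missing:
        raise StructureError(f"residues {sorted(missing)} not found in selection")

    result: list[tuple[Atom, float]] = []
    for chain, resnum in order:
        if resnum not in wanted:
            continue
        res_atoms = by_res[(chain, resnum)]
        name3 = next(iter(res_atoms.values())).residue_name
        needed = [n for n in ("N", "CA", "C", "O") if n not in res_atoms]
        if needed:
            raise StructureError(
                f"residue {chain}:{resnum} ({name3}) lacks backbone atoms {needed}"
            )
        if (chain, resnum - 1) not in by_res or (chain, resnum + 1) not in by_res:
            logger.warning(
                "residue %s:%d is chain-terminal; using interior backbone charges",
                chain,
                resnum,
            )
        for atom_name in charge_table.backbone_atoms(name3):
            q = charge_table.charge(name3, atom_name)
            if atom_name in res_atoms:
                result.append((res_atoms[atom_name], q))
            elif atom_name == "H":
                prev = by_res.get((chain, resnum - 1), {})
                prev_c = prev.get("C")
                h_pos = _reconstruct_amide_h(
                    np.asarray(res_atoms["N"].position),
                    np.asarray(res_atoms["CA"].position),
                    np.asarray(prev_c.position) if prev_c is not None else None,
                )
                result.append(
                    (
                        Atom(
                            chain_id=chain,
                            residue_number=resnum,
                            residue_name=name3,
                            atom_name="H",
                            element="H",
                            position=tuple(h_pos),
                        ),
                        q,
                    )
                )
            else:
                raise StructureError(
                    f"residue {chain}:{resnum} missing charged atom {atom_name}"
                )

    positions = np.array([a.position for a, _ in result])
    net = float(sum(q for _, q in result))
    return ChargedAtomSet(
        atoms=result, net_charge=net, origin=positions.mean(axis=0)
    )


def resultant_dipole(charged: ChargedAtomSet) -> DipoleResult:
    """Net dipole mu = sum q_i (r_i - origin) of a charged atom set, in e nm."""
    if not charged.atoms:
        raise StructureError("empty charged atom set")
    q = charged.charges()
    r = charged.positions() - charged.origin
    mu = q @ r
    magnitude = float(np.linalg.norm(mu))
    origin_dependent = abs(charged.net_charge) > 1e-6
    if origin_dependent:
        warnings.warn(
            f"selection carries net charge {charged.net_charge:.4g} e; "
            "dipole is origin dependent",
            stacklevel=2,
        )
    if magnitude == 0.0:
        raise ZeroDipoleError("selection has exactly zero dipole moment")
    return DipoleResult(
        dipole=tuple(mu),
        dipole_debye=magnitude * DEBYE_PER_E_NM,
        unit_vector=tuple(mu / magnitude),
        net_charge=charged.net_charge,
        origin_dependent=origin_dependent,
    )


def _atom_mass(atom: Atom, mass_table: Mapping[str, float] | None) -> float:
    if mass_table is not None and atom.element in mass_table:
        return float(mass_table[atom.element])
    m = _biotite_mass(atom.element, is_residue=False)
    if m is None or m == 0:
        raise StructureError(f"no atomic mass for element {atom.element!r}")
    return float(m)


def center_of_mass(
    atoms: Sequence[Atom], mass_table: Mapping[str, float] | None = None
) -> np.ndarray:
    """Mass-weighted mean position (nm) using standard atomic masses."""
    if not atoms:
        raise StructureError("empty selection for centre of mass")
    masses = np.array([_atom_mass(a, mass_table) for a in atoms])
    xyz = np.array([a.position for a in atoms])
    return masses @ xyz / masses.sum()


def com_vector(
    structure: Structure,
    receptor_chains: Sequence[str] | str,
    ligand_chain: Sequence[str] | str,
    mass_table: Mapping[str, float] | None = None,
) -> PullVector:
    """Unit vector from receptor COM towards ligand COM (unbinding sense)."""
    if isinstance(receptor_chains, str):
        receptor_chains = [receptor_chains]
    if isinstance(ligand_chain, str):
        ligand_chain = [ligand_chain]
    rec = structure.select_chains(receptor_chains).atoms
    lig = structure.select_chains(ligand_chain).atoms
    sep = center_of_mass(lig, mass_table) - center_of_mass(rec, mass_table)
    norm = float(np.linalg.norm(sep))
    if norm < 1e-12:
        raise StructureError("receptor and ligand centres of mass coincide")
    return PullVector(
        direction=tuple(sep / norm),
        kind="COM",
        source={
            "receptor_chains": list(receptor_chains),
            "ligand_chain": list(ligand_chain),
            "separation_nm": norm,
        },
    )


def rdm_vector(
    structure: Structure,
    receptor_chains: Sequence[str] | str,
    ligand_chain: Sequence[str] | str,
    cutoff_nm: float = 0.45,
    charge_table: ChargeTable | None = None,
    orient: str = "raw",
) -> tuple[PullVector, DipoleResult, "object"]:
    """Resultant-dipole pulling direction for a receptor/ligand complex.

    Convenience wrapper: detects the interface, charges its backbone and
    normalises the dipole.  ``orient`` controls the emitted pulling sense:
    ``raw`` keeps the physical (negative -> positive) dipole direction,
    ``flip`` negates it, and ``toward-ligand`` picks the sign whose dot
    product with the receptor->ligand COM vector is positive.
    """
    from .interface_detection import find_interface  # deferred: avoids cycle

    if isinstance(receptor_chains, str):
        receptor_chains = [receptor_chains]
    if isinstance(ligand_chain, str):
        ligand_chain = [ligand_chain]
    iface = find_interface(structure, receptor_chains, ligand_chain, cutoff_nm)
    if not iface.receptor_residues:
        raise StructureError(
            f"no interface residues at cutoff {cutoff_nm} nm; "
            "cannot define a dipole direction"
        )
    charged = assign_backbone_charges(
        structure, iface.receptor_residues, charge_table, chains=receptor_chains
    )
    dip = resultant_dipole(charged)
    direction = np.asarray(dip.unit_vector)
    if orient == "flip":
        direction = -direction
    elif orient == "toward-ligand":
        com = com_vector(structure, receptor_chains, ligand_chain)
        if float(direction @ np.asarray(com.direction)) < 0:
            direction = -direction
    elif orient != "raw":
        raise ValueError(f"unknown orient mode {orient!r}")
    vec = PullVector(
        direction=tuple(direction),
        kind="RDM",
        source={
            "receptor_chains": list(receptor_chains),
            "ligand_chain": list(ligand_chain),
            "cutoff_nm": cutoff_nm,
            "residues": list(iface.receptor_residues),
            "orient": orient,
        },
    )
    return vec, dip, iface


def angle_between(u: Sequence[float], v: Sequence[float]) -> float:
    """Angle between two vectors in degrees, in [0, 180]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise ValueError("angle undefined for zero vector")
    c = float(np.clip(u @ v / (nu * nv), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))
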