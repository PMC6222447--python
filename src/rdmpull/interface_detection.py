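"""Detection of receptor residues in contact with a bound peptide.

A receptor residue belongs to the interface iff the minimum distance between
any of its heavy atoms and any ligand heavy atom is within the cutoff
(default 0.45 nm, a common heavy-atom contact convention).  The atom set over
which the resultant backbone dipole is computed downstream is exactly this
residue list.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Atom, Structure, StructureError

__all__ = [
    "ContactPair",
    "InterfaceResult",
    "find_interface",
    "format_residue_ranges",
    "parse_residue_ranges",
]

DEFAULT_CUTOFF_NM = 0.45


@dataclasses.dataclass(frozen=True)
class ContactPair:
    receptor_atom: Atom
    ligand_atom: Atom
    distance_nm: float


@dataclasses.dataclass
class InterfaceResult:
    receptor_residues: list[int]
    ligand_residues: list[int]
    contact_pairs: list[ContactPair]
    cutoff_nm: float

    def __post_init__(self) -> None:
        for p in self.contact_pairs:
            if p.distance_nm > self.cutoff_nm + 1e-12:
                raise StructureError("contact pair beyond cutoff")


def _heavy_atoms(structure: Structure, chains: Iterable[str]) -> list[Atom]:
    chains = set(chains)
    return [
        a for a in structure.atoms if a.chain_id in chains and a.element != "H"
    ]


def find_interface(
    structure: Structure,
    receptor_chains: Sequence[str] | str,
    ligand_chain: Sequence[str] | str,
    cutoff_nm: float = DEFAULT_CUTOFF_NM,
) -> InterfaceResult:
    """All receptor residues with a heavy atom within ``cutoff_nm`` of the ligand.

    Uses a KD-tree for the neighbour search; the result is contractually
    identical to the all-pairs scan (tested) and sorted by residue number.
    """
    if isinstance(receptor_chains, str):
        receptor_chains = [receptor_chains]
    if isinstance(ligand_chain, str):
        ligand_chain = [ligand_chain]
    if set(receptor_chains) & set(ligand_chain):
        raise StructureError("receptor and ligand chain selections overlap")
    for c in list(receptor_chains) + list(ligand_chain):
        if c not in structure.chain_ids:
            raise StructureError(
                f"unknown chain id {c!r}; present: {structure.chain_ids}"
            )
    rec = _heavy_atoms(structure, receptor_chains)
    lig = _heavy_atoms(structure, ligand_chain)
    if not rec or not lig:
        raise StructureError("empty heavy-atom selection for receptor or ligand")

    rec_xyz = np.array([a.position for a in rec])
    lig_xyz = np.array([a.position for a in lig])
    pairs_idx = cKDTree(rec_xyz).query_ball_tree(cKDTree(lig_xyz), r=cutoff_nm)

    contact_pairs: list[ContactPair] = []
    rec_res: set[int] = set()
    lig_res: set[int] = set()
    for i, neighbours in enumerate(pairs_idx):
        for j in sorted(neighbours):
            dist = float(np.linalg.norm(rec_xyz[i] - lig_xyz[j]))
            if dist <= cutoff_nm:
                contact_pairs.append(ContactPair(rec[i], lig[j], dist))
                rec_res.add(rec[i].residue_number)
                lig_res.add(lig[j].residue_number)
    return InterfaceResult(
        receptor_residues=sorted(rec_res),
        ligand_residues=sorted(lig_res),
        contact_pairs=contact_pairs,
        cutoff_nm=cutoff_nm,
    )


def format_residue_ranges(residues: Iterable[int]) -> str:
    """Collapse sorted residue numbers to the conventional range string.

    ``{7..21, 25..29, 43}`` becomes ``"7–21, 25–29, 43"`` (en dash).
    """
    nums = sorted(set(int(r) for r in residues))
    if not nums:
        return ""
    runs: list[tuple[int, int]] = []
    start = prev = nums[0]
    for n in nums[1:]:
        if n == prev + 1:
            prev = n
        else:
            runs.append((start, prev))
            start = prev = n
    runs.append((start, prev))
    return ", ".join(f"{a}–{b}" if a != b else f"{a}" for a, b in runs)


def parse_residue_ranges(text: str) -> list[int]:
    """Inverse of :func:`format_residue_ranges`; accepts en dash or hyphen."""
    residues: set[int] = set()
    text = text.strip()
    if not text:
        return []
    for token in re.split(r"\s*,\s*", text):
        m = re.fullmatch(r"(-?\d+)\s*[–-]\s*(-?\d+)", token)
        if m:
            a, b = int(m.group(1)), int(m.group(2))
            if b < a:
                raise ValueError(f"descending range {token!r}")
            residues.update(range(a, b + 1))
        elif re.fullmatch(r"-?\d+", token):
            residues.add(int(token))
        else:
            raise ValueError(f"unparseable residue range token {token!r}")
    return sorted(residues)


def jaccard(a: Iterable[int], b: Iterable[int]) -> float:
    """Jaccard similarity of two residue sets (1.0 for identical sets)."""
    sa, sb = set(a), set(b)
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)
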