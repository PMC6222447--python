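"""PDB structure reading/writing, chain statistics and synthetic toy complexes.

Coordinates are stored in nanometres internally (PDB files are in Angstrom;
the conversion is exactly /10 on read and *10 on write).  Only one model of a
(possibly multi-model NMR) file is held at a time; model 1 is the reproducible
default.  HETATM records (waters, ions, ligand cofactors) are excluded by
default since they enter neither the backbone dipole nor the chain center of
mass definitions used downstream.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as _struc
import biotite.structure.io.pdb as _pdbio

__all__ = [
    "Atom",
    "Structure",
    "ToyComplexSpec",
    "ToyGroundTruth",
    "StructureError",
    "read_structure",
    "write_structure",
    "chain_lengths",
    "generate_toy_complex",
]

ANGSTROM_PER_NM = 10.0


class StructureError(ValueError):
    """Raised for unreadable, empty or inconsistent structural input."""


@dataclasses.dataclass(frozen=True)
class Atom:
    """One atom of one model, position in nm."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    position: tuple[float, float, float]
    insertion_code: str = ""

    @property
    def residue_key(self) -> str:
        """Author residue number with any insertion code appended."""
        return f"{self.residue_number}{self.insertion_code}"

    def __post_init__(self) -> None:
        if not self.element:
            raise StructureError(f"atom {self.atom_name} has empty element")
        if not np.all(np.isfinite(self.position)):
            raise StructureError(f"atom {self.atom_name} has non-finite position")


@dataclasses.dataclass
class Structure:
    """A single model of a (protein-peptide) complex."""

    model_index: int
    atoms: list[Atom]

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """(n, 3) array of positions in nm, in file order."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def select_chains(self, chains: Iterable[str]) -> "Structure":
        chains = set(chains)
        unknown = chains - set(self.chain_ids)
        if unknown:
            raise StructureError(
                f"unknown chain id(s) {sorted(unknown)}; present: {self.chain_ids}"
            )
        return Structure(
            self.model_index, [a for a in self.atoms if a.chain_id in chains]
        )

    def translated(self, shift: Sequence[float]) -> "Structure":
        s = np.asarray(shift, dtype=float)
        return Structure(
            self.model_index,
            [dataclasses.replace(a, position=tuple(np.add(a.position, s)))
             for a in self.atoms],
        )

    def rotated(self, rotation: np.ndarray) -> "Structure":
        """Apply a 3x3 rotation matrix about the origin."""
        r = np.asarray(rotation, dtype=float)
        return Structure(
            self.model_index,
            [dataclasses.replace(a, position=tuple(r @ np.asarray(a.position)))
             for a in self.atoms],
        )

    def validate(self) -> None:
        if not self.atoms:
            raise StructureError("structure has no atoms")
        seen: set[tuple[str, str, str]] = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_key, a.atom_name)
            if key in seen:
                raise StructureError(f"duplicate atom {key} in model")
            seen.add(key)


@dataclasses.dataclass(frozen=True)
class ToyComplexSpec:
    """Parameters of a generated two-chain complex with known ground truth.

    The receptor is an extended backbone of ``receptor_residue_count``
    residues (chain A) and the ligand a shorter parallel backbone (chain B)
    whose closest heavy-atom approach to the receptor equals
    ``binding_gap_nm``.  The whole complex is rigidly oriented so that the
    resultant backbone dipole of the receptor interface points exactly along
    ``placed_dipole_direction``.
    """

    receptor_residue_count: int = 10
    ligand_residue_count: int = 4
    binding_gap_nm: float = 0.30
    placed_dipole_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.receptor_residue_count < 1 or self.ligand_residue_count < 1:
            raise StructureError("residue counts must be >= 1")
        if self.binding_gap_nm <= 0:
            raise StructureError("binding gap must be positive")
        norm = float(np.linalg.norm(self.placed_dipole_direction))
        if abs(norm - 1.0) > 1e-9:
            raise StructureError(
                f"placed_dipole_direction must be unit norm (got {norm:.3g})"
            )


@dataclasses.dataclass(frozen=True)
class ToyGroundTruth:
    """What the generator planted, for closed-loop testing."""

    dipole_direction: tuple[float, float, float]
    interface_receptor_residues: tuple[int, ...]
    receptor_chain: str
    ligand_chain: str
    contact_cutoff_nm: float


def read_structure(
    path: str | Path,
    model_index: int = 1,
    include_hetero: bool = False,
) -> Structure:
    """Read one model of a PDB file into a :class:`Structure` (nm units).

    Alternate locations are resolved to the highest-occupancy conformer
    (ties: first encountered).  Raises distinct errors for a missing file,
    an absent model index, and a file without ATOM records.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"PDB file not found: {path}")
    pdb_file = _pdbio.PDBFile.read(str(path))
    n_models = pdb_file.get_model_count()
    if n_models == 0:
        raise StructureError(f"{path} contains no ATOM records")
    if not 1 <= model_index <= n_models:
        raise StructureError(
            f"model {model_index} not present in {path} ({n_models} model(s))"
        )
    arr = pdb_file.get_structure(model=model_index, altloc="occupancy")
    if not include_hetero:
        arr = arr[~arr.hetero]
    if arr.array_length() == 0:
        raise StructureError(f"{path} has no (non-HETATM) ATOM records")
    atoms = [
        Atom(
            chain_id=str(arr.chain_id[i]),
            residue_number=int(arr.res_id[i]),
            residue_name=str(arr.res_name[i]),
            atom_name=str(arr.atom_name[i]),
            element=str(arr.element[i]).capitalize(),
            position=tuple(arr.coord[i] / ANGSTROM_PER_NM),
            insertion_code=str(arr.ins_code[i]),
        )
        for i in range(arr.array_length())
    ]
    return Structure(model_index=model_index, atoms=atoms)


def write_structure(structure: Structure, path: str | Path) -> Path:
    """Write a structure as a single-model PDB file (coordinates nm -> A).

    Round-trips through :func:`read_structure` to PDB precision (0.001 A).
    Structures whose residue numbers exceed the fixed-width PDB field (9999)
    are rejected rather than silently renumbered.
    """
    structure.validate()
    n = len(structure.atoms)
    if any(a.residue_number > 9999 or a.residue_number < -999 for a in structure.atoms):
        raise StructureError("residue numbers outside the PDB fixed-width field")
    arr = _struc.AtomArray(n)
    arr.chain_id = np.array([a.chain_id for a in structure.atoms])
    arr.res_id = np.array([a.residue_number for a in structure.atoms])
    arr.ins_code = np.array([a.insertion_code for a in structure.atoms])
    arr.res_name = np.array([a.residue_name for a in structure.atoms])
    arr.atom_name = np.array([a.atom_name for a in structure.atoms])
    arr.element = np.array([a.element.upper() for a in structure.atoms])
    arr.hetero = np.zeros(n, dtype=bool)
    arr.coord = structure.coords() * ANGSTROM_PER_NM
    out = _pdbio.PDBFile()
    out.set_structure(arr)
    path = Path(path)
    out.write(str(path))
    return path


def chain_lengths(structure: Structure) -> dict[str, int]:
    """Number of distinct resolved residues per chain."""
    if not structure.atoms:
        raise StructureError("structure has no atoms")
    residues: dict[str, set[str]] = {}
    for a in structure.atoms:
        residues.setdefault(a.chain_id, set()).add(a.residue_key)
    return {c: len(s) for c, s in residues.items()}


# --- toy complex generation -------------------------------------------------

# Local backbone geometry of one pseudo-residue, nm, in its own frame.
# Bond lengths are ideal-geometry values (N-H 0.100 nm, C=O 0.123 nm).
_BACKBONE_TEMPLATE = {
    "N": np.array([-0.145, 0.050, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([0.145, 0.050, 0.0]),
    "O": np.array([0.145, 0.173, 0.0]),
    "H": np.array([-0.145, -0.050, 0.0]),
}
_CA_SPACING_NM = 0.38
_ELEMENT_OF = {"N": "N", "CA": "C", "C": "C", "O": "O", "H": "H"}


def _build_chain(
    chain_id: str,
    n_residues: int,
    origin: np.ndarray,
    rng: np.random.Generator,
    jitter_nm: float = 0.01,
) -> list[Atom]:
    atoms: list[Atom] = []
    for i in range(n_residues):
        base = origin + np.array([i * _CA_SPACING_NM, 0.0, 0.0])
        wobble = rng.normal(scale=jitter_nm, size=3)
        for name in ("N", "H", "CA", "C", "O"):
            pos = base + _BACKBONE_TEMPLATE[name] + wobble
            atoms.append(
                Atom(
                    chain_id=chain_id,
                    residue_number=i + 1,
                    residue_name="ALA",
                    atom_name=name,
                    element=_ELEMENT_OF[name],
                    position=tuple(pos),
                )
            )
    return atoms


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector u onto unit vector v."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = float(np.dot(u, v))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # 180 degrees: rotate about any axis orthogonal to u
        axis = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(u, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    w = np.cross(u, v)
    k = np.array(
        [[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]], dtype=float
    )
    return np.eye(3) + k + k @ k / (1.0 + c)


def generate_toy_complex(
    spec: ToyComplexSpec,
    contact_cutoff_nm: float = 0.45,
) -> tuple[Structure, ToyGroundTruth]:
    """Deterministically generate a two-chain backbone complex.

    Chain A (receptor) and chain B (ligand) are parallel extended backbones;
    the ligand sits against the middle of the receptor at a closest
    heavy-atom separation of exactly ``spec.binding_gap_nm``.  After
    assembly the interface residues and their resultant backbone dipole are
    measured with the package's own detectors, and the whole complex is
    rigidly rotated so that dipole points along
    ``spec.placed_dipole_direction`` — which therefore is the ground truth
    up to numerical precision.
    """
    from . import interface_detection, pull_vectors  # deferred: avoids cycle

    rng = np.random.default_rng(spec.seed)
    receptor = _build_chain("A", spec.receptor_residue_count, np.zeros(3), rng)
    # Centre the ligand along the receptor, offset in +y; exact gap enforced below.
    lig_x0 = (
        (spec.receptor_residue_count - spec.ligand_residue_count)
        / 2.0
        * _CA_SPACING_NM
    )
    ligand = _build_chain(
        "B", spec.ligand_residue_count, np.array([lig_x0, 1.0, 0.0]), rng
    )

    def _heavy(atoms: list[Atom]) -> np.ndarray:
        return np.array([a.position for a in atoms if a.element != "H"])

    d = np.min(
        np.linalg.norm(
            _heavy(receptor)[:, None, :] - _heavy(ligand)[None, :, :], axis=-1
        )
    )
    shift = np.array([0.0, spec.binding_gap_nm - d, 0.0])
    ligand = [
        dataclasses.replace(a, position=tuple(np.add(a.position, shift)))
        for a in ligand
    ]
    structure = Structure(model_index=1, atoms=receptor + ligand)
    structure.validate()

    iface = interface_detection.find_interface(
        structure, ["A"], "B", cutoff_nm=contact_cutoff_nm
    )
    iface_res = tuple(iface.receptor_residues)
    target = np.asarray(spec.placed_dipole_direction, dtype=float)
    if iface_res:
        charged = pull_vectors.assign_backbone_charges(
            structure, iface_res, chains=("A",)
        )
        dip = pull_vectors.resultant_dipole(charged)
        rot = _rotation_between(np.asarray(dip.unit_vector), target)
        structure = structure.rotated(rot)
    else:
        warnings.warn(
            "toy complex has no interface at the requested gap/cutoff; "
            "dipole direction cannot be planted",
            stacklevel=2,
        )
    truth = ToyGroundTruth(
        dipole_direction=tuple(target),
        interface_receptor_residues=iface_res,
        receptor_chain="A",
        ligand_chain="B",
        contact_cutoff_nm=contact_cutoff_nm,
    )
    return structure, truth
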