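"""Dipole and COM pulling vectors: charges, geometry, invariances."""

import dataclasses

import numpy as np
import pytest

from rdmpull.structure_io import Atom, Structure, ToyComplexSpec, generate_toy_complex
from rdmpull import pull_vectors as pv
from rdmpull.constants import DEBYE_PER_E_NM


def _backbone_residue(chain="A", resnum=2, name="ALA", offset=(0.0, 0.0, 0.0), with_h=True):
    """An interior-style residue with ideal-ish backbone geometry."""
    atoms = {
        "N": (-0.145, 0.05, 0.0),
        "H": (-0.145, -0.05, 0.0),
        "CA": (0.0, 0.0, 0.0),
        "C": (0.145, 0.05, 0.0),
        "O": (0.145, 0.173, 0.0),
    }
    if not with_h or name == "PRO":
        atoms.pop("H")
    out = []
    for atom_name, pos in atoms.items():
        element = atom_name[0]
        out.append(
            Atom(chain, resnum, name, atom_name, element, tuple(np.add(pos, offset)))
        )
    return out


def _flanked(center_atoms, resnum=2):
    """Add flanking residues so the centre one is interior."""
    prev = _backbone_residue(resnum=resnum - 1, offset=(-0.38, 0, 0))
    nxt = _backbone_residue(resnum=resnum + 1, offset=(0.38, 0, 0))
    return Structure(model_index=1, atoms=prev + center_atoms + nxt)


def test_charge_table_groups_are_neutral():
    table = pv.load_backbone_charges()
    table.validate_group_neutrality()  # raises on violation


def test_interior_alanine_has_five_neutral_backbone_atoms():
    s = _flanked(_backbone_residue())
    charged = pv.assign_backbone_charges(s, [2])
    assert len(charged.atoms) == 5
    assert charged.net_charge == pytest.approx(0.0, abs=1e-12)


def test_missing_amide_h_is_reconstructed_at_ideal_bond_length():
    s = _flanked(_backbone_residue(with_h=False))
    charged = pv.assign_backbone_charges(s, [2])
    names = [a.atom_name for a, _ in charged.atoms]
    assert "H" in names
    h = next(a for a, _ in charged.atoms if a.atom_name == "H")
    n = next(a for a, _ in charged.atoms if a.atom_name == "N" and a.residue_number == 2)
    assert np.linalg.norm(np.subtract(h.position, n.position)) == pytest.approx(
        0.100, abs=1e-6
    )
    assert h.element == "H"


def test_reconstructed_h_matches_independent_geometry():
    """Bisector construction cross-checked against an explicit computation."""
    s = _flanked(_backbone_residue(with_h=False))
    charged = pv.assign_backbone_charges(s, [2])
    h = next(a for a, _ in charged.atoms if a.atom_name == "H")
    n = np.array([-0.145, 0.05, 0.0])
    ca = np.array([0.0, 0.0, 0.0])
    prev_c = np.array([0.145 - 0.38, 0.05, 0.0])
    u = (n - prev_c) / np.linalg.norm(n - prev_c) + (n - ca) / np.linalg.norm(n - ca)
    expected = n + 0.1 * u / np.linalg.norm(u)
    np.testing.assert_allclose(h.position, expected, atol=1e-12)


def test_proline_contributes_no_amide_h():
    s = _flanked(_backbone_residue(name="PRO"))
    charged = pv.assign_backbone_charges(s, [2])
    assert len(charged.atoms) == 4
    assert "H" not in [a.atom_name for a, _ in charged.atoms]
    assert charged.net_charge == pytest.approx(0.0, abs=1e-12)


def test_missing_backbone_atom_is_an_error():
    atoms = [a for a in _backbone_residue() if a.atom_name != "O"]
    s = _flanked(atoms)
    with pytest.raises(Exception, match="lacks backbone"):
        pv.assign_backbone_charges(s, [2])


def test_two_point_dipole():
    charged = pv.ChargedAtomSet(
        atoms=[
            (Atom("A", 1, "X", "P", "H", (0.0, 0.0, 0.1)), +1.0),
            (Atom("A", 1, "X", "M", "H", (0.0, 0.0, 0.0)), -1.0),
        ],
        net_charge=0.0,
        origin=np.array([0.0, 0.0, 0.05]),
    )
    d = pv.resultant_dipole(charged)
    np.testing.assert_allclose(d.dipole, (0, 0, 0.1), atol=1e-15)
    np.testing.assert_allclose(d.unit_vector, (0, 0, 1), atol=1e-15)
    assert d.dipole_debye == pytest.approx(0.1 * DEBYE_PER_E_NM, rel=1e-6)
    assert d.dipole_debye == pytest.approx(0.1 * 48.0321, rel=1e-5)
    assert not d.origin_dependent


def test_neutral_set_dipole_is_translation_invariant(rng):
    n = 12
    charges = rng.normal(size=n)
    charges -= charges.mean()  # exactly neutral
    positions = rng.normal(size=(n, 3))

    def build(shift):
        atoms = [
            (Atom("A", 1, "X", f"Q{i}", "C", tuple(positions[i] + shift)), charges[i])
            for i in range(n)
        ]
        return pv.ChargedAtomSet(
            atoms=atoms,
            net_charge=float(charges.sum()),
            origin=(positions + shift).mean(axis=0),
        )

    d0 = pv.resultant_dipole(build(np.zeros(3)))
    d1 = pv.resultant_dipole(build(np.array([5.0, -3.0, 11.0])))
    np.testing.assert_allclose(d0.dipole, d1.dipole, atol=1e-9)


def test_dipole_matches_brute_force_sum(rng):
    """Independent oracle: plain sum(q_i * r_i) for a neutral set."""
    n = 30
    charges = rng.normal(size=n)
    charges -= charges.mean()
    positions = rng.normal(size=(n, 3))
    atoms = [
        (Atom("A", 1, "X", f"Q{i}", "C", tuple(positions[i])), charges[i])
        for i in range(n)
    ]
    charged = pv.ChargedAtomSet(
        atoms=atoms, net_charge=float(charges.sum()), origin=positions.mean(axis=0)
    )
    expected = charges @ positions  # origin drops out for a neutral set
    result = pv.resultant_dipole(charged)
    np.testing.assert_allclose(result.dipole, expected, rtol=1e-12, atol=1e-15)


def test_charged_selection_flagged_origin_dependent():
    charged = pv.ChargedAtomSet(
        atoms=[(Atom("A", 1, "X", "Q", "C", (1.0, 0.0, 0.0)), 1.0)],
        net_charge=1.0,
        origin=np.zeros(3),
    )
    with pytest.warns(UserWarning, match="net charge"):
        d = pv.resultant_dipole(charged)
    assert d.origin_dependent


def test_zero_dipole_raises():
    charged = pv.ChargedAtomSet(
        atoms=[
            (Atom("A", 1, "X", "P", "H", (0.0, 0.0, 0.0)), +1.0),
            (Atom("A", 1, "X", "M", "H", (0.0, 0.0, 0.0)), -1.0),
        ],
        net_charge=0.0,
        origin=np.zeros(3),
    )
    with pytest.raises(pv.ZeroDipoleError):
        pv.resultant_dipole(charged)


def test_com_vector_equal_point_masses():
    s = Structure(
        model_index=1,
        atoms=[
            Atom("A", 1, "GLY", "CA", "C", (0.0, 0.0, 0.0)),
            Atom("B", 1, "GLY", "CA", "C", (0.0, 0.0, 2.0)),
        ],
    )
    vec = pv.com_vector(s, "A", "B")
    np.testing.assert_allclose(vec.direction, (0, 0, 1), atol=1e-12)


def test_com_weighted_mean_matches_hand_computation():
    # ligand of C (12.011) and O (15.999): COM = weighted mean of positions
    s = Structure(
        model_index=1,
        atoms=[
            Atom("A", 1, "GLY", "CA", "C", (0.0, 0.0, 0.0)),
            Atom("B", 1, "LIG", "C1", "C", (1.0, 0.0, 0.0)),
            Atom("B", 1, "LIG", "O1", "O", (2.0, 0.0, 0.0)),
        ],
    )
    com = pv.center_of_mass([a for a in s.atoms if a.chain_id == "B"])
    expected = (12.011 * 1.0 + 15.999 * 2.0) / (12.011 + 15.999)
    assert com[0] == pytest.approx(expected, rel=1e-12)
    vec = pv.com_vector(s, "A", "B")
    np.testing.assert_allclose(vec.direction, (1, 0, 0), atol=1e-12)


def test_angle_between_basics():
    assert pv.angle_between((1, 0, 0), (1, 0, 0)) == pytest.approx(0.0)
    assert pv.angle_between((1, 0, 0), (0, 1, 0)) == pytest.approx(90.0)
    assert pv.angle_between((1, 0, 0), (-1, 0, 0)) == pytest.approx(180.0)
    with pytest.raises(ValueError):
        pv.angle_between((0, 0, 0), (1, 0, 0))


def test_printed_reference_vectors_nearly_orthogonal():
    """The published interface-dipole and COM directions for the calmodulin
    N-lobe / ER-alpha peptide complex differ by ~90.7 degrees."""
    rdm = (0.144, 0.983, -0.11)
    com = (0.193, 0.068, 0.979)
    assert pv.angle_between(rdm, com) == pytest.approx(90.75, abs=0.1)


def test_rotation_equivariance_of_both_vectors(toy_structure):
    theta = 1.1
    rot = np.array(
        [
            [np.cos(theta), 0, np.sin(theta)],
            [0, 1, 0],
            [-np.sin(theta), 0, np.cos(theta)],
        ]
    )
    rdm0, _, _ = pv.rdm_vector(toy_structure, ["A"], "B")
    com0 = pv.com_vector(toy_structure, ["A"], "B")
    moved = toy_structure.rotated(rot)
    rdm1, _, _ = pv.rdm_vector(moved, ["A"], "B")
    com1 = pv.com_vector(moved, ["A"], "B")
    np.testing.assert_allclose(rdm1.direction, rot @ np.asarray(rdm0.direction), atol=1e-9)
    np.testing.assert_allclose(com1.direction, rot @ np.asarray(com0.direction), atol=1e-9)


def test_translation_invariance_of_both_vectors(toy_structure):
    moved = toy_structure.translated([3.0, -1.0, 7.0])
    rdm0, _, _ = pv.rdm_vector(toy_structure, ["A"], "B")
    rdm1, _, _ = pv.rdm_vector(moved, ["A"], "B")
    com0 = pv.com_vector(toy_structure, ["A"], "B")
    com1 = pv.com_vector(moved, ["A"], "B")
    np.testing.assert_allclose(rdm1.direction, rdm0.direction, atol=1e-9)
    np.testing.assert_allclose(com1.direction, com0.direction, atol=1e-9)


def test_orient_modes():
    structure, _ = generate_toy_complex(ToyComplexSpec(seed=5))
    raw, _, _ = pv.rdm_vector(structure, ["A"], "B", orient="raw")
    flipped, _, _ = pv.rdm_vector(structure, ["A"], "B", orient="flip")
    np.testing.assert_allclose(flipped.direction, -np.asarray(raw.direction), atol=1e-12)
    toward, _, _ = pv.rdm_vector(structure, ["A"], "B", orient="toward-ligand")
    com = pv.com_vector(structure, ["A"], "B")
    assert np.dot(toward.direction, com.direction) >= 0
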