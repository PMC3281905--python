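"""Structure I/O, interface detection, contact classification, superposition."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from affmat.structures import (
    AtomRecord, Contact, PDBParseError, Structure, StructureError,
    classify_contacts, find_interface_residues, read_structure,
    read_structures, superpose, write_structure, apply_transform,
)
from affmat.synthetic import EnsembleSpec, ToyComplexSpec, make_ensemble, \
    make_toy_complex

MINIMAL_ATOM = (
    "ATOM      1  CA  GLY A   1      11.104  13.207   2.100  1.00  0.00"
    "           C\n")


class TestReadWrite:
    def test_minimal_single_atom_record(self):
        s = read_structure(MINIMAL_ATOM)
        assert len(s) == 1
        a = s.atoms[0]
        assert a.atom_name == "CA" and a.res_name == "GLY"
        assert a.chain_id == "A" and a.res_seq == 1
        assert a.xyz == pytest.approx((11.104, 13.207, 2.100))
        assert a.is_heavy

    def test_round_trip_preserves_coordinates(self, four_class_complex):
        text = write_structure(four_class_complex)
        back = read_structure(text)
        assert len(back) == len(four_class_complex)
        np.testing.assert_allclose(back.coords(), four_class_complex.coords(),
                                   atol=5.1e-4)  # PDB stores 3 decimals

    def test_ensemble_written_as_model_blocks(self, four_class_complex):
        ens = make_ensemble(EnsembleSpec(base=four_class_complex,
                                         n_snapshots=3, positional_sd=0.1,
                                         seed=1))
        text = write_structure(ens.structures())
        assert text.count("MODEL") == 3
        models = read_structures(text)
        assert len(models) == 3
        for model, snap in zip(models, ens.snapshots):
            np.testing.assert_allclose(model.coords(), snap, atol=5.1e-4)

    def test_malformed_record_names_line(self):
        bad = MINIMAL_ATOM + "ATOM      2  CB  GLY A   1      bad coords\n"
        with pytest.raises(PDBParseError, match="line 2"):
            read_structure(bad)

    def test_empty_input_rejected(self):
        with pytest.raises(PDBParseError):
            read_structure("")

    def test_duplicate_positions_rejected(self):
        dup = MINIMAL_ATOM + (
            "ATOM      2  CB  GLY A   1      11.104  13.207   2.100"
            "  1.00  0.00           C\n")
        with pytest.raises(PDBParseError):
            read_structure(dup)

    def test_empty_structure_rejected(self):
        with pytest.raises(StructureError):
            Structure([])

    def test_wide_chain_id_rejected_on_write(self):
        s = Structure([AtomRecord("AB", "GLY", 1, "CA", "C", (0., 0., 0.))])
        with pytest.raises(StructureError):
            write_structure(s)


class TestInterface:
    def test_beyond_cutoff_is_empty(self, point_structure_factory):
        s = point_structure_factory([
            ("A", "GLY", 1, "CA", "C", (0, 0, 0)),
            ("B", "GLY", 1, "CA", "C", (7.2, 0, 0)),
        ])
        assert find_interface_residues(s, ["A"], ["B"], 6.0) == []

    def test_matches_brute_force_scan(self, four_class_complex):
        s = four_class_complex
        contacts = find_interface_residues(s, ["A"], ["B"], 6.0)
        # independent O(N^2) oracle over heavy-atom pairs
        heavy_a = [a for a in s.atoms if a.chain_id == "A" and a.is_heavy]
        heavy_b = [a for a in s.atoms if a.chain_id == "B" and a.is_heavy]
        best = {}
        for aa in heavy_a:
            for ab in heavy_b:
                d = float(np.linalg.norm(np.subtract(aa.xyz, ab.xyz)))
                key = (aa.residue_key, ab.residue_key)
                if d <= 6.0 and d < best.get(key, np.inf):
                    best[key] = d
        assert {(c.residue_a, c.residue_b) for c in contacts} == set(best)
        for c in contacts:
            assert c.min_heavy_distance == pytest.approx(
                best[(c.residue_a, c.residue_b)], abs=1e-9)
        # planted pairs: exactly four contacts
        assert len(contacts) == 4

    def test_interface_is_symmetric(self, four_class_complex):
        ab = find_interface_residues(four_class_complex, ["A"], ["B"], 6.0)
        ba = find_interface_residues(four_class_complex, ["B"], ["A"], 6.0)
        assert {c.residue_b for c in ab} == {c.residue_a for c in ba}
        assert {c.residue_a for c in ab} == {c.residue_b for c in ba}

    def test_unknown_chain_rejected(self, four_class_complex):
        with pytest.raises(StructureError):
            find_interface_residues(four_class_complex, ["Q"], ["B"], 6.0)

    def test_nonpositive_cutoff_rejected(self, four_class_complex):
        with pytest.raises(StructureError):
            find_interface_residues(four_class_complex, ["A"], ["B"], 0.0)


class TestClassification:
    def test_planted_classes_recovered(self, four_class_complex):
        contacts = find_interface_residues(four_class_complex, ["A"], ["B"],
                                           6.0)
        classified = classify_contacts(four_class_complex, contacts)
        by_site = {c.residue_a[1]: c.contact_class for c in classified}
        assert by_site == {1: "salt_bridge", 2: "hbond", 3: "cation_pi",
                           4: "hydrophobic"}

    def test_order_independent_and_deterministic(self, four_class_complex):
        contacts = find_interface_residues(four_class_complex, ["A"], ["B"],
                                           6.0)
        forward = classify_contacts(four_class_complex, contacts)
        reverse = classify_contacts(four_class_complex, contacts[::-1])
        assert {(c.residue_a, c.contact_class) for c in forward} == \
               {(c.residue_a, c.contact_class) for c in reverse}
        again = classify_contacts(four_class_complex, contacts)
        assert [(c.residue_a, c.contact_class) for c in forward] == \
               [(c.residue_a, c.contact_class) for c in again]

    def test_missing_sidechain_atoms_still_classified(self,
                                                      four_class_complex):
        s = four_class_complex
        # drop the Glu carboxylate OE2: salt bridge must survive on OE1
        atoms = [a for a in s.atoms
                 if not (a.chain_id == "B" and a.res_seq == 1
                         and a.atom_name == "OE2")]
        pruned = Structure(atoms)
        contacts = find_interface_residues(pruned, ["A"], ["B"], 6.0)
        classified = classify_contacts(pruned, contacts)
        by_site = {c.residue_a[1]: c.contact_class for c in classified}
        assert by_site[1] == "salt_bridge"


def _rigid(structure, angle_deg, axis, translation):
    rot = Rotation.from_euler(axis, angle_deg, degrees=True).as_matrix()
    return structure.with_coords(structure.coords() @ rot.T
                                 + np.asarray(translation))


def _grid_rmsd_oracle(mobile, reference, step_deg=4.0):
    """Brute-force: min RMSD over an Euler-angle grid, centroids aligned."""
    xm = mobile - mobile.mean(axis=0)
    xr = reference - reference.mean(axis=0)
    angles = np.arange(0.0, 360.0, step_deg)
    half = np.arange(0.0, 180.0 + step_deg, step_deg)
    best = np.inf
    for a in angles:
        for b in half:
            for c in angles:
                rot = Rotation.from_euler("zyz", [a, b, c],
                                          degrees=True).as_matrix()
                r = np.sqrt(np.mean(np.sum((xm @ rot.T - xr) ** 2, axis=1)))
                best = min(best, r)
    return best


class TestSuperposition:
    @staticmethod
    def _ca_square():
        atoms = [AtomRecord("A", "GLY", i + 1, "CA", "C", xyz) for i, xyz in
                 enumerate([(0., 0., 0.), (3.8, 0., 0.), (3.8, 3.8, 0.),
                            (0., 3.8, 0.)])]
        return Structure(atoms)

    def test_identity_gives_zero_rmsd(self, four_class_complex):
        res = superpose(four_class_complex, four_class_complex,
                        atom_names=None)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)

    def test_rigid_motion_recovered(self, four_class_complex):
        moved = _rigid(four_class_complex, 90, "z", (5.0, -3.0, 2.0))
        res = superpose(moved, four_class_complex, atom_names=None)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        restored = apply_transform(moved, res)
        np.testing.assert_allclose(restored.coords(),
                                   four_class_complex.coords(), atol=1e-8)

    @pytest.mark.parametrize("angle,axis,shift", [
        (37.0, "x", (1, 2, 3)), (120.0, "y", (-4, 0, 9)),
        (275.0, "z", (0.5, -0.5, 10.0)),
    ])
    def test_rmsd_invariant_under_rigid_motion(self, four_class_complex,
                                               angle, axis, shift):
        mobile = _rigid(four_class_complex, 15, "y", (1, 1, 1))
        base = superpose(mobile, four_class_complex, atom_names=None).rmsd
        moved = _rigid(mobile, angle, axis, shift)
        again = superpose(moved, four_class_complex, atom_names=None).rmsd
        assert abs(base - again) < 1e-6

    def test_single_displaced_atom_matches_grid_oracle(self):
        ref = self._ca_square()
        coords = ref.coords().copy()
        coords[0] += np.array([0.0, 0.0, 1.0])  # displace one CA by 1 A
        mobile = ref.with_coords(coords)
        res = superpose(mobile, ref, atom_names=["CA"])
        oracle = _grid_rmsd_oracle(mobile.coords(), ref.coords())
        assert res.n_atoms_used == 4
        # Kabsch must match the brute-force rotation grid (grid is coarser)
        assert res.rmsd <= oracle + 1e-9
        assert res.rmsd == pytest.approx(oracle, abs=5e-3)
        # the optimal fit beats the naive no-fit value sqrt(1/4) = 0.5 A
        assert res.rmsd <= 0.5

    def test_too_few_atoms_rejected(self, point_structure_factory):
        s = point_structure_factory([
            ("A", "GLY", 1, "CA", "C", (0, 0, 0)),
            ("A", "GLY", 2, "CA", "C", (3.8, 0, 0)),
        ])
        with pytest.raises(StructureError, match=">=3"):
            superpose(s, s)

    def test_residue_mismatch_requires_index_pairing(
            self, point_structure_factory):
        square = [(0, 0, 0), (3.8, 0, 0), (3.8, 3.8, 0), (0, 3.8, 0)]
        a = point_structure_factory([
            ("A", "GLY", i + 1, "CA", "C", xyz)
            for i, xyz in enumerate(square)])
        b = point_structure_factory([
            ("A", "ALA", i + 1, "CA", "C", xyz)
            for i, xyz in enumerate(square)])
        with pytest.raises(StructureError, match="mismatch"):
            superpose(a, b)
        res = superpose(a, b, pair_by_index=True)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
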