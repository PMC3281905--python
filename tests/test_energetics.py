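"""Coulomb/LJ group energies, H-bond counting, ensemble deltas, additivity."""

import math

import numpy as np
import pytest

from affmat.energetics import (
    ANGSTROM_TO_NM, COULOMB_CONSTANT, EnergeticsError, EnergyDecomposition,
    Ensemble, HBondCriteria, additivity, coulomb_energy, count_hbonds,
    delta_decomposition, ensemble_energy, lj_energy, water_interaction,
)
from affmat.forcefield import ForceFieldError, default_forcefield
from affmat.synthetic import EnsembleSpec, ToyComplexSpec, make_ensemble, \
    make_toy_complex


def two_charges(r_nm, q1=1.0, q2=1.0, point_structure_factory=None,
                point_charge_ff_factory=None):
    s = point_structure_factory([
        ("A", "ION", 1, "X1", "N", (0, 0, 0)),
        ("B", "ION", 2, "X2", "N", (r_nm / ANGSTROM_TO_NM, 0, 0)),
    ])
    ff = point_charge_ff_factory({
        ("ION", "X1"): (q1, 0.3, 0.5), ("ION", "X2"): (q2, 0.3, 0.5)})
    return s, ff


class TestCoulomb:
    def test_two_unit_charges_at_one_nm(self, point_structure_factory,
                                        point_charge_ff_factory):
        s, ff = two_charges(1.0, 1.0, 1.0, point_structure_factory,
                            point_charge_ff_factory)
        e = coulomb_energy(s, [0], [1], ff)
        assert e == pytest.approx(COULOMB_CONSTANT, rel=1e-12)

    def test_zero_charges_give_zero(self, point_structure_factory,
                                    point_charge_ff_factory):
        s, ff = two_charges(1.0, 0.0, 0.0, point_structure_factory,
                            point_charge_ff_factory)
        assert coulomb_energy(s, [0], [1], ff) == 0.0

    def test_matches_brute_force_pair_sum(self, point_structure_factory,
                                          point_charge_ff_factory):
        rng = np.random.default_rng(11)
        coords = rng.uniform(0, 15, size=(5, 3))
        charges = rng.uniform(-1, 1, size=5)
        entries = [("A" if i < 3 else "B", "ION", i + 1, f"X{i}", "N",
                    tuple(coords[i])) for i in range(5)]
        s = point_structure_factory(entries)
        ff = point_charge_ff_factory({
            ("ION", f"X{i}"): (charges[i], 0.3, 0.5) for i in range(5)})
        expected = 0.0
        for i in range(3):
            for j in range(3, 5):
                r = np.linalg.norm(coords[i] - coords[j]) * ANGSTROM_TO_NM
                expected += COULOMB_CONSTANT * charges[i] * charges[j] / r
        got = coulomb_energy(s, [0, 1, 2], [3, 4], ff)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_symmetric_and_bilinear(self, point_structure_factory,
                                    point_charge_ff_factory):
        s, ff = two_charges(0.7, 0.4, -0.8, point_structure_factory,
                            point_charge_ff_factory)
        e_ab = coulomb_energy(s, [0], [1], ff)
        e_ba = coulomb_energy(s, [1], [0], ff)
        assert e_ab == pytest.approx(e_ba, rel=1e-12)
        ff2 = point_charge_ff_factory({
            ("ION", "X1"): (0.8, 0.3, 0.5), ("ION", "X2"): (-0.8, 0.3, 0.5)})
        assert coulomb_energy(s, [0], [1], ff2) == pytest.approx(2 * e_ab,
                                                                 rel=1e-12)

    def test_overlapping_groups_rejected(self, point_structure_factory,
                                         point_charge_ff_factory):
        s, ff = two_charges(1.0, 1.0, 1.0, point_structure_factory,
                            point_charge_ff_factory)
        with pytest.raises(EnergeticsError, match="overlap"):
            coulomb_energy(s, [0, 1], [1], ff)

    def test_unparameterized_atom_named(self, point_structure_factory,
                                        forcefield):
        s = point_structure_factory([
            ("A", "XYZ", 1, "Q1", "C", (0, 0, 0)),
            ("B", "GLY", 2, "CA", "C", (5, 0, 0))])
        with pytest.raises(ForceFieldError, match="XYZ"):
            coulomb_energy(s, [0], [1], forcefield)


class TestLennardJones:
    def _pair(self, r_nm, sigma, eps, psf, pcf):
        s = psf([("A", "ION", 1, "X1", "C", (0, 0, 0)),
                 ("B", "ION", 2, "X2", "C", (r_nm / ANGSTROM_TO_NM, 0, 0))])
        ff = pcf({("ION", "X1"): (0.0, sigma, eps),
                  ("ION", "X2"): (0.0, sigma, eps)})
        return s, ff

    def test_zero_at_sigma(self, point_structure_factory,
                           point_charge_ff_factory):
        s, ff = self._pair(0.34, 0.34, 0.8, point_structure_factory,
                           point_charge_ff_factory)
        assert lj_energy(s, [0], [1], ff) == pytest.approx(0.0, abs=1e-12)

    def test_minimum_minus_epsilon(self, point_structure_factory,
                                   point_charge_ff_factory):
        sigma, eps = 0.34, 0.8
        s, ff = self._pair(2 ** (1 / 6) * sigma, sigma, eps,
                           point_structure_factory, point_charge_ff_factory)
        assert lj_energy(s, [0], [1], ff) == pytest.approx(-eps, rel=1e-12)

    def test_matches_brute_force_pair_sum(self, point_structure_factory,
                                          point_charge_ff_factory):
        rng = np.random.default_rng(5)
        coords = rng.uniform(0, 12, size=(6, 3))
        sig = rng.uniform(0.25, 0.4, size=6)
        eps = rng.uniform(0.1, 1.0, size=6)
        s = point_structure_factory([
            ("A" if i < 2 else "B", "ION", i + 1, f"X{i}", "C",
             tuple(coords[i])) for i in range(6)])
        ff = point_charge_ff_factory({
            ("ION", f"X{i}"): (0.0, sig[i], eps[i]) for i in range(6)})
        expected = 0.0
        for i in range(2):
            for j in range(2, 6):
                r = np.linalg.norm(coords[i] - coords[j]) * ANGSTROM_TO_NM
                s_ij = 0.5 * (sig[i] + sig[j])
                e_ij = math.sqrt(eps[i] * eps[j])
                expected += 4 * e_ij * ((s_ij / r) ** 12 - (s_ij / r) ** 6)
        got = lj_energy(s, [0, 1], [2, 3, 4, 5], ff)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_coincident_atoms_rejected(self, point_structure_factory,
                                       point_charge_ff_factory):
        s = point_structure_factory([
            ("A", "ION", 1, "X1", "C", (0, 0, 0)),
            ("B", "ION", 2, "X2", "C", (3, 0, 0))])
        ff = point_charge_ff_factory({("ION", "X1"): (0, 0.3, 0.5),
                                      ("ION", "X2"): (0, 0.3, 0.5)})
        snap = np.zeros((2, 3))
        with pytest.raises(EnergeticsError, match="zero"):
            lj_energy(s, [0], [1], ff, snapshot=snap)


class TestOracleEquivalence:
    def test_vectorized_equals_naive_double_loop(self, forcefield,
                                                 four_class_complex):
        """On a <=200-atom protein system the kernels must reproduce a
        naive double loop to 1e-9 relative tolerance."""
        s = four_class_complex
        idx_a = [i for i, a in enumerate(s.atoms) if a.chain_id == "A"]
        idx_b = [i for i, a in enumerate(s.atoms) if a.chain_id == "B"]
        assert len(s.atoms) <= 200
        coords = s.coords()
        e_c = e_lj = 0.0
        for i in idx_a:
            qi, si, ei = forcefield.lookup(s.atoms[i].res_name,
                                           s.atoms[i].atom_name)
            for j in idx_b:
                qj, sj, ej = forcefield.lookup(s.atoms[j].res_name,
                                               s.atoms[j].atom_name)
                r = np.linalg.norm(coords[i] - coords[j]) * ANGSTROM_TO_NM
                e_c += COULOMB_CONSTANT * qi * qj / r
                s_ij = 0.5 * (si + sj)
                eps_ij = math.sqrt(ei * ej)
                e_lj += 4 * eps_ij * ((s_ij / r) ** 12 - (s_ij / r) ** 6)
        assert coulomb_energy(s, idx_a, idx_b, forcefield) == \
            pytest.approx(e_c, rel=1e-9)
        assert lj_energy(s, idx_a, idx_b, forcefield) == \
            pytest.approx(e_lj, rel=1e-9)

    def test_additive_over_group_partition(self, forcefield,
                                           four_class_complex):
        s = four_class_complex
        idx_a = [i for i, a in enumerate(s.atoms) if a.chain_id == "A"]
        idx_b = [i for i, a in enumerate(s.atoms) if a.chain_id == "B"]
        half = len(idx_a) // 2
        total = coulomb_energy(s, idx_a, idx_b, forcefield)
        split = (coulomb_energy(s, idx_a[:half], idx_b, forcefield)
                 + coulomb_energy(s, idx_a[half:], idx_b, forcefield))
        assert total == pytest.approx(split, rel=1e-12)


def _hbond_system(point_structure_factory, d_a_dist, angle_deg):
    """Planted N-H...O geometry with a controllable H-D-A angle."""
    theta = math.radians(angle_deg)
    h = (1.0 * math.cos(theta), 1.0 * math.sin(theta), 0.0)
    return point_structure_factory([
        ("A", "GLY", 1, "N", "N", (0, 0, 0)),
        ("A", "GLY", 1, "H", "H", h),
        ("B", "GLY", 2, "O", "O", (d_a_dist, 0, 0)),
    ])


class TestHBondCounting:
    def test_ideal_geometry_counts_one(self, point_structure_factory):
        s = _hbond_system(point_structure_factory, 2.9, 5.0)
        assert count_hbonds(s, [0], [2]) == 1

    def test_beyond_distance_cutoff(self, point_structure_factory):
        s = _hbond_system(point_structure_factory, 4.0, 5.0)
        assert count_hbonds(s, [0], [2]) == 0

    def test_angle_violation_counts_out(self, point_structure_factory):
        """Three planted bonds, one with a bent hydrogen: brute force says 2."""
        entries = []
        for k, angle in enumerate((5.0, 10.0, 60.0)):
            theta = math.radians(angle)
            z = 10.0 * k
            entries += [
                ("A", "GLY", k + 1, "N", "N", (0, 0, z)),
                ("A", "GLY", k + 1, "H", "H",
                 (math.cos(theta), math.sin(theta), z)),
                ("B", "GLY", k + 1, "O", "O", (2.9, 0, z)),
            ]
        s = point_structure_factory(entries)
        donors = [0, 3, 6]
        acceptors = [2, 5, 8]
        # independent triple loop with the 0.35 nm / 30 degree rule
        crit = HBondCriteria()
        coords = s.coords()
        expected = 0
        for d, h in ((0, 1), (3, 4), (6, 7)):
            for a in acceptors:
                v_da = coords[a] - coords[d]
                dist = np.linalg.norm(v_da) * ANGSTROM_TO_NM
                if dist > crit.da_max_nm:
                    continue
                v_dh = coords[h] - coords[d]
                cosang = v_da @ v_dh / (np.linalg.norm(v_da)
                                        * np.linalg.norm(v_dh))
                if math.degrees(math.acos(cosang)) <= crit.hda_max_deg:
                    expected += 1
        assert expected == 2
        assert count_hbonds(s, donors, acceptors) == 2

    def test_missing_hydrogens_instruct_distance_mode(
            self, point_structure_factory):
        s = point_structure_factory([
            ("A", "GLY", 1, "N", "N", (0, 0, 0)),
            ("B", "GLY", 2, "O", "O", (2.9, 0, 0))])
        with pytest.raises(EnergeticsError, match="distance_only"):
            count_hbonds(s, [0], [1])
        assert count_hbonds(s, [0], [1], distance_only=True) == 1


class TestEnsembleAveraging:
    def test_single_snapshot_mean_is_identity(self, forcefield,
                                              four_class_complex):
        ens = Ensemble(topology=four_class_complex,
                       snapshots=[four_class_complex.coords()])
        idx_a = [i for i, a in enumerate(four_class_complex.atoms)
                 if a.chain_id == "A"]
        idx_b = [i for i, a in enumerate(four_class_complex.atoms)
                 if a.chain_id == "B"]
        c, lj, hb = ensemble_energy(ens, idx_a, idx_b, forcefield)
        assert c == pytest.approx(
            coulomb_energy(four_class_complex, idx_a, idx_b, forcefield))

    def test_antisymmetric_snapshots_average_to_zero(
            self, point_structure_factory, point_charge_ff_factory):
        # B holds +1 and -1 charges; swapping their distances flips the sign
        s = point_structure_factory([
            ("A", "ION", 1, "X0", "N", (0, 0, 0)),
            ("B", "ION", 2, "XP", "N", (5, 0, 0)),
            ("B", "ION", 3, "XM", "N", (10, 0, 0))])
        ff = point_charge_ff_factory({
            ("ION", "X0"): (1.0, 0.0, 0.0), ("ION", "XP"): (1.0, 0.0, 0.0),
            ("ION", "XM"): (-1.0, 0.0, 0.0)})
        snap1 = np.array([[0, 0, 0], [5, 0, 0], [10, 0, 0]], dtype=float)
        snap2 = np.array([[0, 0, 0], [10, 0, 0], [5, 0, 0]], dtype=float)
        e1 = coulomb_energy(s, [0], [1, 2], ff, snap1)
        e2 = coulomb_energy(s, [0], [1, 2], ff, snap2)
        assert e1 == pytest.approx(-e2, rel=1e-12)
        ens = Ensemble(topology=s, snapshots=[snap1, snap2])
        c, _, _ = ensemble_energy(ens, [0], [1, 2], ff,
                                  distance_only_hbonds=True)
        assert c == pytest.approx(0.0, abs=1e-12)

    def test_perturbed_mean_consistent_with_base(self, forcefield,
                                                 four_class_complex):
        """Monte-Carlo check: 50 perturbed snapshots average near the
        unperturbed Coulomb energy (within 3 standard errors)."""
        ens = make_ensemble(EnsembleSpec(base=four_class_complex,
                                         n_snapshots=50, positional_sd=0.05,
                                         seed=42))
        idx_a = [i for i, a in enumerate(four_class_complex.atoms)
                 if a.chain_id == "A"]
        idx_b = [i for i, a in enumerate(four_class_complex.atoms)
                 if a.chain_id == "B"]
        values = [coulomb_energy(ens.topology, idx_a, idx_b, forcefield, sn)
                  for sn in ens.snapshots]
        base = coulomb_energy(four_class_complex, idx_a, idx_b, forcefield)
        se = np.std(values, ddof=1) / math.sqrt(len(values))
        assert abs(np.mean(values) - base) < 3 * se + 0.05 * abs(base)

    def test_empty_ensemble_rejected(self, four_class_complex):
        with pytest.raises(EnergeticsError):
            Ensemble(topology=four_class_complex, snapshots=[])


class TestDeltaDecomposition:
    def test_self_difference_is_exactly_zero(self, forcefield,
                                             four_class_complex):
        ens = make_ensemble(EnsembleSpec(base=four_class_complex,
                                         n_snapshots=4, positional_sd=0.2,
                                         seed=9))
        d = delta_decomposition(ens, ens, [("A", 1)], "B", forcefield)
        assert (d.delta_coulomb, d.delta_lj, d.delta_hb) == (0.0, 0.0, 0.0)

    def test_added_charge_pair_analytic(self, point_structure_factory,
                                        point_charge_ff_factory):
        """A mutant adding one +1/-1 contact at 0.5 nm shifts the Coulomb
        term by exactly -f/0.5."""
        base = [("A", "ION", 1, "XQ", "N", (0, 0, 0)),
                ("B", "ION", 1, "XT", "N", (5, 0, 0))]
        s_wt = point_structure_factory(base)
        s_mut = point_structure_factory(base)
        ff_wt = point_charge_ff_factory({
            ("ION", "XQ"): (0.0, 0.0, 0.0), ("ION", "XT"): (-1.0, 0.0, 0.0)})
        ff_mut = point_charge_ff_factory({
            ("ION", "XQ"): (1.0, 0.0, 0.0), ("ION", "XT"): (-1.0, 0.0, 0.0)})
        wt_ens = Ensemble(topology=s_wt, snapshots=[s_wt.coords()])
        mut_ens = Ensemble(topology=s_mut, snapshots=[s_mut.coords()])
        e_mut = coulomb_energy(s_mut, [0], [1], ff_mut)
        e_wt = coulomb_energy(s_wt, [0], [1], ff_wt)
        assert e_mut - e_wt == pytest.approx(-COULOMB_CONSTANT / 0.5,
                                             rel=1e-12)

    def test_planted_extra_hbond_gives_plus_one(self,
                                                point_structure_factory,
                                                forcefield):
        wt = _hbond_system(point_structure_factory, 5.0, 5.0)  # too far
        mut = _hbond_system(point_structure_factory, 2.9, 5.0)  # bonded
        wt_ens = Ensemble(topology=wt, snapshots=[wt.coords()] * 3)
        mut_ens = Ensemble(topology=mut, snapshots=[mut.coords()] * 3)
        d = delta_decomposition(mut_ens, wt_ens, [("A", 1)], "B", forcefield)
        assert d.delta_hb == pytest.approx(1.0)

    def test_missing_site_rejected(self, forcefield, four_class_complex):
        ens = Ensemble(topology=four_class_complex,
                       snapshots=[four_class_complex.coords()])
        with pytest.raises(EnergeticsError):
            delta_decomposition(ens, ens, [("A", 99)], "B", forcefield)


class TestAdditivity:
    def test_perfectly_additive_triple_is_zero(self):
        a = EnergyDecomposition(-3.0, 1.0, 0.5)
        b = EnergyDecomposition(-2.0, -1.5, 0.25)
        x = EnergyDecomposition(-5.0, -0.5, 0.75)
        extra = additivity(x, a, b)
        assert extra == {"coulomb": 0.0, "lj": 0.0, "hb": 0.0}

    def test_antisymmetric_under_composite_swap(self):
        a = EnergyDecomposition(-1.49, -4.97, 0.0)
        b = EnergyDecomposition(-26.10, 3.93, 0.35)
        x = EnergyDecomposition(-32.28, -1.75, 0.50)
        extra = additivity(x, a, b)
        composite = EnergyDecomposition(a.delta_coulomb + b.delta_coulomb,
                                        a.delta_lj + b.delta_lj,
                                        a.delta_hb + b.delta_hb)
        swapped = additivity(composite, x, EnergyDecomposition(0.0, 0.0, 0.0))
        for k in extra:
            assert extra[k] == pytest.approx(-swapped[k], rel=1e-12)


class TestWaterInteraction:
    def test_waterless_ensemble_rejected(self, forcefield,
                                         four_class_complex):
        ens = Ensemble(topology=four_class_complex,
                       snapshots=[four_class_complex.coords()])
        with pytest.raises(EnergeticsError, match="water"):
            water_interaction(ens, ("A", 1), forcefield)

    def test_single_tip3p_water_analytic(self, point_structure_factory,
                                         point_charge_ff_factory):
        """Unit charge 1 nm from a TIP3P water: three-term Coulomb sum."""
        from affmat.forcefield import _WATER_PARAMS

        water_o = np.array([10.0, 0.0, 0.0])
        h1 = water_o + np.array([0.9572, 0, 0])
        h2 = water_o + np.array([-0.2399872, 0.92662721, 0])
        s = point_structure_factory([
            ("A", "ION", 1, "XQ", "N", (0, 0, 0)),
            ("W", "HOH", 1, "O", "O", tuple(water_o)),
            ("W", "HOH", 1, "H1", "H", tuple(h1)),
            ("W", "HOH", 1, "H2", "H", tuple(h2))])
        ff = point_charge_ff_factory({
            ("ION", "XQ"): (1.0, 0.0, 0.0),
            ("HOH", "O"): _WATER_PARAMS["O"],
            ("HOH", "H1"): _WATER_PARAMS["H1"],
            ("HOH", "H2"): _WATER_PARAMS["H2"]})
        ens = Ensemble(topology=s, snapshots=[s.coords()])
        got = water_interaction(ens, ("A", 1), ff)
        expected = COULOMB_CONSTANT * (
            -0.834 / 1.0
            + 0.417 / (np.linalg.norm(h1) * ANGSTROM_TO_NM)
            + 0.417 / (np.linalg.norm(h2) * ANGSTROM_TO_NM))
        assert got == pytest.approx(expected, rel=1e-12)
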