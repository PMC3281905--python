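"""Group-group nonbonded energies and hydrogen-bond counts over ensembles.

Implements the energetic readout used to rationalize affinity changes:
pairwise Coulomb and Lennard-Jones energies between two atom groups
(direct sums, no cutoff, no periodicity), geometric hydrogen-bond
counting, ensemble (snapshot) averaging, mutant-minus-wild-type
decomposition restricted to the mutated residues, and the double-mutant
additivity statistic.

Units: coordinates are Angstrom at the module boundary and converted to
nm internally; energies are kJ/mol throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from . import residues as rc
from .forcefield import ForceFieldTable
from .structures import Structure, StructureError

__all__ = [
    "COULOMB_CONSTANT", "ANGSTROM_TO_NM",
    "Ensemble", "EnergyDecomposition", "HBondCriteria", "EnergeticsError",
    "coulomb_energy", "lj_energy", "count_hbonds", "ensemble_energy",
    "delta_decomposition", "additivity", "water_interaction",
]

#: Electric conversion factor f = 1/(4 pi eps0) in kJ mol^-1 nm e^-2.
COULOMB_CONSTANT = 138.935485

ANGSTROM_TO_NM = 0.1


class EnergeticsError(ValueError):
    """Invalid groups, missing parameters, or degenerate geometry."""


@dataclass
class HBondCriteria:
    """Geometric hydrogen-bond criteria (defaults: 0.35 nm, 30 degrees)."""

    da_max_nm: float = 0.35
    hda_max_deg: float = 30.0


@dataclass
class Ensemble:
    """Snapshots sharing one topology.

    ``topology`` defines atom identities and ordering; each snapshot is an
    (n_atoms, 3) coordinate array in Angstrom congruent with it.
    """

    topology: Structure
    snapshots: List[np.ndarray]

    def __post_init__(self) -> None:
        if not self.snapshots:
            raise EnergeticsError("an Ensemble needs at least one snapshot")
        n = len(self.topology.atoms)
        snaps = []
        for i, snap in enumerate(self.snapshots):
            arr = np.asarray(snap, dtype=float)
            if arr.shape != (n, 3):
                raise EnergeticsError(
                    f"snapshot {i} has shape {arr.shape}, expected ({n}, 3)")
            snaps.append(arr)
        self.snapshots = snaps

    def __len__(self) -> int:
        return len(self.snapshots)

    @classmethod
    def from_structures(cls, models: Sequence[Structure]) -> "Ensemble":
        if not models:
            raise EnergeticsError("empty model list")
        ref = models[0]
        names = [(a.chain_id, a.res_seq, a.atom_name) for a in ref.atoms]
        for m in models[1:]:
            if [(a.chain_id, a.res_seq, a.atom_name) for a in m.atoms] != names:
                raise EnergeticsError("models do not share one topology")
        return cls(topology=ref, snapshots=[m.coords() for m in models])

    def structures(self) -> List[Structure]:
        return [self.topology.with_coords(s) for s in self.snapshots]


@dataclass
class EnergyDecomposition:
    """Mutant-minus-wild-type interaction-energy changes.

    ``delta_coulomb``/``delta_lj`` in kJ/mol, ``delta_hb`` as a change in
    mean hydrogen-bond count, for the mutated-residue group against the
    target chain, averaged over ``n_snapshots`` snapshots.
    """

    delta_coulomb: float
    delta_lj: float
    delta_hb: float
    selection: str = ""
    n_snapshots: int = 1

    def __post_init__(self) -> None:
        for name in ("delta_coulomb", "delta_lj", "delta_hb"):
            if not math.isfinite(getattr(self, name)):
                raise EnergeticsError(f"{name} is not finite")
        if self.n_snapshots < 1:
            raise EnergeticsError("n_snapshots must be >= 1")


# ---------------------------------------------------------------------------
# Pairwise energies
# ---------------------------------------------------------------------------

def _check_groups(group_a: Sequence[int], group_b: Sequence[int],
                  n_atoms: int) -> Tuple[np.ndarray, np.ndarray]:
    ia = np.asarray(list(group_a), dtype=int)
    ib = np.asarray(list(group_b), dtype=int)
    if ia.size == 0 or ib.size == 0:
        raise EnergeticsError("atom groups must be non-empty")
    if ia.max(initial=-1) >= n_atoms or ib.max(initial=-1) >= n_atoms:
        raise EnergeticsError("atom index out of range")
    if set(ia.tolist()) & set(ib.tolist()):
        raise EnergeticsError("atom groups overlap")
    return ia, ib


def _params(top: Structure, idx: np.ndarray, ff: ForceFieldTable):
    q = np.empty(idx.size)
    sigma = np.empty(idx.size)
    eps = np.empty(idx.size)
    for k, i in enumerate(idx):
        a = top.atoms[i]
        q[k], sigma[k], eps[k] = ff.lookup(a.res_name, a.atom_name)
    return q, sigma, eps


def _coords(top: Structure, snapshot: Optional[np.ndarray]) -> np.ndarray:
    if snapshot is None:
        return top.coords()
    arr = np.asarray(snapshot, dtype=float)
    if arr.shape != (len(top.atoms), 3):
        raise EnergeticsError(
            f"snapshot shape {arr.shape} incompatible with topology")
    return arr


def coulomb_energy(top: Structure, group_a: Sequence[int],
                   group_b: Sequence[int], ff: ForceFieldTable,
                   snapshot: Optional[np.ndarray] = None) -> float:
    """Coulomb energy between two disjoint atom groups (kJ/mol).

    E = f * sum_{i in A, j in B} q_i q_j / r_ij with r in nm and
    f = 138.935485 kJ mol^-1 nm e^-2; direct sum, no cutoff.
    """
    ia, ib = _check_groups(group_a, group_b, len(top.atoms))
    coords = _coords(top, snapshot)
    qa, _, _ = _params(top, ia, ff)
    qb, _, _ = _params(top, ib, ff)
    r_nm = cdist(coords[ia], coords[ib]) * ANGSTROM_TO_NM
    if np.any(r_nm < 1e-9):
        raise EnergeticsError("zero interatomic distance between groups")
    return float(COULOMB_CONSTANT * np.sum(np.outer(qa, qb) / r_nm))


def lj_energy(top: Structure, group_a: Sequence[int],
              group_b: Sequence[int], ff: ForceFieldTable,
              snapshot: Optional[np.ndarray] = None) -> float:
    """Lennard-Jones 12-6 energy between two disjoint atom groups (kJ/mol).

    Lorentz-Berthelot combination: sigma_ij = (sigma_i + sigma_j)/2,
    eps_ij = sqrt(eps_i eps_j); direct sum, no cutoff.
    """
    ia, ib = _check_groups(group_a, group_b, len(top.atoms))
    coords = _coords(top, snapshot)
    _, sa, ea = _params(top, ia, ff)
    _, sb, eb = _params(top, ib, ff)
    r_nm = cdist(coords[ia], coords[ib]) * ANGSTROM_TO_NM
    if np.any(r_nm < 1e-9):
        raise EnergeticsError("zero interatomic distance between groups")
    sigma_ij = 0.5 * (sa[:, None] + sb[None, :])
    eps_ij = np.sqrt(np.outer(ea, eb))
    sr6 = (sigma_ij / r_nm) ** 6
    return float(np.sum(4.0 * eps_ij * (sr6 ** 2 - sr6)))


# ---------------------------------------------------------------------------
# Hydrogen-bond counting
# ---------------------------------------------------------------------------

def _donor_map(top: Structure, indices: Iterable[int]) -> List[Tuple[int, List[int]]]:
    """(donor heavy atom index, attached polar-H indices) within a group."""
    by_residue: Dict[Tuple[str, int], Dict[str, int]] = {}
    for i, a in enumerate(top.atoms):
        by_residue.setdefault((a.chain_id, a.res_seq), {})[a.atom_name] = i
    donors = []
    for i in indices:
        a = top.atoms[i]
        res_atoms = by_residue[(a.chain_id, a.res_seq)]
        for source in ("backbone", a.res_name):
            hydrogens = rc.DONORS.get(source, {}).get(a.atom_name)
            if hydrogens is None:
                continue
            h_idx = [res_atoms[h] for h in hydrogens if h in res_atoms]
            donors.append((i, h_idx))
    return donors


def _acceptor_indices(top: Structure, indices: Iterable[int]) -> List[int]:
    out = []
    for i in indices:
        a = top.atoms[i]
        for source in ("backbone", a.res_name):
            if a.atom_name in rc.ACCEPTORS.get(source, ()):
                out.append(i)
                break
    return out


def count_hbonds(top: Structure, donor_group: Sequence[int],
                 acceptor_group: Sequence[int],
                 snapshot: Optional[np.ndarray] = None,
                 criteria: Optional[HBondCriteria] = None,
                 distance_only: bool = False) -> int:
    """Count donor->acceptor hydrogen bonds between two groups.

    A (D, A) pair counts as bonded when the D-A distance is at most
    ``criteria.da_max_nm`` and the H-D-A angle of some hydrogen attached
    to D is at most ``criteria.hda_max_deg``.  Without hydrogens in the
    topology an error is raised unless ``distance_only=True``, which
    falls back to the distance criterion alone.
    """
    crit = criteria or HBondCriteria()
    coords = _coords(top, snapshot)
    donors = _donor_map(top, donor_group)
    acceptors = _acceptor_indices(top, acceptor_group)
    if not donors or not acceptors:
        return 0
    if not distance_only and all(not h for _, h in donors):
        raise EnergeticsError(
            "no hydrogens present on donor atoms; pass distance_only=True "
            "to count on the distance criterion alone")
    da_max_A = crit.da_max_nm / ANGSTROM_TO_NM
    cos_min = math.cos(math.radians(crit.hda_max_deg))
    count = 0
    for d_idx, h_idx in donors:
        pd_ = coords[d_idx]
        for a_idx in acceptors:
            if a_idx == d_idx:
                continue
            pa = coords[a_idx]
            v_da = pa - pd_
            dist = float(np.linalg.norm(v_da))
            if dist > da_max_A or dist < 1e-6:
                continue
            if distance_only or not h_idx:
                if distance_only:
                    count += 1
                continue
            for h in h_idx:
                v_dh = coords[h] - pd_
                denom = dist * float(np.linalg.norm(v_dh))
                if denom < 1e-12:
                    continue
                if float(np.dot(v_da, v_dh)) / denom >= cos_min:
                    count += 1
                    break
    return count


# ---------------------------------------------------------------------------
# Ensemble averaging and decomposition
# ---------------------------------------------------------------------------

def ensemble_energy(ens: Ensemble, group_a: Sequence[int],
                    group_b: Sequence[int], ff: ForceFieldTable,
                    hbond_criteria: Optional[HBondCriteria] = None,
                    distance_only_hbonds: bool = False,
                    ) -> Tuple[float, float, float]:
    """Snapshot-averaged (Coulomb, LJ, hydrogen-bond count) between groups.

    Hydrogen bonds are counted in both donor/acceptor directions between
    the two groups, per snapshot, and averaged with uniform weights.
    """
    coul, lj, hb = [], [], []
    for snap in ens.snapshots:
        coul.append(coulomb_energy(ens.topology, group_a, group_b, ff, snap))
        lj.append(lj_energy(ens.topology, group_a, group_b, ff, snap))
        n_ab = count_hbonds(ens.topology, group_a, group_b, snap,
                            hbond_criteria, distance_only=distance_only_hbonds)
        n_ba = count_hbonds(ens.topology, group_b, group_a, snap,
                            hbond_criteria, distance_only=distance_only_hbonds)
        hb.append(n_ab + n_ba)
    return float(np.mean(coul)), float(np.mean(lj)), float(np.mean(hb))


def _site_group(top: Structure, sites: Sequence[Tuple[str, int]]) -> List[int]:
    group: List[int] = []
    for chain_id, res_seq in sites:
        idx = top.atom_indices(chain_id=chain_id, res_seq=res_seq)
        if not idx:
            raise EnergeticsError(
                f"site ({chain_id}, {res_seq}) not present in topology")
        group.extend(idx)
    return group


def _chain_group(top: Structure, chain_id: str) -> List[int]:
    idx = top.atom_indices(chain_id=chain_id)
    if not idx:
        raise EnergeticsError(f"target chain {chain_id!r} not in topology")
    return idx


def delta_decomposition(mut_ens: Ensemble, wt_ens: Ensemble,
                        mutated_sites: Sequence[Tuple[str, int]],
                        target_chain: str, ff: ForceFieldTable,
                        hbond_criteria: Optional[HBondCriteria] = None,
                        distance_only_hbonds: bool = False,
                        ) -> EnergyDecomposition:
    """Mutant-minus-wild-type energy decomposition for the mutated residues.

    Group A holds all atoms of the mutated sites (mutant residues in the
    mutant ensemble, the corresponding wild-type residues in the wild-type
    ensemble); group B holds every atom of the target chain.  Returns the
    change (mutant minus wild type) in mean Coulomb, LJ and hydrogen-bond
    count.
    """
    results = []
    for ens in (mut_ens, wt_ens):
        group_a = _site_group(ens.topology, mutated_sites)
        group_b = _chain_group(ens.topology, target_chain)
        results.append(ensemble_energy(
            ens, group_a, group_b, ff, hbond_criteria,
            distance_only_hbonds=distance_only_hbonds))
    (c_mut, l_mut, h_mut), (c_wt, l_wt, h_wt) = results
    sel = "+".join(f"{c}:{r}" for c, r in mutated_sites)
    return EnergyDecomposition(
        delta_coulomb=c_mut - c_wt, delta_lj=l_mut - l_wt,
        delta_hb=h_mut - h_wt,
        selection=f"sites[{sel}] vs chain {target_chain}",
        n_snapshots=min(len(mut_ens), len(wt_ens)))


def additivity(double: EnergyDecomposition, single1: EnergyDecomposition,
               single2: EnergyDecomposition) -> Dict[str, float]:
    """Super-additivity of a double mutant: double - (single1 + single2).

    Negative Coulomb/LJ values mean the double mutant is stabilized
    beyond the sum of its constituent single mutations.
    """
    return {
        "coulomb": double.delta_coulomb - (single1.delta_coulomb
                                           + single2.delta_coulomb),
        "lj": double.delta_lj - (single1.delta_lj + single2.delta_lj),
        "hb": double.delta_hb - (single1.delta_hb + single2.delta_hb),
    }


def water_interaction(ens: Ensemble, residue: Tuple[str, int],
                      ff: ForceFieldTable) -> float:
    """Mean Coulomb energy between one residue and all waters (kJ/mol)."""
    top = ens.topology
    water_idx = [i for i, a in enumerate(top.atoms) if a.res_name == rc.WATER]
    if not water_idx:
        raise EnergeticsError("ensemble contains no water (HOH) residues")
    res_idx = _site_group(top, [residue])
    values = [coulomb_energy(top, res_idx, water_idx, ff, snap)
              for snap in ens.snapshots]
    return float(np.mean(values))
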