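"""Coordinate I/O, rigid-body superposition and interface geometry.

Structures are ordered collections of atom records (coordinates in
Angstrom).  PDB reading/writing is delegated to biotite behind this
module's surface; interface detection and geometric contact
classification (salt bridge / hydrogen bond / cation-pi / hydrophobic)
are implemented here with explicit, config-overridable thresholds.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from . import residues as rc

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord", "Structure", "Contact", "SuperpositionResult",
    "ContactCriteria", "StructureError", "PDBParseError",
    "read_structure", "read_structures", "write_structure",
    "find_interface_residues", "classify_contacts", "superpose",
    "contacts_to_frame",
]


class StructureError(ValueError):
    """Invalid structure content or operation preconditions."""


class PDBParseError(StructureError):
    """Malformed PDB input; carries the offending line number."""


ResidueKey = Tuple[str, int, str]  # (chain_id, res_seq, res_name)


@dataclass(frozen=True)
class AtomRecord:
    """One atom: chain, residue identity, atom name, element, position (A)."""

    chain_id: str
    res_name: str
    res_seq: int
    atom_name: str
    element: str
    xyz: Tuple[float, float, float]

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.res_seq, self.res_name)


@dataclass
class Structure:
    """Ordered atom records forming one model of a (complex) structure."""

    atoms: List[AtomRecord]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError("a Structure must contain at least one atom")
        seen = set()
        for a in self.atoms:
            key = (a.chain_id, a.res_seq, a.atom_name)
            if key in seen:
                raise StructureError(f"duplicate atom {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> Tuple[str, ...]:
        out: List[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return tuple(out)

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray, label: Optional[str] = None) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise StructureError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(self.atoms)} atoms")
        atoms = [replace(a, xyz=tuple(float(x) for x in xyz))
                 for a, xyz in zip(self.atoms, coords)]
        return Structure(atoms, label=label if label is not None else self.label)

    def residues(self, chain_ids: Optional[Iterable[str]] = None) -> List[ResidueKey]:
        wanted = set(chain_ids) if chain_ids is not None else None
        out: List[ResidueKey] = []
        for a in self.atoms:
            if wanted is not None and a.chain_id not in wanted:
                continue
            if not out or out[-1] != a.residue_key:
                if a.residue_key not in out:
                    out.append(a.residue_key)
        return out

    def atom_indices(self, chain_id: Optional[str] = None,
                     res_seq: Optional[int] = None,
                     heavy_only: bool = False) -> List[int]:
        idx = []
        for i, a in enumerate(self.atoms):
            if chain_id is not None and a.chain_id != chain_id:
                continue
            if res_seq is not None and a.res_seq != res_seq:
                continue
            if heavy_only and not a.is_heavy:
                continue
            idx.append(i)
        return idx

    def residue_atoms(self, chain_id: str, res_seq: int) -> List[AtomRecord]:
        return [a for a in self.atoms
                if a.chain_id == chain_id and a.res_seq == res_seq]


@dataclass
class Contact:
    """A residue pair across the interface with its minimum heavy-atom distance."""

    residue_a: ResidueKey
    residue_b: ResidueKey
    min_heavy_distance: float
    contact_class: str = "unclassified"


@dataclass
class SuperpositionResult:
    rmsd: float
    rotation: np.ndarray
    translation: np.ndarray
    n_atoms_used: int


@dataclass
class ContactCriteria:
    """Geometric thresholds for contact classification.

    Standard literature values; every threshold can be overridden.
    """

    salt_bridge_max: float = 4.0          # A, charged N/O pair
    hbond_da_max: float = 3.5             # A, donor-acceptor heavy atoms
    hbond_dha_min_deg: float = 150.0      # D-H...A angle when H present
    cation_pi_max: float = 6.0            # A, cation to ring centroid
    cation_pi_angle_deg: float = 45.0     # tilt from ring normal
    hydrophobic_max: float = 4.5          # A, apolar carbon pair


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _prevalidate_pdb(text: str) -> None:
    """Check fixed-width coordinate fields so errors can name the line."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line[:6] not in ("ATOM  ", "HETATM"):
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: truncated coordinate record")
        try:
            float(line[30:38]); float(line[38:46]); float(line[46:54])
            int(line[22:26])
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: malformed fixed-width field "
                                f"({exc})") from None


def _atom_array_to_structure(arr: "bst.AtomArray", label: str) -> Structure:
    atoms = []
    for i in range(arr.array_length()):
        element = str(arr.element[i]).capitalize() or "X"
        atoms.append(AtomRecord(
            chain_id=str(arr.chain_id[i]),
            res_name=str(arr.res_name[i]),
            res_seq=int(arr.res_id[i]),
            atom_name=str(arr.atom_name[i]),
            element=element,
            xyz=tuple(float(x) for x in arr.coord[i]),
        ))
    return Structure(atoms, label=label)


def read_structures(pdb_text: str, label: str = "") -> List[Structure]:
    """Parse PDB text into one Structure per MODEL.

    Waters are retained (residue HOH); alternate locations are resolved
    to the highest-occupancy conformer (ties by altloc letter order).
    Raises :class:`PDBParseError` naming the line for malformed records.
    """
    if not pdb_text.strip():
        raise PDBParseError("empty PDB input")
    _prevalidate_pdb(pdb_text)
    pdb_file = PDBFile.read(io.StringIO(pdb_text))
    n_models = pdb_file.get_model_count()
    if n_models == 0:
        raise PDBParseError("no ATOM/HETATM records found")
    out = []
    for m in range(1, n_models + 1):
        arr = pdb_file.get_structure(model=m, altloc="occupancy")
        model_label = label if n_models == 1 else f"{label}[model {m}]"
        s = _atom_array_to_structure(arr, model_label)
        # reject exact duplicate positions (zero inter-atomic distance)
        coords = s.coords()
        tree = cKDTree(coords)
        pairs = tree.query_pairs(1e-6)
        if pairs:
            i, j = sorted(pairs)[0]
            raise PDBParseError(
                f"atoms {s.atoms[i].atom_name}/{s.atoms[j].atom_name} at "
                f"identical coordinates (residues {s.atoms[i].residue_key} "
                f"and {s.atoms[j].residue_key})")
        out.append(s)
    return out


def read_structure(pdb_text: str, label: str = "") -> Structure:
    """Parse single-model PDB text (first MODEL of a multi-model file)."""
    return read_structures(pdb_text, label=label)[0]


def _structure_to_atom_array(s: Structure) -> "bst.AtomArray":
    n = len(s.atoms)
    arr = bst.AtomArray(n)
    for i, a in enumerate(s.atoms):
        if len(a.chain_id) > 1:
            raise StructureError(
                f"chain id {a.chain_id!r} exceeds the 1-character PDB field")
        arr.chain_id[i] = a.chain_id
        arr.res_id[i] = a.res_seq
        arr.res_name[i] = a.res_name
        arr.atom_name[i] = a.atom_name
        arr.element[i] = a.element.upper()
        arr.coord[i] = a.xyz
        arr.hetero[i] = a.res_name not in rc.THREE_TO_ONE
    return arr


def write_structure(s: Structure | Sequence[Structure]) -> str:
    """Serialize a Structure (or a sequence of congruent Structures as
    one multi-MODEL ensemble) to PDB-dialect text.

    Round-trips coordinates at the format's 3-decimal precision.
    """
    if isinstance(s, Structure):
        arrays = _structure_to_atom_array(s)
    else:
        models = list(s)
        if not models:
            raise StructureError("cannot write an empty model list")
        stack = bst.stack([_structure_to_atom_array(m) for m in models])
        arrays = stack
    pdb_file = PDBFile()
    pdb_file.set_structure(arrays)
    buf = io.StringIO()
    pdb_file.write(buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Interface detection
# ---------------------------------------------------------------------------

def find_interface_residues(s: Structure,
                            chain_set_a: Iterable[str],
                            chain_set_b: Iterable[str],
                            cutoff: float = 6.0) -> List[Contact]:
    """Residue pairs across two chain sets within a heavy-atom distance cutoff.

    For every residue pair (a in A-side chains, b in B-side chains) whose
    minimum heavy-atom/heavy-atom distance is <= ``cutoff`` (A), one
    Contact is emitted with that minimum distance, sorted by the A-side
    residue.  Hydrogens are excluded from the distance criterion.
    """
    if cutoff <= 0:
        raise StructureError(f"cutoff must be positive, got {cutoff}")
    set_a, set_b = list(dict.fromkeys(chain_set_a)), list(dict.fromkeys(chain_set_b))
    present = set(s.chains)
    for cid in (*set_a, *set_b):
        if cid not in present:
            raise StructureError(f"chain {cid!r} not present in structure "
                                 f"(has {sorted(present)})")
    if set(set_a) & set(set_b):
        raise StructureError("chain sets must be disjoint")

    idx_a = [i for i in range(len(s.atoms))
             if s.atoms[i].chain_id in set_a and s.atoms[i].is_heavy]
    idx_b = [i for i in range(len(s.atoms))
             if s.atoms[i].chain_id in set_b and s.atoms[i].is_heavy]
    if not idx_a or not idx_b:
        return []
    coords = s.coords()
    tree_a = cKDTree(coords[idx_a])
    tree_b = cKDTree(coords[idx_b])
    pairs = tree_a.query_ball_tree(tree_b, r=cutoff)

    best: Dict[Tuple[ResidueKey, ResidueKey], float] = {}
    for ia_local, neighbors in enumerate(pairs):
        if not neighbors:
            continue
        atom_a = s.atoms[idx_a[ia_local]]
        pa = coords[idx_a[ia_local]]
        for ib_local in neighbors:
            atom_b = s.atoms[idx_b[ib_local]]
            d = float(np.linalg.norm(pa - coords[idx_b[ib_local]]))
            key = (atom_a.residue_key, atom_b.residue_key)
            if d < best.get(key, np.inf):
                best[key] = d

    contacts = [Contact(residue_a=ka, residue_b=kb, min_heavy_distance=d)
                for (ka, kb), d in best.items()]
    contacts.sort(key=lambda c: (c.residue_a[0], c.residue_a[1],
                                 c.residue_b[0], c.residue_b[1]))
    return contacts


# ---------------------------------------------------------------------------
# Contact classification
# ---------------------------------------------------------------------------

def _residue_atom_map(s: Structure, key: ResidueKey) -> Dict[str, AtomRecord]:
    return {a.atom_name: a for a in s.residue_atoms(key[0], key[1])}


def _pairs_within(atoms_a: List[AtomRecord], atoms_b: List[AtomRecord],
                  cutoff: float):
    for aa in atoms_a:
        pa = np.array(aa.xyz)
        for ab in atoms_b:
            d = float(np.linalg.norm(pa - np.array(ab.xyz)))
            if d <= cutoff:
                yield aa, ab, d


def _is_salt_bridge(map_a, map_b, name_a, name_b, crit: ContactCriteria) -> bool:
    for pos_map, pos_name, neg_map, neg_name in (
            (map_a, name_a, map_b, name_b), (map_b, name_b, map_a, name_a)):
        pos_atoms = [pos_map[n] for n in rc.POSITIVE_ATOMS.get(pos_name, ())
                     if n in pos_map]
        neg_atoms = [neg_map[n] for n in rc.NEGATIVE_ATOMS.get(neg_name, ())
                     if n in neg_map]
        for _ in _pairs_within(pos_atoms, neg_atoms, crit.salt_bridge_max):
            return True
    return False


def _donor_atoms(res_map, res_name):
    out = []
    for source in ("backbone", res_name):
        for heavy, hydrogens in rc.DONORS.get(source, {}).items():
            if heavy in res_map:
                hs = [res_map[h] for h in hydrogens if h in res_map]
                out.append((res_map[heavy], hs))
    return out


def _acceptor_atoms(res_map, res_name):
    out = []
    for source in ("backbone", res_name):
        for name in rc.ACCEPTORS.get(source, ()):
            if name in res_map:
                out.append(res_map[name])
    return out


def _angle_deg(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    v1 = p1 - p2
    v2 = p3 - p2
    cosang = float(np.dot(v1, v2) /
                   (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-12))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def _is_hbond(map_a, map_b, name_a, name_b, crit: ContactCriteria) -> bool:
    for d_map, d_name, a_map, a_name in (
            (map_a, name_a, map_b, name_b), (map_b, name_b, map_a, name_a)):
        donors = _donor_atoms(d_map, d_name)
        acceptors = _acceptor_atoms(a_map, a_name)
        for donor, hydrogens in donors:
            pd = np.array(donor.xyz)
            for acc in acceptors:
                pa = np.array(acc.xyz)
                if float(np.linalg.norm(pd - pa)) > crit.hbond_da_max:
                    continue
                if not hydrogens:
                    return True  # distance-only criterion without hydrogens
                for h in hydrogens:
                    ang = _angle_deg(pd, np.array(h.xyz), pa)
                    if ang >= crit.hbond_dha_min_deg:
                        return True
    return False


def _ring_geometry(res_map, res_name):
    for ring in rc.AROMATIC_RINGS.get(res_name, ()):
        pts = [np.array(res_map[n].xyz) for n in ring if n in res_map]
        if len(pts) < 3:
            continue
        pts_arr = np.array(pts)
        centroid = pts_arr.mean(axis=0)
        centered = pts_arr - centroid
        _, _, vh = np.linalg.svd(centered)
        yield centroid, vh[2]


def _is_cation_pi(map_a, map_b, name_a, name_b, crit: ContactCriteria) -> bool:
    for cat_map, cat_name, ar_map, ar_name in (
            (map_a, name_a, map_b, name_b), (map_b, name_b, map_a, name_a)):
        probes = [cat_map[n] for n in rc.CATION_PI_PROBES.get(cat_name, ())
                  if n in cat_map]
        if not probes or ar_name not in rc.AROMATIC_RINGS:
            continue
        for centroid, normal in _ring_geometry(ar_map, ar_name):
            for probe in probes:
                v = np.array(probe.xyz) - centroid
                dist = float(np.linalg.norm(v))
                if dist > crit.cation_pi_max or dist < 1e-6:
                    continue
                tilt = math.degrees(math.acos(
                    max(-1.0, min(1.0, abs(float(np.dot(v, normal))) / dist))))
                if tilt <= crit.cation_pi_angle_deg:
                    return True
    return False


def _is_hydrophobic(map_a, map_b, name_a, name_b, crit: ContactCriteria) -> bool:
    atoms_a = [map_a[n] for n in rc.APOLAR_CARBONS.get(name_a, ()) if n in map_a]
    atoms_b = [map_b[n] for n in rc.APOLAR_CARBONS.get(name_b, ()) if n in map_b]
    for _ in _pairs_within(atoms_a, atoms_b, crit.hydrophobic_max):
        return True
    return False


_EXPECTED_SIDECHAIN: Dict[str, int] = {
    name: sum(1 for e in topo if e[1] != "H") + (0 if name == "GLY" else 1)
    for name, (_, topo) in rc.SIDECHAIN_TOPOLOGY.items()
}


def classify_contacts(s: Structure, contacts: List[Contact],
                      criteria: Optional[ContactCriteria] = None) -> List[Contact]:
    """Assign a geometric class to each contact.

    Rules are applied in fixed order — salt bridge, hydrogen bond,
    cation-pi, hydrophobic — and the first match wins; pairs matching no
    rule stay ``unclassified``.  Residues with missing side-chain atoms
    are classified from the atoms present (a warning is logged).
    """
    crit = criteria or ContactCriteria()
    out = []
    warned = set()
    for contact in contacts:
        key_a, key_b = contact.residue_a, contact.residue_b
        map_a = _residue_atom_map(s, key_a)
        map_b = _residue_atom_map(s, key_b)
        for key, amap in ((key_a, map_a), (key_b, map_b)):
            name = key[2]
            expected = _EXPECTED_SIDECHAIN.get(name)
            n_heavy = sum(1 for a in amap.values() if a.is_heavy)
            if expected is not None and n_heavy < expected + 4 and key not in warned:
                logger.warning("residue %s has missing atoms; classifying "
                               "from available atoms", key)
                warned.add(key)
        name_a, name_b = key_a[2], key_b[2]
        if _is_salt_bridge(map_a, map_b, name_a, name_b, crit):
            cls = "salt_bridge"
        elif _is_hbond(map_a, map_b, name_a, name_b, crit):
            cls = "hbond"
        elif _is_cation_pi(map_a, map_b, name_a, name_b, crit):
            cls = "cation_pi"
        elif _is_hydrophobic(map_a, map_b, name_a, name_b, crit):
            cls = "hydrophobic"
        else:
            cls = "unclassified"
        out.append(Contact(residue_a=key_a, residue_b=key_b,
                           min_heavy_distance=contact.min_heavy_distance,
                           contact_class=cls))
    return out


def contacts_to_frame(contacts: List[Contact]):
    """Contacts as a DataFrame in the CSV export layout."""
    import pandas as pd

    return pd.DataFrame([
        {
            "chain_a": c.residue_a[0], "res_seq_a": c.residue_a[1],
            "res_name_a": c.residue_a[2],
            "chain_b": c.residue_b[0], "res_seq_b": c.residue_b[1],
            "res_name_b": c.residue_b[2],
            "min_dist_A": round(c.min_heavy_distance, 3),
            "class": c.contact_class,
        }
        for c in contacts
    ])


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def superpose(mobile: Structure, reference: Structure,
              atom_names: Optional[Sequence[str]] = ("CA",),
              chains: Optional[Iterable[str]] = None,
              pair_by_index: bool = False) -> SuperpositionResult:
    """Least-squares rigid superposition (Kabsch) of *mobile* onto *reference*.

    Atoms are paired by (chain, residue number, atom name) present in both
    structures, restricted to ``atom_names`` (default: C-alpha trace) and
    optionally to ``chains``.  With ``pair_by_index=True`` atoms are paired
    positionally instead and residue identity is not checked.  The rotation
    is constrained to be proper (determinant +1).
    """
    wanted_names = set(atom_names) if atom_names is not None else None
    wanted_chains = set(chains) if chains is not None else None

    def _select(s: Structure) -> Dict[Tuple[str, int, str], AtomRecord]:
        sel = {}
        for a in s.atoms:
            if wanted_names is not None and a.atom_name not in wanted_names:
                continue
            if wanted_chains is not None and a.chain_id not in wanted_chains:
                continue
            sel[(a.chain_id, a.res_seq, a.atom_name)] = a
        return sel

    if pair_by_index:
        sel_m = [a for a in mobile.atoms
                 if (wanted_names is None or a.atom_name in wanted_names)
                 and (wanted_chains is None or a.chain_id in wanted_chains)]
        sel_r = [a for a in reference.atoms
                 if (wanted_names is None or a.atom_name in wanted_names)
                 and (wanted_chains is None or a.chain_id in wanted_chains)]
        n = min(len(sel_m), len(sel_r))
        pairs = list(zip(sel_m[:n], sel_r[:n]))
    else:
        sel_m = _select(mobile)
        sel_r = _select(reference)
        common = sorted(set(sel_m) & set(sel_r))
        pairs = []
        for key in common:
            am, ar = sel_m[key], sel_r[key]
            if am.res_name != ar.res_name:
                raise StructureError(
                    f"residue name mismatch at {key}: {am.res_name} vs "
                    f"{ar.res_name}; use pair_by_index=True to override")
            pairs.append((am, ar))

    if len(pairs) < 3:
        raise StructureError(
            f"superposition needs >=3 paired atoms, found {len(pairs)}")

    xm = np.array([p[0].xyz for p in pairs])
    xr = np.array([p[1].xyz for p in pairs])
    cm, cr = xm.mean(axis=0), xr.mean(axis=0)
    rot, _ = Rotation.align_vectors(xr - cr, xm - cm)
    rotation = rot.as_matrix()
    translation = cr - rotation @ cm
    transformed = (rotation @ (xm - cm).T).T + cr
    rmsd = float(np.sqrt(np.mean(np.sum((transformed - xr) ** 2, axis=1))))
    return SuperpositionResult(rmsd=rmsd, rotation=rotation,
                               translation=translation, n_atoms_used=len(pairs))


def apply_transform(s: Structure, result: SuperpositionResult) -> Structure:
    """Apply a superposition transform to all atoms of a structure."""
    coords = s.coords() @ result.rotation.T + result.translation
    return s.with_coords(coords)
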