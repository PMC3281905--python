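"""Amino-acid property tables and ideal-geometry residue templates.

This module is the chemical knowledge base of the package:

* per-residue physicochemical properties (Kyte–Doolittle hydrophobicity,
  side-chain volume, formal charge at pH 7, polarity/aromaticity flags)
  used by the mutation-design rule engine;
* hydrogen-bond donor/acceptor typing and apolar-carbon / aromatic-ring
  atom lists used by geometric contact classification;
* internal-coordinate side-chain templates (bond length, bond angle,
  dihedral per atom) from which idealized residues are constructed with
  the natural-extension-reference-frame (NeRF) algorithm.  Templates
  carry heavy atoms plus polar hydrogens only — enough for geometric
  hydrogen-bond detection and for a reduced point-charge model, without
  pretending to full stereochemical realism.
"""

from __future__ import annotations

import math
from typing import Dict, List, Sequence, Tuple

import numpy as np

# ---------------------------------------------------------------------------
# Naming
# ---------------------------------------------------------------------------

THREE_TO_ONE: Dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: Dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

STANDARD_RESIDUES = tuple(sorted(THREE_TO_ONE))

WATER = "HOH"

# ---------------------------------------------------------------------------
# Physicochemical properties (keyed by 1-letter code)
# ---------------------------------------------------------------------------

#: Kyte & Doolittle hydropathy index.
KYTE_DOOLITTLE: Dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

#: Zamyatnin residue volumes (A^3).
_RESIDUE_VOLUME: Dict[str, float] = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

#: Side-chain volume: residue volume minus the glycine (H side chain) volume,
#: preserving the ordering of the underlying residue-volume scale.
SIDECHAIN_VOLUME: Dict[str, float] = {
    aa: round(v - _RESIDUE_VOLUME["G"], 1) for aa, v in _RESIDUE_VOLUME.items()
}

#: Formal side-chain charge at pH 7 (His treated as neutral).
FORMAL_CHARGE: Dict[str, int] = {aa: 0 for aa in THREE_TO_ONE.values()}
FORMAL_CHARGE.update({"K": 1, "R": 1, "D": -1, "E": -1})

POLAR_SIDECHAIN = frozenset("STNQYCHKRDE")
AROMATIC = frozenset("FYWH")
#: Apolar side chains considered for the hydrophobic design rule.
APOLAR = frozenset("AVLIMFWPG")

# ---------------------------------------------------------------------------
# Contact-classification atom typing (keyed by 3-letter code)
# ---------------------------------------------------------------------------

#: Charged side-chain N/O atoms used by the salt-bridge rule.
POSITIVE_ATOMS: Dict[str, Tuple[str, ...]] = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
}
NEGATIVE_ATOMS: Dict[str, Tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

#: Hydrogen-bond donors: heavy atom -> names of its polar hydrogens.
DONORS: Dict[str, Dict[str, Tuple[str, ...]]] = {
    "backbone": {"N": ("H",)},
    "SER": {"OG": ("HG",)},
    "THR": {"OG1": ("HG1",)},
    "TYR": {"OH": ("HH",)},
    "CYS": {"SG": ("HG",)},
    "TRP": {"NE1": ("HE1",)},
    "ASN": {"ND2": ("HD21", "HD22")},
    "GLN": {"NE2": ("HE21", "HE22")},
    "HIS": {"NE2": ("HE2",)},
    "LYS": {"NZ": ("HZ1", "HZ2", "HZ3")},
    "ARG": {
        "NE": ("HE",),
        "NH1": ("HH11", "HH12"),
        "NH2": ("HH21", "HH22"),
    },
    "HOH": {"O": ("H1", "H2")},
}

#: Hydrogen-bond acceptor heavy atoms (backbone O is always an acceptor).
ACCEPTORS: Dict[str, Tuple[str, ...]] = {
    "backbone": ("O",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "HIS": ("ND1",),
    "MET": ("SD",),
    "HOH": ("O",),
}

#: Side-chain carbons treated as apolar for the hydrophobic contact rule.
APOLAR_CARBONS: Dict[str, Tuple[str, ...]] = {
    "ALA": ("CB",),
    "VAL": ("CB", "CG1", "CG2"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "MET": ("CB", "CG", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2"),
    "PRO": ("CB", "CG", "CD"),
    "LYS": ("CB", "CG", "CD"),
    "ARG": ("CB", "CG"),
    "GLU": ("CB", "CG"),
    "GLN": ("CB", "CG"),
    "ASP": ("CB",),
    "ASN": ("CB",),
    "THR": ("CG2",),
    "HIS": ("CB",),
    "CYS": ("CB",),
    "SER": (),
    "GLY": (),
}

#: Aromatic rings eligible for cation-pi contacts (Phe/Tyr/Trp only).
AROMATIC_RINGS: Dict[str, Tuple[Tuple[str, ...], ...]] = {
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TRP": (
        ("CG", "CD1", "NE1", "CE2", "CD2"),
        ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"),
    ),
}

#: Cationic probe atoms for the cation-pi rule.
CATION_PI_PROBES: Dict[str, Tuple[str, ...]] = {
    "LYS": ("NZ",),
    "ARG": ("CZ",),
}

# ---------------------------------------------------------------------------
# Internal-coordinate templates
# ---------------------------------------------------------------------------

# Entry: (atom_name, element, (a, b, c), bond_A, angle_deg, dihedral)
# The new atom X bonds to c; angle is X-c-b; dihedral is X-c-b-a.
# dihedral is a float (fixed, degrees) or ("chi", k, offset_deg).
_Entry = Tuple[str, str, Tuple[str, str, str], float, float, object]

_BACKBONE: List[_Entry] = [
    # N, CA, C are seeded explicitly; O, H, CB via NeRF.
    ("O", "O", ("N", "CA", "C"), 1.231, 120.5, 180.0),
    ("H", "H", ("C", "CA", "N"), 1.010, 119.0, 180.0),
]

_CB: _Entry = ("CB", "C", ("C", "N", "CA"), 1.530, 110.5, 122.7)


def _chi(k: int, offset: float = 0.0):
    return ("chi", k, offset)


#: Side-chain topology beyond CB; n_chi gives the number of variable chis.
SIDECHAIN_TOPOLOGY: Dict[str, Tuple[int, List[_Entry]]] = {
    "GLY": (0, []),
    "ALA": (0, []),
    "VAL": (1, [
        ("CG1", "C", ("N", "CA", "CB"), 1.521, 110.5, _chi(1)),
        ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, _chi(1, 122.0)),
    ]),
    "LEU": (2, [
        ("CG", "C", ("N", "CA", "CB"), 1.530, 116.3, _chi(1)),
        ("CD1", "C", ("CA", "CB", "CG"), 1.521, 110.7, _chi(2)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.521, 110.7, _chi(2, 122.0)),
    ]),
    "ILE": (2, [
        ("CG1", "C", ("N", "CA", "CB"), 1.530, 110.4, _chi(1)),
        ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, _chi(1, -122.0)),
        ("CD1", "C", ("CA", "CB", "CG1"), 1.513, 113.8, _chi(2)),
    ]),
    "MET": (2, [
        ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
        ("SD", "S", ("CA", "CB", "CG"), 1.803, 112.7, _chi(2)),
        ("CE", "C", ("CB", "CG", "SD"), 1.791, 100.9, 180.0),
    ]),
    "PRO": (1, [
        ("CG", "C", ("N", "CA", "CB"), 1.495, 104.5, _chi(1)),
        ("CD", "C", ("CA", "CB", "CG"), 1.507, 106.1, -35.0),
    ]),
    "PHE": (2, [
        ("CG", "C", ("N", "CA", "CB"), 1.502, 113.8, _chi(1)),
        ("CD1", "C", ("CA", "CB", "CG"), 1.391, 120.8, _chi(2)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.391, 120.8, _chi(2, 180.0)),
        ("CE1", "C", ("CB", "CG", "CD1"), 1.391, 120.0, 180.0),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.391, 120.0, 180.0),
        ("CZ", "C", ("CG", "CD1", "CE1"), 1.391, 120.0, 0.0),
    ]),
    "TYR": (2, [
        ("CG", "C", ("N", "CA", "CB"), 1.512, 113.9, _chi(1)),
        ("CD1", "C", ("CA", "CB", "CG"), 1.391, 120.8, _chi(2)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.391, 120.8, _chi(2, 180.0)),
        ("CE1", "C", ("CB", "CG", "CD1"), 1.391, 120.0, 180.0),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.391, 120.0, 180.0),
        ("CZ", "C", ("CG", "CD1", "CE1"), 1.391, 120.0, 0.0),
        ("OH", "O", ("CD1", "CE1", "CZ"), 1.360, 120.0, 180.0),
        ("HH", "H", ("CE1", "CZ", "OH"), 0.960, 109.0, 180.0),
    ]),
    "TRP": (2, [
        ("CG", "C", ("N", "CA", "CB"), 1.498, 113.6, _chi(1)),
        ("CD1", "C", ("CA", "CB", "CG"), 1.365, 126.9, _chi(2)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.433, 126.6, _chi(2, 180.0)),
        ("NE1", "N", ("CB", "CG", "CD1"), 1.374, 110.1, 180.0),
        ("HE1", "H", ("CG", "CD1", "NE1"), 1.010, 125.5, 180.0),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.409, 107.2, 180.0),
        ("CE3", "C", ("CB", "CG", "CD2"), 1.398, 133.9, 0.0),
        ("CZ2", "C", ("CG", "CD2", "CE2"), 1.394, 122.4, 180.0),
        ("CZ3", "C", ("CG", "CD2", "CE3"), 1.392, 118.6, 180.0),
        ("CH2", "C", ("CD2", "CE2", "CZ2"), 1.368, 117.5, 0.0),
    ]),
    "SER": (1, [
        ("OG", "O", ("N", "CA", "CB"), 1.417, 110.8, _chi(1)),
        ("HG", "H", ("CA", "CB", "OG"), 0.960, 109.5, 180.0),
    ]),
    "THR": (1, [
        ("OG1", "O", ("N", "CA", "CB"), 1.433, 109.6, _chi(1)),
        ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, _chi(1, -122.0)),
        ("HG1", "H", ("CA", "CB", "OG1"), 0.960, 109.5, 180.0),
    ]),
    "CYS": (1, [
        ("SG", "S", ("N", "CA", "CB"), 1.808, 113.8, _chi(1)),
        ("HG", "H", ("CA", "CB", "SG"), 1.340, 96.0, 180.0),
    ]),
    "ASN": (2, [
        ("CG", "C", ("N", "CA", "CB"), 1.516, 112.6, _chi(1)),
        ("OD1", "O", ("CA", "CB", "CG"), 1.231, 120.8, _chi(2)),
        ("ND2", "N", ("CA", "CB", "CG"), 1.328, 116.4, _chi(2, 180.0)),
        ("HD21", "H", ("CB", "CG", "ND2"), 1.010, 120.0, 0.0),
        ("HD22", "H", ("CB", "CG", "ND2"), 1.010, 120.0, 180.0),
    ]),
    "GLN": (2, [
        ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
        ("CD", "C", ("CA", "CB", "CG"), 1.516, 112.6, _chi(2)),
        ("OE1", "O", ("CB", "CG", "CD"), 1.231, 120.8, 0.0),
        ("NE2", "N", ("CB", "CG", "CD"), 1.328, 116.4, 180.0),
        ("HE21", "H", ("CG", "CD", "NE2"), 1.010, 120.0, 0.0),
        ("HE22", "H", ("CG", "CD", "NE2"), 1.010, 120.0, 180.0),
    ]),
    "ASP": (2, [
        ("CG", "C", ("N", "CA", "CB"), 1.516, 112.6, _chi(1)),
        ("OD1", "O", ("CA", "CB", "CG"), 1.249, 118.4, _chi(2)),
        ("OD2", "O", ("CA", "CB", "CG"), 1.249, 118.4, _chi(2, 180.0)),
    ]),
    "GLU": (2, [
        ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
        ("CD", "C", ("CA", "CB", "CG"), 1.516, 112.6, _chi(2)),
        ("OE1", "O", ("CB", "CG", "CD"), 1.249, 118.4, 0.0),
        ("OE2", "O", ("CB", "CG", "CD"), 1.249, 118.4, 180.0),
    ]),
    "LYS": (2, [
        ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
        ("CD", "C", ("CA", "CB", "CG"), 1.520, 111.3, _chi(2)),
        ("CE", "C", ("CB", "CG", "CD"), 1.520, 111.3, 180.0),
        ("NZ", "N", ("CG", "CD", "CE"), 1.489, 112.0, 180.0),
        ("HZ1", "H", ("CD", "CE", "NZ"), 1.010, 109.5, 60.0),
        ("HZ2", "H", ("CD", "CE", "NZ"), 1.010, 109.5, 180.0),
        ("HZ3", "H", ("CD", "CE", "NZ"), 1.010, 109.5, 300.0),
    ]),
    "ARG": (2, [
        ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
        ("CD", "C", ("CA", "CB", "CG"), 1.520, 111.3, _chi(2)),
        ("NE", "N", ("CB", "CG", "CD"), 1.461, 112.0, 180.0),
        ("CZ", "C", ("CG", "CD", "NE"), 1.329, 124.2, 180.0),
        ("HE", "H", ("CG", "CD", "NE"), 1.010, 118.0, 0.0),
        ("NH1", "N", ("CD", "NE", "CZ"), 1.326, 120.0, 0.0),
        ("NH2", "N", ("CD", "NE", "CZ"), 1.326, 120.0, 180.0),
        ("HH11", "H", ("NE", "CZ", "NH1"), 1.010, 120.0, 0.0),
        ("HH12", "H", ("NE", "CZ", "NH1"), 1.010, 120.0, 180.0),
        ("HH21", "H", ("NE", "CZ", "NH2"), 1.010, 120.0, 0.0),
        ("HH22", "H", ("NE", "CZ", "NH2"), 1.010, 120.0, 180.0),
    ]),
    "HIS": (2, [
        ("CG", "C", ("N", "CA", "CB"), 1.492, 113.7, _chi(1)),
        ("ND1", "N", ("CA", "CB", "CG"), 1.380, 122.8, _chi(2)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.356, 131.0, _chi(2, 180.0)),
        ("CE1", "C", ("CB", "CG", "ND1"), 1.324, 109.1, 180.0),
        ("NE2", "N", ("CB", "CG", "CD2"), 1.373, 107.2, 180.0),
        ("HE2", "H", ("CG", "CD2", "NE2"), 1.010, 125.5, 180.0),
    ]),
}

#: Default chi values for template construction (extended conformation).
DEFAULT_CHI = (180.0, 180.0)

#: Rotamer chi grids for the fixed-backbone mutant builder (<= 9 combos).
ROTAMER_CHI_VALUES = (-60.0, 60.0, 180.0)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF placement: position X bonded to *c* given internal coordinates.

    ``bond`` = |X-c|, ``angle`` = X-c-b, ``dihedral`` = X-c-b-a.
    """
    theta = math.radians(angle_deg)
    phi = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n_norm = np.linalg.norm(n)
    if n_norm < 1e-10:
        # a, b, c collinear: pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        n_norm = np.linalg.norm(n)
    n /= n_norm
    m = np.cross(n, bc)
    d = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(phi),
        bond * math.sin(theta) * math.sin(phi),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_residue(res_name: str,
                  chi: Sequence[float] | None = None,
                  include_backbone_h: bool = True) -> Dict[str, Tuple[str, np.ndarray]]:
    """Construct an idealized residue in a local frame.

    Returns an ordered mapping ``atom_name -> (element, xyz)`` with the
    backbone seeded at N=(0,0,0), CA on +x and C in the xy-plane.  ``chi``
    supplies variable side-chain dihedrals (degrees); missing values fall
    back to the extended conformation.
    """
    res_name = res_name.upper()
    if res_name not in SIDECHAIN_TOPOLOGY:
        raise KeyError(f"no template for residue {res_name!r}")
    n_chi, entries = SIDECHAIN_TOPOLOGY[res_name]
    chi_vals = list(DEFAULT_CHI[:n_chi])
    if chi is not None:
        for i, v in enumerate(chi):
            if i < n_chi:
                chi_vals[i] = float(v)

    coords: Dict[str, Tuple[str, np.ndarray]] = {}
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([1.458, 0.0, 0.0])
    c = ca + 1.525 * np.array([math.cos(math.radians(69.0)),
                               math.sin(math.radians(69.0)), 0.0])
    coords["N"] = ("N", n)
    coords["CA"] = ("C", ca)
    coords["C"] = ("C", c)

    backbone = list(_BACKBONE)
    if not include_backbone_h or res_name == "PRO":
        backbone = [e for e in backbone if e[0] != "H"]
    all_entries = backbone + ([] if res_name == "GLY" else [_CB]) + entries

    for name, element, (ra, rb, rc), bond, angle, dihedral in all_entries:
        if isinstance(dihedral, tuple):
            _, k, offset = dihedral
            dih = chi_vals[k - 1] + offset
        else:
            dih = float(dihedral)
        xyz = place_atom(coords[ra][1], coords[rb][1], coords[rc][1],
                         bond, angle, dih)
        coords[name] = (element, xyz)
    return coords


def sidechain_reach(aa: str) -> float:
    """Maximum heavy-atom distance (A) from CA in the extended template.

    A geometric measure of how far a side chain can extend toward a
    partner; used by the hydrogen-bond design rule's notion of a "longer"
    side chain.
    """
    res3 = ONE_TO_THREE[aa] if len(aa) == 1 else aa.upper()
    tmpl = build_residue(res3)
    ca = tmpl["CA"][1]
    reach = 0.0
    backbone = {"N", "CA", "C", "O", "H"}
    for name, (element, xyz) in tmpl.items():
        if name in backbone or element == "H":
            continue
        reach = max(reach, float(np.linalg.norm(xyz - ca)))
    return reach


def rotamer_chi_sets(res_name: str) -> List[Tuple[float, ...]]:
    """Enumerate the embedded chi-angle grid for a residue (<= 9 combos)."""
    n_chi, _ = SIDECHAIN_TOPOLOGY[res_name.upper()]
    if n_chi == 0:
        return [()]
    if n_chi == 1:
        return [(x,) for x in ROTAMER_CHI_VALUES]
    return [(x, y) for x in ROTAMER_CHI_VALUES for y in ROTAMER_CHI_VALUES]
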