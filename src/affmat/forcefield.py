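"""Reduced nonbonded parameter table (point charges + Lennard-Jones).

A deliberately compact, self-contained parameter set for the 20 standard
residues plus three-site (TIP3P-charged) water, sufficient for
group-group Coulomb/LJ decomposition over idealized polar-hydrogen
structures.  Charges follow a simplified scheme in which every residue's
charges sum exactly to its formal charge at pH 7; LJ sigma/epsilon are
assigned per element.  The table is keyed by (res_name, atom_name), can
be exported/loaded as CSV, and is fully replaceable by a user-supplied
table of the same layout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Tuple

import pandas as pd

from . import residues as rc

__all__ = ["ForceFieldTable", "ForceFieldError", "default_forcefield"]


class ForceFieldError(KeyError):
    """Missing or inconsistent nonbonded parameters."""


# Backbone charge set shared by all residues (sums to zero).
_BACKBONE_CHARGES = {"N": -0.40, "H": 0.30, "CA": 0.00, "C": 0.50, "O": -0.40}
_PRO_BACKBONE = {"N": -0.10, "CA": 0.00, "C": 0.50, "O": -0.40}

# Side-chain charges; atoms absent from a residue's map carry zero.
# Each side chain sums to the residue's formal charge.
_SIDECHAIN_CHARGES: Dict[str, Dict[str, float]] = {
    "SER": {"CB": 0.15, "OG": -0.55, "HG": 0.40},
    "THR": {"CB": 0.15, "OG1": -0.55, "HG1": 0.40},
    "TYR": {"CZ": 0.15, "OH": -0.55, "HH": 0.40},
    "CYS": {"CB": 0.15, "SG": -0.40, "HG": 0.25},
    "TRP": {"NE1": -0.35, "HE1": 0.35},
    "ASN": {"CG": 0.55, "OD1": -0.55, "ND2": -0.60,
            "HD21": 0.30, "HD22": 0.30},
    "GLN": {"CD": 0.55, "OE1": -0.55, "NE2": -0.60,
            "HE21": 0.30, "HE22": 0.30},
    "ASP": {"CG": 0.30, "OD1": -0.65, "OD2": -0.65},
    "GLU": {"CD": 0.30, "OE1": -0.65, "OE2": -0.65},
    "LYS": {"CE": 0.25, "NZ": -0.30, "HZ1": 0.35, "HZ2": 0.35, "HZ3": 0.35},
    "ARG": {"CD": 0.20, "NE": -0.55, "HE": 0.35, "CZ": 0.80,
            "NH1": -0.60, "NH2": -0.60,
            "HH11": 0.35, "HH12": 0.35, "HH21": 0.35, "HH22": 0.35},
    "HIS": {"CG": 0.10, "ND1": -0.30, "CD2": 0.10, "CE1": 0.25,
            "NE2": -0.50, "HE2": 0.35},
}

# LJ parameters per element (sigma in nm, epsilon in kJ/mol).
_ELEMENT_LJ: Dict[str, Tuple[float, float]] = {
    "C": (0.340, 0.360),
    "N": (0.325, 0.711),
    "O": (0.296, 0.879),
    "S": (0.356, 1.046),
    "H": (0.107, 0.066),
}

_WATER_PARAMS: Dict[str, Tuple[float, float, float]] = {
    # TIP3P charges; oxygen carries the LJ site.
    "O": (-0.834, 0.31506, 0.6364),
    "H1": (0.417, 0.0, 0.0),
    "H2": (0.417, 0.0, 0.0),
}


@dataclass
class ForceFieldTable:
    """Lookup of (res_name, atom_name) -> (charge e, sigma nm, epsilon kJ/mol)."""

    parameters: Dict[Tuple[str, str], Tuple[float, float, float]]

    def lookup(self, res_name: str, atom_name: str) -> Tuple[float, float, float]:
        key = (res_name.upper(), atom_name)
        try:
            return self.parameters[key]
        except KeyError:
            raise ForceFieldError(
                f"no nonbonded parameters for (res_name={key[0]!r}, "
                f"atom_name={key[1]!r})") from None

    def charge(self, res_name: str, atom_name: str) -> float:
        return self.lookup(res_name, atom_name)[0]

    def residue_charge_sums(self) -> Dict[str, float]:
        sums: Dict[str, float] = {}
        for (res, _), (q, _, _) in self.parameters.items():
            sums[res] = sums.get(res, 0.0) + q
        return {res: round(q, 6) for res, q in sums.items()}

    def validate(self, tol: float = 1e-3) -> None:
        """Check that per-residue charges sum to the integer formal charge."""
        for res, total in self.residue_charge_sums().items():
            if res == rc.WATER:
                expected = 0
            elif res in rc.THREE_TO_ONE:
                expected = rc.FORMAL_CHARGE[rc.THREE_TO_ONE[res]]
            else:
                continue
            if abs(total - expected) > tol:
                raise ForceFieldError(
                    f"residue {res} charges sum to {total}, expected {expected}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"res_name": res, "atom_name": atom, "charge_e": q,
             "sigma_nm": s, "epsilon_kj": e}
            for (res, atom), (q, s, e) in sorted(self.parameters.items())
        ]
        return pd.DataFrame(rows)

    def to_csv(self) -> str:
        return self.to_frame().to_csv(index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ForceFieldTable":
        params = {
            (str(r.res_name).upper(), str(r.atom_name)):
                (float(r.charge_e), float(r.sigma_nm), float(r.epsilon_kj))
            for r in frame.itertuples()
        }
        return cls(params)

    @classmethod
    def from_csv(cls, text: str) -> "ForceFieldTable":
        return cls.from_frame(pd.read_csv(io.StringIO(text)))


def _residue_atom_list(res_name: str) -> Iterable[Tuple[str, str]]:
    tmpl = rc.build_residue(res_name)
    for atom_name, (element, _) in tmpl.items():
        yield atom_name, element


def default_forcefield() -> ForceFieldTable:
    """Build the embedded reduced parameter table for 20 residues + water."""
    params: Dict[Tuple[str, str], Tuple[float, float, float]] = {}
    for res_name in rc.SIDECHAIN_TOPOLOGY:
        backbone = _PRO_BACKBONE if res_name == "PRO" else _BACKBONE_CHARGES
        side = _SIDECHAIN_CHARGES.get(res_name, {})
        for atom_name, element in _residue_atom_list(res_name):
            q = backbone.get(atom_name, side.get(atom_name, 0.0))
            sigma, epsilon = _ELEMENT_LJ[element.upper()]
            params[(res_name, atom_name)] = (q, sigma, epsilon)
    for atom_name, (q, sigma, epsilon) in _WATER_PARAMS.items():
        params[(rc.WATER, atom_name)] = (q, sigma, epsilon)
    table = ForceFieldTable(params)
    table.validate()
    return table
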