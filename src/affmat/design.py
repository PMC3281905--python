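"""Rule-based mutation design and fixed-backbone mutant building.

Encodes three design rules for raising the affinity of an interface,
mirroring how a designer reads a complex structure:

* **hydrophobic** — the partner side chain is apolar: propose larger,
  more hydrophobic residues to strengthen/extend packing;
* **charge** — the partner carries a formal charge: propose the
  opposite-charge residue to create a salt bridge;
* **hbond** — the partner is polar or charged: propose a polar residue
  whose side chain reaches at least as far as the wild type's, to gain a
  hydrogen bond.

Mutants are built with a fixed backbone: N/CA/C/O (and CB) stay exactly
where they are and the new side chain is grown from an ideal-geometry
template in the least-clashing rotamer of a small embedded chi grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import residues as rc
from .structures import AtomRecord, Contact, Structure, StructureError

logger = logging.getLogger(__name__)

__all__ = [
    "MutationSpec", "ResiduePropertyTable", "DesignError",
    "propose_mutations", "build_mutant", "proposals_to_frame",
    "HYDROPHOBIC_CANDIDATES", "HBOND_CANDIDATES",
]


class DesignError(ValueError):
    """Invalid mutation specification or design input."""


RATIONALES = ("hydrophobic", "charge", "hbond")

#: Candidate sets of the three rules.
HYDROPHOBIC_CANDIDATES = ("W", "F", "L", "I", "Y")
HBOND_CANDIDATES = ("N", "Q", "E", "K")

#: Tolerance (A) when requiring a candidate's side-chain reach to be at
#: least the wild type's under the hbond rule.
REACH_TOLERANCE = 0.5


@dataclass(frozen=True)
class MutationSpec:
    """A single-site substitution with its design rationale."""

    chain: str
    position: int
    wt_res: str
    new_res: str
    rationale: str
    partner: Tuple[str, int, str]

    def __post_init__(self) -> None:
        if self.wt_res == self.new_res:
            raise DesignError(
                f"mutation at {self.chain}{self.position} replaces "
                f"{self.wt_res} with itself")
        if self.rationale not in RATIONALES:
            raise DesignError(f"unknown rationale {self.rationale!r}")

    @property
    def name(self) -> str:
        return f"{self.wt_res}{self.position}{self.new_res}"


@dataclass
class ResiduePropertyTable:
    """Per-amino-acid properties driving the design rules."""

    hydrophobicity: Dict[str, float]
    volume: Dict[str, float]
    charge: Dict[str, int]
    polar: frozenset
    aromatic: frozenset
    reach: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for aa in rc.THREE_TO_ONE.values():
            if aa not in self.hydrophobicity or aa not in self.volume:
                raise DesignError(f"property table misses residue {aa}")
            if self.volume[aa] < 0:
                raise DesignError(f"non-positive volume for {aa}")
        if not self.reach:
            self.reach = {aa: rc.sidechain_reach(aa)
                          for aa in rc.THREE_TO_ONE.values()}

    @classmethod
    def default(cls) -> "ResiduePropertyTable":
        return cls(
            hydrophobicity=dict(rc.KYTE_DOOLITTLE),
            volume=dict(rc.SIDECHAIN_VOLUME),
            charge=dict(rc.FORMAL_CHARGE),
            polar=rc.POLAR_SIDECHAIN,
            aromatic=rc.AROMATIC,
        )


def _one_letter(res_name: str) -> str:
    try:
        return rc.THREE_TO_ONE[res_name.upper()]
    except KeyError:
        raise DesignError(
            f"residue {res_name!r} is not in the property table") from None


def _hydrophobic_proposals(wt: str, props: ResiduePropertyTable) -> List[str]:
    candidates = [aa for aa in HYDROPHOBIC_CANDIDATES
                  if aa != wt and props.volume[aa] > props.volume[wt]]
    return sorted(candidates, key=lambda aa: -props.hydrophobicity[aa])


def _charge_proposals(wt: str, partner_charge: int,
                      props: ResiduePropertyTable) -> List[str]:
    if partner_charge > 0:
        ranked = ["E", "D"]
    else:
        ranked = ["K", "R"]
    return [aa for aa in ranked if aa != wt]


def _hbond_proposals(wt: str, props: ResiduePropertyTable) -> List[str]:
    wt_reach = props.reach[wt]
    candidates = [aa for aa in HBOND_CANDIDATES
                  if aa != wt and props.reach[aa] >= wt_reach - REACH_TOLERANCE]
    # smallest sufficient polar residue first
    return sorted(candidates, key=lambda aa: props.volume[aa])


def propose_mutations(contacts: Sequence[Contact],
                      props: Optional[ResiduePropertyTable] = None,
                      max_per_site: int = 2) -> List[MutationSpec]:
    """Propose substitutions for the A-side residue of each contact.

    Per contact, every applicable rule emits up to ``max_per_site``
    ranked proposals; duplicates arising from multiple contacts of the
    same site are dropped (first occurrence wins).  The output order is
    deterministic: position, then rule (hydrophobic, charge, hbond),
    then rank.
    """
    if max_per_site < 1:
        raise DesignError("max_per_site must be >= 1")
    props = props or ResiduePropertyTable.default()

    staged: List[Tuple[int, int, int, MutationSpec]] = []
    seen = set()
    for contact in contacts:
        chain, position, wt_name = contact.residue_a
        wt = _one_letter(wt_name)
        partner = contact.residue_b
        partner_aa = _one_letter(partner[2])
        partner_charge = props.charge[partner_aa]
        partner_polar = partner_aa in props.polar or partner_charge != 0
        partner_apolar = partner_aa in rc.APOLAR

        rules: List[Tuple[int, List[str], str]] = []
        if partner_apolar:
            rules.append((0, _hydrophobic_proposals(wt, props), "hydrophobic"))
        if partner_charge != 0:
            rules.append((1, _charge_proposals(wt, partner_charge, props),
                          "charge"))
        if partner_polar:
            rules.append((2, _hbond_proposals(wt, props), "hbond"))

        for rule_order, ranked, rationale in rules:
            for rank, aa in enumerate(ranked[:max_per_site]):
                key = (chain, position, aa, rationale)
                if key in seen:
                    continue
                seen.add(key)
                staged.append((position, rule_order, rank, MutationSpec(
                    chain=chain, position=position, wt_res=wt, new_res=aa,
                    rationale=rationale, partner=partner)))

    staged.sort(key=lambda t: (t[0], t[1], t[2]))
    return [m for _, _, _, m in staged]


def proposals_to_frame(proposals: Sequence[MutationSpec]):
    """Proposals as a DataFrame in the CSV export layout."""
    import pandas as pd

    return pd.DataFrame([
        {
            "chain": m.chain, "position": m.position, "wt": m.wt_res,
            "new": m.new_res, "rationale": m.rationale,
            "partner_chain": m.partner[0], "partner_pos": m.partner[1],
        }
        for m in proposals
    ])


# ---------------------------------------------------------------------------
# Fixed-backbone mutant builder
# ---------------------------------------------------------------------------

_BACKBONE_KEEP = ("N", "H", "CA", "C", "O")
CLASH_DISTANCE = 2.5  # A, heavy-atom pair


def _construct_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    from .residues import place_atom

    return place_atom(c, n, ca, 1.530, 110.5, 122.7)


def _grow_sidechain(res_name: str, anchors: Dict[str, np.ndarray],
                    chi: Sequence[float]) -> List[Tuple[str, str, np.ndarray]]:
    """Grow side-chain atoms beyond CB in the target residue's own frame."""
    from .residues import SIDECHAIN_TOPOLOGY, place_atom

    n_chi, entries = SIDECHAIN_TOPOLOGY[res_name]
    chi_vals = list(rc.DEFAULT_CHI[:n_chi])
    for i, v in enumerate(chi):
        if i < n_chi:
            chi_vals[i] = float(v)
    coords = dict(anchors)
    out = []
    for name, element, (ra, rb, rcn), bond, angle, dihedral in entries:
        if isinstance(dihedral, tuple):
            _, k, offset = dihedral
            dih = chi_vals[k - 1] + offset
        else:
            dih = float(dihedral)
        xyz = place_atom(coords[ra], coords[rb], coords[rcn], bond, angle, dih)
        coords[name] = xyz
        out.append((name, element, xyz))
    return out


def build_mutant(s: Structure, m: MutationSpec) -> Structure:
    """Apply a single substitution with the backbone held fixed.

    Backbone atoms (N, CA, C, O, and CB when the new residue has one)
    keep their input coordinates bit-for-bit; the side chain beyond CB is
    rebuilt from the ideal-geometry template in the rotamer of the
    embedded chi grid with the fewest heavy-atom clashes (< 2.5 A)
    against the rest of the structure.  All other residues are untouched.
    """
    old_atoms = s.residue_atoms(m.chain, m.position)
    if not old_atoms:
        raise DesignError(f"no residue at ({m.chain!r}, {m.position})")
    wt_name = old_atoms[0].res_name
    if _one_letter(wt_name) != m.wt_res:
        raise DesignError(
            f"wild-type mismatch at {m.chain}{m.position}: structure has "
            f"{wt_name} ({_one_letter(wt_name)}), spec says {m.wt_res}")
    new_name = rc.ONE_TO_THREE[m.new_res]

    atom_pos = {a.atom_name: np.array(a.xyz) for a in old_atoms}
    for required in ("N", "CA", "C"):
        if required not in atom_pos:
            raise DesignError(
                f"residue {m.chain}{m.position} misses backbone atom "
                f"{required}")
    anchors = {k: atom_pos[k] for k in ("N", "CA", "C")}
    if new_name != "GLY":
        if "CB" in atom_pos:
            anchors["CB"] = atom_pos["CB"]
        else:
            anchors["CB"] = _construct_cb(anchors["N"], anchors["CA"],
                                          anchors["C"])
            logger.warning("constructed CB from backbone geometry at %s%d",
                           m.chain, m.position)

    # environment heavy atoms (everything outside the mutated residue)
    env = np.array([a.xyz for a in s.atoms
                    if not (a.chain_id == m.chain and a.res_seq == m.position)
                    and a.is_heavy])

    best: Optional[List[Tuple[str, str, np.ndarray]]] = None
    best_clashes = None
    for chi in rc.rotamer_chi_sets(new_name):
        grown = _grow_sidechain(new_name, anchors, chi)
        heavy = np.array([xyz for _, element, xyz in grown if element != "H"])
        if heavy.size and env.size:
            from scipy.spatial.distance import cdist

            clashes = int(np.sum(cdist(heavy, env) < CLASH_DISTANCE))
        else:
            clashes = 0
        if best_clashes is None or clashes < best_clashes:
            best, best_clashes = grown, clashes
        if best_clashes == 0:
            break

    kept = []
    for name in _BACKBONE_KEEP:
        if name in atom_pos:
            old = next(a for a in old_atoms if a.atom_name == name)
            kept.append(replace(old, res_name=new_name))
    if new_name != "GLY":
        if "CB" in atom_pos:
            old = next(a for a in old_atoms if a.atom_name == "CB")
            kept.append(replace(old, res_name=new_name))
        else:
            kept.append(AtomRecord(
                chain_id=m.chain, res_name=new_name, res_seq=m.position,
                atom_name="CB", element="C",
                xyz=tuple(float(x) for x in anchors["CB"])))
    for name, element, xyz in best or []:
        kept.append(AtomRecord(
            chain_id=m.chain, res_name=new_name, res_seq=m.position,
            atom_name=name, element=element,
            xyz=tuple(float(x) for x in xyz)))

    new_atoms: List[AtomRecord] = []
    inserted = False
    for a in s.atoms:
        if a.chain_id == m.chain and a.res_seq == m.position:
            if not inserted:
                new_atoms.extend(kept)
                inserted = True
            continue
        new_atoms.append(a)
    return Structure(new_atoms, label=f"{s.label}|{m.name}" if s.label
                     else m.name)
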