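"""Published affinity and energy tables for the TV3/MD2 system, as fixtures.

These are the experimentally measured SPR rate/affinity tables for the
TLR4 decoy receptor (TV3) single and double mutants binding MD2, and the
MD-derived interaction-energy change table.  They serve as *inputs* to
the table arithmetic (K_D = kd/ka, fold-increase, summaries, additivity)
— the absolute energy values are trajectory- and force-field-dependent
and are not recomputed here.
"""

from __future__ import annotations

from typing import List, Tuple

import pandas as pd

from .kinetics import AffinityRow

__all__ = [
    "single_mutant_affinity_table", "double_mutant_affinity_table",
    "energy_change_table", "fixture_tables", "affinity_rows",
]

_T1_COLUMNS = ["mutant", "ka", "ka_err", "kd", "kd_err", "KD", "KD_err",
               "fold_increase"]

_TABLE1 = [
    # mutant, ka (1/M/s), +-, kd (1/s), +-, KD (M), +-, fold
    ("Wild-type", 2.84e4, 0.02e4, 2.22e-3, 0.05e-3, 7.80e-8, 0.14e-8, 1.0),
    ("M41E",      1.64e4, 0.57e4, 5.29e-5, 0.80e-5, 3.21e-9, 1.02e-9, 24.3),
    ("F63L",      2.65e4, 0.02e4, 1.15e-3, 0.01e-3, 4.33e-8, 0.03e-8, 1.8),
    ("F63W",      1.39e4, 0.10e4, 3.97e-5, 2.13e-5, 2.84e-9, 1.66e-9, 27.5),
    ("V132F",     6.91e4, 3.69e4, 1.54e-3, 0.01e-3, 2.22e-8, 1.41e-8, 3.5),
    ("V134L",     2.67e4, 0.28e4, 1.10e-4, 0.01e-4, 4.11e-9, 0.50e-9, 19.0),
    ("N156I",     1.97e4, 0.33e4, 8.05e-5, 4.77e-5, 4.07e-9, 1.71e-9, 19.2),
    ("H159Q",     2.14e3, 1.21e3, 1.00e-5, 0.44e-5, 4.30e-9, 3.23e-9, 18.1),
    ("D181E",     1.91e4, 0.10e4, 9.24e-4, 1.35e-4, 4.82e-8, 0.44e-8, 1.6),
    ("S184K",     7.66e3, 0.02e3, 1.41e-3, 0.02e-3, 1.83e-7, 0.04e-7, 0.4),
]

_TABLE2 = [
    ("Wild-type",   2.84e4, 0.02e4, 2.22e-3, 0.05e-3, 7.80e-8, 0.14e-8, 1.0),
    ("M41E/F63W",   2.01e4, 0.01e4, 5.23e-7, 0.5e-7, 2.60e-11, 0.24e-11, 3000.0),
    ("M41E/H159Q",  3.16e3, 2.60e3, 4.61e-4, 3.90e-4, 1.45e-7, 0.48e-7, 0.5),
    ("F63W/V134L",  3.66e3, 0.01e3, 1.03e-3, 0.22e-3, 2.83e-7, 0.62e-7, 0.3),
    ("F63W/D181E",  5.83e2, 0.32e2, 2.27e-5, 0.92e-5, 3.90e-8, 1.80e-8, 2.0),
    ("V134L/H159Q", 4.41e4, 0.60e4, 6.12e-6, 1.11e-6, 1.38e-10, 0.06e-10, 565.0),
]

# Interaction-energy changes (mutant minus wild type, kJ/mol; HB counts are
# mean hydrogen-bond numbers).  Parenthesized crystal-structure rerun values
# are kept in *_xtal columns for the three resolved single mutants.
_TABLE3 = [
    # mutant, dCoulomb, dLJ, dHB, dCoulomb_xtal, dLJ_xtal, dHB_xtal
    ("M41E",        -86.32,  4.53, 1.27, -48.14,  5.14, 0.63),
    ("F63W",        -17.08, -11.02, 0.80,   3.82, -2.08, 0.04),
    ("V134L",        -1.49,  -4.97, 0.00,  -1.38, -1.80, 0.00),
    ("H159Q",       -26.10,   3.93, 0.35, None, None, None),
    ("D181E",        -9.00,   0.60, 0.38, None, None, None),
    ("M41E/F63W",  -150.41,   0.30, 2.53, None, None, None),
    ("F63W/D181E",   21.79,   4.68, -0.01, None, None, None),
    ("V134L/H159Q", -32.28,  -1.75, 0.50, None, None, None),
]


def single_mutant_affinity_table() -> pd.DataFrame:
    """Single-mutant SPR rates/affinities (wild type + 9 single mutants)."""
    return pd.DataFrame(_TABLE1, columns=_T1_COLUMNS)


def double_mutant_affinity_table() -> pd.DataFrame:
    """Double-mutant SPR rates/affinities (wild type + 5 double mutants)."""
    return pd.DataFrame(_TABLE2, columns=_T1_COLUMNS)


def energy_change_table() -> pd.DataFrame:
    """Mutant-minus-wild-type Coulomb/LJ/H-bond change table."""
    return pd.DataFrame(_TABLE3, columns=[
        "mutant", "delta_coulomb", "delta_lj", "delta_hb",
        "delta_coulomb_xtal", "delta_lj_xtal", "delta_hb_xtal"])


def fixture_tables() -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(single-mutant affinities, double-mutant affinities, energy changes)."""
    return (single_mutant_affinity_table(), double_mutant_affinity_table(),
            energy_change_table())


def affinity_rows(frame: pd.DataFrame) -> List[AffinityRow]:
    """Convert an affinity-table DataFrame to AffinityRow objects."""
    return [AffinityRow(mutant=r.mutant, ka=r.ka, kd=r.kd, KD=r.KD,
                        fold_increase=r.fold_increase)
            for r in frame.itertuples()]
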