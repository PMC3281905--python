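import numpy as np
import pytest

from affmat.forcefield import ForceFieldTable, default_forcefield
from affmat.structures import AtomRecord, Structure
from affmat.synthetic import ToyComplexSpec, make_benchmark_complex, \
    make_toy_complex


@pytest.fixture(scope="session")
def forcefield():
    return default_forcefield()


@pytest.fixture(scope="session")
def four_class_complex():
    """Toy complex with one planted contact of each geometric class."""
    spec = ToyComplexSpec(
        n_residues_a=6, n_residues_b=6,
        planted_contacts=(("salt_bridge", 3.0), ("hbond", 2.9),
                          ("cation_pi", 4.5), ("hydrophobic", 4.0)),
        seed=7)
    return make_toy_complex(spec)


@pytest.fixture(scope="session")
def benchmark_complex():
    return make_benchmark_complex()


def make_point_structure(entries, label="points"):
    """Structure from (chain, res_name, res_seq, atom_name, element, xyz)."""
    return Structure([AtomRecord(chain_id=c, res_name=rn, res_seq=rs,
                                 atom_name=an, element=el,
                                 xyz=tuple(map(float, xyz)))
                      for c, rn, rs, an, el, xyz in entries], label=label)


@pytest.fixture
def point_structure_factory():
    return make_point_structure


def point_charge_ff(entries):
    """Ad-hoc force-field table: {(res, atom): (q, sigma_nm, eps_kj)}."""
    return ForceFieldTable(dict(entries))


@pytest.fixture
def point_charge_ff_factory():
    return point_charge_ff
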