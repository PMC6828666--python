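import numpy as np
import pytest

from openpocket.fixtures import (
    build_peptide,
    make_collapsed_pocket,
    make_hollow_sphere,
    make_toy_hit_table,
    make_two_cavity,
)
from openpocket.structure import Residue, Structure
from openpocket.fixtures import _atom


@pytest.fixture(scope="session")
def peptide():
    return build_peptide(["MET", "LYS", "LEU", "SER", "ALA", "GLY"])


@pytest.fixture(scope="session")
def hollow_sphere():
    return make_hollow_sphere(4.0, 200, seed=0)


@pytest.fixture(scope="session")
def two_cavity():
    return make_two_cavity(4.0, 200, seed=0)


@pytest.fixture(scope="session")
def collapsed_pocket():
    return make_collapsed_pocket(seed=0)


@pytest.fixture(scope="session")
def hit_table_small():
    return make_toy_hit_table(200, seed=7)


def single_atom_structure(element="C", coords=(0.0, 0.0, 0.0)):
    return Structure(residues=[Residue(
        "A", 1, "", "UNK", [_atom(1, element, element, coords)])])


def atoms_structure(points, element="C"):
    residues = [
        Residue("A", i + 1, "", "UNK",
                [_atom(i + 1, element, element, xyz)])
        for i, xyz in enumerate(points)
    ]
    return Structure(residues=residues)


@pytest.fixture
def single_atom():
    return single_atom_structure()
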