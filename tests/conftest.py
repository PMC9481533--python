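"""Shared fixtures: synthetic fibrils, ligand columns and toy atom builders."""

import numpy as np
import pytest
import biotite.structure as struc

from fibrilstab import FixtureSpec, make_fibril, make_ligand_column
from fibrilstab.structure import annotate


def build_toy(coords, names, elements, res_ids, res_names, chains, hetero=None):
    """Hand-built structure from parallel per-atom lists."""
    n = len(names)
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.atom_name = np.asarray(names, dtype="U6")
    arr.element = np.asarray(elements, dtype="U2")
    arr.res_id = np.asarray(res_ids, dtype=int)
    arr.res_name = np.asarray(res_names, dtype="U5")
    arr.chain_id = np.asarray(chains, dtype="U4")
    arr.hetero = np.asarray(hetero if hetero is not None else [False] * n, dtype=bool)
    return annotate(arr)


@pytest.fixture
def toy():
    return build_toy


def single_atom(element="C", pos=(0.0, 0.0, 0.0)):
    return build_toy([pos], [f"{element}1"], [element], [1], ["LIG"], ["A"], [True])


@pytest.fixture(scope="session")
def default_spec():
    return FixtureSpec()


@pytest.fixture(scope="session")
def fibril(default_spec):
    return make_fibril(default_spec)


@pytest.fixture(scope="session")
def liganded_fibril(default_spec, fibril):
    return make_ligand_column(fibril, default_spec)


@pytest.fixture(scope="session")
def small_spec():
    # 3 layers x 2 protofilaments, short strands: fast SASA/occupancy paths
    return FixtureSpec(n_layers=3, residues_per_strand=8)


@pytest.fixture(scope="session")
def small_fibril(small_spec):
    return make_fibril(small_spec)
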