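"""Shared fixtures: desk-scale dimensions, synthetic data, fixture files."""

from __future__ import annotations

import numpy as np
import pytest

from liggen import ModelDims, generate_synthetic_dataset
from liggen.networks import NetConfig


@pytest.fixture(scope="session")
def toy_dims() -> ModelDims:
    """Small dimensions used throughout the unit tests."""
    return ModelDims(n_atoms=9, n_protein_atoms=64, x_dim=8, z_dim=8,
                     feat_dim=16)


@pytest.fixture(scope="session")
def tiny_net() -> NetConfig:
    return NetConfig(gen_hidden=(32, 32), gnn_layers=2, head_hidden=(16,))


@pytest.fixture(scope="session")
def toy_dataset(toy_dims):
    return generate_synthetic_dataset(64, toy_dims, n_classes=3, seed=7)


def random_valid_graph(dims: ModelDims, rng: np.random.Generator,
                       n_heavy: int | None = None):
    """A random valid one-hot ligand graph (spanning tree + extra edges)."""
    from liggen.io_prep import _class_profiles, _synthetic_ligand

    atom_p, bond_p = _class_profiles(3, dims.n_atom_types - 1,
                                     dims.n_relations)
    return _synthetic_ligand(int(rng.integers(0, 3)), dims, atom_p, bond_p,
                             rng)


def permute_graph(g, perm: np.ndarray):
    """Apply one atom permutation to both the atom matrix and bond tensor."""
    from liggen import LigandGraph

    return LigandGraph(atoms=g.atoms[perm],
                       bonds=g.bonds[np.ix_(perm, perm)])


ETHANOL_SDF = """ethanol
  handbuilt

  9  8  0  0  0  0  0  0  0  0999 V2000
   -0.8959    0.1465    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.4350   -0.5903    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5183    0.3245    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
   -1.7000    0.8800    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.0200   -0.5500    0.8300 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.0200   -0.5500   -0.8300 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.5500    0.1100    0.8900 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.5500    0.1100   -0.8900 H   0  0  0  0  0  0  0  0  0  0  0  0
    2.3600   -0.1500    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  1  4  1  0
  1  5  1  0
  1  6  1  0
  2  7  1  0
  2  8  1  0
  3  9  1  0
M  END
$$$$
"""

_PDB_ROW = ("{kind:<6}{serial:>5} {name:^4}{alt:1}{res:<3} {chain:1}"
            "{resseq:>4}{icode:1}   {x:>8.3f}{y:>8.3f}{z:>8.3f}"
            "{occ:>6.2f}{b:>6.2f}          {elem:>2}\n")


def make_pdb_text(atoms: list[tuple[str, float, float, float]]) -> str:
    """Minimal single-chain PDB text from (element, x, y, z) records."""
    rows = []
    for i, (elem, x, y, z) in enumerate(atoms, start=1):
        rows.append(_PDB_ROW.format(kind="ATOM", serial=i,
                                    name=elem + str(i % 10), alt=" ",
                                    res="ALA", chain="A", resseq=1, icode=" ",
                                    x=x, y=y, z=z, occ=1.0, b=0.0,
                                    elem=elem.upper()))
    rows.append("END\n")
    return "".join(rows)


@pytest.fixture()
def ethanol_sdf(tmp_path):
    path = tmp_path / "ethanol.sdf"
    path.write_text(ETHANOL_SDF)
    return path


@pytest.fixture()
def small_pdb(tmp_path):
    """Ten atoms, four of them hydrogens, with exactly known coordinates."""
    atoms = [("N", 11.104, 6.134, -6.504), ("C", 12.500, 6.700, -6.300),
             ("C", 13.400, 5.600, -5.700), ("O", 13.100, 4.400, -5.900),
             ("C", 12.400, 8.000, -5.500), ("S", 14.000, 8.800, -5.200),
             ("H", 10.500, 6.800, -7.000), ("H", 12.900, 7.000, -7.250),
             ("H", 11.800, 8.700, -6.100), ("H", 12.000, 7.900, -4.480)]
    path = tmp_path / "mini.pdb"
    path.write_text(make_pdb_text(atoms))
    return path, atoms
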