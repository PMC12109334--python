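"""Shared fixtures: tiny hand-built structures and small synthetic datasets.

Everything is generated programmatically; nothing is read from disk except
files the tests themselves write into tmp_path.
"""

from __future__ import annotations

import numpy as np
import pytest

import graphbind as gb

# A 6-heavy-atom toy ligand (aminopropanol-like chain C-C-C-O plus N and C
# branches) with explicit CONECT records: 6 atoms, 5 bonds.
TOY_LIGAND_PDB = """\
HETATM    1  C1  LIG A   1       0.000   0.000   0.000  1.00  0.00           C
HETATM    2  C2  LIG A   1       1.520   0.000   0.000  1.00  0.00           C
HETATM    3  C3  LIG A   1       2.080   1.420   0.000  1.00  0.00           C
HETATM    4  O1  LIG A   1       3.500   1.400   0.100  1.00  0.00           O
HETATM    5  N1  LIG A   1      -0.560  -1.340   0.200  1.00  0.00           N
HETATM    6  C4  LIG A   1       1.980  -0.760   1.250  1.00  0.00           C
CONECT    1    2
CONECT    1    5
CONECT    2    3
CONECT    2    6
CONECT    3    4
END
"""

TOY_LIGAND_MOL2 = """\
@<TRIPOS>MOLECULE
toy
6 5 1
SMALL
GASTEIGER
@<TRIPOS>ATOM
1 C1 0.000 0.000 0.000 C.3 1 LIG 0.0
2 C2 1.520 0.000 0.000 C.3 1 LIG 0.0
3 C3 2.080 1.420 0.000 C.3 1 LIG 0.0
4 O1 3.500 1.400 0.100 O.3 1 LIG 0.0
5 N1 -0.560 -1.340 0.200 N.3 1 LIG 0.0
6 C4 1.980 -0.760 1.250 C.3 1 LIG 0.0
@<TRIPOS>BOND
1 1 2 1
2 1 5 1
3 2 3 1
4 2 6 1
5 3 4 1
"""


@pytest.fixture()
def toy_ligand_path(tmp_path):
    p = tmp_path / "toy_ligand.pdb"
    p.write_text(TOY_LIGAND_PDB)
    return p


@pytest.fixture()
def toy_ligand(toy_ligand_path):
    return gb.load_structure(toy_ligand_path, role="ligand")


@pytest.fixture()
def toy_mol2_path(tmp_path):
    p = tmp_path / "toy_ligand.mol2"
    p.write_text(TOY_LIGAND_MOL2)
    return p


@pytest.fixture(scope="session")
def small_dataset():
    """24 noiseless complexes for cheap model/evaluate tests."""
    spec = gb.FixtureSpec(seed=11, n_complexes=24, noise_sd=0.0,
                          ligand_size_range=(6, 14), n_pocket_atoms=36)
    ds = gb.make_dataset(spec)
    graphs, y = gb.featurize_dataset(ds)
    return ds, graphs, y


@pytest.fixture(scope="session")
def tiny_model_config():
    """Cheap but functional training configuration for unit tests."""
    return gb.ModelConfig(hidden_channels=16, n_conv_layers=2, epochs=15,
                          batch_size=8, dropout=0.0, edge_dropout=0.0,
                          seed=5, xgb_n_estimators=30, xgb_max_depth=3)


def random_complex_graph(rng: np.random.Generator, n_pocket: int = 5,
                         n_ligand: int = 3, node_dim: int = 7,
                         edge_dim: int = 3, affinity: float = 5.0
                         ) -> gb.ComplexGraph:
    """Small random graph with tree bonds inside each molecule."""
    n = n_pocket + n_ligand

    def tree_edges(n0, off):
        edges = []
        for i in range(1, n0):
            p = int(rng.integers(0, i))
            edges.append((p + off, i + off))
            edges.append((i + off, p + off))
        return edges

    edges = tree_edges(n_pocket, 0) + tree_edges(n_ligand, n_pocket)
    ei = np.array(edges).T if edges else np.zeros((2, 0), dtype=int)
    return gb.ComplexGraph(
        node_matrix=rng.normal(size=(n, node_dim)),
        edge_index=ei,
        edge_matrix=rng.normal(size=(ei.shape[1], edge_dim)),
        graph_vector=rng.normal(size=140),
        node_provenance=np.array(["pocket"] * n_pocket + ["ligand"] * n_ligand),
        complex_id="rnd", affinity=affinity)
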