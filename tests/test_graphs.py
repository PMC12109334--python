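"""Pocket selection, complex-graph assembly, and normalization."""

import numpy as np
import pytest

import graphbind as gb
from graphbind.errors import EmptyPocketError
from graphbind.graphs import GraphConfig, NormalizationStats, _scale
from graphbind.structures import AtomRecord, BondRecord, MolecularStructure

from conftest import random_complex_graph


def _point_cloud(points, role):
    atoms = [AtomRecord(index=i, element="C", atomic_number=6,
                        coords=tuple(p), residue_name="ALA" if role != "ligand" else "LIG",
                        residue_index=1, is_ligand=(role == "ligand"))
             for i, p in enumerate(points)]
    return MolecularStructure(atoms, [], role=role, source_id=role)


def brute_force_pocket(protein, ligand, cutoff):
    """Independent O(N*M) double loop over atom pairs."""
    kept = []
    for a in protein.atoms:
        best = min(np.linalg.norm(np.array(a.coords) - np.array(b.coords))
                   for b in ligand.atoms)
        if best <= cutoff:
            kept.append(a.index)
    return kept


def test_boundary_atoms_in_and_out():
    ligand = _point_cloud([(0.0, 0.0, 0.0)], "ligand")
    protein = _point_cloud([(4.9, 0.0, 0.0), (5.1, 0.0, 0.0)], "protein")
    pocket = gb.select_pocket_atoms(protein, ligand, GraphConfig(pocket_cutoff=5.0))
    assert pocket.n_atoms == 1
    assert pocket.atoms[0].coords[0] == pytest.approx(4.9)


@pytest.mark.parametrize("seed", range(10))
def test_pocket_selection_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    ligand = _point_cloud(rng.uniform(-2, 2, size=(5, 3)), "ligand")
    protein = _point_cloud(rng.uniform(-8, 8, size=(40, 3)), "protein")
    cutoff = float(rng.uniform(3, 6))
    expected = brute_force_pocket(protein, ligand, cutoff)
    if not expected:
        with pytest.raises(EmptyPocketError):
            gb.select_pocket_atoms(protein, ligand, GraphConfig(pocket_cutoff=cutoff))
        return
    pocket = gb.select_pocket_atoms(protein, ligand, GraphConfig(pocket_cutoff=cutoff))
    assert pocket.n_atoms == len(expected)
    np.testing.assert_allclose(pocket.coords,
                               protein.coords[np.array(expected)])


def test_disjoint_molecules_raise_empty_pocket():
    ligand = _point_cloud([(0.0, 0.0, 0.0)], "ligand")
    protein = _point_cloud([(50.0, 0.0, 0.0)], "protein")
    with pytest.raises(EmptyPocketError):
        gb.select_pocket_atoms(protein, ligand, GraphConfig(pocket_cutoff=1e-9))


def test_pocket_bonds_restricted_to_survivors():
    ligand = _point_cloud([(0.0, 0.0, 0.0)], "ligand")
    atoms = [AtomRecord(index=i, element="C", atomic_number=6,
                        coords=(1.5 * (i + 1), 0.0, 0.0), residue_name="GLY",
                        residue_index=1) for i in range(5)]
    bonds = [BondRecord(i, i + 1) for i in range(4)]
    protein = MolecularStructure(atoms, bonds, role="protein", source_id="chain")
    pocket = gb.select_pocket_atoms(protein, ligand, GraphConfig(pocket_cutoff=5.0))
    assert pocket.n_atoms == 3      # atoms at 1.5, 3.0, 4.5 A
    assert len(pocket.bonds) == 2   # only bonds among survivors


def test_assembly_counts_and_provenance(small_dataset):
    ds, graphs, _ = small_dataset
    rec = ds.records[0]
    lig = gb.sanitize_structure(rec.ligand)
    pocket = gb.select_pocket_atoms(gb.sanitize_structure(rec.protein), lig)
    pocket = gb.assign_gasteiger_charges(gb.sanitize_structure(pocket))
    lig = gb.assign_gasteiger_charges(lig)
    g = gb.assemble_complex_graph(pocket, lig)
    n_p, n_l = pocket.n_atoms, lig.n_atoms
    assert g.n_nodes == n_p + n_l
    assert g.n_edges == 2 * (len(pocket.bonds) + len(lig.bonds))
    assert (g.node_provenance == "pocket").sum() == n_p
    assert (g.node_provenance == "ligand").sum() == n_l
    assert g.graph_vector.shape == (140,)


def test_no_edge_crosses_partition(small_dataset):
    _, graphs, _ = small_dataset
    for g in graphs:
        is_lig = g.node_provenance == "ligand"
        src, dst = g.edge_index
        # exhaustive scan over the directed edge list
        assert not np.any(is_lig[src] != is_lig[dst])


def test_edges_stored_both_directions(small_dataset):
    _, graphs, _ = small_dataset
    g = graphs[0]
    pairs = set(map(tuple, g.edge_index.T))
    assert all((b, a) in pairs for a, b in pairs)


def test_minmax_basic_columns():
    lo, hi = np.array([1.0]), np.array([3.0])
    np.testing.assert_allclose(_scale(np.array([[1.0], [2.0], [3.0]]), lo, hi),
                               [[0.0], [0.5], [1.0]])
    # constant column maps to zero
    np.testing.assert_allclose(_scale(np.array([[7.0], [7.0]]),
                                      np.array([7.0]), np.array([7.0])),
                               [[0.0], [0.0]])
    # out-of-range value under train stats is clipped: (4-1)/(3-1) = 1.5 -> 1
    np.testing.assert_allclose(_scale(np.array([[4.0]]), lo, hi), [[1.0]])


def test_normalized_dataset_lies_in_unit_interval(small_dataset):
    _, graphs, _ = small_dataset
    norm, stats = gb.minmax_normalize(graphs)
    for g in norm:
        for block in (g.node_matrix, g.edge_matrix, g.graph_vector):
            assert block.min() >= 0.0 and block.max() <= 1.0
    # applying the same stats is idempotent on in-range data
    again, _ = gb.minmax_normalize(graphs, stats)
    np.testing.assert_allclose(again[0].node_matrix, norm[0].node_matrix)


def test_apply_time_stats_not_refit(small_dataset):
    _, graphs, _ = small_dataset
    _, stats = gb.minmax_normalize(graphs[:12])
    held_out, stats2 = gb.minmax_normalize(graphs[12:], stats)
    assert stats2 is stats
    for g in held_out:
        assert g.node_matrix.min() >= 0.0 and g.node_matrix.max() <= 1.0


def test_assembly_permutation_safe(small_dataset):
    """Relabeling atoms changes node order only, not the feature multiset."""
    import dataclasses
    ds, _, _ = small_dataset
    rec = ds.records[1]
    lig = gb.sanitize_structure(rec.ligand)
    n = lig.n_atoms
    rng = np.random.default_rng(4)
    perm = rng.permutation(n)
    atoms = [dataclasses.replace(lig.atoms[old], index=int(perm[old]))
             for old in range(n)]
    atoms.sort(key=lambda a: a.index)
    bonds = [dataclasses.replace(b, i=int(perm[b.i]), j=int(perm[b.j]))
             for b in lig.bonds]
    shuffled = MolecularStructure(atoms, bonds, "ligand", lig.source_id)
    X0 = gb.compute_node_features(lig)
    X1 = gb.compute_node_features(gb.sanitize_structure(shuffled))
    assert sorted(map(tuple, np.round(X0, 9))) == sorted(map(tuple, np.round(X1, 9)))


def test_jsonl_round_trip(tmp_path, small_dataset):
    _, graphs, _ = small_dataset
    p = tmp_path / "graphs.jsonl"
    gb.save_graphs_jsonl(graphs[:3], p)
    again = gb.load_graphs_jsonl(p)
    assert len(again) == 3
    for a, b in zip(again, graphs[:3]):
        np.testing.assert_allclose(a.node_matrix, b.node_matrix)
        np.testing.assert_array_equal(a.edge_index, b.edge_index)
        np.testing.assert_allclose(a.graph_vector, b.graph_vector)
        assert a.complex_id == b.complex_id
        assert a.affinity == pytest.approx(b.affinity)


def test_cross_partition_edge_rejected():
    rng = np.random.default_rng(0)
    g = random_complex_graph(rng)
    bad_edge = np.array([[0], [g.n_nodes - 1]])  # pocket -> ligand
    with pytest.raises(gb.GraphBindError):
        gb.ComplexGraph(g.node_matrix, np.hstack([g.edge_index, bad_edge]),
                        np.vstack([g.edge_matrix, np.zeros((1, 3))]),
                        g.graph_vector, g.node_provenance, "bad", 5.0)
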