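"""Node, edge, and molecule-level featurization."""

import numpy as np
import pytest

import graphbind as gb
from graphbind.errors import ChargeAssignmentError, SchemaError
from graphbind.features import ElectrostaticSpec, PAULING_ELECTRONEGATIVITY
from graphbind.structures import AtomRecord, BondRecord, MolecularStructure


@pytest.fixture()
def clean_ligand(toy_ligand):
    return gb.sanitize_structure(toy_ligand)


def test_schema_counts():
    schema = gb.default_schema()
    assert len(schema.node_groups) == 14
    assert len(schema.edge_groups) == 6
    assert len(schema.graph_scalars) == 70


def test_schema_json_round_trip(tmp_path):
    schema = gb.default_schema()
    p = tmp_path / "schema.json"
    schema.to_json(p)
    again = gb.FeatureSchema.from_json(p)
    assert again == schema


def test_ablated_schema_has_13_groups():
    schema = gb.default_schema().ablate_node_group("voronoi")
    assert len(schema.node_groups) == 13
    with pytest.raises(SchemaError):
        gb.default_schema().ablate_node_group("nonexistent")


def test_node_features_shape_and_residue_slot(clean_ligand):
    schema = gb.default_schema()
    X = gb.compute_node_features(clean_ligand, schema)
    assert X.shape == (6, schema.node_dim)
    res = X[:, schema.node_slice("residue_onehot")]
    # every ligand atom uses the OTHER slot, never an amino-acid slot
    assert np.all(res[:, -1] == 1.0)
    assert np.all(res[:, :-1] == 0.0)


def test_electronegativity_column(clean_ligand):
    schema = gb.default_schema()
    X = gb.compute_node_features(clean_ligand, schema)
    en = X[:, schema.node_slice("electronegativity")][:, 0]
    elements = [a.element for a in clean_ligand.atoms]
    o_val = en[elements.index("O")]
    c_val = en[elements.index("C")]
    assert o_val == pytest.approx(PAULING_ELECTRONEGATIVITY["O"])
    assert c_val == pytest.approx(PAULING_ELECTRONEGATIVITY["C"])
    assert o_val > c_val


def test_node_features_translation_invariant_except_coordinates(clean_ligand):
    import dataclasses
    schema = gb.default_schema()
    X0 = gb.compute_node_features(clean_ligand, schema)
    shifted = MolecularStructure(
        [dataclasses.replace(a, coords=(a.coords[0] + 10.0,
                                        a.coords[1] - 3.0,
                                        a.coords[2] + 5.0))
         for a in clean_ligand.atoms],
        [dataclasses.replace(b) for b in clean_ligand.bonds],
        clean_ligand.role, clean_ligand.source_id)
    X1 = gb.compute_node_features(shifted, schema)
    coord_sl = schema.node_slice("coordinates")
    keep = np.r_[0:coord_sl.start, coord_sl.stop:schema.node_dim]
    np.testing.assert_allclose(X0[:, keep], X1[:, keep], atol=1e-9)
    assert not np.allclose(X0[:, coord_sl], X1[:, coord_sl])


def test_node_features_deterministic(clean_ligand):
    X0 = gb.compute_node_features(clean_ligand)
    X1 = gb.compute_node_features(clean_ligand)
    assert np.array_equal(X0, X1)


def test_edge_features_require_charges(clean_ligand):
    with pytest.raises(ChargeAssignmentError):
        gb.compute_edge_features(clean_ligand)


def test_edge_features_values(clean_ligand):
    charged = gb.assign_gasteiger_charges(clean_ligand)
    schema = gb.default_schema()
    E = gb.compute_edge_features(charged, schema=schema)
    assert E.shape == (5, schema.edge_dim)
    # all single bonds: one-hot slot 0 set, numeric order 1, no ring
    assert np.all(E[:, 0] == 1.0)
    assert np.all(E[:, 6] == 1.0)
    assert np.all(E[:, 5] == 0.0)
    # bond lengths positive and < 2 A for this fixture
    assert np.all((E[:, 7] > 1.0) & (E[:, 7] < 2.0))


def test_coulomb_term_formula():
    # two atoms, q = 0.2 each, r = 1.5 A, k = 1 -> 0.2*0.2/1.5
    atoms = [AtomRecord(index=0, element="C", atomic_number=6,
                        coords=(0.0, 0.0, 0.0), partial_charge=0.2, is_ligand=True),
             AtomRecord(index=1, element="C", atomic_number=6,
                        coords=(1.5, 0.0, 0.0), partial_charge=0.2, is_ligand=True)]
    s = MolecularStructure(atoms, [BondRecord(0, 1)], role="ligand",
                           source_id="pair", charges_assigned=True)
    E = gb.compute_edge_features(s)
    assert E[0, -1] == pytest.approx(0.2 * 0.2 / 1.5)


def test_zero_charge_atom_kills_electrostatics():
    atoms = [AtomRecord(index=0, element="C", atomic_number=6,
                        coords=(0.0, 0.0, 0.0), partial_charge=0.0, is_ligand=True),
             AtomRecord(index=1, element="O", atomic_number=8,
                        coords=(1.4, 0.0, 0.0), partial_charge=-0.4, is_ligand=True)]
    s = MolecularStructure(atoms, [BondRecord(0, 1)], role="ligand",
                           source_id="zero", charges_assigned=True)
    E = gb.compute_edge_features(s)
    assert E[0, -1] == 0.0


def test_min_distance_floor():
    atoms = [AtomRecord(index=0, element="C", atomic_number=6,
                        coords=(0.0, 0.0, 0.0), partial_charge=0.3, is_ligand=True),
             AtomRecord(index=1, element="C", atomic_number=6,
                        coords=(0.1, 0.0, 0.0), partial_charge=0.3, is_ligand=True)]
    s = MolecularStructure(atoms, [BondRecord(0, 1)], role="ligand",
                           source_id="close", charges_assigned=True)
    E = gb.compute_edge_features(s, ElectrostaticSpec(min_distance=0.5))
    assert E[0, -1] == pytest.approx(0.3 * 0.3 / 0.5)


def test_descriptor_vector_length_and_pocket_zeroing(clean_ligand, small_dataset):
    vec = gb.molecular_descriptors(clean_ligand, role="ligand")
    assert vec.values.shape == (70,)
    schema = gb.default_schema()
    idx = {n: i for i, n in enumerate(schema.graph_scalars)}
    # the same structure treated as a pocket zeroes the ligand-only entries
    as_pocket = gb.molecular_descriptors(clean_ligand, role="pocket")
    for name in ("mol_logp", "nhoh_count", "no_count", "qed"):
        assert as_pocket.values[idx[name]] == 0.0
    assert vec.values[idx["qed"]] > 0.0


def test_hbond_donor_count(clean_ligand):
    # fixture has one hydroxyl O and one amine N -> 2 donors
    schema = gb.default_schema()
    idx = {n: i for i, n in enumerate(schema.graph_scalars)}
    vec = gb.molecular_descriptors(clean_ligand, role="ligand")
    assert vec.values[idx["num_h_donors"]] == 2.0


def test_unknown_element_maps_to_other_slot():
    atoms = [AtomRecord(index=0, element="Fe", atomic_number=26,
                        coords=(0.0, 0.0, 0.0)),
             AtomRecord(index=1, element="O", atomic_number=8,
                        coords=(2.0, 0.0, 0.0))]
    s = MolecularStructure(atoms, [], role="pocket", source_id="metal")
    schema = gb.default_schema()
    with pytest.warns(UserWarning, match="alphabet"):
        X = gb.compute_node_features(s, schema)
    one_hot = X[0, schema.node_slice("element_onehot")]
    assert one_hot[-1] == 1.0 and one_hot[:-1].sum() == 0.0
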