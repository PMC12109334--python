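"""Node, edge, and molecule-level feature computation.

Each molecule (pocket or ligand) contributes three feature blocks:

* **14 node feature groups** per atom — atomic number, total degree,
  hybridization (one-hot), total hydrogens (explicit + implicit), atomic
  mass, H-bond donor/acceptor flags, an atomic hydrophobicity index
  (Crippen logP contribution), Pauling electronegativity, element one-hot,
  residue one-hot (20 amino acids + OTHER; OTHER for every ligand atom),
  the Voronoi cell volume, the spherical-harmonics power descriptor, and
  the raw Cartesian coordinates.
* **6 edge feature groups** per covalent bond — bond-type one-hot,
  conjugation flag, ring flag, numeric bond order (aromatic = 1.5), bond
  length in A, and a Coulomb-style electrostatic term
  k * q_i * q_j / max(r_ij, min_distance) from Gasteiger partial charges.
* **70 graph-level scalars** — shape, surface-area, topology and
  hydrophobicity descriptors (Table-style registry below) with three hashed
  fingerprints folded to their set-bit counts.  Four ligand-specific entries
  (MolLogP, NHOH count, NO count, QED) are zeroed for pockets.

The ordered registry of groups lives in :class:`FeatureSchema`; ablation
runs rebuild inputs by dropping one named group.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors3D, Lipinski, QED
from rdkit.Chem import rdFingerprintGenerator, rdMolDescriptors
from rdkit.Chem.EState import EState_VSA

from .errors import ChargeAssignmentError, GraphBindError, SchemaError
from .geometry import (SphericalHarmonicSpec, VoronoiSpec,
                       spherical_harmonics_descriptor, voronoi_descriptor)
from .structures import AMINO_ACIDS, MolecularStructure, structure_to_rdkit

__all__ = [
    "FeatureSchema",
    "ElectrostaticSpec",
    "DescriptorVector",
    "default_schema",
    "compute_node_features",
    "compute_edge_features",
    "molecular_descriptors",
    "node_feature_frame",
    "edge_feature_frame",
]

ELEMENT_ALPHABET = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "H", "OTHER")

#: Pauling electronegativities; elements absent from the table get the
#: generic 1.8 used for metals.
PAULING_ELECTRONEGATIVITY = {
    "H": 2.20, "B": 2.04, "C": 2.55, "N": 3.04, "O": 3.44, "F": 3.98,
    "Si": 1.90, "P": 2.19, "S": 2.58, "Cl": 3.16, "Se": 2.55, "Br": 2.96,
    "I": 2.66, "Na": 0.93, "K": 0.82, "Mg": 1.31, "Ca": 1.00, "Fe": 1.83,
    "Zn": 1.65, "Cu": 1.90, "Mn": 1.55, "Co": 1.88, "Ni": 1.91,
}
_DEFAULT_EN = 1.8

_HYBRIDIZATIONS = ("SP", "SP2", "SP3", "SP3D", "SP3D2", "OTHER")
_BOND_TYPES = ("single", "double", "triple", "aromatic")
_NUMERIC_ORDER = {"single": 1.0, "double": 2.0, "triple": 3.0, "aromatic": 1.5}

#: graph-level entries zeroed when the molecule is a pocket
LIGAND_ONLY_SCALARS = ("mol_logp", "nhoh_count", "no_count", "qed")


@dataclass(frozen=True)
class ElectrostaticSpec:
    """Coulomb-term control for the electrostatic edge feature."""

    charge_model: str = "gasteiger"
    coulomb_constant: float = 1.0
    min_distance: float = 0.5  # A floor guarding against malformed coordinates

    def __post_init__(self) -> None:
        if self.min_distance <= 0:
            raise ValueError("min_distance must be positive")
        if self.charge_model != "gasteiger":
            raise ValueError("only the gasteiger charge model is supported")


def _graph_scalar_names() -> tuple[str, ...]:
    names = [
        "asphericity", "eccentricity", "exact_mol_wt", "fraction_csp3",
        "inertial_shape_factor", "num_aliphatic_carbocycles", "num_amide_bonds",
        "num_aromatic_carbocycles", "hall_kier_alpha", "num_h_acceptors",
        "num_h_donors", "num_heteroatoms", "num_rotatable_bonds",
        "mol_logp", "nhoh_count", "no_count", "qed",
    ]
    names += [f"peoe_vsa{i}" for i in range(1, 15)]
    names += [f"smr_vsa{i}" for i in range(1, 9)]
    names += [f"slogp_vsa{i}" for i in range(1, 13)]
    names += [f"vsa_estate{i}" for i in range(1, 11)]
    names += ["mol_mr", "tpsa", "kappa1", "labute_asa", "pbf", "chi0n"]
    names += ["morgan_fp_bits", "torsion_fp_bits", "atom_pair_fp_bits"]
    return tuple(names)


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered registry of feature groups and their widths."""

    node_groups: tuple[tuple[str, int], ...]
    edge_groups: tuple[tuple[str, int], ...]
    graph_scalars: tuple[str, ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.node_groups]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate node group names")
        if any(w < 1 for _, w in self.node_groups + self.edge_groups):
            raise SchemaError("group widths must be >= 1")
        if len(set(self.graph_scalars)) != len(self.graph_scalars):
            raise SchemaError("duplicate graph scalar names")

    @property
    def node_dim(self) -> int:
        return sum(w for _, w in self.node_groups)

    @property
    def edge_dim(self) -> int:
        return sum(w for _, w in self.edge_groups)

    @property
    def graph_dim(self) -> int:
        return len(self.graph_scalars)

    def node_slice(self, name: str) -> slice:
        start = 0
        for gname, width in self.node_groups:
            if gname == name:
                return slice(start, start + width)
            start += width
        raise SchemaError(f"unknown node group {name!r}")

    def ablate_node_group(self, name: str) -> "FeatureSchema":
        """Schema with one node group removed (for ablation runs)."""
        if name not in {n for n, _ in self.node_groups}:
            raise SchemaError(f"unknown node group {name!r}")
        return FeatureSchema(
            tuple((n, w) for n, w in self.node_groups if n != name),
            self.edge_groups, self.graph_scalars,
        )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "node_groups": [list(g) for g in self.node_groups],
            "edge_groups": [list(g) for g in self.edge_groups],
            "graph_scalars": list(self.graph_scalars),
        }, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "FeatureSchema":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        return cls(tuple(tuple(g) for g in d["node_groups"]),
                   tuple(tuple(g) for g in d["edge_groups"]),
                   tuple(d["graph_scalars"]))


def default_schema() -> FeatureSchema:
    """The canonical 14-node-group / 6-edge-group / 70-scalar registry."""
    node_groups = (
        ("atomic_number", 1),
        ("total_degree", 1),
        ("hybridization", len(_HYBRIDIZATIONS)),
        ("total_hydrogens", 1),
        ("mass", 1),
        ("h_bond_donor", 1),
        ("h_bond_acceptor", 1),
        ("hydrophobicity", 1),
        ("electronegativity", 1),
        ("element_onehot", len(ELEMENT_ALPHABET)),
        ("residue_onehot", len(AMINO_ACIDS) + 1),
        ("voronoi", 1),
        ("spherical_harmonics", 1),
        ("coordinates", 3),
    )
    edge_groups = (
        ("bond_type_onehot", len(_BOND_TYPES)),
        ("conjugation", 1),
        ("ring", 1),
        ("bond_order", 1),
        ("bond_length", 1),
        ("electrostatic", 1),
    )
    return FeatureSchema(node_groups, edge_groups, _graph_scalar_names())


@dataclass
class DescriptorVector:
    """The 70 molecule-level scalars in registry order."""

    values: np.ndarray
    role: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (70,):
            raise GraphBindError(f"descriptor vector must have 70 entries, "
                                 f"got {self.values.shape}")


def compute_node_features(s: MolecularStructure,
                          schema: FeatureSchema | None = None,
                          voronoi_spec: VoronoiSpec | None = None,
                          sh_spec: SphericalHarmonicSpec | None = None) -> np.ndarray:
    """Per-atom feature matrix (n_atoms x schema.node_dim).

    The structure must be sanitized.  Elements outside the supported
    alphabet fall into the OTHER one-hot slot with a warning; ligand atoms
    always use the OTHER residue slot.
    """
    schema = schema or default_schema()
    mol = structure_to_rdkit(s, sanitize=True)
    coords = s.coords
    voro = voronoi_descriptor(coords, voronoi_spec)
    sh = spherical_harmonics_descriptor(coords, sh_spec)
    crippen = rdMolDescriptors._CalcCrippenContribs(mol)
    donors = {i for match in mol.GetSubstructMatches(Lipinski.HDonorSmarts)
              for i in match}
    acceptors = {i for match in mol.GetSubstructMatches(Lipinski.HAcceptorSmarts)
                 for i in match}

    columns: dict[str, np.ndarray] = {}
    n = s.n_atoms
    columns["atomic_number"] = np.array(
        [[a.atomic_number] for a in s.atoms], dtype=float)
    columns["total_degree"] = np.array(
        [[mol.GetAtomWithIdx(i).GetTotalDegree()] for i in range(n)], dtype=float)
    hyb = np.zeros((n, len(_HYBRIDIZATIONS)))
    for i in range(n):
        name = str(mol.GetAtomWithIdx(i).GetHybridization())
        j = _HYBRIDIZATIONS.index(name) if name in _HYBRIDIZATIONS \
            else _HYBRIDIZATIONS.index("OTHER")
        hyb[i, j] = 1.0
    columns["hybridization"] = hyb
    columns["total_hydrogens"] = np.array(
        [[mol.GetAtomWithIdx(i).GetTotalNumHs(includeNeighbors=True)]
         for i in range(n)], dtype=float)
    columns["mass"] = np.array(
        [[mol.GetAtomWithIdx(i).GetMass()] for i in range(n)], dtype=float)
    columns["h_bond_donor"] = np.array(
        [[1.0 if i in donors else 0.0] for i in range(n)])
    columns["h_bond_acceptor"] = np.array(
        [[1.0 if i in acceptors else 0.0] for i in range(n)])
    columns["hydrophobicity"] = np.array([[c[0]] for c in crippen])
    columns["electronegativity"] = np.array(
        [[PAULING_ELECTRONEGATIVITY.get(a.element, _DEFAULT_EN)] for a in s.atoms])
    elem = np.zeros((n, len(ELEMENT_ALPHABET)))
    for i, a in enumerate(s.atoms):
        if a.element in ELEMENT_ALPHABET:
            elem[i, ELEMENT_ALPHABET.index(a.element)] = 1.0
        else:
            warnings.warn(f"element {a.element!r} outside supported alphabet; "
                          f"mapped to OTHER", stacklevel=2)
            elem[i, ELEMENT_ALPHABET.index("OTHER")] = 1.0
    columns["element_onehot"] = elem
    res = np.zeros((n, len(AMINO_ACIDS) + 1))
    for i, a in enumerate(s.atoms):
        if (not a.is_ligand) and a.residue_name in AMINO_ACIDS:
            res[i, AMINO_ACIDS.index(a.residue_name)] = 1.0
        else:
            res[i, -1] = 1.0  # OTHER: ligand atoms and non-standard residues
    columns["residue_onehot"] = res
    columns["voronoi"] = voro[:, None]
    columns["spherical_harmonics"] = sh[:, None]
    columns["coordinates"] = coords

    blocks = []
    for name, width in schema.node_groups:
        if name not in columns:
            raise SchemaError(f"unknown node group {name!r}")
        block = columns[name]
        if block.shape[1] != width:
            raise SchemaError(f"group {name!r} width {block.shape[1]} != {width}")
        blocks.append(block)
    return np.hstack(blocks) if blocks else np.zeros((n, 0))


def compute_edge_features(s: MolecularStructure,
                          spec: ElectrostaticSpec | None = None,
                          schema: FeatureSchema | None = None) -> np.ndarray:
    """Per-bond feature matrix (n_bonds x schema.edge_dim), undirected order.

    Requires partial charges on the atoms (``assign_gasteiger_charges``);
    raises :class:`ChargeAssignmentError` otherwise.
    """
    spec = spec or ElectrostaticSpec()
    schema = schema or default_schema()
    if not getattr(s, "charges_assigned", False):
        raise ChargeAssignmentError(
            f"{s.source_id}: partial charges not assigned; "
            f"run assign_gasteiger_charges first")
    q = {a.index: a.partial_charge for a in s.atoms}
    rows = []
    for b in s.bonds:
        onehot = [0.0] * len(_BOND_TYPES)
        onehot[_BOND_TYPES.index(b.order)] = 1.0
        elec = (spec.coulomb_constant * q[b.i] * q[b.j]
                / max(b.length, spec.min_distance))
        rows.append(onehot + [
            1.0 if b.is_conjugated else 0.0,
            1.0 if b.is_in_ring else 0.0,
            _NUMERIC_ORDER[b.order],
            b.length,
            elec,
        ])
    out = np.array(rows, dtype=float) if rows else np.zeros((0, schema.edge_dim))
    if out.shape[1] != schema.edge_dim:
        raise SchemaError(f"edge feature width {out.shape[1]} != {schema.edge_dim}")
    return out


def _shape_descriptor(fn, mol) -> float:
    val = fn(mol)
    # linear/diatomic molecules give degenerate inertia tensors
    return float(val) if np.isfinite(val) else 0.0


def molecular_descriptors(s: MolecularStructure, role: str | None = None,
                          schema: FeatureSchema | None = None) -> DescriptorVector:
    """The 70 molecule-level scalars for one structure.

    ``role`` defaults to the structure's own role; ligand-only entries
    (MolLogP, NHOH count, NO count, QED) are zeroed for pockets/proteins.
    """
    schema = schema or default_schema()
    role = role or ("ligand" if s.role == "ligand" else "pocket")
    mol = structure_to_rdkit(s, sanitize=True)
    is_ligand = role == "ligand"

    morgan = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
    torsion = rdFingerprintGenerator.GetTopologicalTorsionGenerator(fpSize=2048)
    atompair = rdFingerprintGenerator.GetAtomPairGenerator(fpSize=2048)

    scalar_fns = {
        "asphericity": lambda m: _shape_descriptor(Descriptors3D.Asphericity, m),
        "eccentricity": lambda m: _shape_descriptor(Descriptors3D.Eccentricity, m),
        "exact_mol_wt": rdMolDescriptors.CalcExactMolWt,
        "fraction_csp3": rdMolDescriptors.CalcFractionCSP3,
        "inertial_shape_factor":
            lambda m: _shape_descriptor(Descriptors3D.InertialShapeFactor, m),
        "num_aliphatic_carbocycles": rdMolDescriptors.CalcNumAliphaticCarbocycles,
        "num_amide_bonds": rdMolDescriptors.CalcNumAmideBonds,
        "num_aromatic_carbocycles": rdMolDescriptors.CalcNumAromaticCarbocycles,
        "hall_kier_alpha": rdMolDescriptors.CalcHallKierAlpha,
        "num_h_acceptors": rdMolDescriptors.CalcNumHBA,
        "num_h_donors": rdMolDescriptors.CalcNumHBD,
        "num_heteroatoms": rdMolDescriptors.CalcNumHeteroatoms,
        "num_rotatable_bonds": rdMolDescriptors.CalcNumRotatableBonds,
        "mol_logp": Crippen.MolLogP,
        "nhoh_count": Lipinski.NHOHCount,
        "no_count": Lipinski.NOCount,
        "qed": QED.qed,
        "mol_mr": Crippen.MolMR,
        "tpsa": rdMolDescriptors.CalcTPSA,
        "kappa1": rdMolDescriptors.CalcKappa1,
        "labute_asa": rdMolDescriptors.CalcLabuteASA,
        "pbf": rdMolDescriptors.CalcPBF,
        "chi0n": rdMolDescriptors.CalcChi0n,
        "morgan_fp_bits": lambda m: morgan.GetFingerprint(m).GetNumOnBits(),
        "torsion_fp_bits": lambda m: torsion.GetFingerprint(m).GetNumOnBits(),
        "atom_pair_fp_bits": lambda m: atompair.GetFingerprint(m).GetNumOnBits(),
    }

    vsa_blocks: dict[str, list[float]] = {}

    def _vsa(prefix: str, values: list[float]) -> None:
        for i, v in enumerate(values, start=1):
            vsa_blocks[f"{prefix}{i}"] = v

    try:
        _vsa("peoe_vsa", list(rdMolDescriptors.PEOE_VSA_(mol)))
        _vsa("smr_vsa", list(rdMolDescriptors.SMR_VSA_(mol))[:8])
        _vsa("slogp_vsa", list(rdMolDescriptors.SlogP_VSA_(mol)))
        _vsa("vsa_estate", list(EState_VSA.VSA_EState_(mol)))
    except Exception as exc:
        raise GraphBindError(f"{s.source_id}: VSA descriptor block failed ({exc})") from exc

    values = np.zeros(70)
    for k, name in enumerate(schema.graph_scalars):
        if (not is_ligand) and name in LIGAND_ONLY_SCALARS:
            values[k] = 0.0
            continue
        try:
            if name in scalar_fns:
                values[k] = float(scalar_fns[name](mol))
            elif name in vsa_blocks:
                values[k] = float(vsa_blocks[name])
            else:
                raise SchemaError(f"unknown graph scalar {name!r}")
        except SchemaError:
            raise
        except Exception as exc:
            raise GraphBindError(
                f"{s.source_id}: descriptor {name!r} failed ({exc})") from exc
    return DescriptorVector(values=values, role="ligand" if is_ligand else "pocket")


def _expanded_columns(groups: tuple[tuple[str, int], ...]) -> list[str]:
    cols: list[str] = []
    for name, width in groups:
        if width == 1:
            cols.append(name)
        else:
            cols.extend(f"{name}_{k}" for k in range(width))
    return cols


def node_feature_frame(s: MolecularStructure,
                       schema: FeatureSchema | None = None,
                       voronoi_spec: VoronoiSpec | None = None,
                       sh_spec: SphericalHarmonicSpec | None = None,
                       path=None) -> pd.DataFrame:
    """Node feature table with schema-named columns; optionally write TSV."""
    schema = schema or default_schema()
    X = compute_node_features(s, schema, voronoi_spec, sh_spec)
    df = pd.DataFrame(X, columns=_expanded_columns(schema.node_groups))
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def edge_feature_frame(s: MolecularStructure,
                       spec: ElectrostaticSpec | None = None,
                       schema: FeatureSchema | None = None,
                       path=None) -> pd.DataFrame:
    """Edge feature table with schema-named columns; optionally write TSV."""
    schema = schema or default_schema()
    E = compute_edge_features(s, spec, schema)
    df = pd.DataFrame(E, columns=_expanded_columns(schema.edge_groups))
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
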