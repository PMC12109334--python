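"""Pocket selection, complex-graph assembly, and dataset-wide normalization.

A complex graph is the disjoint union of the pocket graph and the ligand
graph: nodes are atoms, edges are covalent bonds (stored in both
directions), and the two 70-entry molecule-level vectors are concatenated
into one 140-entry graph vector.  No edge ever crosses the pocket/ligand
partition — omitting explicit intermolecular features is the point of a
structure-only model.

Pocket atoms are the protein atoms whose minimum distance to any ligand
atom is at most ``pocket_cutoff`` (default 5 A).  Min-max normalization is
fit on training data only and applied (with clipping to [0, 1]) elsewhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DimensionError, EmptyPocketError
from .features import (ElectrostaticSpec, FeatureSchema, compute_edge_features,
                       compute_node_features, default_schema,
                       molecular_descriptors)
from .geometry import SphericalHarmonicSpec, VoronoiSpec
from .structures import (BondRecord, MolecularStructure,
                         assign_gasteiger_charges, sanitize_structure)

__all__ = [
    "GraphConfig",
    "ComplexGraph",
    "NormalizationStats",
    "select_pocket_atoms",
    "assemble_complex_graph",
    "build_complex_graph",
    "minmax_normalize",
    "save_graphs_jsonl",
    "load_graphs_jsonl",
]


@dataclass(frozen=True)
class GraphConfig:
    """Distance cutoff (A) for pocket atom selection."""

    pocket_cutoff: float = 5.0

    def __post_init__(self) -> None:
        if self.pocket_cutoff <= 0:
            raise ValueError("pocket_cutoff must be positive")


@dataclass
class ComplexGraph:
    """Disjoint union of pocket and ligand graphs for one complex."""

    node_matrix: np.ndarray          # (n_atoms, node_dim)
    edge_index: np.ndarray           # (2, n_edges) directed, both directions
    edge_matrix: np.ndarray          # (n_edges, edge_dim)
    graph_vector: np.ndarray         # (140,) pocket 70 || ligand 70
    node_provenance: np.ndarray      # (n_atoms,) "pocket" | "ligand"
    complex_id: str = ""
    affinity: float | None = None    # -log10(Kd/Ki), absent at screening time

    def __post_init__(self) -> None:
        if self.graph_vector.shape != (140,):
            raise DimensionError(f"{self.complex_id}: graph vector must be 140-long")
        if self.edge_index.size:
            is_lig = self.node_provenance == "ligand"
            src, dst = self.edge_index
            if np.any(is_lig[src] != is_lig[dst]):
                raise DimensionError(
                    f"{self.complex_id}: edge crosses the pocket/ligand partition")

    @property
    def n_nodes(self) -> int:
        return self.node_matrix.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[1] if self.edge_index.size else 0


def select_pocket_atoms(protein: MolecularStructure, ligand: MolecularStructure,
                        cfg: GraphConfig | None = None) -> MolecularStructure:
    """Cut the binding pocket: protein atoms within the cutoff of the ligand.

    Keeps exactly the protein atoms whose minimum distance to any ligand
    atom is <= ``cfg.pocket_cutoff``; bonds are restricted to surviving
    atoms.  Raises :class:`EmptyPocketError` when nothing survives.
    """
    cfg = cfg or GraphConfig()
    if protein.n_atoms == 0 or ligand.n_atoms == 0:
        raise EmptyPocketError("empty input structure")
    d = cdist(protein.coords, ligand.coords)
    keep_mask = d.min(axis=1) <= cfg.pocket_cutoff
    keep = [a.index for a, k in zip(protein.atoms, keep_mask) if k]
    if not keep:
        raise EmptyPocketError(
            f"{protein.source_id}: no protein atom within "
            f"{cfg.pocket_cutoff} A of ligand {ligand.source_id}")
    remap = {old: new for new, old in enumerate(keep)}
    atoms = [replace(protein.atoms[old], index=new) for old, new in remap.items()]
    bonds = [BondRecord(remap[b.i], remap[b.j], order=b.order,
                        is_conjugated=b.is_conjugated, is_in_ring=b.is_in_ring)
             for b in protein.bonds if b.i in remap and b.j in remap]
    return MolecularStructure(atoms, bonds, role="pocket",
                              source_id=protein.source_id)


def _molecule_graph(s: MolecularStructure, schema: FeatureSchema,
                    voronoi_spec: VoronoiSpec | None,
                    sh_spec: SphericalHarmonicSpec | None,
                    elec_spec: ElectrostaticSpec | None):
    nodes = compute_node_features(s, schema, voronoi_spec, sh_spec)
    edges_undirected = compute_edge_features(s, elec_spec, schema)
    if s.bonds:
        src = np.array([b.i for b in s.bonds] + [b.j for b in s.bonds])
        dst = np.array([b.j for b in s.bonds] + [b.i for b in s.bonds])
        edge_index = np.vstack([src, dst])
        edge_matrix = np.vstack([edges_undirected, edges_undirected])
    else:
        edge_index = np.zeros((2, 0), dtype=int)
        edge_matrix = np.zeros((0, schema.edge_dim))
    return nodes, edge_index, edge_matrix


def assemble_complex_graph(pocket: MolecularStructure, ligand: MolecularStructure,
                           schema: FeatureSchema | None = None,
                           voronoi_spec: VoronoiSpec | None = None,
                           sh_spec: SphericalHarmonicSpec | None = None,
                           elec_spec: ElectrostaticSpec | None = None,
                           complex_id: str = "",
                           affinity: float | None = None) -> ComplexGraph:
    """Featurize both molecules and take their disjoint union.

    Ligand node indices are offset by the pocket size; each covalent bond
    appears as two directed edges; no pocket-ligand edges are added.
    """
    schema = schema or default_schema()
    pn, pe_idx, pe_mat = _molecule_graph(pocket, schema, voronoi_spec, sh_spec, elec_spec)
    ln, le_idx, le_mat = _molecule_graph(ligand, schema, voronoi_spec, sh_spec, elec_spec)
    if pn.shape[1] != schema.node_dim or ln.shape[1] != schema.node_dim:
        raise DimensionError("node feature width disagrees with schema")
    offset = pn.shape[0]
    node_matrix = np.vstack([pn, ln])
    edge_index = np.hstack([pe_idx, le_idx + offset]).astype(int)
    edge_matrix = np.vstack([pe_mat, le_mat])
    gp = molecular_descriptors(pocket, role="pocket", schema=schema).values
    gl = molecular_descriptors(ligand, role="ligand", schema=schema).values
    provenance = np.array(["pocket"] * pn.shape[0] + ["ligand"] * ln.shape[0])
    return ComplexGraph(node_matrix, edge_index, edge_matrix,
                        np.concatenate([gp, gl]), provenance,
                        complex_id=complex_id or f"{pocket.source_id}:{ligand.source_id}",
                        affinity=affinity)


def build_complex_graph(protein: MolecularStructure, ligand: MolecularStructure,
                        cfg: GraphConfig | None = None,
                        schema: FeatureSchema | None = None,
                        voronoi_spec: VoronoiSpec | None = None,
                        sh_spec: SphericalHarmonicSpec | None = None,
                        elec_spec: ElectrostaticSpec | None = None,
                        complex_id: str = "",
                        affinity: float | None = None) -> ComplexGraph:
    """Full per-complex pipeline: sanitize, cut pocket, charge, featurize."""
    ligand = sanitize_structure(ligand)
    protein = sanitize_structure(protein)
    pocket = select_pocket_atoms(protein, ligand, cfg)
    pocket = sanitize_structure(pocket)
    pocket = assign_gasteiger_charges(pocket)
    ligand = assign_gasteiger_charges(ligand)
    return assemble_complex_graph(pocket, ligand, schema, voronoi_spec, sh_spec,
                                  elec_spec, complex_id=complex_id, affinity=affinity)


@dataclass
class NormalizationStats:
    """Per-feature min/max for node, edge, and graph-level blocks."""

    node_min: np.ndarray
    node_max: np.ndarray
    edge_min: np.ndarray
    edge_max: np.ndarray
    graph_min: np.ndarray
    graph_max: np.ndarray

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({k: getattr(self, k).tolist() for k in
                              ("node_min", "node_max", "edge_min", "edge_max",
                               "graph_min", "graph_max")})
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "NormalizationStats":
        p = Path(str(text_or_path))
        d = json.loads(p.read_text() if p.exists() else str(text_or_path))
        return cls(**{k: np.asarray(v, dtype=float) for k, v in d.items()})


def _scale(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    out = (x - lo) / safe
    out = np.where(span > 0, out, 0.0)  # constant columns map to 0
    return np.clip(out, 0.0, 1.0)


def minmax_normalize(graphs: list[ComplexGraph],
                     stats: NormalizationStats | None = None
                     ) -> tuple[list[ComplexGraph], NormalizationStats]:
    """Min-max scale every feature column to [0, 1].

    When ``stats`` is None they are fit on the given graphs (training
    time); otherwise the supplied statistics are applied without refitting
    and out-of-range values are clipped (test time).
    """
    if not graphs:
        raise ValueError("need at least one graph")
    if stats is None:
        all_nodes = np.vstack([g.node_matrix for g in graphs])
        edge_stack = [g.edge_matrix for g in graphs if g.n_edges]
        all_edges = np.vstack(edge_stack) if edge_stack \
            else np.zeros((1, graphs[0].edge_matrix.shape[1]))
        all_graph = np.vstack([g.graph_vector for g in graphs])
        stats = NormalizationStats(
            node_min=all_nodes.min(axis=0), node_max=all_nodes.max(axis=0),
            edge_min=all_edges.min(axis=0), edge_max=all_edges.max(axis=0),
            graph_min=all_graph.min(axis=0), graph_max=all_graph.max(axis=0),
        )
    out = []
    for g in graphs:
        out.append(ComplexGraph(
            node_matrix=_scale(g.node_matrix, stats.node_min, stats.node_max),
            edge_index=g.edge_index.copy(),
            edge_matrix=(_scale(g.edge_matrix, stats.edge_min, stats.edge_max)
                         if g.n_edges else g.edge_matrix.copy()),
            graph_vector=_scale(g.graph_vector, stats.graph_min, stats.graph_max),
            node_provenance=g.node_provenance.copy(),
            complex_id=g.complex_id, affinity=g.affinity,
        ))
    return out, stats


def save_graphs_jsonl(graphs: list[ComplexGraph], path: str | Path) -> None:
    """One complex per line: ids, matrices, provenance, affinity."""
    with open(path, "w") as fh:
        for g in graphs:
            fh.write(json.dumps({
                "complex_id": g.complex_id,
                "affinity": g.affinity,
                "node_matrix": g.node_matrix.tolist(),
                "edge_index": g.edge_index.tolist(),
                "edge_matrix": g.edge_matrix.tolist(),
                "graph_vector": g.graph_vector.tolist(),
                "node_provenance": g.node_provenance.tolist(),
            }) + "\n")


def load_graphs_jsonl(path: str | Path) -> list[ComplexGraph]:
    graphs = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        d = json.loads(line)
        edge_index = np.asarray(d["edge_index"], dtype=int)
        if edge_index.size == 0:
            edge_index = np.zeros((2, 0), dtype=int)
        edge_matrix = np.asarray(d["edge_matrix"], dtype=float)
        if edge_matrix.size == 0:
            edge_matrix = edge_matrix.reshape(0, default_schema().edge_dim)
        graphs.append(ComplexGraph(
            node_matrix=np.asarray(d["node_matrix"], dtype=float),
            edge_index=edge_index,
            edge_matrix=edge_matrix,
            graph_vector=np.asarray(d["graph_vector"], dtype=float),
            node_provenance=np.asarray(d["node_provenance"]),
            complex_id=d["complex_id"], affinity=d["affinity"],
        ))
    return graphs
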