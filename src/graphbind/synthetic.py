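"""Synthetic pocket-ligand complex generator with a known affinity law.

Real affinity corpora are multi-gigabyte downloads; development, testing
and calibration instead run on fabricated complexes that exercise every
pipeline stage: random chemically valid ligands (tree/branched topologies
over C/N/O/S with correct valences and clash-free 3D coordinates),
protein-like residue clouds placed in a radial shell around the ligand,
and affinities drawn from a *stated structural law*,

    y = mean + sd * standardize(w_h * heavy_atoms
                                + w_c * contacts(<= 4 A)
                                + w_v * mean ligand Voronoi volume) + noise,

clipped to the 2-12 -log10(Kd/Ki) range.  The Voronoi term carries the
largest weight on purpose: ablation experiments then have a known
ground-truth driver among the node features.  Ligand elongation (the
``chain_bias`` knob) varies the Voronoi volumes independently of atom
count, so the three law terms are not collinear.

Everything is a pure function of (seed, spec): two different seeds give
disjoint structure sets, one seed gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureSchema
from .geometry import VoronoiSpec, voronoi_descriptor
from .graphs import ComplexGraph, GraphConfig, build_complex_graph
from .structures import (AMINO_ACIDS, AtomRecord, BondRecord,
                         MolecularStructure, write_pdb)

__all__ = [
    "AffinityLaw", "FixtureSpec", "ComplexRecord", "FixtureDataset",
    "make_ligand", "make_pocket", "make_dataset", "make_active_decoy_sets",
    "featurize_dataset", "write_dataset",
]

_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2}
_ELEMENTS = ("C", "N", "O", "S")
_ELEMENT_P = (0.70, 0.10, 0.15, 0.05)
_ATOMIC_NUM = {"C": 6, "N": 7, "O": 8, "S": 16}
_MIN_SEPARATION = 1.0   # A, steric floor between non-bonded ligand atoms
_BOND_RANGE = (1.3, 1.6)


@dataclass(frozen=True)
class AffinityLaw:
    """Weights and scaling of the structural affinity law."""

    w_heavy: float = 0.4
    w_contacts: float = 0.4
    w_voronoi: float = 1.0
    contact_cutoff: float = 4.0   # A
    target_mean: float = 7.0
    target_sd: float = 1.5
    clip_lo: float = 2.0
    clip_hi: float = 12.0


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one fabricated dataset."""

    seed: int = 0
    n_complexes: int = 100
    ligand_size_range: tuple[int, int] = (6, 30)
    pocket_shell: tuple[float, float] = (3.0, 8.0)
    n_pocket_atoms: int = 60
    noise_sd: float = 0.25
    law: AffinityLaw = field(default_factory=AffinityLaw)

    def __post_init__(self) -> None:
        lo, hi = self.ligand_size_range
        if not (2 <= lo <= hi):
            raise ValueError("ligand_size_range must be ordered and >= 2")
        inner, outer = self.pocket_shell
        if not (0 < inner < outer):
            raise ValueError("pocket_shell radii must be positive and ordered")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class ComplexRecord:
    complex_id: str
    protein: MolecularStructure
    ligand: MolecularStructure
    affinity: float


@dataclass
class FixtureDataset:
    """Generated complexes plus the law bookkeeping needed for recovery tests."""

    records: list[ComplexRecord]
    law: AffinityLaw
    law_features: pd.DataFrame      # heavy, contacts, voronoi per complex
    standardization: dict           # means/stds used inside the law

    @property
    def affinities(self) -> np.ndarray:
        return np.array([r.affinity for r in self.records])


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def make_ligand(seed: int, n_heavy: int,
                chain_bias: float | None = None) -> MolecularStructure:
    """Random chemically valid single-bonded molecule over {C, N, O, S}.

    A random tree respecting element valences is grown atom by atom;
    ``chain_bias`` in [0, 1] controls elongation (1 = chain-like, 0 =
    star-like), defaulting to a seed-drawn uniform value.  Coordinates are
    embedded with bond lengths in 1.3-1.6 A and no non-bonded pair closer
    than 1 A (placement retries internally).
    """
    if n_heavy < 2:
        raise ValueError("n_heavy must be >= 2")
    rng = np.random.default_rng(seed)
    if chain_bias is None:
        chain_bias = float(rng.uniform())
    elements = ["C"]
    degrees = [0]
    parents: list[int] = []
    for _ in range(1, n_heavy):
        free = [i for i, e in enumerate(elements) if degrees[i] < _VALENCE[e]]
        if rng.uniform() < chain_bias:
            parent = free[-1]          # extend the growing end: chain
        else:
            parent = free[rng.integers(len(free))]
        elem = _ELEMENTS[rng.choice(len(_ELEMENTS), p=_ELEMENT_P)]
        parents.append(parent)
        degrees[parent] += 1
        elements.append(elem)
        degrees.append(1)
    coords = np.zeros((n_heavy, 3))
    for i in range(1, n_heavy):
        p = parents[i - 1]
        placed = coords[:i]
        best, best_sep = None, -np.inf
        for _try in range(60):
            cand = coords[p] + _random_unit(rng) * rng.uniform(*_BOND_RANGE)
            sep = np.min(np.linalg.norm(placed - cand, axis=1)[
                np.arange(i) != p]) if i > 1 else np.inf
            if sep > best_sep:
                best, best_sep = cand, sep
            if sep >= _MIN_SEPARATION:
                break
        coords[i] = best
    atoms = [AtomRecord(index=i, element=e, atomic_number=_ATOMIC_NUM[e],
                        coords=tuple(coords[i]), residue_name="LIG",
                        residue_index=1, is_ligand=True)
             for i, e in enumerate(elements)]
    bonds = [BondRecord(p, i) for i, p in enumerate(parents, start=1)]
    return MolecularStructure(atoms, bonds, role="ligand",
                              source_id=f"lig{seed}")


def make_pocket(ligand: MolecularStructure, seed: int, n_atoms: int = 60,
                shell: tuple[float, float] = (3.0, 8.0)) -> MolecularStructure:
    """Protein-like residue cloud in a radial shell around the ligand.

    Residues are N-CA-C backbone triplets with 20-letter amino-acid labels,
    anchored at shell distances from randomly chosen ligand atoms; local
    bonding is peptide-like (two ~1.5 A bonds per residue).  The shell is
    chosen to straddle the pocket cutoff so selection keeps a strict,
    non-empty subset.
    """
    rng = np.random.default_rng(seed)
    inner, outer = shell
    lig_xyz = ligand.coords
    n_res = max(1, int(np.ceil(n_atoms / 3)))
    atoms: list[AtomRecord] = []
    bonds: list[BondRecord] = []
    placed: list[np.ndarray] = []
    idx = 0
    for r in range(n_res):
        resname = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
        for _try in range(80):
            anchor = lig_xyz[rng.integers(len(lig_xyz))]
            center = anchor + _random_unit(rng) * rng.uniform(inner, outer)
            tri = [center]
            for blen in (1.46, 1.52):
                tri.append(tri[-1] + _random_unit(rng) * blen)
            tri_arr = np.array(tri)
            d_lig = np.linalg.norm(
                lig_xyz[None, :, :] - tri_arr[:, None, :], axis=-1).min()
            d_pocket = (np.linalg.norm(
                np.array(placed)[None, :, :] - tri_arr[:, None, :],
                axis=-1).min() if placed else np.inf)
            if d_lig >= 1.9 and d_pocket >= 1.8:
                break
        for k, (pos, elem) in enumerate(zip(tri, ("N", "C", "C"))):
            atoms.append(AtomRecord(
                index=idx + k, element=elem, atomic_number=_ATOMIC_NUM[elem],
                coords=tuple(pos), residue_name=resname, residue_index=r + 1))
            placed.append(np.asarray(pos))
        bonds.append(BondRecord(idx, idx + 1))
        bonds.append(BondRecord(idx + 1, idx + 2))
        idx += 3
        if idx >= n_atoms:
            break
    return MolecularStructure(atoms[:], bonds, role="protein",
                              source_id=f"prot{seed}")


def _law_features(protein: MolecularStructure, ligand: MolecularStructure,
                  law: AffinityLaw) -> tuple[float, float, float]:
    heavy = float(ligand.heavy_atom_count())
    d = np.linalg.norm(protein.coords[:, None, :] - ligand.coords[None, :, :],
                       axis=-1)
    # contact count = protein atoms in contact (within the cutoff) with the
    # ligand; an atom count, so the quantity stays visible to a
    # structure-only featurizer through the selected pocket
    contacts = float(np.sum(d.min(axis=1) <= law.contact_cutoff))
    voro = float(np.mean(voronoi_descriptor(ligand.coords, VoronoiSpec())))
    return heavy, contacts, voro


def _generate_records(spec: FixtureSpec, rng: np.random.Generator,
                      tag: str, chain_bias_fn=None,
                      shell: tuple[float, float] | None = None
                      ) -> tuple[list[ComplexRecord], pd.DataFrame]:
    lo, hi = spec.ligand_size_range
    shell = shell or spec.pocket_shell
    records, rows = [], []
    for k in range(spec.n_complexes):
        lig_seed = int(rng.integers(2 ** 31 - 1))
        pock_seed = int(rng.integers(2 ** 31 - 1))
        n_heavy = int(rng.integers(lo, hi + 1))
        bias = chain_bias_fn(rng) if chain_bias_fn else None
        ligand = make_ligand(lig_seed, n_heavy, chain_bias=bias)
        protein = make_pocket(ligand, pock_seed, spec.n_pocket_atoms, shell)
        cid = f"{tag}{k:04d}"
        records.append(ComplexRecord(cid, protein, ligand, float("nan")))
        h, c, v = _law_features(protein, ligand, spec.law)
        rows.append({"complex_id": cid, "heavy": h, "contacts": c, "voronoi": v})
    return records, pd.DataFrame(rows)


def _apply_law(records: list[ComplexRecord], feats: pd.DataFrame,
               law: AffinityLaw, noise_sd: float,
               rng: np.random.Generator,
               standardization: dict | None = None) -> dict:
    if standardization is None:
        standardization = {
            c: (float(feats[c].mean()), float(max(feats[c].std(ddof=0), 1e-12)))
            for c in ("heavy", "contacts", "voronoi")}
    z = {c: (feats[c].to_numpy() - standardization[c][0]) / standardization[c][1]
         for c in ("heavy", "contacts", "voronoi")}
    raw = (law.w_heavy * z["heavy"] + law.w_contacts * z["contacts"]
           + law.w_voronoi * z["voronoi"])
    # standardize the combination itself: the law terms are correlated, so
    # the weight norm would understate the spread
    if "_raw" not in standardization:
        standardization["_raw"] = (float(raw.mean()),
                                   float(max(raw.std(), 1e-12)))
    rm, rs = standardization["_raw"]
    y = law.target_mean + law.target_sd * (raw - rm) / rs
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=len(y))
    y = np.clip(y, law.clip_lo, law.clip_hi)
    for rec, val in zip(records, y):
        rec.affinity = float(val)
    return standardization


def make_dataset(spec: FixtureSpec | None = None) -> FixtureDataset:
    """Fabricate ``n_complexes`` pocket-ligand pairs with law affinities."""
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    records, feats = _generate_records(spec, rng, tag="cplx")
    standardization = _apply_law(records, feats, spec.law, spec.noise_sd, rng)
    return FixtureDataset(records, spec.law, feats, standardization)


def _scaled_law_value(heavy: float, contacts: float, voronoi: float,
                      law: AffinityLaw, standardization: dict) -> float:
    z = [(heavy - standardization["heavy"][0]) / standardization["heavy"][1],
         (contacts - standardization["contacts"][0]) / standardization["contacts"][1],
         (voronoi - standardization["voronoi"][0]) / standardization["voronoi"][1]]
    raw = law.w_heavy * z[0] + law.w_contacts * z[1] + law.w_voronoi * z[2]
    rm, rs = standardization["_raw"]
    return law.target_mean + law.target_sd * (raw - rm) / rs


def make_active_decoy_sets(spec: FixtureSpec | None = None, shift: float = 3.0,
                           candidates_per_active: int = 24
                           ) -> tuple[FixtureDataset, FixtureDataset]:
    """Active/decoy pair of datasets for screening evaluation.

    Decoys come from the plain generator and define the law's reference
    frame (standardization).  Each active reuses one decoy's ligand size
    (exact size matching) and is chosen, among a few structurally biased
    candidates (elongated ligand, pocket shell pulled inward), as the one
    whose *structural* law value lies closest to the decoy population
    mean + ``shift`` — actives really are better binders by the stated
    margin, not merely relabelled, and they share a potency band the way
    screening actives do.  Labels are the (shifted) law values plus the
    usual noise.  shift = 0 reduces to size-matched draws centred on the
    same mean.
    """
    spec = spec or FixtureSpec()
    if shift < 0:
        raise ValueError("shift must be >= 0")
    law = spec.law
    rng = np.random.default_rng(spec.seed + 7)
    decoy_records, decoy_feats = _generate_records(spec, rng, tag="dcy")
    standardization = _apply_law(decoy_records, decoy_feats, law,
                                 spec.noise_sd, rng)
    decoy_scaled = np.array([
        _scaled_law_value(r.heavy, r.contacts, r.voronoi, law, standardization)
        for r in decoy_feats.itertuples(index=False)])

    inner, outer = spec.pocket_shell
    active_shell = (max(1.9, inner - 0.35 * shift), outer)
    bias_exponent = 1.0 / (1.0 + 2.0 * shift)  # u**e skews chain_bias -> 1

    target = float(decoy_scaled.mean()) + shift
    records, rows = [], []
    for k, dec_rec in enumerate(decoy_records):
        n_heavy = dec_rec.ligand.heavy_atom_count()
        best = None
        for _cand in range(max(1, candidates_per_active)):
            lig_seed = int(rng.integers(2 ** 31 - 1))
            pock_seed = int(rng.integers(2 ** 31 - 1))
            bias = float(rng.uniform() ** bias_exponent)
            ligand = make_ligand(lig_seed, n_heavy, chain_bias=bias)
            protein = make_pocket(ligand, pock_seed, spec.n_pocket_atoms,
                                  active_shell)
            h, c, v = _law_features(protein, ligand, law)
            s = _scaled_law_value(h, c, v, law, standardization)
            if best is None or abs(s - target) < abs(best[0] - target):
                best = (s, ligand, protein, h, c, v)
            if abs(s - target) < 0.2:
                break
        s, ligand, protein, h, c, v = best
        y = s + (rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0)
        y = float(np.clip(y, law.clip_lo, law.clip_hi))
        cid = f"act{k:04d}"
        records.append(ComplexRecord(cid, protein, ligand, y))
        rows.append({"complex_id": cid, "heavy": h, "contacts": c, "voronoi": v})
    actives = FixtureDataset(records, law, pd.DataFrame(rows), standardization)
    decoys = FixtureDataset(decoy_records, law, decoy_feats, standardization)
    return actives, decoys


def featurize_dataset(dataset: FixtureDataset,
                      graph_config: GraphConfig | None = None,
                      schema: FeatureSchema | None = None
                      ) -> tuple[list[ComplexGraph], np.ndarray]:
    """Build complex graphs + affinity vector for every record."""
    graphs = []
    for rec in dataset.records:
        graphs.append(build_complex_graph(
            rec.protein, rec.ligand, graph_config, schema,
            complex_id=rec.complex_id, affinity=rec.affinity))
    return graphs, dataset.affinities


def write_dataset(dataset: FixtureDataset, directory: str | Path) -> Path:
    """Write PDB-style files + manifest TSV shaped like a real-data manifest."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in dataset.records:
        pocket_path = d / f"{rec.complex_id}_pocket.pdb"
        ligand_path = d / f"{rec.complex_id}_ligand.pdb"
        write_pdb(rec.protein, pocket_path)
        write_pdb(rec.ligand, ligand_path)
        rows.append({"complex_id": rec.complex_id,
                     "pocket_path": pocket_path.name,
                     "ligand_path": ligand_path.name,
                     "affinity": rec.affinity,
                     "affinity_type": "Kd"})
    manifest = d / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest
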