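"""Reading, validating and sanitizing 3D molecular structures.

Structures arrive as PDB-style (ATOM/HETATM/CONECT) or mol2-style
(@<TRIPOS> sections) files describing either a protein, a pre-cut binding
pocket, or a ligand.  They are held in a light internal representation
(:class:`MolecularStructure`) that records atoms, covalent bonds and a role
tag; chemistry checks (valence, aromaticity) are delegated to RDKit through
:func:`sanitize_structure`, which rejects invalid structures rather than
repairing them.

PDB files without CONECT records carry no bond information; covalent bonds
are then inferred with the standard covalent-radius heuristic
(bond iff d_ij < r_i + r_j + 0.45 A).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from .errors import EmptyStructureError, ParseError, SanitizationError

__all__ = [
    "AtomRecord",
    "BondRecord",
    "MolecularStructure",
    "load_structure",
    "sanitize_structure",
    "structure_to_rdkit",
    "write_pdb",
    "read_manifest",
]

_PT = Chem.GetPeriodicTable()

#: Covalent radii in Angstrom used for distance-based bond inference.
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "Cl": 1.02, "Br": 1.20, "I": 1.39, "B": 0.84, "Si": 1.11,
}
_BOND_SLACK = 0.45  # A added on top of the radius sum

_ORDER_TO_RDKIT = {
    "single": Chem.BondType.SINGLE,
    "double": Chem.BondType.DOUBLE,
    "triple": Chem.BondType.TRIPLE,
    "aromatic": Chem.BondType.AROMATIC,
}
_RDKIT_TO_ORDER = {v: k for k, v in _ORDER_TO_RDKIT.items()}

AMINO_ACIDS = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)


@dataclass
class AtomRecord:
    """One atom: element, position, residue context and charges."""

    index: int
    element: str
    atomic_number: int
    coords: tuple[float, float, float]
    residue_name: str = "LIG"
    residue_index: int = 0
    formal_charge: int = 0
    partial_charge: float = 0.0
    is_ligand: bool = False

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.coords):
            raise ParseError(f"atom {self.index}: non-finite coordinates {self.coords}")
        if self.atomic_number <= 0:
            raise ParseError(f"atom {self.index}: bad atomic number {self.atomic_number}")


@dataclass
class BondRecord:
    """One covalent bond between atoms ``i`` and ``j`` of the same molecule."""

    i: int
    j: int
    order: str = "single"
    is_conjugated: bool = False
    is_in_ring: bool = False
    length: float = 0.0

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ParseError(f"bond connects atom {self.i} to itself")
        if self.order not in _ORDER_TO_RDKIT:
            raise ParseError(f"unknown bond order {self.order!r}")


@dataclass
class MolecularStructure:
    """Atoms + bonds of one molecule with a role (protein | pocket | ligand)."""

    atoms: list[AtomRecord]
    bonds: list[BondRecord]
    role: str
    source_id: str = ""
    charges_assigned: bool = False

    def __post_init__(self) -> None:
        if self.role not in ("protein", "pocket", "ligand"):
            raise ValueError(f"unknown role {self.role!r}")
        n = len(self.atoms)
        seen = {a.index for a in self.atoms}
        if len(seen) != n:
            raise ParseError("duplicate atom indices")
        for b in self.bonds:
            if b.i not in seen or b.j not in seen:
                raise ParseError(f"bond ({b.i},{b.j}) references a missing atom")
        # bond lengths always derived from coordinates
        pos = {a.index: np.asarray(a.coords) for a in self.atoms}
        for b in self.bonds:
            b.length = float(np.linalg.norm(pos[b.i] - pos[b.j]))

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in atom order."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def heavy_atom_count(self) -> int:
        return sum(1 for a in self.atoms if a.element != "H")


def _element_from_pdb_line(line: str) -> str:
    elem = line[76:78].strip() if len(line) >= 78 else ""
    if not elem:
        # fall back on the atom-name columns, stripping digits/remoteness codes
        name = line[12:16].strip()
        elem = "".join(ch for ch in name if ch.isalpha())[:2]
        if len(elem) == 2 and elem[1].islower() is False:
            elem = elem[0]
    return elem.capitalize() if len(elem) == 2 else elem.upper()


def _infer_bonds(atoms: list[AtomRecord]) -> list[BondRecord]:
    """Covalent-radius heuristic bonds for coordinate-only files."""
    coords = np.array([a.coords for a in atoms])
    radii = np.array([COVALENT_RADII.get(a.element, 1.5) for a in atoms])
    bonds: list[BondRecord] = []
    n = len(atoms)
    if n < 2:
        return bonds
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    thr = radii[:, None] + radii[None, :] + _BOND_SLACK
    ii, jj = np.where((d < thr) & (d > 1e-6))
    for i, j in zip(ii.tolist(), jj.tolist()):
        if i < j:
            bonds.append(BondRecord(atoms[i].index, atoms[j].index))
    return bonds


def _parse_pdb(path: Path, role: str) -> MolecularStructure:
    atoms: list[AtomRecord] = []
    conect: set[tuple[int, int]] = set()
    serial_to_index: dict[int, int] = {}
    is_lig = role == "ligand"
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        rec = line[:6].strip()
        if rec in ("ATOM", "HETATM"):
            try:
                serial = int(line[6:11])
                x = float(line[30:38]); y = float(line[38:46]); z = float(line[46:54])
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: malformed coordinate record") from exc
            elem = _element_from_pdb_line(line)
            try:
                anum = _PT.GetAtomicNumber(elem)
            except Exception as exc:
                raise ParseError(f"{path.name}:{lineno}: unknown element {elem!r}") from exc
            resname = line[17:20].strip() or ("LIG" if is_lig else "UNK")
            try:
                resseq = int(line[22:26])
            except ValueError:
                resseq = 0
            idx = len(atoms)
            serial_to_index[serial] = idx
            atoms.append(AtomRecord(
                index=idx, element=elem, atomic_number=anum, coords=(x, y, z),
                residue_name="LIG" if is_lig else resname, residue_index=resseq,
                is_ligand=is_lig,
            ))
        elif rec == "CONECT":
            fields = line.split()[1:]
            try:
                serials = [int(f) for f in fields]
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: malformed CONECT record") from exc
            if serials:
                a0, partners = serials[0], serials[1:]
                for p in partners:
                    conect.add((min(a0, p), max(a0, p)))
    if not atoms:
        raise EmptyStructureError(f"{path.name}: no ATOM/HETATM records")
    if conect:
        bonds = []
        for s_i, s_j in sorted(conect):
            if s_i not in serial_to_index or s_j not in serial_to_index:
                raise ParseError(f"{path.name}: CONECT references missing atom serial "
                                 f"{s_i if s_i not in serial_to_index else s_j}")
            bonds.append(BondRecord(serial_to_index[s_i], serial_to_index[s_j]))
    else:
        bonds = _infer_bonds(atoms)
    return MolecularStructure(atoms, bonds, role, source_id=path.stem)


_MOL2_ORDER = {"1": "single", "2": "double", "3": "triple", "ar": "aromatic",
               "am": "single", "du": "single", "un": "single"}


def _parse_mol2(path: Path, role: str) -> MolecularStructure:
    atoms: list[AtomRecord] = []
    bonds: list[BondRecord] = []
    id_to_index: dict[int, int] = {}
    section = None
    is_lig = role == "ligand"
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if line.startswith("@<TRIPOS>"):
            section = line[9:].upper()
            continue
        if not line or line.startswith("#") or section is None:
            continue
        if section == "ATOM":
            parts = line.split()
            if len(parts) < 6:
                raise ParseError(f"{path.name}:{lineno}: short ATOM record")
            try:
                aid = int(parts[0])
                x, y, z = float(parts[2]), float(parts[3]), float(parts[4])
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: malformed ATOM record") from exc
            elem = parts[5].split(".")[0]
            elem = elem.capitalize() if len(elem) > 1 else elem.upper()
            try:
                anum = _PT.GetAtomicNumber(elem)
            except Exception as exc:
                raise ParseError(f"{path.name}:{lineno}: unknown element {elem!r}") from exc
            resname = parts[7][:3].upper() if len(parts) > 7 else "LIG"
            charge = float(parts[8]) if len(parts) > 8 else 0.0
            idx = len(atoms)
            id_to_index[aid] = idx
            atoms.append(AtomRecord(
                index=idx, element=elem, atomic_number=anum, coords=(x, y, z),
                residue_name="LIG" if is_lig else resname,
                residue_index=int(parts[6]) if len(parts) > 6 else 0,
                partial_charge=charge, is_ligand=is_lig,
            ))
        elif section == "BOND":
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"{path.name}:{lineno}: short BOND record")
            try:
                ai, aj = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: malformed BOND record") from exc
            order = _MOL2_ORDER.get(parts[3].lower(), "single")
            if ai not in id_to_index or aj not in id_to_index:
                raise ParseError(f"{path.name}:{lineno}: bond references missing atom id")
            bonds.append(BondRecord(id_to_index[ai], id_to_index[aj], order=order))
    if not atoms:
        raise EmptyStructureError(f"{path.name}: no atoms in TRIPOS ATOM section")
    return MolecularStructure(atoms, bonds, role, source_id=path.stem)


def load_structure(path: str | Path, role: str) -> MolecularStructure:
    """Parse a PDB-style or mol2-style file into a :class:`MolecularStructure`.

    Hydrogens are retained when present and never added.  Bond orders are
    taken from the file when available (mol2, CONECT multiplicity ignored)
    and inferred geometrically otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix == ".mol2":
        return _parse_mol2(path, role)
    return _parse_pdb(path, role)


def structure_to_rdkit(s: MolecularStructure, sanitize: bool = True) -> Chem.Mol:
    """Build an RDKit molecule (with 3D conformer) from a structure.

    Raises :class:`SanitizationError` naming the offending atom when RDKit's
    chemistry checks fail.
    """
    mol = Chem.RWMol()
    for a in s.atoms:
        atom = Chem.Atom(a.atomic_number)
        atom.SetFormalCharge(a.formal_charge)
        mol.AddAtom(atom)
    index_map = {a.index: pos for pos, a in enumerate(s.atoms)}
    aromatic_atoms = set()
    for b in s.bonds:
        bi, bj = index_map[b.i], index_map[b.j]
        mol.AddBond(bi, bj, _ORDER_TO_RDKIT[b.order])
        if b.order == "aromatic":
            aromatic_atoms.update((bi, bj))
    for pos in aromatic_atoms:
        mol.GetAtomWithIdx(pos).SetIsAromatic(True)
    for b in s.bonds:
        if b.order == "aromatic":
            mol.GetBondBetweenAtoms(index_map[b.i], index_map[b.j]).SetIsAromatic(True)
    conf = Chem.Conformer(mol.GetNumAtoms())
    for a in s.atoms:
        conf.SetAtomPosition(index_map[a.index], a.coords)
    mol.AddConformer(conf, assignId=True)
    out = mol.GetMol()
    if sanitize:
        try:
            Chem.SanitizeMol(out)
        except Chem.AtomValenceException as exc:
            # RDKit reports the atom index in the message
            raise SanitizationError(f"{s.source_id}: valence violation ({exc})") from exc
        except Exception as exc:
            raise SanitizationError(f"{s.source_id}: sanitization failed ({exc})") from exc
    return out


def _structure_from_rdkit(mol: Chem.Mol, template: MolecularStructure,
                          keep: list[int]) -> MolecularStructure:
    """Rebuild a structure from a sanitized RDKit mol, refreshing bond flags."""
    conf = mol.GetConformer()
    old_atoms = [template.atoms[k] for k in keep]
    atoms = []
    for new_idx, (rd_atom, old) in enumerate(zip(mol.GetAtoms(), old_atoms)):
        p = conf.GetAtomPosition(new_idx)
        atoms.append(replace(old, index=new_idx, coords=(p.x, p.y, p.z),
                             formal_charge=rd_atom.GetFormalCharge()))
    bonds = []
    for rd_bond in mol.GetBonds():
        bt = rd_bond.GetBondType()
        order = "aromatic" if rd_bond.GetIsAromatic() else _RDKIT_TO_ORDER.get(bt, "single")
        bonds.append(BondRecord(
            rd_bond.GetBeginAtomIdx(), rd_bond.GetEndAtomIdx(), order=order,
            is_conjugated=rd_bond.GetIsConjugated(), is_in_ring=rd_bond.IsInRing(),
        ))
    return MolecularStructure(atoms, bonds, template.role, template.source_id,
                              charges_assigned=template.charges_assigned)


def sanitize_structure(s: MolecularStructure) -> MolecularStructure:
    """Validate chemistry and refresh aromaticity/conjugation/ring flags.

    Valences are checked per element; aromatic rings are perceived
    consistently; a failing structure raises :class:`SanitizationError`
    (filter, don't repair).  A ligand with disconnected fragments keeps its
    largest connected component with a warning (counter-ions are artifacts).

    Idempotent: ``sanitize(sanitize(s)) == sanitize(s)``.
    """
    if s.role == "ligand" and s.heavy_atom_count() < 1:
        raise SanitizationError(f"{s.source_id}: ligand has no heavy atoms")
    keep = list(range(s.n_atoms))
    work = s
    if s.role == "ligand" and s.bonds is not None:
        comps = _connected_components(s)
        if len(comps) > 1:
            warnings.warn(
                f"{s.source_id}: ligand has {len(comps)} fragments; keeping largest",
                stacklevel=2,
            )
            largest = max(comps, key=len)
            keep = sorted(largest)
            remap = {old: new for new, old in enumerate(keep)}
            atoms = [replace(s.atoms[k], index=remap[k]) for k in keep]
            bonds = [replace(b, i=remap[b.i], j=remap[b.j])
                     for b in s.bonds if b.i in remap and b.j in remap]
            work = MolecularStructure(atoms, bonds, s.role, s.source_id)
    mol = structure_to_rdkit(work, sanitize=True)
    return _structure_from_rdkit(mol, s, keep)


def _connected_components(s: MolecularStructure) -> list[set[int]]:
    adj: dict[int, set[int]] = {a.index: set() for a in s.atoms}
    for b in s.bonds:
        adj[b.i].add(b.j)
        adj[b.j].add(b.i)
    seen: set[int] = set()
    comps = []
    for start in adj:
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            stack.extend(adj[v] - comp)
        seen |= comp
        comps.append(comp)
    return comps


def write_pdb(s: MolecularStructure, path: str | Path) -> None:
    """Canonical PDB-style dump (ATOM/HETATM + CONECT) used for round-trips."""
    lines = []
    hetatm = s.role == "ligand"
    for a in s.atoms:
        rec = "HETATM" if hetatm else "ATOM  "
        name = f"{a.element}{a.index % 100}"[:4]
        x, y, z = a.coords
        lines.append(
            f"{rec}{a.index + 1:>5} {name:<4} {a.residue_name:>3} A"
            f"{a.residue_index:>4}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}          {a.element:>2}"
        )
    for b in s.bonds:
        lines.append(f"CONECT{b.i + 1:>5}{b.j + 1:>5}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_manifest(path: str | Path, drop_ic50: bool = True) -> pd.DataFrame:
    """Read a dataset manifest (TSV/CSV).

    Columns: complex_id, pocket_path, ligand_path, affinity, affinity_type.
    Complexes whose affinity is reported as IC50 are excluded by default,
    since IC50 is measured on a different scale than Kd/Ki.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    required = {"complex_id", "pocket_path", "ligand_path", "affinity"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path.name}: manifest missing columns {sorted(missing)}")
    if drop_ic50 and "affinity_type" in df.columns:
        df = df[df["affinity_type"].str.upper() != "IC50"].reset_index(drop=True)
    return df


def assign_gasteiger_charges(s: MolecularStructure) -> MolecularStructure:
    """Populate ``partial_charge`` on every atom with Gasteiger charges."""
    mol = structure_to_rdkit(s, sanitize=True)
    AllChem.ComputeGasteigerCharges(mol)
    atoms = []
    for a, rd_atom in zip(s.atoms, mol.GetAtoms()):
        q = rd_atom.GetDoubleProp("_GasteigerCharge")
        if not math.isfinite(q):
            q = 0.0
        atoms.append(replace(a, partial_charge=q))
    return MolecularStructure(atoms, [replace(b) for b in s.bonds], s.role,
                              s.source_id, charges_assigned=True)
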