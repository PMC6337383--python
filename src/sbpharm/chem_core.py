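"""Domain types and file readers/writers used by every pipeline stage.

Conventions: coordinates in Angstrom, energies in kcal/mol, time in ps.
Residue numbering is preserved verbatim from the source PDB so that residue
labels render exactly as they appear in structure-based reports (e.g. "F252").
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Geometry import Point3D

from .errors import ModelValidationError, PDBParseError, SDFParseError

# ---------------------------------------------------------------------------
# element data
# ---------------------------------------------------------------------------

SUPPORTED_ELEMENTS = {
    "H", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I",
    "Na", "K", "Mg", "Ca", "Zn", "Fe", "B", "Se",
}

HALOGENS = {"F", "Cl", "Br", "I"}

#: halogens eligible as sigma-hole donors in halogen bonds
XB_HALOGENS = {"Cl", "Br", "I"}

# single-bond covalent radii (Angstrom), used only for distance-based bond
# inference on coordinate-only inputs (PDB ligands, intra-residue graphs)
_COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "P": 1.07,
    "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39, "B": 0.84, "Se": 1.20,
    "Na": 1.66, "K": 2.03, "Mg": 1.41, "Ca": 1.76, "Zn": 1.22, "Fe": 1.32,
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

FEATURE_KINDS = ("H", "HBD", "HBA", "AR", "PI", "NI")

#: default tolerance radius per feature kind (Angstrom)
DEFAULT_FEATURE_RADII = {"H": 1.5, "HBD": 1.5, "HBA": 1.5, "AR": 1.5, "PI": 1.5, "NI": 1.5}


def normalize_element(raw: str) -> str:
    raw = raw.strip()
    if len(raw) > 1:
        return raw[0].upper() + raw[1:].lower()
    return raw.upper()


# ---------------------------------------------------------------------------
# atoms, molecules
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class AtomRecord:
    """One atom: element, position and the derived interaction roles.

    ``hydrophobic``, ``is_donor``, ``is_acceptor`` and ``is_halogen`` are
    derived deterministically from the element and the bonded neighbourhood by
    :func:`assign_derived_flags`; they default to False until assigned.
    """

    index: int
    element: str
    coords: np.ndarray
    formal_charge: int = 0
    partial_charge: float | None = None
    is_aromatic: bool = False
    hydrophobic: bool = False
    is_donor: bool = False
    is_acceptor: bool = False
    is_halogen: bool = False
    name: str | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.index}: coords must be a finite 3-vector")
        self.element = normalize_element(self.element)
        if self.element not in SUPPORTED_ELEMENTS:
            raise ValueError(f"atom {self.index}: unsupported element {self.element!r}")

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass(eq=False)
class Bond:
    i: int
    j: int
    order: int = 1
    aromatic: bool = False


@dataclass(eq=False)
class Molecule:
    """A molecule: ordered atoms, bonds and a string-valued property map."""

    name: str
    atoms: list[AtomRecord]
    bonds: list[Bond] = field(default_factory=list)
    properties: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.atoms)
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n) or b.i == b.j:
                raise ValueError(f"bond ({b.i},{b.j}) has invalid endpoints")
        assign_derived_flags(self)

    @property
    def heavy_atom_count(self) -> int:
        return sum(1 for a in self.atoms if a.is_heavy)

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.is_heavy]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms if a.is_heavy], dtype=float)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def neighbors(self, idx: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.i == idx:
                out.append(b.j)
            elif b.j == idx:
                out.append(b.i)
        return out

    def attached_hydrogens(self, idx: int) -> list[AtomRecord]:
        return [self.atoms[j] for j in self.neighbors(idx) if self.atoms[j].element == "H"]


def assign_derived_flags(mol: Molecule) -> None:
    """Assign hydrophobic/donor/acceptor/halogen role flags in place.

    Hydrophobic: carbon whose bonded neighbours are exclusively C, H, S or a
    halogen; plus S, Cl, Br and I themselves.  Donor-H carrier: N or O with a
    bonded hydrogen, or a positively charged nitrogen (implicit protonation).
    Acceptor: any N or O that is not a positively charged nitrogen.
    """
    adjacency: dict[int, list[int]] = {a.index: [] for a in mol.atoms}
    for b in mol.bonds:
        adjacency[b.i].append(b.j)
        adjacency[b.j].append(b.i)
    for a in mol.atoms:
        a.is_halogen = a.element in HALOGENS
        nbr_elems = {mol.atoms[j].element for j in adjacency[a.index]}
        if a.element == "C":
            a.hydrophobic = nbr_elems <= ({"C", "H", "S"} | HALOGENS)
        else:
            a.hydrophobic = a.element in {"S", "Cl", "Br", "I"}
        has_h = any(mol.atoms[j].element == "H" for j in adjacency[a.index])
        if a.element in ("N", "O"):
            a.is_donor = has_h or (a.element == "N" and a.formal_charge > 0)
            a.is_acceptor = not (a.element == "N" and a.formal_charge > 0)
        else:
            a.is_donor = False
            a.is_acceptor = False


def infer_bonds(atoms: Sequence[AtomRecord], slack: float = 0.45) -> list[Bond]:
    """Distance-based single bonds for coordinate-only inputs (PDB ligands)."""
    bonds = []
    for i, a in enumerate(atoms):
        ra = _COVALENT_RADII.get(a.element, 0.8)
        for j in range(i + 1, len(atoms)):
            b = atoms[j]
            rb = _COVALENT_RADII.get(b.element, 0.8)
            if np.linalg.norm(a.coords - b.coords) <= ra + rb + slack:
                bonds.append(Bond(i, j, 1))
    return bonds


# ---------------------------------------------------------------------------
# poses, protein, frames
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class LigandPose:
    """One docked geometry of one ligand.

    ``scaffold_map`` is an ordered list of atom indices defining the common
    core shared across the ligand series; RMSD between poses is computed over
    these corresponding atoms.  ``automorphisms`` optionally lists alternative
    index orderings equivalent under scaffold symmetry.
    """

    ligand_id: str
    pose_id: str
    molecule: Molecule
    scaffold_map: list[int] = field(default_factory=list)
    scores: dict[str, float] = field(default_factory=dict)
    automorphisms: list[list[int]] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for idx in self.scaffold_map:
            if idx in seen:
                raise ValueError(f"pose {self.pose_id}: duplicate scaffold index {idx}")
            seen.add(idx)
            if not self.molecule.atoms[idx].is_heavy:
                raise ValueError(f"pose {self.pose_id}: scaffold index {idx} is a hydrogen")

    def scaffold_coords(self, order: Sequence[int] | None = None) -> np.ndarray:
        order = self.scaffold_map if order is None else order
        return np.array([self.molecule.atoms[i].coords for i in order], dtype=float)


@dataclass(eq=False)
class Residue:
    """One protein residue with numbering preserved from the source PDB."""

    chain_id: str
    number: int
    name: str
    atoms: list[AtomRecord]
    icode: str = ""
    bonds: list[Bond] = field(default_factory=list)

    def __post_init__(self):
        if not self.bonds and len(self.atoms) > 1:
            self.bonds = infer_bonds(self.atoms)
        # derive role flags on the intra-residue graph
        tmp = Molecule(name=self.label, atoms=self.atoms, bonds=self.bonds)
        self.bonds = tmp.bonds

    @property
    def label(self) -> str:
        """One-letter code + PDB number, e.g. PHE 252 -> 'F252'."""
        one = THREE_TO_ONE.get(self.name.upper(), "X")
        return f"{one}{self.number}{self.icode.strip()}"

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.is_heavy]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms if a.is_heavy], dtype=float)


@dataclass(eq=False)
class ProteinStructure:
    residues: list[Residue]

    def residue_by_label(self, label: str) -> Residue:
        for r in self.residues:
            if r.label == label:
                return r
        raise KeyError(f"unknown residue id {label!r}")

    def heavy_coords(self) -> np.ndarray:
        return np.vstack([r.heavy_coords() for r in self.residues])

    def iter_atoms(self) -> Iterator[tuple[Residue, AtomRecord]]:
        for r in self.residues:
            for a in r.atoms:
                yield r, a


@dataclass(eq=False)
class TrajectoryFrame:
    """A timestamped protein + ligand snapshot (time in ps)."""

    time: float
    protein: ProteinStructure
    ligand: LigandPose


# ---------------------------------------------------------------------------
# pharmacophore types
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class PharmacophoreFeature:
    kind: str
    position: np.ndarray
    radius: float
    ligand_atoms: tuple[int, ...]
    direction: np.ndarray | None = None
    partner_residues: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ModelValidationError(f"unknown feature kind {self.kind!r}")
        if self.radius <= 0:
            raise ModelValidationError("feature radius must be > 0")
        self.position = np.asarray(self.position, dtype=float)
        self.ligand_atoms = tuple(sorted(set(int(i) for i in self.ligand_atoms)))
        if not self.ligand_atoms:
            raise ModelValidationError("feature must reference at least one ligand atom")
        if self.direction is not None:
            self.direction = np.asarray(self.direction, dtype=float)
            if abs(np.linalg.norm(self.direction) - 1.0) > 1e-6:
                raise ModelValidationError("feature direction must be unit-norm")
        self.partner_residues = tuple(self.partner_residues)

    @property
    def signature(self) -> tuple[str, tuple[int, ...]]:
        """Identity used for occupancy counting: kind + ligand atom set."""
        return (self.kind, self.ligand_atoms)


@dataclass(eq=False)
class ExclusionVolume:
    center: np.ndarray
    radius: float

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise ModelValidationError("exclusion sphere radius must be > 0")


@dataclass(eq=False)
class PharmacophoreModel:
    name: str
    features: list[PharmacophoreFeature]
    exclusion_volumes: list[ExclusionVolume] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self):
        if not self.features:
            raise ModelValidationError(f"model {self.name!r} has no features")

    def signatures(self) -> set[tuple[str, tuple[int, ...]]]:
        return {f.signature for f in self.features}

    def positions(self) -> np.ndarray:
        return np.array([f.position for f in self.features], dtype=float)


@dataclass(eq=False)
class EfficiencyRecord:
    ligand_id: str
    pIC50: float
    logP: float
    HAC: int
    LE: float
    LLE: float
    FQ: float


# ---------------------------------------------------------------------------
# SDF IO (RDKit-backed)
# ---------------------------------------------------------------------------

_BOND_TYPE_FROM_RDKIT = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: 1,
}
_BOND_TYPE_TO_RDKIT = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}


def molecule_from_rdkit(rdmol: Chem.Mol, name: str | None = None) -> Molecule:
    conf = rdmol.GetConformer()
    atoms = []
    for a in rdmol.GetAtoms():
        i = a.GetIdx()
        p = conf.GetAtomPosition(i)
        atoms.append(
            AtomRecord(
                index=i,
                element=a.GetSymbol(),
                coords=np.array([p.x, p.y, p.z]),
                formal_charge=a.GetFormalCharge(),
                is_aromatic=a.GetIsAromatic(),
            )
        )
    bonds = []
    for b in rdmol.GetBonds():
        aromatic = b.GetBondType() == Chem.BondType.AROMATIC or b.GetIsAromatic()
        bonds.append(
            Bond(
                b.GetBeginAtomIdx(),
                b.GetEndAtomIdx(),
                _BOND_TYPE_FROM_RDKIT.get(b.GetBondType(), 1),
                aromatic,
            )
        )
        if aromatic:
            atoms[b.GetBeginAtomIdx()].is_aromatic = True
            atoms[b.GetEndAtomIdx()].is_aromatic = True
    props = {k: rdmol.GetProp(k) for k in rdmol.GetPropNames()}
    if name is None:
        name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else ""
    return Molecule(name=name, atoms=atoms, bonds=bonds, properties=props)


def molecule_to_rdkit(mol: Molecule) -> Chem.Mol:
    rw = Chem.RWMol()
    for a in mol.atoms:
        ra = Chem.Atom(a.element)
        ra.SetFormalCharge(a.formal_charge)
        ra.SetNoImplicit(True)
        ra.SetIsAromatic(a.is_aromatic)
        rw.AddAtom(ra)
    for b in mol.bonds:
        bt = Chem.BondType.AROMATIC if b.aromatic else _BOND_TYPE_TO_RDKIT.get(b.order, Chem.BondType.SINGLE)
        rw.AddBond(b.i, b.j, bt)
        if b.aromatic:
            rw.GetBondBetweenAtoms(b.i, b.j).SetIsAromatic(True)
    conf = Chem.Conformer(len(mol.atoms))
    for i, a in enumerate(mol.atoms):
        conf.SetAtomPosition(i, Point3D(*a.coords))
    out = rw.GetMol()
    out.AddConformer(conf)
    out.SetProp("_Name", mol.name)
    for k, v in mol.properties.items():
        out.SetProp(k, str(v))
    out.UpdatePropertyCache(strict=False)
    return out


def read_sdf(path: str | Path) -> list[Molecule]:
    """Read a multi-record V2000 SDF.  Multi-conformer sets share a name."""
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    mols = []
    for i, rdmol in enumerate(supplier):
        if rdmol is None:
            raise SDFParseError(f"{path}: malformed SDF record at index {i}")
        mols.append(molecule_from_rdkit(rdmol))
    return mols


def write_sdf(mols: Iterable[Molecule], path: str | Path) -> None:
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    for m in mols:
        writer.write(molecule_to_rdkit(m))
    writer.close()


def group_conformers(mols: Sequence[Molecule]) -> dict[str, list[Molecule]]:
    """Group SDF records into multi-conformer sets keyed by molecule name."""
    groups: dict[str, list[Molecule]] = {}
    for m in mols:
        groups.setdefault(m.name, []).append(m)
    return groups


# ---------------------------------------------------------------------------
# PDB IO
# ---------------------------------------------------------------------------

#: residue names treated as ligand records in trajectory PDB files
DEFAULT_LIGAND_RESNAMES = ("LIG", "UNL", "AAL", "MOL")

#: default trajectory frame spacing when MODEL records carry no times (ps)
DEFAULT_FRAME_DT = 2.0


def _parse_pdb_models(path: str | Path) -> list[list[tuple]]:
    """Return per-MODEL lists of raw atom tuples.

    Tuple layout: (record, name, altloc, resname, chain, resseq, icode,
    xyz, element, lineno).
    """
    models: list[list[tuple]] = []
    open_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                models.append([])
                open_model = True
            elif rec == "ENDMDL":
                open_model = False
            elif rec in ("ATOM", "HETATM"):
                if not models:
                    models.append([])  # single-model file without MODEL records
                elif not open_model and len(models) > 1:
                    raise PDBParseError(f"{path}:{lineno}: coordinates outside MODEL scope")
                try:
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except ValueError as exc:
                    raise PDBParseError(f"{path}:{lineno}: missing or malformed coordinates") from exc
                name = line[12:16].strip()
                element = line[76:78].strip() if len(line) >= 78 else ""
                if not element:
                    # fall back to the atom name; prefer two letters only for halogens
                    alpha = "".join(c for c in name if c.isalpha())
                    element = alpha[:2] if alpha[:2].upper() in ("CL", "BR") else alpha[:1]
                try:
                    resseq = int(line[22:26])
                except ValueError as exc:
                    raise PDBParseError(f"{path}:{lineno}: malformed residue number") from exc
                models[-1].append(
                    (
                        rec,
                        name,
                        line[16:17],
                        line[17:20].strip(),
                        line[21:22].strip(),
                        resseq,
                        line[26:27].strip(),
                        np.array([x, y, z]),
                        normalize_element(element),
                        lineno,
                    )
                )
    return [m for m in models if m]


def _build_structure(records: list[tuple], ligand_resnames: Sequence[str]) -> tuple[ProteinStructure, Molecule | None, str]:
    residues: list[Residue] = []
    key_order: list[tuple] = []
    grouped: dict[tuple, list[tuple]] = {}
    ligand_records: list[tuple] = []
    ligand_resname = ""
    for r in records:
        if r[3] in ligand_resnames:
            ligand_records.append(r)
            ligand_resname = r[3]
            continue
        key = (r[4], r[5], r[6], r[3])
        if key not in grouped:
            grouped[key] = []
            key_order.append(key)
        grouped[key].append(r)
    for chain, num, icode, resname in key_order:
        atoms = [
            AtomRecord(index=i, element=rec[8], coords=rec[7], name=rec[1])
            for i, rec in enumerate(grouped[(chain, num, icode, resname)])
        ]
        residues.append(Residue(chain_id=chain, number=num, name=resname, atoms=atoms, icode=icode))
    ligand = None
    if ligand_records:
        atoms = [
            AtomRecord(index=i, element=rec[8], coords=rec[7], name=rec[1])
            for i, rec in enumerate(ligand_records)
        ]
        ligand = Molecule(name=ligand_resname, atoms=atoms, bonds=infer_bonds(atoms))
    return ProteinStructure(residues=residues), ligand, ligand_resname


def read_pdb(path: str | Path, ligand_resnames: Sequence[str] = ()) -> ProteinStructure:
    """Read the first model of a PDB file as a protein structure."""
    models = _parse_pdb_models(path)
    if not models:
        raise PDBParseError(f"{path}: no coordinate records found")
    structure, _, _ = _build_structure(models[0], ligand_resnames)
    return structure


def read_trajectory(
    path: str | Path,
    dt: float = DEFAULT_FRAME_DT,
    ligand_resnames: Sequence[str] = DEFAULT_LIGAND_RESNAMES,
    ligand_template: Molecule | None = None,
) -> list[TrajectoryFrame]:
    """Read a multi-model PDB as a trajectory (one frame per MODEL).

    Unannotated frames receive times 0, dt, 2*dt, ... ps.  When a
    ``ligand_template`` is supplied its bonds/flags are transferred onto the
    per-frame ligand coordinates (PDB carries no connectivity).
    """
    models = _parse_pdb_models(path)
    if not models:
        raise PDBParseError(f"{path}: no coordinate records found")
    frames = []
    n_atoms = None
    for i, records in enumerate(models):
        if n_atoms is None:
            n_atoms = len(records)
        elif len(records) != n_atoms:
            raise PDBParseError(f"{path}: model {i + 1} atom count differs from model 1")
        protein, ligand, resname = _build_structure(records, ligand_resnames)
        if ligand is None:
            raise PDBParseError(f"{path}: model {i + 1} contains no ligand residue")
        if ligand_template is not None:
            atoms = [
                AtomRecord(
                    index=a.index,
                    element=a.element,
                    coords=ligand.atoms[a.index].coords,
                    formal_charge=a.formal_charge,
                    partial_charge=a.partial_charge,
                    is_aromatic=a.is_aromatic,
                    name=a.name,
                )
                for a in ligand_template.atoms
            ]
            ligand = Molecule(
                name=ligand_template.name,
                atoms=atoms,
                bonds=list(ligand_template.bonds),
                properties=dict(ligand_template.properties),
            )
        pose = LigandPose(ligand_id=ligand.name or resname, pose_id=f"frame{i}", molecule=ligand)
        frames.append(TrajectoryFrame(time=i * dt, protein=protein, ligand=pose))
    return frames


def _format_pdb_atom(serial: int, record: str, atom: AtomRecord, resname: str, chain: str, resseq: int, icode: str) -> str:
    name = atom.name or atom.element
    name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
    x, y, z = atom.coords
    element = atom.element.upper()
    return (
        f"{record:<6s}{serial:>5d} {name_field}{'':1s}{resname:>3s} {chain or 'A':1s}"
        f"{resseq:>4d}{icode or '':1s}   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def write_pdb(structure: ProteinStructure, path: str | Path, ligand: Molecule | None = None, ligand_resname: str = "LIG") -> None:
    lines = _structure_lines(structure, ligand, ligand_resname)
    Path(path).write_text("\n".join(lines + ["END"]) + "\n")


def _structure_lines(structure: ProteinStructure, ligand: Molecule | None, ligand_resname: str) -> list[str]:
    lines = []
    serial = 1
    for res in structure.residues:
        for atom in res.atoms:
            lines.append(_format_pdb_atom(serial, "ATOM", atom, res.name, res.chain_id, res.number, res.icode))
            serial += 1
    if ligand is not None:
        for atom in ligand.atoms:
            lines.append(_format_pdb_atom(serial, "HETATM", atom, ligand_resname, "L", 1, ""))
            serial += 1
    return lines


def write_trajectory(frames: Sequence[TrajectoryFrame], path: str | Path, ligand_resname: str = "LIG") -> None:
    out = []
    for i, fr in enumerate(frames, start=1):
        out.append(f"MODEL     {i:>4d}")
        out.extend(_structure_lines(fr.protein, fr.ligand.molecule, ligand_resname))
        out.append("ENDMDL")
    out.append("END")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# pharmacophore model JSON
# ---------------------------------------------------------------------------

_MODEL_KEYS = {"name", "features", "exclusion_volumes", "provenance"}
_FEATURE_KEYS = {"kind", "position", "radius", "direction", "ligand_atoms", "partner_residues"}
_EV_KEYS = {"center", "radius"}


def model_to_dict(model: PharmacophoreModel) -> dict:
    return {
        "name": model.name,
        "features": [
            {
                "kind": f.kind,
                "position": [float(v) for v in f.position],
                "radius": float(f.radius),
                "direction": None if f.direction is None else [float(v) for v in f.direction],
                "ligand_atoms": list(f.ligand_atoms),
                "partner_residues": list(f.partner_residues),
            }
            for f in model.features
        ],
        "exclusion_volumes": [
            {"center": [float(v) for v in ev.center], "radius": float(ev.radius)}
            for ev in model.exclusion_volumes
        ],
        "provenance": model.provenance,
    }


def model_from_dict(data: dict) -> PharmacophoreModel:
    if not isinstance(data, dict):
        raise ModelValidationError("model JSON must be an object")
    unknown = set(data) - _MODEL_KEYS
    if unknown:
        raise ModelValidationError(f"unknown model keys: {sorted(unknown)}")
    missing = _MODEL_KEYS - set(data)
    if missing:
        raise ModelValidationError(f"missing model keys: {sorted(missing)}")
    features = []
    for fd in data["features"]:
        unknown = set(fd) - _FEATURE_KEYS
        if unknown:
            raise ModelValidationError(f"unknown feature keys: {sorted(unknown)}")
        features.append(
            PharmacophoreFeature(
                kind=fd["kind"],
                position=fd["position"],
                radius=fd["radius"],
                direction=fd.get("direction"),
                ligand_atoms=fd["ligand_atoms"],
                partner_residues=tuple(fd.get("partner_residues", ())),
            )
        )
    evs = []
    for ed in data["exclusion_volumes"]:
        unknown = set(ed) - _EV_KEYS
        if unknown:
            raise ModelValidationError(f"unknown exclusion volume keys: {sorted(unknown)}")
        evs.append(ExclusionVolume(center=ed["center"], radius=ed["radius"]))
    return PharmacophoreModel(
        name=data["name"], features=features, exclusion_volumes=evs, provenance=data["provenance"]
    )


def read_model_json(path: str | Path) -> PharmacophoreModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))


def write_model_json(model: PharmacophoreModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=2)
        fh.write("\n")


def models_equal(a: PharmacophoreModel, b: PharmacophoreModel, tol: float = 1e-9) -> bool:
    """Field-wise equality, used by round-trip tests."""
    if a.name != b.name or a.provenance != b.provenance:
        return False
    if len(a.features) != len(b.features) or len(a.exclusion_volumes) != len(b.exclusion_volumes):
        return False
    for fa, fb in zip(a.features, b.features):
        if fa.kind != fb.kind or fa.ligand_atoms != fb.ligand_atoms:
            return False
        if fa.partner_residues != fb.partner_residues:
            return False
        if abs(fa.radius - fb.radius) > tol or np.max(np.abs(fa.position - fb.position)) > tol:
            return False
        if (fa.direction is None) != (fb.direction is None):
            return False
        if fa.direction is not None and np.max(np.abs(fa.direction - fb.direction)) > tol:
            return False
    for ea, eb in zip(a.exclusion_volumes, b.exclusion_volumes):
        if abs(ea.radius - eb.radius) > tol or np.max(np.abs(ea.center - eb.center)) > tol:
            return False
    return True


# ---------------------------------------------------------------------------
# score tables
# ---------------------------------------------------------------------------

SCORE_TABLE_COLUMNS = ["molecule_id", "conformer_id", "score_name", "value"]


def read_score_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"molecule_id": str, "conformer_id": str})
    if list(df.columns) != SCORE_TABLE_COLUMNS:
        raise ValueError(f"score table must have columns {SCORE_TABLE_COLUMNS}, got {list(df.columns)}")
    return df


def write_score_table(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, SCORE_TABLE_COLUMNS].to_csv(path, index=False)
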