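"""Contact, hydrogen-bond, hydrophobic and halogen-bond detection, plus
interaction fingerprints over pose ensembles (static) and trajectories
(dynamic) and a per-residue interaction-energy decomposition.

Geometric criteria are not dictated by any docking engine here; they are
explicit, config-overridable defaults (see :class:`ContactCriteria`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .chem_core import AtomRecord, LigandPose, Molecule, ProteinStructure, Residue, TrajectoryFrame
from .errors import MissingParameterError

COULOMB_CONSTANT = 332.0636  # kcal*Angstrom/(mol*e^2), vacuum dielectric

CHANNELS = ("any_contact", "hbond", "hydrophobic", "halogen")


@dataclass(frozen=True)
class ContactCriteria:
    """All geometric thresholds used by the detectors (Angstrom / degrees)."""

    contact_cutoff: float = 5.0
    hbond_distance: float = 3.5
    hbond_angle: float = 120.0
    halogen_distance: float = 3.8
    halogen_angle: float = 140.0
    hydrophobic_distance: float = 4.5

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


DEFAULT_CRITERIA = ContactCriteria()


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    v1 = a - vertex
    v2 = b - vertex
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def detect_hbond(
    donor_heavy: np.ndarray,
    donor_h: np.ndarray | None,
    acceptor: np.ndarray,
    criteria: ContactCriteria = DEFAULT_CRITERIA,
) -> tuple[bool, float, float | None]:
    """Hydrogen bond test: D...A distance, plus D-H...A angle when H is known.

    Returns (is_bonded, distance, angle or None).  Without an explicit
    hydrogen the rule degrades to distance-only.
    """
    donor_heavy = np.asarray(donor_heavy, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    dist = float(np.linalg.norm(donor_heavy - acceptor))
    if dist > criteria.hbond_distance:
        return False, dist, None
    if donor_h is None:
        return True, dist, None
    angle = _angle_deg(donor_heavy, np.asarray(donor_h, dtype=float), acceptor)
    return angle >= criteria.hbond_angle, dist, angle


def detect_halogen_bond(
    carbon: np.ndarray,
    halogen: np.ndarray,
    acceptor: np.ndarray,
    criteria: ContactCriteria = DEFAULT_CRITERIA,
) -> tuple[bool, float, float]:
    """Halogen bond: X...A distance and C-X...A sigma-hole angle."""
    dist = float(np.linalg.norm(np.asarray(halogen) - np.asarray(acceptor)))
    angle = _angle_deg(np.asarray(carbon), np.asarray(halogen), np.asarray(acceptor))
    return dist <= criteria.halogen_distance and angle >= criteria.halogen_angle, dist, angle


# ---------------------------------------------------------------------------
# pairwise ligand-residue channel detectors
# ---------------------------------------------------------------------------


def _ligand_donors(mol: Molecule) -> list[tuple[AtomRecord, list[AtomRecord]]]:
    return [(a, mol.attached_hydrogens(a.index)) for a in mol.atoms if a.is_heavy and a.is_donor]


def _residue_donors(res: Residue) -> list[tuple[AtomRecord, list[AtomRecord]]]:
    out = []
    adjacency: dict[int, list[int]] = {a.index: [] for a in res.atoms}
    for b in res.bonds:
        adjacency[b.i].append(b.j)
        adjacency[b.j].append(b.i)
    for a in res.atoms:
        if a.is_heavy and a.is_donor:
            hs = [res.atoms[j] for j in adjacency[a.index] if res.atoms[j].element == "H"]
            out.append((a, hs))
    return out


def _hbond_between(
    donors: Iterable[tuple[AtomRecord, list[AtomRecord]]],
    acceptors: Iterable[AtomRecord],
    criteria: ContactCriteria,
) -> bool:
    acceptors = list(acceptors)
    for donor, hs in donors:
        for acc in acceptors:
            if not hs:
                ok, _, _ = detect_hbond(donor.coords, None, acc.coords, criteria)
                if ok:
                    return True
            else:
                for h in hs:
                    ok, _, _ = detect_hbond(donor.coords, h.coords, acc.coords, criteria)
                    if ok:
                        return True
    return False


def has_hbond(ligand: Molecule, res: Residue, criteria: ContactCriteria = DEFAULT_CRITERIA) -> bool:
    """Any hydrogen bond between a ligand and a residue, in either direction."""
    res_acceptors = [a for a in res.atoms if a.is_heavy and a.is_acceptor]
    if _hbond_between(_ligand_donors(ligand), res_acceptors, criteria):
        return True
    lig_acceptors = [a for a in ligand.atoms if a.is_heavy and a.is_acceptor]
    return _hbond_between(_residue_donors(res), lig_acceptors, criteria)


def has_hydrophobic_contact(ligand: Molecule, res: Residue, criteria: ContactCriteria = DEFAULT_CRITERIA) -> bool:
    lig = np.array([a.coords for a in ligand.atoms if a.is_heavy and a.hydrophobic])
    prot = np.array([a.coords for a in res.atoms if a.is_heavy and a.hydrophobic])
    if lig.size == 0 or prot.size == 0:
        return False
    d2 = np.sum((lig[:, None, :] - prot[None, :, :]) ** 2, axis=2)
    return bool(np.min(d2) <= criteria.hydrophobic_distance**2)


def has_halogen_bond(ligand: Molecule, res: Residue, criteria: ContactCriteria = DEFAULT_CRITERIA) -> bool:
    from .chem_core import XB_HALOGENS

    acceptors = [a for a in res.atoms if a.is_heavy and a.is_acceptor]
    if not acceptors:
        return False
    for a in ligand.atoms:
        if a.element not in XB_HALOGENS:
            continue
        carbons = [ligand.atoms[j] for j in ligand.neighbors(a.index) if ligand.atoms[j].element == "C"]
        if not carbons:
            continue
        for acc in acceptors:
            ok, _, _ = detect_halogen_bond(carbons[0].coords, a.coords, acc.coords, criteria)
            if ok:
                return True
    return False


def residues_near(
    ligand: LigandPose,
    protein: ProteinStructure,
    cutoff: float = 5.0,
) -> set[str]:
    """Residue labels with any heavy atom within ``cutoff`` of a ligand heavy atom."""
    lig = ligand.molecule.heavy_coords()
    out = set()
    for res in protein.residues:
        prot = res.heavy_coords()
        if prot.size == 0:
            continue
        d2 = np.sum((lig[:, None, :] - prot[None, :, :]) ** 2, axis=2)
        if np.min(d2) <= cutoff**2:
            out.add(res.label)
    return out


# ---------------------------------------------------------------------------
# interaction profiles
# ---------------------------------------------------------------------------


@dataclass
class InteractionProfile:
    """Per-residue involvement percentages per channel over poses or frames."""

    percentages: dict[str, dict[str, float]]
    n_observations: int
    favorable_counts: dict[str, int] = field(default_factory=dict)

    def percent(self, residue: str, channel: str) -> float:
        return self.percentages.get(residue, {}).get(channel, 0.0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"residue": res, "channel": ch, "percent": pct}
            for res, chans in sorted(self.percentages.items())
            for ch, pct in chans.items()
        ]
        return pd.DataFrame(rows, columns=["residue", "channel", "percent"])


def _profile(observations: Sequence[tuple[Molecule, ProteinStructure]], criteria: ContactCriteria) -> InteractionProfile:
    counts: dict[str, dict[str, int]] = {}
    favorable: dict[str, int] = {}
    n = len(observations)
    for ligand, protein in observations:
        lig_heavy = ligand.heavy_coords()
        for res in protein.residues:
            prot = res.heavy_coords()
            if prot.size == 0:
                continue
            d2 = np.sum((lig_heavy[:, None, :] - prot[None, :, :]) ** 2, axis=2)
            if np.min(d2) > criteria.contact_cutoff**2:
                continue
            chans = counts.setdefault(res.label, {ch: 0 for ch in CHANNELS})
            chans["any_contact"] += 1
            hb = has_hbond(ligand, res, criteria)
            hp = has_hydrophobic_contact(ligand, res, criteria)
            if hb:
                chans["hbond"] += 1
            if hp:
                chans["hydrophobic"] += 1
            if has_halogen_bond(ligand, res, criteria):
                chans["halogen"] += 1
            favorable[res.label] = favorable.get(res.label, 0) + int(hb) + int(hp)
    percentages = {
        res: {ch: 100.0 * c / n for ch, c in chans.items()} for res, chans in counts.items()
    }
    return InteractionProfile(percentages=percentages, n_observations=n, favorable_counts=favorable)


def sift_profile(
    poses: Sequence[LigandPose],
    protein: ProteinStructure,
    criteria: ContactCriteria = DEFAULT_CRITERIA,
) -> InteractionProfile:
    """Structural interaction fingerprint over a docked pose ensemble."""
    if not poses:
        raise ValueError("sift_profile requires at least one pose")
    return _profile([(p.molecule, protein) for p in poses], criteria)


def dift_profile(
    frames: Sequence[TrajectoryFrame],
    criteria: ContactCriteria = DEFAULT_CRITERIA,
) -> InteractionProfile:
    """Dynamic interaction fingerprint: residue involvement over trajectory frames."""
    if not frames:
        raise ValueError("dift_profile requires at least one frame")
    return _profile([(f.ligand.molecule, f.protein) for f in frames], criteria)


def pair_hbond_occupancy(
    frames: Sequence[TrajectoryFrame],
    residue_a: str,
    residue_b: str,
    criteria: ContactCriteria = DEFAULT_CRITERIA,
) -> float:
    """Percent of frames with >= 1 hydrogen bond between two residues."""
    if not frames:
        raise ValueError("no frames")
    frames[0].protein.residue_by_label(residue_a)  # raises KeyError if unknown
    frames[0].protein.residue_by_label(residue_b)
    hits = 0
    for fr in frames:
        ra = fr.protein.residue_by_label(residue_a)
        rb = fr.protein.residue_by_label(residue_b)
        fwd = _hbond_between(_residue_donors(ra), [x for x in rb.atoms if x.is_heavy and x.is_acceptor], criteria)
        rev = fwd or _hbond_between(_residue_donors(rb), [x for x in ra.atoms if x.is_heavy and x.is_acceptor], criteria)
        if fwd or rev:
            hits += 1
    return 100.0 * hits / len(frames)


# ---------------------------------------------------------------------------
# per-residue interaction energies
# ---------------------------------------------------------------------------


@dataclass
class ForceFieldParams:
    """Per-element Lennard-Jones parameters and fallback partial charges.

    An atom's own ``partial_charge`` takes precedence over the per-element
    fallback charge.  sigma in Angstrom, epsilon in kcal/mol.
    """

    elements: Mapping[str, Mapping[str, float]]

    @classmethod
    def from_yaml(cls, path) -> "ForceFieldParams":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(elements=data["elements"])

    def lookup(self, atom: AtomRecord) -> tuple[float, float, float]:
        entry = self.elements.get(atom.element)
        if entry is None or "sigma" not in entry or "epsilon" not in entry:
            raise MissingParameterError(atom.element)
        charge = atom.partial_charge
        if charge is None:
            charge = entry.get("charge")
        if charge is None:
            raise MissingParameterError(atom.element)
        return float(charge), float(entry["sigma"]), float(entry["epsilon"])


@dataclass
class EnergyDecomposition:
    """Per-residue electrostatic/van-der-Waals split of the ligand interaction."""

    per_residue: dict[str, dict[str, float]]
    center: np.ndarray
    radius: float

    def total(self) -> float:
        return sum(v["total"] for v in self.per_residue.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"residue": res, **vals} for res, vals in sorted(self.per_residue.items())
        ]
        return pd.DataFrame(rows, columns=["residue", "electrostatic", "vdw", "total"])


def pair_energy(qi: float, qj: float, sigma_i: float, sigma_j: float, eps_i: float, eps_j: float, r: float) -> tuple[float, float]:
    """Coulomb + Lennard-Jones pair terms with Lorentz-Berthelot combining."""
    elec = COULOMB_CONSTANT * qi * qj / r
    sigma = 0.5 * (sigma_i + sigma_j)
    eps = math.sqrt(eps_i * eps_j)
    sr6 = (sigma / r) ** 6
    vdw = 4.0 * eps * (sr6**2 - sr6)
    return elec, vdw


def residue_energies(
    pose: LigandPose,
    protein: ProteinStructure,
    params: ForceFieldParams,
    center: np.ndarray,
    radius: float = 12.0,
) -> EnergyDecomposition:
    """Ligand-residue interaction energy for residues near a grid center.

    A residue is included when any of its atoms is within ``radius`` of
    ``center``.  Electrostatics use the vacuum Coulomb term; dispersion uses
    12-6 Lennard-Jones.  Atoms lacking parameters raise an error naming them.
    """
    center = np.asarray(center, dtype=float)
    lig_atoms = [a for a in pose.molecule.atoms]
    missing = []
    lig_params = []
    for a in lig_atoms:
        try:
            lig_params.append(params.lookup(a))
        except MissingParameterError:
            missing.append(f"ligand:{a.index}:{a.element}")
            lig_params.append(None)
    per_residue = {}
    for res in protein.residues:
        coords = np.array([a.coords for a in res.atoms])
        if np.min(np.linalg.norm(coords - center, axis=1)) > radius:
            continue
        elec_sum = 0.0
        vdw_sum = 0.0
        for a in res.atoms:
            try:
                qj, sj, ej = params.lookup(a)
            except MissingParameterError:
                missing.append(f"{res.label}:{a.index}:{a.element}")
                continue
            for la, lp in zip(lig_atoms, lig_params):
                if lp is None:
                    continue
                qi, si, ei = lp
                r = float(np.linalg.norm(la.coords - a.coords))
                e, v = pair_energy(qi, qj, si, sj, ei, ej, r)
                elec_sum += e
                vdw_sum += v
        per_residue[res.label] = {
            "electrostatic": elec_sum,
            "vdw": vdw_sum,
            "total": elec_sum + vdw_sum,
        }
    if missing:
        raise MissingParameterError(f"missing force-field parameters for atoms: {sorted(set(missing))}")
    return EnergyDecomposition(per_residue=per_residue, center=center, radius=radius)
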