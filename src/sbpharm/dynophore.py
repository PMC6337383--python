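"""Per-frame structure-based pharmacophore perception and occupancy profiling.

A pharmacophore model is perceived independently for every trajectory frame;
features are identified across frames by their *signature* (feature kind plus
the exact set of ligand atoms involved), which makes occupancy counting
order-independent.  Models are then compared through translation/rotation
invariant radial-distribution-function (RDF) descriptor vectors, clustered by
average linkage on cosine distance, and each cluster is summarized by its
medoid, the representative pharmacophore model (RPM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Sequence

import numpy as np
import pandas as pd

from .chem_core import (
    DEFAULT_FEATURE_RADII,
    FEATURE_KINDS,
    ExclusionVolume,
    Molecule,
    PharmacophoreFeature,
    PharmacophoreModel,
    TrajectoryFrame,
)
from .errors import EmptyModelError
from .interactions import ContactCriteria, DEFAULT_CRITERIA, detect_hbond, _residue_donors
from .scaffold_cluster import agglomerative_cut

# protein side-chain aromatic ring atoms, by residue name
_AROMATIC_RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

# protein charged-group atoms, by residue name
_NEGATIVE_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_POSITIVE_ATOMS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}


@dataclass(frozen=True)
class PerceptionRules:
    """Every geometric threshold used during feature perception (Angstrom).

    These are explicit replacements for tool-internal perception settings;
    they are serialized into run logs so a model is reproducible from its
    provenance.
    """

    criteria: ContactCriteria = DEFAULT_CRITERIA
    hydrophobic_feature_distance: float = 5.0
    min_hydrophobic_partners: int = 3
    aromatic_distance: float = 5.5
    ionic_distance: float = 5.0
    evs_distance: float = 5.0
    evs_radius: float = 1.0
    feature_radii: dict = field(default_factory=lambda: dict(DEFAULT_FEATURE_RADII))

    def as_dict(self) -> dict:
        d = {
            "hydrophobic_feature_distance": self.hydrophobic_feature_distance,
            "min_hydrophobic_partners": self.min_hydrophobic_partners,
            "aromatic_distance": self.aromatic_distance,
            "ionic_distance": self.ionic_distance,
            "evs_distance": self.evs_distance,
            "evs_radius": self.evs_radius,
            "feature_radii": dict(self.feature_radii),
        }
        d.update(self.criteria.as_dict())
        return d


DEFAULT_RULES = PerceptionRules()


# ---------------------------------------------------------------------------
# ligand-side grouping helpers
# ---------------------------------------------------------------------------


def _connected_components(indices: set[int], mol: Molecule) -> list[list[int]]:
    adj = {i: [] for i in indices}
    for b in mol.bonds:
        if b.i in indices and b.j in indices:
            adj[b.i].append(b.j)
            adj[b.j].append(b.i)
    seen: set[int] = set()
    comps = []
    for start in sorted(indices):
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        comps.append(sorted(comp))
    return comps


def hydrophobic_fragments(mol: Molecule) -> list[list[int]]:
    """Contiguous hydrophobic heavy-atom fragments; each halogen stands alone."""
    halogens = [a.index for a in mol.atoms if a.is_heavy and a.hydrophobic and a.is_halogen]
    rest = {a.index for a in mol.atoms if a.is_heavy and a.hydrophobic and not a.is_halogen}
    return _connected_components(rest, mol) + [[h] for h in sorted(halogens)]


def aromatic_rings(mol: Molecule) -> list[list[int]]:
    """Connected aromatic heavy-atom systems of ring size (>= 5 atoms)."""
    arom = {a.index for a in mol.atoms if a.is_heavy and a.is_aromatic}
    return [c for c in _connected_components(arom, mol) if len(c) >= 5]


def charged_groups(mol: Molecule, sign: int) -> list[list[int]]:
    charged = {a.index for a in mol.atoms if a.is_heavy and np.sign(a.formal_charge) == sign}
    return _connected_components(charged, mol)


def _centroid(mol: Molecule, indices: Sequence[int]) -> np.ndarray:
    return np.mean([mol.atoms[i].coords for i in indices], axis=0)


# ---------------------------------------------------------------------------
# ligand-only feature perception (used by screening)
# ---------------------------------------------------------------------------


def perceive_ligand_features(mol: Molecule, rules: PerceptionRules = DEFAULT_RULES) -> list[PharmacophoreFeature]:
    """Emit every *potential* ligand feature, ignoring the protein.

    Every donor, acceptor, hydrophobic fragment, aromatic ring and charged
    group yields a feature; screening decides which subset matches a model.
    """
    radii = rules.feature_radii
    feats: list[PharmacophoreFeature] = []
    for a in mol.atoms:
        if a.is_heavy and a.is_donor:
            feats.append(PharmacophoreFeature("HBD", a.coords, radii["HBD"], (a.index,)))
    for a in mol.atoms:
        if a.is_heavy and a.is_acceptor:
            feats.append(PharmacophoreFeature("HBA", a.coords, radii["HBA"], (a.index,)))
    for frag in hydrophobic_fragments(mol):
        feats.append(PharmacophoreFeature("H", _centroid(mol, frag), radii["H"], tuple(frag)))
    for ring in aromatic_rings(mol):
        feats.append(PharmacophoreFeature("AR", _centroid(mol, ring), radii["AR"], tuple(ring)))
    for grp in charged_groups(mol, +1):
        feats.append(PharmacophoreFeature("PI", _centroid(mol, grp), radii["PI"], tuple(grp)))
    for grp in charged_groups(mol, -1):
        feats.append(PharmacophoreFeature("NI", _centroid(mol, grp), radii["NI"], tuple(grp)))
    return feats


# ---------------------------------------------------------------------------
# frame perception (protein-aware)
# ---------------------------------------------------------------------------


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def perceive_features(frame: TrajectoryFrame, rules: PerceptionRules = DEFAULT_RULES) -> PharmacophoreModel:
    """Perceive a structure-based pharmacophore model for one frame.

    Emits HBD/HBA features at ligand donor/acceptor atoms satisfying the
    hydrogen-bond criteria against the protein, H features at hydrophobic
    fragment centroids with enough hydrophobic protein partners, AR features
    at aromatic ring centroids facing a protein ring, PI/NI features against
    complementary charged protein partners, and 1 A exclusion spheres at
    nearby protein heavy atoms that partner no feature.
    """
    lig = frame.ligand.molecule
    protein = frame.protein
    crit = rules.criteria
    radii = rules.feature_radii
    feats: list[PharmacophoreFeature] = []
    partner_atoms: set[tuple[int, int]] = set()  # (residue idx, atom idx)

    # hydrogen-bond donors (ligand) vs protein acceptors
    for a in lig.atoms:
        if not (a.is_heavy and a.is_donor):
            continue
        hs = lig.attached_hydrogens(a.index)
        partners = []
        direction = None
        for ri, res in enumerate(protein.residues):
            for pa in res.atoms:
                if not (pa.is_heavy and pa.is_acceptor):
                    continue
                if hs:
                    ok = any(detect_hbond(a.coords, h.coords, pa.coords, crit)[0] for h in hs)
                else:
                    ok = detect_hbond(a.coords, None, pa.coords, crit)[0]
                if ok:
                    partners.append((ri, pa.index, res.label))
                    if direction is None:
                        direction = _unit(pa.coords - a.coords)
        if partners:
            partner_atoms.update((ri, ai) for ri, ai, _ in partners)
            feats.append(
                PharmacophoreFeature(
                    "HBD", a.coords, radii["HBD"], (a.index,),
                    direction=direction,
                    partner_residues=tuple(dict.fromkeys(lbl for _, _, lbl in partners)),
                )
            )

    # hydrogen-bond acceptors (ligand) vs protein donors
    for a in lig.atoms:
        if not (a.is_heavy and a.is_acceptor):
            continue
        partners = []
        direction = None
        for ri, res in enumerate(protein.residues):
            for donor, dhs in _residue_donors(res):
                if dhs:
                    ok = any(detect_hbond(donor.coords, h.coords, a.coords, crit)[0] for h in dhs)
                else:
                    ok = detect_hbond(donor.coords, None, a.coords, crit)[0]
                if ok:
                    partners.append((ri, donor.index, res.label))
                    if direction is None:
                        direction = _unit(donor.coords - a.coords)
        if partners:
            partner_atoms.update((ri, ai) for ri, ai, _ in partners)
            feats.append(
                PharmacophoreFeature(
                    "HBA", a.coords, radii["HBA"], (a.index,),
                    direction=direction,
                    partner_residues=tuple(dict.fromkeys(lbl for _, _, lbl in partners)),
                )
            )

    # hydrophobic fragment centroids with enough hydrophobic protein partners
    for frag in hydrophobic_fragments(lig):
        centroid = _centroid(lig, frag)
        partners = []
        for ri, res in enumerate(protein.residues):
            for pa in res.atoms:
                if pa.is_heavy and pa.hydrophobic:
                    if np.linalg.norm(pa.coords - centroid) <= rules.hydrophobic_feature_distance:
                        partners.append((ri, pa.index, res.label))
        if len(partners) >= rules.min_hydrophobic_partners:
            partner_atoms.update((ri, ai) for ri, ai, _ in partners)
            feats.append(
                PharmacophoreFeature(
                    "H", centroid, radii["H"], tuple(frag),
                    partner_residues=tuple(dict.fromkeys(lbl for _, _, lbl in partners)),
                )
            )

    # aromatic rings vs protein aromatic rings
    for ring in aromatic_rings(lig):
        centroid = _centroid(lig, ring)
        partners = []
        for ri, res in enumerate(protein.residues):
            names = _AROMATIC_RING_ATOMS.get(res.name.upper())
            if not names:
                continue
            ring_atoms = [pa for pa in res.atoms if (pa.name or "").upper() in names]
            if len(ring_atoms) < 5:
                continue
            ring_centroid = np.mean([pa.coords for pa in ring_atoms], axis=0)
            if np.linalg.norm(ring_centroid - centroid) <= rules.aromatic_distance:
                partners.extend((ri, pa.index, res.label) for pa in ring_atoms)
        if partners:
            partner_atoms.update((ri, ai) for ri, ai, _ in partners)
            coords = np.array([lig.atoms[i].coords for i in ring])
            _, _, vt = np.linalg.svd(coords - coords.mean(axis=0))
            feats.append(
                PharmacophoreFeature(
                    "AR", centroid, radii["AR"], tuple(ring),
                    direction=_unit(vt[-1]),
                    partner_residues=tuple(dict.fromkeys(lbl for _, _, lbl in partners)),
                )
            )

    # charged groups vs complementary protein partners
    for sign, kind, table in ((+1, "PI", _NEGATIVE_ATOMS), (-1, "NI", _POSITIVE_ATOMS)):
        for grp in charged_groups(lig, sign):
            centroid = _centroid(lig, grp)
            partners = []
            for ri, res in enumerate(protein.residues):
                names = table.get(res.name.upper(), ())
                for pa in res.atoms:
                    named = (pa.name or "").upper() in names
                    charged = np.sign(pa.formal_charge) == -sign
                    if (named or charged) and np.linalg.norm(pa.coords - centroid) <= rules.ionic_distance:
                        partners.append((ri, pa.index, res.label))
            if partners:
                partner_atoms.update((ri, ai) for ri, ai, _ in partners)
                feats.append(
                    PharmacophoreFeature(
                        kind, centroid, radii[kind], tuple(grp),
                        partner_residues=tuple(dict.fromkeys(lbl for _, _, lbl in partners)),
                    )
                )

    if not feats:
        raise EmptyModelError(f"no pharmacophore features perceivable at t={frame.time} ps")

    # exclusion spheres at non-partner protein heavy atoms near the ligand
    lig_heavy = lig.heavy_coords()
    evs = []
    for ri, res in enumerate(protein.residues):
        for pa in res.atoms:
            if not pa.is_heavy or (ri, pa.index) in partner_atoms:
                continue
            d = np.min(np.linalg.norm(lig_heavy - pa.coords, axis=1))
            if d <= rules.evs_distance:
                evs.append(ExclusionVolume(center=pa.coords, radius=rules.evs_radius))

    return PharmacophoreModel(
        name=f"frame_t{frame.time:g}",
        features=feats,
        exclusion_volumes=evs,
        provenance=f"perceived from frame at t={frame.time:g} ps",
    )


# ---------------------------------------------------------------------------
# occupancy
# ---------------------------------------------------------------------------


@dataclass
class OccupancyProfile:
    """Per-signature occurrence percentages over a stream of frame models."""

    percents: dict[tuple[str, tuple[int, ...]], float]
    n_frames: int
    major_threshold: float

    @property
    def major(self) -> set[tuple[str, tuple[int, ...]]]:
        return {s for s, p in self.percents.items() if p >= self.major_threshold}

    @property
    def minor(self) -> set[tuple[str, tuple[int, ...]]]:
        return {s for s, p in self.percents.items() if p < self.major_threshold}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "signature_kind": kind,
                "atom_indices": ",".join(map(str, atoms)),
                "percent": pct,
                "class": "major" if pct >= self.major_threshold else "minor",
            }
            for (kind, atoms), pct in sorted(self.percents.items())
        ]
        return pd.DataFrame(rows, columns=["signature_kind", "atom_indices", "percent", "class"])


def occupancy_profile(models: Sequence[PharmacophoreModel], major_threshold: float = 70.0) -> OccupancyProfile:
    """Count identical feature signatures across frame models.

    A feature's incidence is incremented whenever a model contains a feature
    of the same kind involving exactly the same ligand atoms.
    """
    if not models:
        raise ValueError("occupancy_profile requires at least one model")
    counts: dict[tuple[str, tuple[int, ...]], int] = {}
    for m in models:
        for sig in m.signatures():
            counts[sig] = counts.get(sig, 0) + 1
    n = len(models)
    return OccupancyProfile(
        percents={s: 100.0 * c / n for s, c in counts.items()},
        n_frames=n,
        major_threshold=major_threshold,
    )


def evs_stats(models: Sequence[PharmacophoreModel]) -> tuple[float, list[int]]:
    """Mean and per-frame count of exclusion volume spheres."""
    if not models:
        raise ValueError("evs_stats requires at least one model")
    counts = [len(m.exclusion_volumes) for m in models]
    return float(np.mean(counts)), counts


# ---------------------------------------------------------------------------
# RDF codes and model clustering
# ---------------------------------------------------------------------------

RDF_R_MAX = 20.0
RDF_BIN_WIDTH = 0.5
RDF_SIGMA = 0.5

_KIND_PAIRS = list(combinations_with_replacement(FEATURE_KINDS, 2))
_PAIR_INDEX = {p: i for i, p in enumerate(_KIND_PAIRS)}
_N_BINS = int(RDF_R_MAX / RDF_BIN_WIDTH)
_BIN_CENTERS = (np.arange(_N_BINS) + 0.5) * RDF_BIN_WIDTH


def rdf_code(model: PharmacophoreModel) -> np.ndarray:
    """Rigid-motion-invariant descriptor of a model's feature geometry.

    One Gaussian-smeared distance histogram per unordered feature-kind pair,
    concatenated in fixed kind-pair order; blocks with mass are L2-normalized.
    """
    n = len(model.features)
    code = np.zeros(len(_KIND_PAIRS) * _N_BINS)
    if n < 2:
        warnings.warn("rdf_code of a single-feature model is the zero vector")
        return code
    for i in range(n):
        for j in range(i + 1, n):
            fi, fj = model.features[i], model.features[j]
            pair = tuple(sorted((fi.kind, fj.kind), key=FEATURE_KINDS.index))
            block = _PAIR_INDEX[pair]
            d = np.linalg.norm(fi.position - fj.position)
            g = np.exp(-((_BIN_CENTERS - d) ** 2) / (2.0 * RDF_SIGMA**2))
            code[block * _N_BINS : (block + 1) * _N_BINS] += g
    for block in range(len(_KIND_PAIRS)):
        seg = code[block * _N_BINS : (block + 1) * _N_BINS]
        norm = np.linalg.norm(seg)
        if norm > 0:
            seg /= norm
    return code


def _cosine_distance_matrix(codes: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(codes, axis=1)
    safe = np.where(norms > 1e-12, norms, 1.0)
    unit = codes / safe[:, None]
    sim = unit @ unit.T
    zero = norms <= 1e-12
    if zero.any():
        sim[zero, :] = 0.0
        sim[:, zero] = 0.0
        sim[np.ix_(zero, zero)] = 1.0
    np.clip(sim, -1.0, 1.0, out=sim)
    np.fill_diagonal(sim, 1.0)
    dmat = 1.0 - sim
    np.fill_diagonal(dmat, 0.0)
    return dmat


@dataclass
class ModelClustering:
    clusters: list[list[int]]  # member indices, population-descending
    rpm_indices: list[int]  # medoid model index per cluster
    distance_matrix: np.ndarray


def cluster_models(
    models: Sequence[PharmacophoreModel],
    similarity_cutoff: float = 0.5,
    top: int | None = None,
) -> ModelClustering:
    """Average-linkage clustering of RDF codes at cosine similarity cutoff.

    Distance is 1 - cosine similarity; the dendrogram is cut at distance
    ``1 - similarity_cutoff`` ... i.e. models merging at similarity above the
    cutoff share a cluster.  Clusters come back population-descending with the
    medoid model (RPM) of each; ``top`` clamps to the most populated clusters.
    """
    if not models:
        raise ValueError("cluster_models requires at least one model")
    codes = np.vstack([rdf_code(m) for m in models])
    dmat = _cosine_distance_matrix(codes)
    if len(models) == 1:
        clusters = [[0]]
    else:
        clusters, _ = agglomerative_cut(dmat, 1.0 - similarity_cutoff, "average")
    rpms = []
    for members in clusters:
        sub = dmat[np.ix_(members, members)]
        if len(members) == 1:
            rpms.append(members[0])
        else:
            mean_d = sub.sum(axis=1) / (len(members) - 1)
            rpms.append(members[int(np.argmin(mean_d))])
    if top is not None:
        clusters = clusters[:top]
        rpms = rpms[:top]
    return ModelClustering(clusters=clusters, rpm_indices=rpms, distance_matrix=dmat)


def deduplicate_by_signatures(models: Sequence[PharmacophoreModel]) -> list[PharmacophoreModel]:
    """Drop models whose full signature set duplicates an earlier model's."""
    seen: set[frozenset] = set()
    out = []
    for m in models:
        key = frozenset(m.signatures())
        if key not in seen:
            seen.add(key)
            out.append(m)
    return out
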