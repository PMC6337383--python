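"""Deterministic, seeded generators emulating the statistical structure of the
upstream black-box engines (docking, MD, decoy generation).

Every generator takes an explicit integer seed, routes all randomness through
one ``numpy.random.Generator``, and emits a machine-readable truth record so
the test suite can verify planted structure exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chem_core import (
    AtomRecord,
    Bond,
    LigandPose,
    Molecule,
    ProteinStructure,
    Residue,
    TrajectoryFrame,
    write_sdf,
)

SCAFFOLD_SIZE = 14  # heavy atoms of the rigid bicyclic amino-acid template


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


# ---------------------------------------------------------------------------
# rigid scaffold template
# ---------------------------------------------------------------------------


def scaffold_template() -> Molecule:
    """A rigid 14-heavy-atom bicyclic amino-acid-like scaffold.

    Fused six-membered rings (one aromatic), a protonated amine and a
    carboxylate on the quaternary ring carbon -- the dimensions of a small
    conformationally restricted amino acid.
    """
    s = 1.4  # ring bond length
    hex1 = [np.array([s * math.cos(k * math.pi / 3), s * math.sin(k * math.pi / 3), 0.0]) for k in range(6)]
    # second ring centre mirrored across the shared edge hex1[0]-hex1[1]
    c2 = hex1[0] + hex1[1]
    hex2 = [c2 + np.array([s * math.cos(k * math.pi / 3), s * math.sin(k * math.pi / 3), 0.0]) for k in range(6)]
    coords = list(hex1)
    for p in hex2:
        if all(np.linalg.norm(p - q) > 0.1 for q in coords):
            coords.append(p)
    assert len(coords) == 10
    alpha = coords[7]  # a carbon of the saturated ring
    n_pos = alpha + 1.47 * _unit([0.2, 0.8, 0.9])
    c_carb = alpha + 1.52 * _unit([0.9, 0.3, -0.8])
    o1 = c_carb + 1.25 * _unit([1.0, -0.3, -0.4])
    o2 = c_carb + 1.25 * _unit([-0.2, 1.0, -0.9])
    coords += [n_pos, c_carb, o1, o2]
    atoms = []
    for i, p in enumerate(coords):
        element = {10: "N", 11: "C", 12: "O", 13: "O"}.get(i, "C")
        charge = {10: 1, 12: -1}.get(i, 0)
        atoms.append(AtomRecord(index=i, element=element, coords=p, formal_charge=charge, is_aromatic=i < 6))
    bonds = [Bond(k, (k + 1) % 6, 1, aromatic=True) for k in range(6)]
    # fused saturated ring: shared edge is atoms 0-1; new atoms 6..9
    bonds += [Bond(0, 9, 1), Bond(9, 6, 1), Bond(6, 7, 1), Bond(7, 8, 1), Bond(8, 1, 1)]
    bonds += [Bond(7, 10, 1), Bond(7, 11, 1), Bond(11, 12, 1), Bond(11, 13, 2)]
    return Molecule(name="scaffold", atoms=atoms, bonds=bonds)


# ---------------------------------------------------------------------------
# docked pose ensembles with planted cluster structure
# ---------------------------------------------------------------------------


def _cluster_translations(n_clusters: int, separation: float) -> list[np.ndarray]:
    axes = np.eye(3)
    out = []
    for c in range(n_clusters):
        out.append(separation * (1 + c // 3) * axes[c % 3])
    return out


def gen_pose_ensemble(
    n_ligands: int = 5,
    poses_per_ligand: int = 100,
    n_clusters: int = 5,
    separation: float = 6.0,
    jitter_sd: float = 0.3,
    membership: dict[str, Sequence[float]] | None = None,
    n_decoration_atoms: int = 2,
    seed: int = 0,
) -> tuple[list[LigandPose], pd.DataFrame]:
    """Pose ensemble with planted cluster structure across a ligand series.

    Every pose is the rigid scaffold placed at its cluster's pose (one common
    random orientation, cluster-specific translations at least ``separation``
    apart) plus isotropic Gaussian jitter of ``jitter_sd`` per coordinate.
    Ligand decorations beyond the scaffold are randomized.  Returns the poses
    and a truth table (pose_id, ligand_id, cluster).
    """
    if separation < 2 * jitter_sd:
        import warnings

        warnings.warn("cluster separation below 2x jitter scale; planted structure may not be recoverable")
    rng = np.random.default_rng(seed)
    template = scaffold_template()
    rotation = random_rotation(rng)
    translations = _cluster_translations(n_clusters, separation)
    ligand_ids = [f"L{i + 1}" for i in range(n_ligands)]
    poses = []
    truth_rows = []
    for lig_idx, lig in enumerate(ligand_ids):
        weights = np.full(n_clusters, 1.0 / n_clusters)
        if membership and lig in membership:
            weights = np.asarray(membership[lig], dtype=float)
            weights = weights / weights.sum()
        for p in range(poses_per_ligand):
            cluster = int(rng.choice(n_clusters, p=weights))
            base = np.array([a.coords for a in template.atoms]) @ rotation.T + translations[cluster]
            jitter = rng.normal(scale=jitter_sd, size=base.shape) if jitter_sd > 0 else 0.0
            coords = base + jitter
            atoms = [
                AtomRecord(
                    index=i,
                    element=a.element,
                    coords=coords[i],
                    formal_charge=a.formal_charge,
                    is_aromatic=a.is_aromatic,
                )
                for i, a in enumerate(template.atoms)
            ]
            bonds = [Bond(b.i, b.j, b.order, b.aromatic) for b in template.bonds]
            # per-ligand decorations: extra atoms hanging off the aromatic ring
            for d in range(n_decoration_atoms):
                anchor = atoms[2 + d % 3]
                offset = rng.normal(scale=1.0, size=3)
                pos = anchor.coords + 1.5 * _unit(offset + 0.1)
                idx = len(atoms)
                atoms.append(AtomRecord(index=idx, element="C" if (lig_idx + d) % 2 else "Cl", coords=pos))
                bonds.append(Bond(anchor.index, idx, 1))
            pose_id = f"{lig}_p{p:03d}"
            mol = Molecule(
                name=pose_id,
                atoms=atoms,
                bonds=bonds,
                properties={"ligand_id": lig, "pose_id": pose_id},
            )
            poses.append(
                LigandPose(
                    ligand_id=lig,
                    pose_id=pose_id,
                    molecule=mol,
                    scaffold_map=list(range(SCAFFOLD_SIZE)),
                    scores={"GlideScore": float(-6.0 + rng.normal())},
                )
            )
            truth_rows.append({"pose_id": pose_id, "ligand_id": lig, "cluster": cluster})
    return poses, pd.DataFrame(truth_rows)


def write_pose_ensemble(poses: Sequence[LigandPose], truth: pd.DataFrame, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_sdf([p.molecule for p in poses], outdir / "poses.sdf")
    with open(outdir / "scaffold.json", "w") as fh:
        json.dump({"scaffold_map": list(range(SCAFFOLD_SIZE))}, fh)
        fh.write("\n")
    truth.to_csv(outdir / "truth.csv", index=False)


# ---------------------------------------------------------------------------
# toy binding pocket + planted amino-acid-like ligand
# ---------------------------------------------------------------------------


@dataclass
class PocketBundle:
    """A toy pocket, its planted ligand and the machine-readable truth."""

    protein: ProteinStructure
    ligand: LigandPose
    truth: dict = field(default_factory=dict)


def _make_residue(chain: str, number: int, name: str, atom_spec: list[tuple[str, str, np.ndarray, int]]) -> Residue:
    atoms = [
        AtomRecord(index=i, element=elem, coords=pos, formal_charge=charge, name=aname)
        for i, (aname, elem, pos, charge) in enumerate(atom_spec)
    ]
    return Residue(chain_id=chain, number=number, name=name, atoms=atoms)


def gen_toy_pocket(
    seed: int = 0,
    include_aromatic: bool = True,
    include_halogen_site: bool = True,
    include_charged_partners: bool = True,
    include_gate_pair: bool = True,
    n_hydrophobic: int = 4,
) -> PocketBundle:
    """Small pocket in which a planted ligand realizes a configured set of
    hydrogen bonds (3 donated + 2 accepted), hydrophobic contacts, an aromatic
    stack, a halogen-bond site and (optionally) charged partners.

    The geometry is deterministic; ``seed`` only perturbs nothing here but is
    accepted for interface uniformity.
    """
    del seed  # construction is fully deterministic

    # --- ligand -----------------------------------------------------------
    ca = np.array([0.0, 0.0, 0.0])
    n_pos = ca + 1.47 * _unit([0.95, 0.25, 0.2])
    u = _unit(n_pos - ca)
    # orthonormal frame around the N-CA axis
    v = _unit(np.cross(u, [0.0, 0.0, 1.0]))
    w = np.cross(u, v)
    theta = math.radians(70.0)
    h_dirs = []
    for phi in (0.0, 2 * math.pi / 3, 4 * math.pi / 3):
        h_dirs.append(_unit(math.cos(theta) * u + math.sin(theta) * (math.cos(phi) * v + math.sin(phi) * w)))
    h_atoms = [n_pos + 1.01 * d for d in h_dirs]

    c_carb = ca + 1.52 * _unit([-0.55, 0.95, 0.0])
    o1 = c_carb + 1.25 * _unit([-1.0, 0.35, 0.25])
    o2 = c_carb + 1.25 * _unit([0.3, 1.0, -0.3])

    cb = ca + 1.52 * _unit([-0.3, -0.95, 0.1])
    ring_center = ca + 3.8 * _unit([-0.5, -1.6, 0.15])
    ring_u = _unit(cb - ring_center)
    ring_v = _unit(np.cross(ring_u, [0.05, 0.1, 1.0]))
    ring = [ring_center + 1.39 * (math.cos(k * math.pi / 3) * ring_u + math.sin(k * math.pi / 3) * ring_v) for k in range(6)]
    cl_pos = ring[3] + 1.74 * _unit(ring[3] - ring_center)

    lig_atoms = []
    coords_and_meta = [
        ("CA", "C", ca, 0, False),
        ("N", "N", n_pos, 1, False),
        ("C", "C", c_carb, 0, False),
        ("O1", "O", o1, -1, False),
        ("O2", "O", o2, 0, False),
        ("CB", "C", cb, 0, False),
    ]
    for k, p in enumerate(ring):
        coords_and_meta.append((f"CR{k}", "C", p, 0, True))
    coords_and_meta.append(("CL", "Cl", cl_pos, 0, False))
    for k, p in enumerate(h_atoms):
        coords_and_meta.append((f"HN{k + 1}", "H", p, 0, False))
    for i, (aname, elem, pos, charge, arom) in enumerate(coords_and_meta):
        lig_atoms.append(AtomRecord(index=i, element=elem, coords=pos, formal_charge=charge, is_aromatic=arom, name=aname))
    i_ca, i_n, i_c, i_o1, i_o2, i_cb = 0, 1, 2, 3, 4, 5
    ring_idx = list(range(6, 12))
    i_cl = 12
    h_idx = [13, 14, 15]
    bonds = [
        Bond(i_ca, i_n), Bond(i_ca, i_c), Bond(i_c, i_o1), Bond(i_c, i_o2, 2), Bond(i_ca, i_cb),
        Bond(i_cb, ring_idx[0]),
        Bond(ring_idx[3], i_cl),
    ]
    bonds += [Bond(ring_idx[k], ring_idx[(k + 1) % 6], 1, aromatic=True) for k in range(6)]
    bonds += [Bond(i_n, h) for h in h_idx]
    ligand_mol = Molecule(name="AAL", atoms=lig_atoms, bonds=bonds, properties={"ligand_id": "AAL"})
    ligand = LigandPose(ligand_id="AAL", pose_id="planted", molecule=ligand_mol)

    lig_centroid = np.mean([a.coords for a in lig_atoms if a.is_heavy], axis=0)

    # --- pocket residues --------------------------------------------------
    residues: list[Residue] = []
    toggle_units: dict[str, list[str]] = {}
    planted_hbonds: list[tuple[int, str]] = []

    # three backbone carbonyl acceptors opposite the N-H vectors
    for k, d in enumerate(h_dirs):
        o_pos = n_pos + 2.9 * d
        c_pos = o_pos + 1.23 * d
        residues.append(_make_residue("A", 10 + k, "GLY", [("O", "O", o_pos, 0), ("C", "C", c_pos, 0)]))
        planted_hbonds.append((i_n, f"G{10 + k}"))
    toggle_units["hbd"] = ["G10", "G11", "G12"]

    # two backbone amide donors pointing at the carboxylate oxygens
    for k, (o_pos, num) in enumerate(((o1, 20), (o2, 21))):
        d = _unit(o_pos - c_carb)
        npos = o_pos + 2.9 * d
        hpos = npos - 1.01 * d
        residues.append(_make_residue("A", num, "GLY", [("N", "N", npos, 0), ("H", "H", hpos, 0)]))
        planted_hbonds.append((i_o1 if k == 0 else i_o2, f"G{num}"))
        toggle_units[f"hba{k + 1}"] = [f"G{num}"]

    # hydrophobic side chains facing the ring fragment centroid
    frag_centroid = np.mean([lig_atoms[i].coords for i in [i_cb] + ring_idx], axis=0)
    normal = np.cross(ring_u, ring_v)
    hydro_spec = []
    for k in range(n_hydrophobic):
        d = _unit(normal + 0.35 * (math.cos(k * 2.2) * ring_u + math.sin(k * 2.2) * ring_v))
        hydro_spec.append((f"CG{k + 1}", "C", frag_centroid + 4.0 * d, 0))
    residues.append(_make_residue("A", 30, "ILE", hydro_spec))
    # the hydrophobic/aromatic sites all fall within range of both ligand
    # hydrophobic fragments, so they toggle as one unit
    toggle_units["hydrophobics"] = ["I30"]

    if include_aromatic:
        ar_center = ring_center - 4.6 * normal
        ar_names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
        ar_spec = [
            (ar_names[k], "C", ar_center + 1.39 * (math.cos(k * math.pi / 3) * ring_u + math.sin(k * math.pi / 3) * ring_v), 0)
            for k in range(6)
        ]
        residues.append(_make_residue("A", 31, "PHE", ar_spec))
        toggle_units["hydrophobics"].append("F31")

    if include_halogen_site:
        xd = _unit(cl_pos - ring[3])
        o_pos = cl_pos + 3.1 * xd
        residues.append(_make_residue("A", 33, "GLY", [("O", "O", o_pos, 0), ("C", "C", o_pos + 1.23 * xd, 0)]))
        v32 = []
        for k in range(3):
            d = _unit(np.cross(xd, ring_v) + 0.4 * math.cos(k * 2.0) * ring_u + 0.4 * math.sin(k * 2.0) * ring_v)
            v32.append((f"CG{k + 1}", "C", cl_pos + 4.0 * d, 0))
        residues.append(_make_residue("A", 32, "VAL", v32))
        toggle_units["hydrophobics"].append("V32")

    if include_charged_partners:
        residues.append(_make_residue("A", 40, "ASP", [("OD1", "O", n_pos + 4.5 * _unit(u + 0.6 * v), -1)]))
        residues.append(_make_residue("A", 41, "LYS", [("NZ", "N", o1 + 4.5 * _unit(o1 - lig_centroid), 1)]))

    if include_gate_pair:
        gate_dir = _unit([1.0, 0.4, -0.3])
        nd2 = lig_centroid + 12.0 * gate_dir
        oe1 = nd2 + 2.9 * gate_dir
        hd = nd2 + 1.01 * gate_dir
        residues.append(_make_residue("A", 50, "ASN", [("ND2", "N", nd2, 0), ("HD21", "H", hd, 0)]))
        residues.append(_make_residue("A", 51, "GLU", [("OE1", "O", oe1, 0)]))
        toggle_units["gate"] = ["E51"]

    protein = ProteinStructure(residues=residues)

    expected_signatures = [
        ("HBD", (i_n,)),
        ("HBA", (i_o1,)),
        ("HBA", (i_o2,)),
        ("H", tuple(sorted([i_cb] + ring_idx))),
    ]
    if include_halogen_site:
        expected_signatures.append(("H", (i_cl,)))
    if include_aromatic:
        expected_signatures.append(("AR", tuple(ring_idx)))
    if include_charged_partners:
        expected_signatures.append(("PI", (i_n,)))
        expected_signatures.append(("NI", (i_o1,)))

    truth = {
        "planted_hbonds": planted_hbonds,
        "expected_signatures": expected_signatures,
        "toggle_units": toggle_units,
        "gate_pair": ("N50", "E51") if include_gate_pair else None,
        "ligand_centroid": lig_centroid,
        # signatures whose occupancy tracks each toggle unit's probability
        "signatures_of_toggle": {
            "hbd": [("HBD", (i_n,))],
            "hba1": [("HBA", (i_o1,))],
            "hba2": [("HBA", (i_o2,))],
            "hydrophobics": [("H", tuple(sorted([i_cb] + ring_idx)))]
            + ([("H", (i_cl,))] if include_halogen_site else [])
            + ([("AR", tuple(ring_idx))] if include_aromatic else []),
        },
    }
    return PocketBundle(protein=protein, ligand=ligand, truth=truth)


# ---------------------------------------------------------------------------
# trajectories with planted per-feature toggle probabilities
# ---------------------------------------------------------------------------


def gen_trajectory(
    bundle: PocketBundle,
    n_frames: int = 10_000,
    toggles: dict[str, float] | None = None,
    positional_jitter_sd: float = 0.0,
    dt: float = 2.0,
    seed: int = 0,
) -> tuple[list[TrajectoryFrame], pd.DataFrame]:
    """Trajectory whose toggle units are realized independently per frame.

    For each named toggle unit (see ``bundle.truth['toggle_units']``) and each
    frame, the unit is present with its configured probability; absent units
    have their residues displaced 6 A away from the ligand so the underlying
    geometric criterion fails.  Ligand coordinates receive optional Gaussian
    jitter; untouched residues are shared between frames.
    """
    toggles = toggles or {}
    rng = np.random.default_rng(seed)
    unit_map = bundle.truth["toggle_units"]
    unknown = set(toggles) - set(unit_map)
    if unknown:
        raise KeyError(f"unknown toggle units: {sorted(unknown)}")
    lig_centroid = bundle.truth["ligand_centroid"]

    # precompute displaced variants of every toggleable residue
    base_residues = list(bundle.protein.residues)
    displaced: dict[str, Residue] = {}
    for unit in toggles:
        for label in unit_map[unit]:
            res = bundle.protein.residue_by_label(label)
            centroid = np.mean([a.coords for a in res.atoms], axis=0)
            vec = 6.0 * _unit(centroid - lig_centroid)
            displaced[label] = _make_residue(
                res.chain_id,
                res.number,
                res.name,
                [(a.name, a.element, a.coords + vec, a.formal_charge) for a in res.atoms],
            )

    frames = []
    rows = []
    lig = bundle.ligand.molecule
    for f in range(n_frames):
        states = {unit: bool(rng.random() < p) for unit, p in toggles.items()}
        off_labels = {label for unit, on in states.items() if not on for label in unit_map[unit]}
        if off_labels:
            residues = [displaced[r.label] if r.label in off_labels else r for r in base_residues]
            protein = ProteinStructure(residues=residues)
        else:
            protein = bundle.protein
        if positional_jitter_sd > 0:
            atoms = [
                AtomRecord(
                    index=a.index,
                    element=a.element,
                    coords=a.coords + rng.normal(scale=positional_jitter_sd, size=3),
                    formal_charge=a.formal_charge,
                    is_aromatic=a.is_aromatic,
                    name=a.name,
                )
                for a in lig.atoms
            ]
            mol = Molecule(name=lig.name, atoms=atoms, bonds=list(lig.bonds), properties=dict(lig.properties))
        else:
            mol = lig
        pose = LigandPose(ligand_id=bundle.ligand.ligand_id, pose_id=f"frame{f}", molecule=mol)
        frames.append(TrajectoryFrame(time=f * dt, protein=protein, ligand=pose))
        rows.append({"frame": f, "time": f * dt, **{f"on_{u}": s for u, s in states.items()}})
    return frames, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# screening populations and libraries
# ---------------------------------------------------------------------------


def gen_screening_population(
    n_actives: int = 97,
    n_decoys: int = 5300,
    score_separation: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Active/decoy score populations: Normal(delta, 1) vs Normal(0, 1)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i, s in enumerate(rng.normal(loc=score_separation, size=n_actives)):
        rows.append({"molecule_id": f"active{i:04d}", "is_active": True, "score": float(s)})
    for i, s in enumerate(rng.normal(loc=0.0, size=n_decoys)):
        rows.append({"molecule_id": f"decoy{i:04d}", "is_active": False, "score": float(s)})
    return pd.DataFrame(rows)


def gen_decoy_molecule(name: str, rng: np.random.Generator, n_atoms: int = 7) -> Molecule:
    """An all-carbon blob: only hydrophobic features are perceivable."""
    coords = rng.uniform(-3.0, 3.0, size=(n_atoms, 3))
    atoms = [AtomRecord(index=i, element="C", coords=c) for i, c in enumerate(coords)]
    return Molecule(name=name, atoms=atoms, bonds=[], properties={"molecule_id": name})


def gen_screening_library(
    bundle: PocketBundle,
    n_decoys: int = 100,
    seed: int = 0,
) -> dict[str, list[Molecule]]:
    """Library of hydrophobic decoys plus the planted pocket ligand."""
    rng = np.random.default_rng(seed)
    library: dict[str, list[Molecule]] = {}
    for i in range(n_decoys):
        name = f"decoy{i:03d}"
        library[name] = [gen_decoy_molecule(name, rng)]
    planted = bundle.ligand.molecule
    library[planted.name] = [planted]
    return library
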