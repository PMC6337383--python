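import itertools

import numpy as np
import pytest

from sbpharm import dynophore as dy
from sbpharm import screen as scr
from sbpharm import synthetic_data as sd
from sbpharm.chem_core import (
    AtomRecord,
    ExclusionVolume,
    Molecule,
    PharmacophoreFeature,
    PharmacophoreModel,
)
from sbpharm.errors import DegenerateGeometryError


def _model(positions, kinds, radius=1.5, name="m"):
    feats = [
        PharmacophoreFeature(k, p, radius, (i,))
        for i, (p, k) in enumerate(zip(positions, kinds))
    ]
    return PharmacophoreModel(name=name, features=feats)


def _conformer_from_features(positions, kinds, name="conf"):
    """Molecule whose perceived ligand features sit exactly at ``positions``.

    HBD -> charged N, HBA -> lone O, H -> lone C, hydrogens omitted.
    """
    element = {"HBD": "N", "HBA": "O", "H": "C"}
    atoms = []
    for i, (p, k) in enumerate(zip(positions, kinds)):
        charge = 1 if k == "HBD" else 0
        atoms.append(AtomRecord(i, element[k], p, formal_charge=charge))
    return Molecule(name=name, atoms=atoms, bonds=[], properties={"molecule_id": name})


# ---------------------------------------------------------------------------
# kabsch
# ---------------------------------------------------------------------------


def test_kabsch_identity(rng):
    P = rng.normal(size=(5, 3))
    R, t, rmsd = scr.kabsch(P, P)
    assert rmsd == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(R, np.eye(3), atol=1e-9)


def test_kabsch_recovers_rotation(rng):
    P = rng.normal(size=(6, 3))
    Rz = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])  # 90 degrees about z
    Q = P @ Rz.T + np.array([1.0, 2.0, 3.0])
    R, t, rmsd = scr.kabsch(P, Q)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(R, Rz, atol=1e-9)


def test_kabsch_rejects_reflection():
    P = np.array([[0.0, 0, 0], [2, 0, 0], [0, 1, 0], [0.5, 0.2, 1.5]])
    Q = P.copy()
    Q[:, 0] *= -1  # mirror image
    _, _, rmsd = scr.kabsch(P, Q)
    assert rmsd > 0.1  # proper rotations cannot undo a reflection


def test_kabsch_collinear_error():
    P = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
    with pytest.raises(DegenerateGeometryError):
        scr.kabsch(P, P + 1.0)


# ---------------------------------------------------------------------------
# match_conformer
# ---------------------------------------------------------------------------

POSITIONS6 = np.array(
    [[0, 0, 0], [4, 0, 0], [2, 3, 0], [1, 1, 2.5], [3.5, 2, 1], [0.5, 3, 1.5]], dtype=float
)
KINDS6 = ["HBD", "HBA", "H", "H", "HBA", "HBD"]


def test_exact_self_match(rng):
    model = _model(POSITIONS6, KINDS6)
    R = sd.random_rotation(rng)
    conf = _conformer_from_features(POSITIONS6 @ R.T + 7.0, KINDS6)
    m = scr.match_conformer(conf, model)
    assert m is not None
    assert m.n_matched == 6 and m.omitted == []
    assert m.feature_rmsd == pytest.approx(0.0, abs=1e-6)
    assert m.passed_exclusion


def test_one_omission_allowed():
    model = _model(POSITIONS6, KINDS6)
    conf = _conformer_from_features(POSITIONS6[:-1], KINDS6[:-1])
    m = scr.match_conformer(conf, model, max_omit=1)
    assert m is not None and m.n_matched == 5 and len(m.omitted) == 1
    assert scr.match_conformer(conf, model, max_omit=0) is None


def test_two_missing_features_rejected():
    model = _model(POSITIONS6, KINDS6)
    conf = _conformer_from_features(POSITIONS6[:-2], KINDS6[:-2])
    assert scr.match_conformer(conf, model, max_omit=1) is None


def test_fit_score_hand_values():
    assert scr.fit_score(6, 0.0, 1.5) == pytest.approx(69.0)
    assert scr.fit_score(5, 0.0, 1.5) == pytest.approx(59.0)
    # any 6-feature score beats any 5-feature score
    assert scr.fit_score(6, 100.0, 1.5) > scr.fit_score(5, 0.0, 1.5)
    # geometric term clamps at zero
    assert scr.fit_score(4, 2.0, 1.5) == pytest.approx(40.0)


def test_check_exclusion_boundaries():
    model = _model(POSITIONS6[:3], KINDS6[:3])
    model.exclusion_volumes = [ExclusionVolume([10.0, 0, 0], 1.0)]
    assert scr.check_exclusion(np.array([[11.1, 0, 0]]), model)
    assert not scr.check_exclusion(np.array([[10.9, 0, 0]]), model)


def test_exclusion_blocks_match():
    # unique kinds pin the correspondence; max_omit=0 pins the alignment
    positions = POSITIONS6[:3]
    kinds = ["HBD", "HBA", "H"]
    model = _model(positions, kinds)
    conf = _conformer_from_features(positions, kinds)
    m = scr.match_conformer(conf, model, max_omit=0)
    assert m.passed_exclusion and m.fit_score is not None
    model.exclusion_volumes = [ExclusionVolume(positions[0], 1.0)]
    m2 = scr.match_conformer(conf, model, max_omit=0)
    assert not m2.passed_exclusion and m2.fit_score is None


# ---------------------------------------------------------------------------
# brute-force oracle (correspondences x dense rotation grid)
# ---------------------------------------------------------------------------


def _rotation_grid(n_axes=200, n_angles=36):
    """Quasi-uniform rotation grid: Fibonacci axes x uniform angles."""
    rotations = [np.eye(3)]
    golden = (1 + 5**0.5) / 2
    for i in range(n_axes):
        z = 1 - 2 * (i + 0.5) / n_axes
        r = np.sqrt(max(0.0, 1 - z * z))
        phi = 2 * np.pi * i / golden
        axis = np.array([r * np.cos(phi), r * np.sin(phi), z])
        for k in range(1, n_angles):
            theta = 2 * np.pi * k / n_angles
            K = np.array(
                [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
            )
            rotations.append(np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * K @ K)
    return rotations


_GRID = _rotation_grid()


def oracle_best_match(conf_feats, model, max_omit):
    """Exhaustive correspondences + rotation grid; returns best matched count."""
    n = len(model.features)
    best = 0
    model_pos = np.array([f.position for f in model.features])
    conf_pos = np.array([f.position for f in conf_feats])
    for size in range(n, max(n - max_omit, 1) - 1, -1):
        if size <= best:
            break
        for subset in itertools.combinations(range(n), size):
            cands = [
                [ci for ci, f in enumerate(conf_feats) if f.kind == model.features[mi].kind]
                for mi in subset
            ]
            for assignment in itertools.product(*cands):
                if len(set(assignment)) != size:
                    continue
                P = conf_pos[list(assignment)]
                Q = model_pos[list(subset)]
                radii = np.array([model.features[mi].radius for mi in subset])
                for R in _GRID:
                    aligned = P @ R.T
                    aligned = aligned + (Q.mean(axis=0) - aligned.mean(axis=0))
                    if np.all(np.linalg.norm(aligned - Q, axis=1) <= radii):
                        best = max(best, size)
                        break
                if best == size:
                    break
            if best == size:
                break
    return best


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_match_agrees_with_brute_force(seed):
    rng = np.random.default_rng(seed)
    positions = rng.normal(scale=2.0, size=(5, 3))
    kinds = ["HBD", "HBA", "H", "H", "HBA"]
    model = _model(positions, kinds)
    R = sd.random_rotation(rng)

    # exact rigid copy: both must find all 5
    conf = _conformer_from_features(positions @ R.T + 5.0, kinds)
    feats = dy.perceive_ligand_features(conf)
    ours = scr.match_conformer(conf, model, max_omit=1)
    assert ours is not None and ours.n_matched == 5
    assert oracle_best_match(feats, model, max_omit=1) == 5

    # one feature displaced far: both must fall back to 4 (n-1)
    moved = positions.copy()
    moved[2] += np.array([8.0, 0, 0])
    conf2 = _conformer_from_features(moved @ R.T + 5.0, kinds)
    feats2 = dy.perceive_ligand_features(conf2)
    ours2 = scr.match_conformer(conf2, model, max_omit=1)
    assert ours2 is not None and ours2.n_matched == 4
    assert oracle_best_match(feats2, model, max_omit=1) == 4

    # doubled geometry: no match for either
    conf3 = _conformer_from_features(2.5 * positions, kinds)
    feats3 = dy.perceive_ligand_features(conf3)
    assert scr.match_conformer(conf3, model, max_omit=1) is None
    assert oracle_best_match(feats3, model, max_omit=1) < 4


# ---------------------------------------------------------------------------
# library screening
# ---------------------------------------------------------------------------


def test_self_hit_closure(pocket_bundle, pocket_model):
    m = scr.match_conformer(pocket_bundle.ligand.molecule, pocket_model)
    assert m is not None
    assert m.n_matched == len(pocket_model.features)
    assert m.passed_exclusion
    assert m.feature_rmsd == pytest.approx(0.0, abs=1e-6)


def test_planted_library_retrieval(pocket_bundle, pocket_model):
    library = sd.gen_screening_library(pocket_bundle, n_decoys=100, seed=3)
    hits = scr.screen_library(library, pocket_model)
    assert [h.molecule_id for h in hits] == ["AAL"]


def test_all_decoy_library_empty(pocket_bundle, pocket_model):
    library = sd.gen_screening_library(pocket_bundle, n_decoys=30, seed=3)
    del library["AAL"]
    assert scr.screen_library(library, pocket_model) == []


def test_empty_library_rejected(pocket_model):
    with pytest.raises(ValueError):
        scr.screen_library({}, pocket_model)


def test_max_omit_monotonicity(pocket_bundle, pocket_model, rng):
    # drop one feature from the planted ligand so only the n-1 rule fires
    mol = pocket_bundle.ligand.molecule
    atoms_without_cl = [a for a in mol.atoms if a.element != "Cl"]
    reindex = {a.index: i for i, a in enumerate(atoms_without_cl)}
    from sbpharm.chem_core import Bond

    bonds = [
        Bond(reindex[b.i], reindex[b.j], b.order, b.aromatic)
        for b in mol.bonds
        if b.i in reindex and b.j in reindex
    ]
    atoms = [
        AtomRecord(i, a.element, a.coords, a.formal_charge, None, a.is_aromatic)
        for i, a in enumerate(atoms_without_cl)
    ]
    pruned = Molecule(name="pruned", atoms=atoms, bonds=bonds)
    lib = {"pruned": [pruned]}
    strict = scr.screen_library(lib, pocket_model, max_omit=0)
    relaxed = scr.screen_library(lib, pocket_model, max_omit=1)
    assert {h.molecule_id for h in strict} <= {h.molecule_id for h in relaxed}
    assert [h.molecule_id for h in relaxed] == ["pruned"]


def test_exclusion_anti_monotonicity(pocket_bundle, pocket_model):
    library = sd.gen_screening_library(pocket_bundle, n_decoys=20, seed=6)
    before = {h.molecule_id for h in scr.screen_library(library, pocket_model)}
    import copy

    blocked = PharmacophoreModel(
        name=pocket_model.name,
        features=pocket_model.features,
        exclusion_volumes=list(pocket_model.exclusion_volumes)
        + [ExclusionVolume(pocket_bundle.ligand.molecule.atoms[0].coords, 1.2)],
        provenance=pocket_model.provenance,
    )
    after = {h.molecule_id for h in scr.screen_library(library, blocked)}
    assert after <= before


def test_rigid_motion_invariance(pocket_bundle, pocket_model, rng):
    library = sd.gen_screening_library(pocket_bundle, n_decoys=10, seed=8)
    baseline = scr.hits_to_frame(scr.screen_library(library, pocket_model))
    R = sd.random_rotation(rng)
    t = rng.normal(size=3) * 20
    moved = {}
    for name, confs in library.items():
        moved[name] = [
            Molecule(
                name=c.name,
                atoms=[
                    AtomRecord(a.index, a.element, a.coords @ R.T + t, a.formal_charge, None, a.is_aromatic)
                    for a in c.atoms
                ],
                bonds=list(c.bonds),
                properties=dict(c.properties),
            )
            for c in confs
        ]
    shifted = scr.hits_to_frame(scr.screen_library(moved, pocket_model))
    assert list(baseline["molecule_id"]) == list(shifted["molecule_id"])
    np.testing.assert_allclose(baseline["fit_score"], shifted["fit_score"], atol=1e-6)


# ---------------------------------------------------------------------------
# common hits approach
# ---------------------------------------------------------------------------


def test_cha_ranking(pocket_bundle, pocket_model):
    # second model: same features, no exclusion volumes
    m2 = PharmacophoreModel(name="m2", features=pocket_model.features, provenance="copy")
    library = sd.gen_screening_library(pocket_bundle, n_decoys=5, seed=10)
    df = scr.cha_screen(library, [pocket_model, m2])
    assert list(df["molecule_id"]) == ["AAL"]
    assert df.loc[0, "hit_count"] == 2


def test_cha_requires_two_models(pocket_model):
    with pytest.raises(ValueError):
        scr.cha_screen({}, [pocket_model])


def test_cha_tie_broken_by_mean_fit():
    positions = POSITIONS6[:4]
    kinds = KINDS6[:4]
    models = [_model(positions, kinds, name="ma"), _model(positions, kinds, name="mb")]
    exact = _conformer_from_features(positions, kinds, name="exact")
    # perturbed within the tolerance spheres: hits both models with lower fit
    rng = np.random.default_rng(3)
    wobbled = _conformer_from_features(positions + rng.normal(scale=0.25, size=positions.shape), kinds, name="wobbled")
    df = scr.cha_screen({"exact": [exact], "wobbled": [wobbled]}, models)
    assert list(df["hit_count"]) == [2, 2]
    assert list(df["molecule_id"]) == ["exact", "wobbled"]
    assert df.loc[0, "mean_fit"] > df.loc[1, "mean_fit"]
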