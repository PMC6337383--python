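import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sbpharm import dynophore as dy
from sbpharm import synthetic_data as sd
from sbpharm.chem_core import (
    AtomRecord,
    LigandPose,
    Molecule,
    PharmacophoreFeature,
    PharmacophoreModel,
    ProteinStructure,
    Residue,
    TrajectoryFrame,
)
from sbpharm.errors import EmptyModelError


def _simple_model(positions, kinds, name="m"):
    feats = [
        PharmacophoreFeature(k, p, 1.5, (i,))
        for i, (p, k) in enumerate(zip(positions, kinds))
    ]
    return PharmacophoreModel(name=name, features=feats)


# ---------------------------------------------------------------------------
# perception
# ---------------------------------------------------------------------------


def test_perceived_signatures_match_truth(pocket_bundle, pocket_model):
    expected = {(k, tuple(a)) for k, a in pocket_bundle.truth["expected_signatures"]}
    assert pocket_model.signatures() == expected


def test_hbd_direction_points_at_acceptor(pocket_bundle, pocket_model):
    hbd = next(f for f in pocket_model.features if f.kind == "HBD")
    assert hbd.direction is not None
    assert np.linalg.norm(hbd.direction) == pytest.approx(1.0, abs=1e-6)
    assert set(hbd.partner_residues) == {"G10", "G11", "G12"}


def test_amino_donor_fixture():
    """A lone N-H donating to a backbone carbonyl at 2.9 A / ~180 deg."""
    n = AtomRecord(0, "N", [0, 0, 0], formal_charge=1)
    h = AtomRecord(1, "H", [1.01, 0, 0])
    mol = Molecule(name="amine", atoms=[n, h], bonds=[__import__("sbpharm.chem_core", fromlist=["Bond"]).Bond(0, 1)])
    res = Residue("A", 5, "GLY", [AtomRecord(0, "O", [2.9, 0, 0], name="O")])
    frame = TrajectoryFrame(0.0, ProteinStructure([res]), LigandPose("a", "a", mol))
    model = dy.perceive_features(frame)
    hbds = [f for f in model.features if f.kind == "HBD"]
    assert len(hbds) == 1 and hbds[0].ligand_atoms == (0,)


def test_hydrophobic_feature_requires_three_partners():
    ring = [AtomRecord(i, "C", [np.cos(i), np.sin(i), 0.0]) for i in range(4)]
    mol = Molecule(name="blob", atoms=ring, bonds=[])
    partners = [
        Residue("A", 10 + k, "ILE", [AtomRecord(0, "C", [4.0, 0, 0.5 * k], name="CG1")])
        for k in range(4)
    ]
    frame = TrajectoryFrame(0.0, ProteinStructure(partners), LigandPose("b", "b", mol))
    model = dy.perceive_features(frame)
    assert any(f.kind == "H" for f in model.features)
    # with only two partner atoms the feature disappears
    frame2 = TrajectoryFrame(0.0, ProteinStructure(partners[:2]), LigandPose("b", "b", mol))
    with pytest.raises(EmptyModelError):
        dy.perceive_features(frame2)


def test_isolated_ligand_raises(pocket_bundle):
    mol = pocket_bundle.ligand.molecule
    shifted = Molecule(
        name="far",
        atoms=[
            AtomRecord(a.index, a.element, a.coords + np.array([50.0, 0, 0]), a.formal_charge, None, a.is_aromatic)
            for a in mol.atoms
        ],
        bonds=list(mol.bonds),
    )
    frame = TrajectoryFrame(0.0, pocket_bundle.protein, LigandPose("far", "far", shifted))
    with pytest.raises(EmptyModelError):
        dy.perceive_features(frame)


def test_exclusion_spheres_exclude_partner_atoms(pocket_bundle, pocket_model):
    # all EVS centers must be > hbond range from any feature partner position
    partner_positions = []
    for f in pocket_model.features:
        for lbl in f.partner_residues:
            res = pocket_bundle.protein.residue_by_label(lbl)
            partner_positions.extend(a.coords for a in res.atoms if a.is_heavy)
    assert len(pocket_model.exclusion_volumes) > 0
    for ev in pocket_model.exclusion_volumes:
        assert ev.radius == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# occupancy
# ---------------------------------------------------------------------------


def test_occupancy_always_present_is_major(pocket_bundle):
    frames, _ = sd.gen_trajectory(pocket_bundle, n_frames=10, toggles={}, seed=0)
    models = [dy.perceive_features(f) for f in frames]
    occ = dy.occupancy_profile(models)
    assert all(p == 100.0 for p in occ.percents.values())
    assert occ.minor == set()


def test_occupancy_rare_feature_is_minor():
    base = _simple_model([[0, 0, 0], [5, 0, 0]], ["HBD", "HBA"])
    rare = _simple_model([[0, 0, 0], [5, 0, 0], [2, 2, 0]], ["HBD", "HBA", "H"])
    models = [rare] + [base] * 9999
    occ = dy.occupancy_profile(models)
    assert occ.percents[("H", (2,))] == pytest.approx(0.01)
    assert ("H", (2,)) in occ.minor


def test_occupancy_binomial_recovery():
    rng = np.random.default_rng(5)
    base = _simple_model([[0, 0, 0], [5, 0, 0]], ["HBD", "HBA"])
    extra = _simple_model([[0, 0, 0], [5, 0, 0], [2, 2, 0]], ["HBD", "HBA", "H"])
    n = 10_000
    draws = rng.random(n) < 0.5
    models = [extra if d else base for d in draws]
    occ = dy.occupancy_profile(models)
    sigma = 100 * np.sqrt(0.25 / n)
    assert occ.percents[("H", (2,))] == pytest.approx(50.0, abs=3 * sigma)


def test_occupancy_order_independent(pocket_bundle):
    frames, _ = sd.gen_trajectory(pocket_bundle, n_frames=50, toggles={"hbd": 0.5}, seed=1)
    models = [dy.perceive_features(f) for f in frames]
    occ1 = dy.occupancy_profile(models)
    rng = np.random.default_rng(0)
    shuffled = list(models)
    rng.shuffle(shuffled)
    occ2 = dy.occupancy_profile(shuffled)
    assert occ1.percents == occ2.percents


def test_occupancy_strictly_positive(pocket_bundle):
    frames, _ = sd.gen_trajectory(pocket_bundle, n_frames=30, toggles={"hbd": 0.3}, seed=2)
    models = [dy.perceive_features(f) for f in frames]
    occ = dy.occupancy_profile(models)
    assert all(p > 0 for p in occ.percents.values())


# ---------------------------------------------------------------------------
# EVS stats
# ---------------------------------------------------------------------------


def test_evs_constant():
    m = _simple_model([[0, 0, 0], [5, 0, 0]], ["HBD", "HBA"])
    m.exclusion_volumes = [
        __import__("sbpharm.chem_core", fromlist=["ExclusionVolume"]).ExclusionVolume([9, 9, 9], 1.0)
    ] * 17
    mean, counts = dy.evs_stats([m] * 5)
    assert mean == 17.0 and counts == [17] * 5


def test_evs_alternating():
    from sbpharm.chem_core import ExclusionVolume

    a = _simple_model([[0, 0, 0], [5, 0, 0]], ["HBD", "HBA"])
    b = _simple_model([[0, 0, 0], [5, 0, 0]], ["HBD", "HBA"])
    a.exclusion_volumes = [ExclusionVolume([9, 9, 9], 1.0)] * 10
    b.exclusion_volumes = [ExclusionVolume([9, 9, 9], 1.0)] * 20
    mean, _ = dy.evs_stats([a, b, a, b])
    assert mean == 15.0


def test_evs_empty():
    m = _simple_model([[0, 0, 0], [5, 0, 0]], ["HBD", "HBA"])
    mean, _ = dy.evs_stats([m, m])
    assert mean == 0.0


# ---------------------------------------------------------------------------
# RDF codes
# ---------------------------------------------------------------------------


def test_rdf_rigid_motion_invariance(rng):
    positions = rng.normal(scale=4.0, size=(5, 3))
    kinds = ["H", "HBD", "HBA", "H", "AR"]
    m1 = _simple_model(positions, kinds)
    R = sd.random_rotation(rng)
    t = rng.normal(size=3) * 10
    m2 = _simple_model(positions @ R.T + t, kinds)
    np.testing.assert_allclose(dy.rdf_code(m1), dy.rdf_code(m2), atol=1e-9)


def test_rdf_feature_order_invariance(rng):
    positions = rng.normal(scale=4.0, size=(4, 3))
    kinds = ["H", "HBD", "HBA", "AR"]
    m1 = _simple_model(positions, kinds)
    order = [2, 0, 3, 1]
    m2 = _simple_model(positions[order], [kinds[i] for i in order])
    np.testing.assert_allclose(dy.rdf_code(m1), dy.rdf_code(m2), atol=1e-9)


def test_rdf_peak_location():
    m = _simple_model([[0, 0, 0], [5, 0, 0]], ["HBD", "HBA"])
    code = dy.rdf_code(m)
    nz_blocks = code.reshape(len(dy._KIND_PAIRS), dy._N_BINS)
    mass = np.linalg.norm(nz_blocks, axis=1)
    assert np.count_nonzero(mass) == 1
    block = nz_blocks[int(np.argmax(mass))]
    # peak at the bin whose centre is nearest 5.0 A
    assert abs(dy._BIN_CENTERS[int(np.argmax(block))] - 5.0) <= dy.RDF_BIN_WIDTH / 2


def test_rdf_scaling_changes_code():
    m1 = _simple_model([[0, 0, 0], [5, 0, 0]], ["HBD", "HBA"])
    m2 = _simple_model([[0, 0, 0], [10, 0, 0]], ["HBD", "HBA"])
    assert not np.allclose(dy.rdf_code(m1), dy.rdf_code(m2))


def test_rdf_single_feature_zero_vector():
    m = PharmacophoreModel(name="one", features=[PharmacophoreFeature("H", [0, 0, 0], 1.5, (0,))])
    with pytest.warns(UserWarning):
        code = dy.rdf_code(m)
    assert not code.any()


# ---------------------------------------------------------------------------
# model clustering
# ---------------------------------------------------------------------------


def test_identical_models_one_cluster():
    m = _simple_model([[0, 0, 0], [5, 0, 0], [2, 3, 0]], ["HBD", "HBA", "H"])
    clustering = dy.cluster_models([m] * 6)
    assert len(clustering.clusters) == 1
    assert clustering.rpm_indices == [0]  # lowest index tie rule


def test_two_planted_families(rng):
    fam_a = _simple_model([[0, 0, 0], [5, 0, 0], [2, 3, 0]], ["HBD", "HBA", "H"])
    fam_b = _simple_model([[0, 0, 0], [11, 0, 0], [2, 9, 0]], ["HBD", "HBA", "H"])
    models, labels = [], []
    for i in range(10):
        src = fam_a if i % 2 == 0 else fam_b
        R = sd.random_rotation(rng)
        moved = _simple_model(
            np.array([f.position for f in src.features]) @ R.T + rng.normal(size=3),
            [f.kind for f in src.features],
        )
        models.append(moved)
        labels.append(i % 2)
    clustering = dy.cluster_models(models)
    assert len(clustering.clusters) == 2
    for cluster in clustering.clusters:
        assert len({labels[i] for i in cluster}) == 1


def test_top_clamp():
    m = _simple_model([[0, 0, 0], [5, 0, 0]], ["HBD", "HBA"])
    models = []
    for k in range(7):  # 7 well-separated geometries
        models.append(_simple_model([[0, 0, 0], [3.0 + 2 * k, 0, 0]], ["HBD", "HBA"]))
    clustering = dy.cluster_models(models, top=10)
    assert len(clustering.clusters) <= 7


@settings(max_examples=20, deadline=None)
@given(st.integers(2, 8), st.integers(0, 2**31 - 1))
def test_rpm_is_medoid_brute_force(n, seed):
    rng = np.random.default_rng(seed)
    models = [
        _simple_model(rng.normal(scale=3, size=(3, 3)), ["HBD", "HBA", "H"]) for _ in range(n)
    ]
    clustering = dy.cluster_models(models, similarity_cutoff=-1.0)  # everything in one cluster
    assert len(clustering.clusters) == 1
    members = clustering.clusters[0]
    dmat = clustering.distance_matrix
    means = [np.mean([dmat[i, j] for j in members if j != i]) for i in members]
    best = min(range(len(members)), key=lambda k: (means[k], members[k]))
    assert clustering.rpm_indices[0] == members[best]


def test_deduplicate_by_signatures():
    a = _simple_model([[0, 0, 0], [5, 0, 0]], ["HBD", "HBA"])
    b = _simple_model([[1, 0, 0], [7, 0, 0]], ["HBD", "HBA"])  # same signatures
    c = _simple_model([[0, 0, 0], [5, 0, 0], [2, 2, 2]], ["HBD", "HBA", "H"])
    out = dy.deduplicate_by_signatures([a, b, c])
    assert out == [a, c]


# ---------------------------------------------------------------------------
# end-to-end occupancy recovery
# ---------------------------------------------------------------------------


def test_end_to_end_toggle_recovery(pocket_bundle):
    toggles = {"hbd": 0.9, "hba1": 0.6, "hydrophobics": 0.75}
    n = 2000
    frames, _ = sd.gen_trajectory(pocket_bundle, n_frames=n, toggles=toggles, seed=21)
    models = [dy.perceive_features(f) for f in frames]
    occ = dy.occupancy_profile(models, major_threshold=70.0)
    for unit, p in toggles.items():
        sigma = 100 * np.sqrt(p * (1 - p) / n)
        for kind, atoms in pocket_bundle.truth["signatures_of_toggle"][unit]:
            assert occ.percents[(kind, tuple(atoms))] == pytest.approx(100 * p, abs=3 * sigma)
    # dominant set: untouched signatures at 100%, toggled ones classified by p
    majors = occ.major
    for kind, atoms in pocket_bundle.truth["signatures_of_toggle"]["hba1"]:
        assert (kind, tuple(atoms)) not in majors  # 60% < 70% threshold
    for kind, atoms in pocket_bundle.truth["signatures_of_toggle"]["hbd"]:
        assert (kind, tuple(atoms)) in majors
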