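import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from allostate.errors import DegenerateGeometryError, MissingAtomError
from allostate.geometry import (
    align_reference_to_x,
    dihedral,
    distance_series,
    helix_angle,
    helix_angles,
    rotation_about_axis,
    superpose,
)
from allostate.structure_io import AtomRef


@pytest.fixture()
def cloud(rng):
    return rng.normal(size=(40, 3)) * 5.0


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def test_identical_sets_give_identity(cloud):
    sup = superpose(cloud, cloud)
    np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-12)
    np.testing.assert_allclose(sup.translation, 0.0, atol=1e-12)
    assert sup.rmsd == pytest.approx(0.0, abs=1e-12)


def test_recovers_planted_rotation(cloud, rng):
    # independent construction via scipy Rotation
    axis = rng.normal(size=3)
    R_true = Rotation.from_rotvec(np.deg2rad(12.0) * axis / np.linalg.norm(axis)).as_matrix()
    t_true = np.array([1.0, -2.0, 3.0])
    moved = cloud @ R_true.T + t_true
    sup = superpose(moved, cloud)
    np.testing.assert_allclose(sup.rotation @ R_true, np.eye(3), atol=1e-6)
    assert sup.rmsd == pytest.approx(0.0, abs=1e-8)
    np.testing.assert_allclose(sup.apply(moved), cloud, atol=1e-8)


def test_reflected_set_still_proper_rotation(cloud):
    mirrored = cloud * np.array([1.0, 1.0, -1.0])
    sup = superpose(mirrored, cloud)
    assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)
    assert sup.rmsd > 0.1


def test_rmsd_invariant_under_rigid_pretransform(cloud, rng):
    target = cloud + rng.normal(size=cloud.shape) * 0.5
    base = superpose(cloud, target).rmsd
    for _ in range(5):
        R = Rotation.random(random_state=rng.integers(1 << 31)).as_matrix()
        t = rng.normal(size=3) * 20
        assert superpose(cloud @ R.T + t, target).rmsd == pytest.approx(base, abs=1e-9)


def test_degenerate_inputs_rejected(cloud):
    with pytest.raises(DegenerateGeometryError):
        superpose(cloud[:2], cloud[:2])
    line = np.outer(np.arange(10.0), [1.0, 2.0, 3.0])
    with pytest.raises(DegenerateGeometryError, match="collinear"):
        superpose(line, line)


def test_weighted_superpose_prefers_heavy_points(rng):
    base = rng.normal(size=(20, 3)) * 4
    target = base.copy()
    target[0] += [5.0, 0, 0]  # one outlier
    w = np.ones(20)
    w[0] = 1e-9
    sup = superpose(base, target, weights=w)
    np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-4)


# ---------------------------------------------------------------------------
# reference X-alignment and the helix angle
# ---------------------------------------------------------------------------

def test_reference_already_aligned_is_identity(ref_ensemble):
    ref = align_reference_to_x(ref_ensemble, "A")
    p0 = ref.coordinates(AtomRef("A", 167, "CA"), 0)
    v = ref.coordinates(AtomRef("A", 181, "CA"), 0) - p0
    np.testing.assert_allclose(p0, 0.0, atol=1e-9)
    np.testing.assert_allclose(v / np.linalg.norm(v), [1, 0, 0], atol=1e-9)


def test_z_helix_maps_to_x(ref_ensemble):
    rot = rotation_about_axis([0.0, 1.0, 0.0], -90.0)  # +X -> +Z
    tilted = ref_ensemble.transformed(rot, np.zeros(3))
    tilted.residue_maps = dict(ref_ensemble.residue_maps)
    p0 = tilted.coordinates(AtomRef("A", 167, "CA"), 0)
    v = tilted.coordinates(AtomRef("A", 181, "CA"), 0) - p0
    np.testing.assert_allclose(v / np.linalg.norm(v), [0, 0, 1], atol=1e-9)
    ref = align_reference_to_x(tilted, "A")
    v2 = ref.coordinates(AtomRef("A", 181, "CA"), 0) - ref.coordinates(
        AtomRef("A", 167, "CA"), 0
    )
    np.testing.assert_allclose(v2 / np.linalg.norm(v2), [1, 0, 0], atol=1e-9)


def test_angle_zero_on_reference(ref_ensemble):
    ref = align_reference_to_x(ref_ensemble, "A")
    assert helix_angle(ref, 0, "A", ref) == pytest.approx(0.0, abs=1e-9)


def test_planted_in_plane_rotation_recovered(ref_ensemble):
    ref = align_reference_to_x(ref_ensemble, "A")
    from allostate.synthetic_data import EnsembleSpec, make_ensemble

    spec = EnsembleSpec(
        seed=2, n_frames=1,
        fractions={"R_like": 1.0, "T_like": 0.0, "intermediate": 0.0},
        r_theta=(15.0, 0.0), r_distance_modes=((15.0, 0.0, 1.0),),
        mirror_noise_sd=0.0, loop_sd=0.0, chi_sd=0.0,
    )
    frame, truth = make_ensemble(spec)
    theta = helix_angle(frame, 0, "A", ref, fit="non_helix")
    assert theta == pytest.approx(15.0, abs=1e-6)


def test_out_of_plane_rotation_leaves_angle_zero(ref_ensemble):
    ref = align_reference_to_x(ref_ensemble, "A")
    # rotate the whole reference about X: helix stays on +X, angle stays 0
    rot = rotation_about_axis([1.0, 0.0, 0.0], 25.0)
    moved = ref.transformed(rot, np.zeros(3))
    moved.residue_maps = dict(ref.residue_maps)
    assert helix_angle(moved, 0, "A", ref) == pytest.approx(0.0, abs=1e-9)
    # and without any fit the projection alone still reads 0
    assert helix_angle(moved, 0, "A", ref, fit=None) == pytest.approx(0.0, abs=1e-9)


def test_angle_invariant_to_global_rigid_motion(ref_ensemble, rng):
    ref = align_reference_to_x(ref_ensemble, "A")
    from allostate.synthetic_data import EnsembleSpec, make_ensemble

    spec = EnsembleSpec(
        seed=3, n_frames=1,
        fractions={"R_like": 1.0, "T_like": 0.0, "intermediate": 0.0},
        r_theta=(9.0, 0.0), r_distance_modes=((15.0, 0.0, 1.0),),
        mirror_noise_sd=0.0, loop_sd=0.0, chi_sd=0.0,
    )
    frame, _ = make_ensemble(spec)
    base = helix_angle(frame, 0, "A", ref, fit="non_helix")
    R = Rotation.random(random_state=7).as_matrix()
    moved = frame.transformed(R, rng.normal(size=3) * 30)
    moved.residue_maps = dict(frame.residue_maps)
    assert helix_angle(moved, 0, "A", ref, fit="non_helix") == pytest.approx(
        base, abs=1e-8
    )


def test_angle_series_matches_truth(ensemble_and_truth, ref_ensemble):
    ens, truth = ensemble_and_truth
    ref = align_reference_to_x(ref_ensemble, "A")
    theta = helix_angles(ens, "A", ref, fit="non_helix")
    np.testing.assert_allclose(
        theta, truth["chains"]["A"]["theta_deg"], atol=1e-9
    )


def test_missing_endpoint_atom(ref_ensemble):
    from allostate.structure_io import ConformerEnsemble, attach_identity_numbering

    keep = ~(
        (ref_ensemble.atoms["chain"] == "A")
        & (ref_ensemble.atoms["resid"] == 181)
        & (ref_ensemble.atoms["atom"] == "CA")
    )
    crippled = ConformerEnsemble(
        atoms=ref_ensemble.atoms[keep].reset_index(drop=True),
        coords=ref_ensemble.coords[:, keep.to_numpy(), :],
    )
    attach_identity_numbering(crippled)
    from allostate.errors import AbsentPositionError

    # the endpoint residue vanished entirely, so either the atom-level or the
    # position-level resolution error is the correct refusal
    with pytest.raises((MissingAtomError, AbsentPositionError)):
        align_reference_to_x(crippled, "A")


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def test_three_four_five():
    import pandas as pd

    from allostate.structure_io import ConformerEnsemble, attach_identity_numbering

    atoms = pd.DataFrame(
        [("A", 1, "ALA", "CA"), ("A", 2, "ALA", "CA"), ("A", 3, "ALA", "CA")],
        columns=["chain", "resid", "resname", "atom"],
    )
    coords = np.array([[[0.0, 0, 0], [3.0, 4.0, 0], [1.0, 0, 0]]])
    ens = attach_identity_numbering(ConformerEnsemble(atoms=atoms, coords=coords))
    series = distance_series(ens, AtomRef("A", 1, "CA"), AtomRef("A", 2, "CA"))
    assert series.values[0] == pytest.approx(5.0)


def test_distance_symmetry_and_rigid_invariance(ensemble_and_truth, rng):
    ens, _ = ensemble_and_truth
    a, b = AtomRef("A", 171, "CG"), AtomRef("B", 68, "CG")
    ab = distance_series(ens, a, b).values
    ba = distance_series(ens, b, a).values
    np.testing.assert_allclose(ab, ba)
    R = Rotation.random(random_state=11).as_matrix()
    moved = ens.transformed(R, rng.normal(size=3) * 15)
    moved.residue_maps = dict(ens.residue_maps)
    np.testing.assert_allclose(distance_series(moved, a, b).values, ab, atol=1e-9)


def test_unresolvable_pair_names_context(ensemble_and_truth):
    ens, _ = ensemble_and_truth
    with pytest.raises(MissingAtomError, match="frame 0"):
        distance_series(ens, AtomRef("A", 141, "CG"), AtomRef("A", 167, "CA"))


def test_mirror_anticorrelation(ensemble_and_truth):
    ens, _ = ensemble_and_truth
    d_p141 = distance_series(ens, AtomRef("A", 171, "CG"), AtomRef("A", 141, "CA")).values
    d_n181 = distance_series(ens, AtomRef("A", 171, "CG"), AtomRef("A", 181, "CA")).values
    assert np.corrcoef(d_p141, d_n181)[0, 1] < 0


# ---------------------------------------------------------------------------
# dihedrals
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("angle", [-150.0, -60.0, 0.0, 60.0, 175.0])
def test_dihedral_against_construction(angle):
    # butane-like frame: rotate the fourth atom about the central bond
    p0 = np.array([1.0, 1.0, 0.0])
    p1 = np.array([0.0, 0.0, 0.0])
    p2 = np.array([0.0, 0.0, 1.5])
    base = np.array([1.0, 1.0, 1.5])  # torsion 0 by construction
    R = rotation_about_axis([0.0, 0.0, 1.0], angle)
    p3 = p2 + R @ (base - p2)
    assert dihedral(p0, p1, p2, p3) == pytest.approx(angle, abs=1e-9)


def test_dihedral_degenerate_bond():
    with pytest.raises(DegenerateGeometryError):
        dihedral([1, 0, 0], [0, 0, 0], [0, 0, 0], [0, 1, 0])
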