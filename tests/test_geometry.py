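"""Rigid fitting, rotation angles, inter-PF angle tables and axial offsets."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from axonarray.geometry import (
    LatticeModel,
    PointSet,
    RigidTransform,
    axial_offset,
    domain_rotation_between_states,
    fit_rigid,
    inter_pf_angle_table,
    principal_axis,
    rotation_angle_between,
)
from axonarray.synthetic import SyntheticLatticeConfig, make_lattice


def _cloud(seed, n=30, spread=10.0):
    return np.random.default_rng(seed).normal(scale=spread, size=(n, 3))


def test_fit_rigid_identity():
    ps = PointSet("a", _cloud(0))
    t = fit_rigid(ps, ps)
    np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-9)
    np.testing.assert_allclose(t.translation, 0, atol=1e-9)


def test_fit_rigid_recovers_known_motion():
    coords = _cloud(1)
    R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
    t_true = np.array([5.0, -3.0, 12.0])
    moved = coords @ R.T + t_true
    fit = fit_rigid(PointSet("m", coords), PointSet("f", moved))
    np.testing.assert_allclose(fit.rotation, R, atol=1e-6)
    np.testing.assert_allclose(fit.translation, t_true, atol=1e-6)
    np.testing.assert_allclose(fit.apply(coords), moved, atol=1e-6)


def test_fit_rigid_matches_hand_kabsch_oracle():
    """Independent SVD superposition oracle on random rigid pairs."""
    rng = np.random.default_rng(4)
    for _ in range(10):
        a = rng.normal(size=(12, 3))
        b = rng.normal(size=(12, 3))
        fit = fit_rigid(PointSet("a", a), PointSet("b", b))
        ac = a - a.mean(0)
        bc = b - b.mean(0)
        u, _, vt = np.linalg.svd(ac.T @ bc)
        d = np.sign(np.linalg.det(vt.T @ u.T))
        R = vt.T @ np.diag([1, 1, d]) @ u.T
        np.testing.assert_allclose(fit.rotation, R, atol=1e-8)


def test_fit_rigid_reduces_rmsd_and_never_reflects():
    rng = np.random.default_rng(2)
    a = _cloud(3)
    b = a + rng.normal(scale=0.5, size=a.shape)
    fit = fit_rigid(PointSet("a", a), PointSet("b", b))
    pre = np.sqrt(((a - b) ** 2).sum(1).mean())
    post = np.sqrt(((fit.apply(a) - b) ** 2).sum(1).mean())
    assert post <= pre + 1e-12
    assert np.linalg.det(fit.rotation) > 0


def test_fit_rigid_rejects_collinear_points():
    line = np.outer(np.arange(5.0), [1.0, 2.0, 0.5])
    with pytest.raises(ValueError):
        fit_rigid(PointSet("l", line), PointSet("l2", line + 1))


def test_rigid_transform_rejects_improper_matrices():
    with pytest.raises(ValueError):
        RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))
    with pytest.raises(ValueError):
        RigidTransform(np.full((3, 3), 0.5), np.zeros(3))


def test_rotation_angle_between_cases():
    t = RigidTransform.identity()
    assert rotation_angle_between(t, t) == pytest.approx(0.0)
    r30 = RigidTransform(Rotation.from_euler("x", 30, degrees=True).as_matrix(), np.zeros(3))
    assert rotation_angle_between(t, r30) == pytest.approx(30.0, abs=1e-9)
    rng = np.random.default_rng(5)
    for _ in range(10):
        a = RigidTransform(Rotation.random(rng=rng).as_matrix(), rng.normal(size=3))
        b = RigidTransform(Rotation.random(rng=rng).as_matrix(), rng.normal(size=3))
        assert rotation_angle_between(a, b) == pytest.approx(
            rotation_angle_between(b, a), abs=1e-9
        )
        # invariance under a common global rotation
        g = Rotation.random(rng=rng).as_matrix()
        ga = RigidTransform(g @ a.rotation, a.translation)
        gb = RigidTransform(g @ b.rotation, b.translation)
        assert rotation_angle_between(ga, gb) == pytest.approx(
            rotation_angle_between(a, b), abs=1e-8
        )


def test_interpf_angles_recovered_noise_free():
    lattice, truth = make_lattice(
        SyntheticLatticeConfig(inter_pf_angles_deg=(30.0, 25.0, 35.0))
    )
    summary = inter_pf_angle_table(lattice).summary()
    np.testing.assert_allclose(
        summary["mean"].to_numpy(), truth["angle_deg"].to_numpy(), atol=1e-6
    )
    np.testing.assert_allclose(summary["sd"].to_numpy(), 0.0, atol=1e-6)


def test_closed_tube_angles_sum_to_360():
    cfg = SyntheticLatticeConfig(
        n_protofilaments=13,
        inter_pf_angles_deg=tuple([360.0 / 13] * 13),
        closed=True,
    )
    lattice, _ = make_lattice(cfg)
    summary = inter_pf_angle_table(lattice).summary()
    np.testing.assert_allclose(summary["mean"].to_numpy(), 360.0 / 13, atol=1e-6)
    assert summary["mean"].sum() == pytest.approx(360.0, abs=1e-6)


def test_interpf_angles_with_noise():
    lattice, truth = make_lattice(
        SyntheticLatticeConfig(coordinate_noise_sd_A=0.3, seed=17)
    )
    summary = inter_pf_angle_table(lattice).summary()
    err = np.abs(summary["mean"].to_numpy() - truth["angle_deg"].to_numpy())
    assert err.max() < 0.5


def test_interpf_missing_dimer_is_named():
    lattice, _ = make_lattice(SyntheticLatticeConfig())
    del lattice.dimers[(1, 0)]
    with pytest.raises(ValueError, match=r"\(1, 0\)"):
        inter_pf_angle_table(lattice, regions=[[0], [2], [5]])


def test_recovery_error_grows_with_noise():
    """Median recovered-angle error is monotone in the coordinate noise."""
    med = []
    for noise in (0.1, 1.0, 4.0):
        errs = []
        for seed in range(8):
            lattice, truth = make_lattice(
                SyntheticLatticeConfig(coordinate_noise_sd_A=noise, seed=seed)
            )
            s = inter_pf_angle_table(lattice).summary()
            errs.append(
                np.abs(s["mean"].to_numpy() - truth["angle_deg"].to_numpy()).mean()
            )
        med.append(np.median(errs))
    assert med[0] < med[1] < med[2]


def _two_state_pair(angle_deg, seed=0):
    """Two states sharing an align domain; the measure domain rotates."""
    rng = np.random.default_rng(seed)
    align = rng.normal(scale=20.0, size=(40, 3))
    measure = rng.normal(scale=8.0, size=(25, 3)) + np.array([30.0, 0, 0])
    R = Rotation.from_euler("y", angle_deg, degrees=True).as_matrix()
    pivot = measure.mean(0)
    measure2 = (measure - pivot) @ R.T + pivot
    state1 = {"pf": PointSet("pf", align), "stalk": PointSet("stalk", measure)}
    # bury state 2 in an arbitrary global motion
    G = Rotation.from_euler("xyz", [11, -7, 23], degrees=True).as_matrix()
    shift = np.array([100.0, -50.0, 8.0])
    state2 = {
        "pf": PointSet("pf", align @ G.T + shift),
        "stalk": PointSet("stalk", measure2 @ G.T + shift),
    }
    return state1, state2


def test_domain_rotation_zero_for_identical_states():
    s1, _ = _two_state_pair(18.0)
    assert domain_rotation_between_states(s1, s1, ["pf"], ["stalk"]) == pytest.approx(
        0.0, abs=1e-9
    )


def test_domain_rotation_recovers_planted_18_degrees():
    """The stalk reorientation between binding states, on synthetic models."""
    s1, s2 = _two_state_pair(18.0, seed=3)
    got = domain_rotation_between_states(s1, s2, ["pf"], ["stalk"])
    assert got == pytest.approx(18.0, abs=1e-6)


def test_domain_rotation_requires_selections():
    s1, s2 = _two_state_pair(5.0)
    with pytest.raises(ValueError):
        domain_rotation_between_states(s1, s2, [], ["stalk"])
    with pytest.raises(ValueError):
        domain_rotation_between_states(s1, s2, ["pf"], ["missing"])


def test_axial_offset_along_one_protofilament_is_the_rise():
    lattice, _ = make_lattice(SyntheticLatticeConfig(axial_rise_nm=8.0))
    axis = principal_axis(lattice)
    a = lattice.dimers[(0, 2)]
    b = lattice.dimers[(0, 3)]
    assert axial_offset(a, b, axis) == pytest.approx(8.0, abs=1e-9)
    assert axial_offset(a, a, axis) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        axial_offset(a, b, np.zeros(3))


def test_lattice_file_round_trip_preserves_angles(tmp_path):
    from axonarray.io import read_lattice, write_lattice

    lattice, truth = make_lattice(SyntheticLatticeConfig(n_points_per_dimer=20))
    for name in ("lat.pdb", "lat.cif"):
        path = tmp_path / name
        write_lattice(path, lattice)
        back = read_lattice(path)
        summary = inter_pf_angle_table(back).summary()
        np.testing.assert_allclose(
            summary["mean"].to_numpy(), truth["angle_deg"].to_numpy(), atol=1e-3
        )
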