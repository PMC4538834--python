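"""Superposition, axis rotation angles and center-of-mass shifts."""

import numpy as np
import pytest

from bridgenet.geometry import (apply_transform, com_shift, rotation_angle,
                                rotation_series, superpose)
from bridgenet.model_io import RotationAxis

from conftest import load_run


def _rot(axis, deg):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(deg)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)


@pytest.fixture
def cloud():
    rng = np.random.default_rng(17)
    return rng.uniform(-10, 10, (40, 3))


def test_identity_superposition(cloud):
    rot, trans, rmsd = superpose(cloud, cloud)
    np.testing.assert_allclose(rot, np.eye(3), atol=1e-12)
    assert rmsd == pytest.approx(0.0, abs=1e-12)


def test_recovers_known_rotation(cloud):
    r_true = _rot([1, 2, 3], 37.0)
    moved = cloud @ r_true.T + np.array([1.0, -2.0, 0.5])
    rot, trans, rmsd = superpose(moved, cloud)
    np.testing.assert_allclose(rot @ r_true, np.eye(3), atol=1e-9)
    assert rmsd < 1e-9


def test_reflection_input_keeps_proper_rotation(cloud):
    mirrored = cloud * np.array([-1.0, 1.0, 1.0])
    rot, trans, rmsd = superpose(mirrored, cloud)
    assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)
    assert rmsd > 0.1


def test_collinear_fit_set_is_error():
    line = np.outer(np.arange(5, dtype=float), [1.0, 0.0, 0.0])
    with pytest.raises(ValueError, match="collinear|degenerate"):
        superpose(line, line + 1.0)


def test_superposition_idempotence(cloud):
    r_true = _rot([0, 1, 1], 22.0)
    moved = cloud @ r_true.T + 5.0
    rot, trans, rmsd1 = superpose(moved, cloud)
    once = apply_transform(moved, rot, trans)
    rot2, trans2, rmsd2 = superpose(once, cloud)
    assert abs(rmsd2 - rmsd1) < 1e-12


def _axis_system(rng, n_fit=80, n_mobile=80):
    fit = rng.uniform(-20, 20, (n_fit, 3)) + np.array([0, 0, -15.0])
    ang = rng.uniform(0, 2 * np.pi, n_mobile)
    rad = rng.uniform(10, 25, n_mobile)
    mobile = np.column_stack([rad * np.cos(ang), rad * np.sin(ang),
                              rng.uniform(5, 15, n_mobile)])
    axis = RotationAxis(name="z", origin=np.zeros(3), direction=np.array([0.0, 0.0, 1.0]),
                        fit_group="fit", mobile_group="mobile")
    return fit, mobile, axis


def test_angle_zero_for_identical_frame():
    rng = np.random.default_rng(0)
    fit, mobile, axis = _axis_system(rng)
    ref = np.vstack([fit, mobile])
    got = rotation_angle(ref, ref, axis, np.arange(len(fit)),
                         np.arange(len(fit), len(ref)))
    assert got == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("theta", [-15.0, -5.0, 0.0, 7.5, 12.5, 20.0])
def test_planted_rotation_recovered_noise_free(theta):
    rng = np.random.default_rng(1)
    fit, mobile, axis = _axis_system(rng)
    ref = np.vstack([fit, mobile])
    frame = np.vstack([fit, mobile @ _rot([0, 0, 1], theta).T])
    got = rotation_angle(frame, ref, axis, np.arange(len(fit)),
                         np.arange(len(fit), len(ref)))
    assert got == pytest.approx(theta, abs=1e-6)


def test_rotation_composition_cancels():
    rng = np.random.default_rng(2)
    fit, mobile, axis = _axis_system(rng)
    ref = np.vstack([fit, mobile])
    r = _rot([0, 0, 1], 9.0)
    back = mobile @ r.T @ r  # +θ then −θ
    frame = np.vstack([fit, back])
    got = rotation_angle(frame, ref, axis, np.arange(len(fit)),
                         np.arange(len(fit), len(ref)))
    assert got == pytest.approx(0.0, abs=1e-6)


def test_mobile_atoms_on_axis_is_error():
    rng = np.random.default_rng(3)
    fit, _, axis = _axis_system(rng)
    on_axis = np.column_stack([np.zeros(5), np.zeros(5), np.linspace(5, 9, 5)])
    ref = np.vstack([fit, on_axis])
    with pytest.raises(ValueError, match="axis"):
        rotation_angle(ref, ref, axis, np.arange(len(fit)),
                       np.arange(len(fit), len(ref)))


def test_sweep_recovery_with_and_without_jitter():
    """−15°..+20° sweep: exact noise-free; within 0.2° at 0.3 Å jitter."""
    rng = np.random.default_rng(4)
    fit, mobile, axis = _axis_system(rng, n_fit=120, n_mobile=120)
    ref = np.vstack([fit, mobile])
    fit_idx = np.arange(len(fit))
    mob_idx = np.arange(len(fit), len(ref))
    for theta in np.arange(-15.0, 21.0, 1.0):
        frame = np.vstack([fit, mobile @ _rot([0, 0, 1], theta).T])
        got = rotation_angle(frame, ref, axis, fit_idx, mob_idx)
        assert abs(got - theta) < 0.01
        # recovery from 10 jittered frames (thermal noise averages out)
        est = np.mean([
            rotation_angle(frame + rng.normal(scale=0.3, size=frame.shape),
                           ref, axis, fit_idx, mob_idx)
            for _ in range(10)
        ])
        assert abs(est - theta) < 0.2


def test_generator_angles_recovered(clusterable_run):
    spec, files, gt = clusterable_run
    top, groups, axes, ens = load_run(files)
    series = rotation_series(ens, axes["body_rotation"], groups,
                             reference=top.positions)
    for state, planted in gt.rotation_angles.items():
        assert np.mean(series.angles[state]) == pytest.approx(planted, abs=0.2)
    summ = series.summary()
    assert (summ["q1"] <= summ["median"]).all() and (summ["median"] <= summ["q3"]).all()


def test_com_shift_planted_translation(tmp_path):
    """A cluster side translated 10 Å between states reads back as 10 Å."""
    from bridgenet import synthetic
    shift = (6.0, 0.0, 8.0)  # |shift| = 10
    cluster = synthetic.PlantedCluster(
        name="shifty", residues_A=["GLY"], residues_B=["GLY", "GLY"],
        contacts={0: [(0, 0, 0.9)], 1: [(0, 0, 0.9)]},
        b_shift={1: shift},
    )
    spec = synthetic.SyntheticSpec(seed=8, n_states=2, frames_per_state=150,
                                   rotation_angles=[0.0, 0.0], clusters=[cluster])
    files, gt = synthetic.generate(spec, tmp_path)
    top, groups, axes, ens = load_run(files)
    b_res = [k for k, cid in gt.memberships.items() if k[0] == "B"]
    d = com_shift(ens, b_res, "state00", "state01", groups["bodyA_core"],
                  reference=top.positions)
    assert d == pytest.approx(10.0, abs=0.15)
    # same state twice -> 0
    assert com_shift(ens, b_res, "state00", "state00", groups["bodyA_core"],
                     reference=top.positions) == 0.0


def test_com_shift_invariant_to_global_rigid_motion():
    from bridgenet.model_io import StateEnsemble
    from conftest import make_groups, make_topology
    rng = np.random.default_rng(6)
    beads = [{"chain": "A", "resid": i + 1, "resname": "COR",
              "pos": tuple(rng.uniform(-10, 10, 3))} for i in range(6)]
    beads += [{"chain": "B", "resid": 1, "resname": "GLY", "pos": (5.0, 0, 0)}]
    top, frame = make_topology(beads)
    groups = make_groups(top, {"A": "subunit_A", "B": "subunit_B"})
    f2 = frame.copy()
    f2[-1] += np.array([0, 0, 4.0])
    ens1 = StateEnsemble(topology=top, states=["s1", "s2"],
                         trajectories={"s1": np.stack([frame] * 2), "s2": np.stack([f2] * 2)})
    r = _rot([1, 1, 0], 30.0)
    g1, g2 = frame @ r.T + 3.0, f2 @ r.T + 3.0
    ens2 = StateEnsemble(topology=top, states=["s1", "s2"],
                         trajectories={"s1": np.stack([g1] * 2), "s2": np.stack([g2] * 2)})
    sel = [("B", 1, "GLY")]
    d1 = com_shift(ens1, sel, "s1", "s2", groups["A"])
    d2 = com_shift(ens2, sel, "s1", "s2", groups["A"])
    assert d1 == pytest.approx(4.0, abs=1e-9)
    assert d2 == pytest.approx(d1, abs=1e-9)
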