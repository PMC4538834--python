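"""Nonbonded energies: oracle equivalence, decomposition, entropy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bridgenet.energetics import (COULOMB_CONSTANT, ChargePairDecomposition,
                                  ExponentialHBond, charge_pair_coulomb,
                                  cluster_enthalpies, group_pair_enthalpies,
                                  hbond_energy, ligand_bridging, pair_enthalpy,
                                  schlitter_entropy)
from bridgenet.clustering import Cluster, ClusterSet
from bridgenet.model_io import GroupDefinition, StateEnsemble

from conftest import brute_force_enthalpy, load_run, make_groups, make_topology

_KB = 1.380649e-23
_NA = 6.02214076e23
_HBAR = 1.054571817e-34
_AMU = 1.66053906660e-27


def test_two_unit_charges_at_one_nm():
    top, frame = make_topology([
        {"chain": "A", "resid": 1, "resname": "R", "pos": (0, 0, 0), "charge": 1.0},
        {"chain": "B", "resid": 1, "resname": "R", "pos": (0, 0, 10.0), "charge": 1.0},
    ])
    e = pair_enthalpy(frame, top, [("A", 1, "R")], [("B", 1, "R")])
    assert e == pytest.approx(138.935458, abs=1e-4)
    assert round(e, 3) == 138.935


def test_neutral_zero_epsilon_system_is_exactly_zero():
    top, frame = make_topology([
        {"chain": "A", "resid": 1, "resname": "R", "pos": (0, 0, 0)},
        {"chain": "B", "resid": 1, "resname": "R", "pos": (1, 2, 3)},
    ])
    assert pair_enthalpy(frame, top, [("A", 1, "R")], [("B", 1, "R")]) == 0.0


def _random_system(rng, n=30):
    beads = []
    for i in range(n):
        chain = "A" if i < n // 2 else "B"
        beads.append({
            "chain": chain, "resid": i % (n // 2) + 1, "resname": "R",
            "pos": tuple(rng.uniform(0, 15, 3)),
            "charge": float(rng.uniform(-1, 1)),
            "sigma_A": float(rng.uniform(2.0, 4.0)),
            "eps": float(rng.uniform(0.0, 1.0)),
        })
    top, frame = make_topology(beads)
    groups = make_groups(top, {"A": "subunit_A", "B": "subunit_B"})
    return top, frame, groups


def test_matches_double_loop_oracle():
    rng = np.random.default_rng(9)
    for _ in range(5):
        top, frame, groups = _random_system(rng)
        fast = pair_enthalpy(frame, top, groups["A"], groups["B"])
        slow = brute_force_enthalpy(frame, top, groups["A"], groups["B"])
        assert fast == pytest.approx(slow, rel=1e-9)


def test_overlapping_atoms_raise():
    top, frame = make_topology([
        {"chain": "A", "resid": 1, "resname": "R", "pos": (1, 1, 1), "charge": 1.0},
        {"chain": "B", "resid": 1, "resname": "R", "pos": (1, 1, 1), "charge": 1.0},
    ])
    with pytest.raises(ValueError, match="overlap"):
        pair_enthalpy(frame, top, [("A", 1, "R")], [("B", 1, "R")])


@settings(max_examples=20, derandomize=True, deadline=None)
@given(st.integers(0, 10_000))
def test_symmetry_and_additivity(seed):
    rng = np.random.default_rng(seed)
    top, frame, groups = _random_system(rng, n=12)
    A = sorted(groups["A"].members)
    B = sorted(groups["B"].members)
    assert pair_enthalpy(frame, top, A, B) == pair_enthalpy(frame, top, B, A)
    b1, b2 = B[:3], B[3:]
    whole = pair_enthalpy(frame, top, A, B)
    e1 = pair_enthalpy(frame, top, A, b1)
    e2 = pair_enthalpy(frame, top, A, b2)
    # tolerance scaled by term magnitude: the parts may nearly cancel
    assert abs(whole - (e1 + e2)) <= 1e-12 * (abs(e1) + abs(e2) + 1.0)


def _static_ensemble(top, frames):
    return StateEnsemble(topology=top, states=["s"], trajectories={"s": frames})


def test_cluster_enthalpy_mean_and_std():
    top, frame = make_topology([
        {"chain": "A", "resid": 1, "resname": "R", "pos": (0, 0, 0), "charge": 1.0},
        {"chain": "B", "resid": 1, "resname": "R", "pos": (0, 0, 10.0), "charge": -1.0},
    ])
    far = frame.copy()
    far[1, 2] = 20.0
    e1 = pair_enthalpy(frame, top, [("A", 1, "R")], [("B", 1, "R")])
    e2 = pair_enthalpy(far, top, [("A", 1, "R")], [("B", 1, "R")])
    cs = ClusterSet(clusters=[Cluster(1, {("A", 1, "R")}, {("B", 1, "R")})])
    ens = _static_ensemble(top, np.stack([frame, far]))
    table = cluster_enthalpies(ens, cs)
    assert table.mean[1]["s"] == pytest.approx((e1 + e2) / 2)
    assert table.std[1]["s"] == pytest.approx(abs(e1 - e2) / 2)
    # identical frames -> zero std
    table0 = cluster_enthalpies(_static_ensemble(top, np.stack([frame, frame])), cs)
    assert table0.std[1]["s"] == 0.0


def test_empty_cluster_side_flagged_absent():
    top, frame = make_topology([
        {"chain": "A", "resid": 1, "resname": "R", "pos": (0, 0, 0)},
        {"chain": "B", "resid": 1, "resname": "R", "pos": (0, 0, 5)},
    ])
    cs = ClusterSet(clusters=[Cluster(1, {("A", 1, "R")}, set())])
    table = cluster_enthalpies(_static_ensemble(top, np.stack([frame, frame])), cs)
    assert 1 in table.absent and 1 not in table.mean


def test_planted_strength_ranking(clusterable_run):
    """Charged planted clusters outrank the near-inert leftover in |mean H|."""
    _, files, gt = clusterable_run
    top, groups, axes, ens = load_run(files)
    from bridgenet.contacts import occupancies
    from bridgenet.clustering import cluster_contacts
    table = occupancies(ens, groups["bodyA"], groups["bodyB"])
    cs = cluster_contacts(table, groups["bodyA"], groups["bodyB"])
    ent = cluster_enthalpies(ens, cs)
    charged = [cid for cid in ent.mean
               if any(r[2] in ("ARG", "NUC") for c in cs.clusters if c.id == cid
                      for r in c.residues)]
    neutral = [cid for cid in ent.mean if cid not in charged]
    for s in ens.states:
        weakest_charged = min(abs(ent.mean[c][s]) for c in charged)
        strongest_neutral = max((abs(ent.mean[c][s]) for c in neutral), default=0.0)
        assert weakest_charged > strongest_neutral


def test_ligand_bridging_weakest_link(tmp_path):
    from bridgenet import synthetic
    spec = synthetic.preset_bridging_ligand(seed=5, n_states=3, frames_per_state=80)
    files, gt = synthetic.generate(spec, tmp_path)
    top, groups, axes, ens = load_run(files)
    table = ligand_bridging(ens, groups, ["ligand1"], body_A="bodyA", body_B="bodyB",
                            mrna="mRNA")
    for s in ens.states:
        assert abs(table.mean["ligand1-bodyB"][s]) > abs(table.mean["ligand1-bodyA"][s])
    # single-frame consistency with direct pair calls
    e = pair_enthalpy(ens.frames(ens.states[0])[0], top,
                      groups["ligand1"].members, groups["bodyB"].members)
    assert np.isfinite(e)
    assert "ligand1-bridging" in table.mean
    for s in ens.states:
        assert table.mean["ligand1-bridging"][s] == pytest.approx(
            table.mean["ligand1-bodyA"][s] + table.mean["ligand1-mRNA"][s])


def test_charge_pair_signs_and_conservation():
    top, frame = make_topology([
        {"chain": "A", "resid": 1, "resname": "ARG", "pos": (0, 0, 0), "charge": 1.0},
        {"chain": "A", "resid": 2, "resname": "GLY", "pos": (8, 0, 0), "charge": 0.3},
        {"chain": "B", "resid": 1, "resname": "NUC", "pos": (0, 0, 4), "charge": -1.0},
        {"chain": "B", "resid": 2, "resname": "ARG", "pos": (8, 0, 4), "charge": 1.0},
    ])
    groups = make_groups(top, {"A": "subunit_A", "B": "subunit_B"})
    ens = _static_ensemble(top, np.stack([frame, frame]))
    dec = charge_pair_coulomb(ens, groups["A"], groups["B"])
    assert dec.attractive["s"] < 0 < dec.repulsive["s"]
    # decomposition sums exactly to the total cross-part Coulomb energy
    f = 138.935458
    total = 0.0
    for i in range(2):
        for j in range(2, 4):
            r_nm = np.linalg.norm(frame[i] - frame[j]) * 0.1
            total += f * top.charges[i] * top.charges[j] / r_nm
    assert dec.total("s") == pytest.approx(total, rel=1e-9)


def test_charge_pair_single_pairs():
    top, frame = make_topology([
        {"chain": "A", "resid": 1, "resname": "ARG", "pos": (0, 0, 0), "charge": 1.0},
        {"chain": "B", "resid": 1, "resname": "NUC", "pos": (0, 0, 4), "charge": -1.0},
    ])
    groups = make_groups(top, {"A": "subunit_A", "B": "subunit_B"})
    dec = charge_pair_coulomb(_static_ensemble(top, np.stack([frame, frame])),
                              groups["A"], groups["B"])
    assert dec.attractive["s"] < 0 and dec.repulsive["s"] == 0.0


def test_hbond_model_shape():
    m = ExponentialHBond(e0=8.0, d0=2.8, lam=0.5, d_max=3.5)
    assert hbond_energy(2.8, m) == pytest.approx(-8.0)
    assert hbond_energy(3.5, m) == 0.0
    assert hbond_energy(5.0, m) == 0.0
    grid = np.linspace(2.0, 3.49, 40)
    vals = [hbond_energy(d, m) for d in grid]
    assert all(v1 <= v2 + 1e-12 for v1, v2 in zip(vals, vals[1:]))
    with pytest.raises(ValueError):
        hbond_energy(-1.0, m)


def test_schlitter_zero_covariance_is_zero():
    seg = np.zeros((10, 2, 3))
    seg += np.arange(2)[None, :, None]  # distinct static positions
    s = schlitter_entropy(seg, np.array([12.0, 12.0]), fit=False)
    assert s == pytest.approx(0.0, abs=1e-12)


def test_schlitter_matches_1d_closed_form():
    rng = np.random.default_rng(3)
    xs = rng.normal(scale=0.2, size=400)  # Å
    seg = np.zeros((400, 1, 3))
    seg[:, 0, 0] = xs
    mass = 15.0
    temperature = 300.0
    s = schlitter_entropy(seg, np.array([mass]), temperature, fit=False)
    var_m2 = np.var(xs) * 1e-20
    expected = 0.5 * _KB * _NA * np.log(
        1.0 + _KB * temperature * np.e ** 2 / _HBAR ** 2 * mass * _AMU * var_m2)
    assert s == pytest.approx(expected, rel=1e-9)


def test_schlitter_block_additivity():
    # orthogonal designs make the cross-covariance exactly zero
    a, b = 0.4, 0.9
    seg = np.zeros((4, 2, 3))
    seg[:, 0, 0] = [a, -a, a, -a]
    seg[:, 1, 1] = [b, b, -b, -b]
    masses = np.array([12.0, 31.0])
    total = schlitter_entropy(seg, masses, fit=False)
    s1 = schlitter_entropy(seg[:, :1, :], masses[:1], fit=False)
    s2 = schlitter_entropy(seg[:, 1:, :], masses[1:], fit=False)
    assert total == pytest.approx(s1 + s2, rel=1e-9)


def test_enthalpy_entropy_correlation_hook(clusterable_run):
    """ΔH and ΔH − TΔS track each other when entropy differences are small."""
    _, files, _ = clusterable_run
    top, groups, axes, ens = load_run(files)
    from bridgenet.contacts import occupancies
    from bridgenet.clustering import cluster_contacts
    table = occupancies(ens, groups["bodyA"], groups["bodyB"])
    cs = cluster_contacts(table, groups["bodyA"], groups["bodyB"])
    ent = cluster_enthalpies(ens, cs)
    hs, gs = [], []
    state = ens.states[0]
    for c in cs.clusters:
        if c.id not in ent.mean:
            continue
        idx = top.atom_indices(c.residues)
        seg = ens.frames(state)[:, idx, :]
        s_conf = schlitter_entropy(seg, top.masses[idx], 300.0, fit=len(idx) >= 3)
        h = ent.mean[c.id][state]
        hs.append(h)
        gs.append(h - 300.0 * s_conf / 1000.0)  # J/(mol·K) -> kJ/mol
    r = np.corrcoef(hs, gs)[0, 1]
    assert r >= 0.0
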