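"""Shared fixtures: in-memory toy topologies and generated synthetic presets."""

from __future__ import annotations

import math

import numpy as np
import pytest

from bridgenet.contacts import ContactTable
from bridgenet.model_io import AtomRecord, GroupDefinition, Topology


def make_topology(beads):
    """Build a Topology plus one coordinate frame from bead dicts.

    Each bead: dict(chain, resid, resname, pos, atoms=[(name, offset)],
    charge, sigma_A, eps, mass). Single-atom beads by default.
    """
    records, coords = [], []
    aid = 1
    for b in beads:
        atoms = b.get("atoms", [("C1", (0.0, 0.0, 0.0))])
        for name, off in atoms:
            records.append(AtomRecord(
                atom_id=aid, name=name,
                residue_key=(b["chain"], b["resid"], b["resname"]),
                charge=b.get("charge", 0.0),
                lj_sigma=b.get("sigma_A", 0.0),
                lj_epsilon=b.get("eps", 0.0),
                mass=b.get("mass", 12.0),
            ))
            coords.append(np.asarray(b["pos"], dtype=float) + np.asarray(off, dtype=float))
            aid += 1
    return Topology(records), np.array(coords)


def make_groups(topology, side_of):
    """GroupDefinitions from a chain -> side mapping (e.g. {'A': 'subunit_A'})."""
    groups = {}
    for chain, side in side_of.items():
        members = frozenset(k for k in topology.residue_keys if k[0] == chain)
        groups[chain] = GroupDefinition(name=chain, members=members, side=side)
    return groups


def make_table(states, entries):
    """ContactTable from {((chainA,residA,nameA),(chainB,residB,nameB)): {state: occ}}."""
    table = ContactTable(states=list(states))
    for pair, occ in entries.items():
        table.occupancy[pair] = {s: float(occ.get(s, 0.0)) for s in states}
    return table


def brute_force_contacts(frame, topology, group_A, group_B, cutoff=3.0):
    """Independent all-atom-pairs contact oracle (pure-Python double loop)."""
    rmap = topology.residue_atom_map()
    pairs = set()
    for ra in sorted(group_A.members):
        for rb in sorted(group_B.members):
            dmin = min(
                math.dist(frame[i], frame[j])
                for i in rmap[ra] for j in rmap[rb]
            )
            if dmin < cutoff:
                pairs.add((ra, rb))
    return pairs


def brute_force_enthalpy(frame, topology, group_A, group_B):
    """Independent O(N²) nonbonded energy oracle (pure-Python double loop)."""
    f = 138.935458
    rmap = topology.residue_atom_map()
    idx_a = [i for r in sorted(group_A.members) for i in rmap[r]]
    idx_b = [i for r in sorted(group_B.members) for i in rmap[r]]
    total = 0.0
    for i in idx_a:
        for j in idx_b:
            r_nm = math.dist(frame[i], frame[j]) * 0.1
            total += f * topology.charges[i] * topology.charges[j] / r_nm
            eps = math.sqrt(topology.epsilons[i] * topology.epsilons[j])
            if eps > 0.0:
                sig = 0.5 * (topology.sigmas[i] + topology.sigmas[j]) * 0.1
                sr6 = (sig / r_nm) ** 6
                total += 4.0 * eps * (sr6 * sr6 - sr6)
    return total


@pytest.fixture(scope="session")
def clusterable_run(tmp_path_factory):
    """Generated 'clusterable interface' preset (k=3) plus its analysis."""
    from bridgenet import synthetic
    d = tmp_path_factory.mktemp("clusterable")
    spec = synthetic.preset_clusterable(seed=2024, k=3, n_states=3, frames_per_state=120)
    files, gt = synthetic.generate(spec, d)
    return spec, files, gt


@pytest.fixture(scope="session")
def sliding_run(tmp_path_factory):
    from bridgenet import synthetic
    d = tmp_path_factory.mktemp("sliding")
    spec = synthetic.preset_sliding_b1(seed=77, n_states=5, frames_per_state=250)
    files, gt = synthetic.generate(spec, d)
    return spec, files, gt


@pytest.fixture(scope="session")
def tracking_run(tmp_path_factory):
    from bridgenet import synthetic
    d = tmp_path_factory.mktemp("tracking")
    spec = synthetic.preset_tracking_arm(seed=11, n_states=3, frames_per_state=170)
    files, gt = synthetic.generate(spec, d)
    return spec, files, gt


def load_run(files, stride=1):
    """Load a generated run back through the real I/O path."""
    from bridgenet import model_io
    top = model_io.load_topology(files.topology, files.parameters)
    groups, axes, manifest = model_io.load_groups_config(files.config, top)
    ens = model_io.load_ensemble(top, files.topology, manifest, stride=stride)
    return top, groups, axes, ens
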