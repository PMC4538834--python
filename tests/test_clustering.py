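"""Two-stage contact clustering: hand-traced steps, oracles, ground truth."""

import numpy as np
import pytest

from bridgenet.clustering import (ClusterSet, Cluster, build_common_clusters,
                                  cluster_contacts, prune_by_enthalpy,
                                  stage2_assign, state_components)
from bridgenet.contacts import occupancies
from bridgenet.model_io import GroupDefinition

from conftest import load_run, make_table

# residue keys: lowercase = subunit A side, x/y/z/u/v/w = subunit B side
a = ("A", 1, "R")
b = ("A", 2, "R")
c = ("A", 3, "R")
d = ("B", 4, "R")
x = ("B", 1, "R")
y = ("B", 2, "R")
u = ("B", 3, "R")
v = ("A", 4, "R")


def group_of(*keys, side, name="g"):
    return GroupDefinition(name, frozenset(keys), side=side)


class UnionFind:
    """Textbook union-find oracle for connected components."""

    def __init__(self):
        self.parent = {}

    def find(self, k):
        self.parent.setdefault(k, k)
        while self.parent[k] != k:
            self.parent[k] = self.parent[self.parent[k]]
            k = self.parent[k]
        return k

    def union(self, i, j):
        self.parent[self.find(i)] = self.find(j)

    def components(self):
        comps = {}
        for k in self.parent:
            comps.setdefault(self.find(k), set()).add(k)
        return {frozenset(s) for s in comps.values()}


def test_state_components_simple_shapes():
    t = make_table(["s"], {(a, x): {"s": 0.5}, (b, x): {"s": 0.6}})
    comps = state_components(t, "s")
    assert [set(sc.residues) for sc in comps] == [{a, b, x}]
    t = make_table(["s"], {(a, x): {"s": 0.5}, (b, y): {"s": 0.6}})
    assert len(state_components(t, "s")) == 2


def test_state_components_respect_threshold():
    t = make_table(["s"], {(a, x): {"s": 0.30}, (b, y): {"s": 0.29}})
    comps = state_components(t, "s")
    assert [set(sc.residues) for sc in comps] == [{a, x}]


def test_state_components_match_union_find_oracle():
    rng = np.random.default_rng(42)
    res_a = [("A", i, "R") for i in range(1, 16)]
    res_b = [("B", i, "R") for i in range(1, 16)]
    for _ in range(10):
        entries = {}
        for _ in range(30):
            ra = res_a[rng.integers(len(res_a))]
            rb = res_b[rng.integers(len(res_b))]
            entries[(ra, rb)] = {"s": float(rng.uniform(0, 1))}
        uf = UnionFind()
        for (ra, rb), occ in entries.items():
            if occ["s"] >= 0.30:
                uf.union(ra, rb)
        t = make_table(["s"], entries)
        got = {frozenset(sc.residues) for sc in state_components(t, "s")}
        assert got == uf.components()


def test_step2_smallest_first_greedy_acceptance():
    """States S1: {a,x},{c,y}; S2: {a,x,c,y} -> accepted {a,x} and {c,y}."""
    t = make_table(["s1", "s2"], {
        (a, x): {"s1": 0.9, "s2": 0.9},
        (c, y): {"s1": 0.9, "s2": 0.9},
        (a, y): {"s2": 0.5},            # bridges the two in s2 only
    })
    per_state = [sc for s in t.states for sc in state_components(t, s)]
    common = build_common_clusters(per_state, t, t.states)
    assert sorted(map(sorted, common)) == sorted(map(sorted, [{a, x}, {c, y}]))


def test_step3_merges_single_overlap_cluster():
    """Rejected {a,x,d} overlapping only {a,x} -> d merged into it."""
    t = make_table(["s1", "s2"], {
        (a, x): {"s1": 0.9, "s2": 0.9},
        (a, d): {"s2": 0.6},
    })
    per_state = [sc for s in t.states for sc in state_components(t, s)]
    common = build_common_clusters(per_state, t, t.states)
    assert common == [{a, x, d}]


def test_step4_assigns_by_summed_closeness():
    """A residue bridging two accepted clusters joins the closer one."""
    t = make_table(["s1", "s2", "s3"], {
        (a, x): {"s1": 0.9, "s2": 0.9, "s3": 0.9},
        (c, y): {"s1": 0.9, "s2": 0.9, "s3": 0.9},
        # u weakly touches a throughout, and both a and c strongly in s2 only
        (a, u): {"s1": 0.25, "s2": 0.5, "s3": 0.25},
        (c, u): {"s2": 0.4},
    })
    per_state = [sc for s in t.states for sc in state_components(t, s)]
    common = build_common_clusters(per_state, t, t.states)
    by_membership = {frozenset(cl) for cl in common}
    # closeness(u -> {a,x}) = 0.25+0.5+0.25 beats closeness(u -> {c,y}) = 0.4
    assert by_membership == {frozenset({a, x, u}), frozenset({c, y})}


def test_stage2_direct_and_chained_assignment():
    """u joins via a 0.2 contact; v follows through u once u is assigned."""
    t = make_table(["s"], {
        (a, x): {"s": 0.9},
        (a, u): {"s": 0.2},
        (v, u): {"s": 0.1},
    })
    common = [{a, x}]
    clusters, leftover = stage2_assign(common, t)
    assert clusters == [{a, x, u, v}]
    assert leftover == set()


def test_stage2_leftover_group():
    t = make_table(["s"], {
        (a, x): {"s": 0.9},
        (b, y): {"s": 0.1},   # retained pair with no link to any cluster
    })
    clusters, leftover = stage2_assign([{a, x}], t)
    assert clusters == [{a, x}]
    assert leftover == {b, y}


def test_partition_property_and_determinism(clusterable_run):
    _, files, _ = clusterable_run
    top, groups, axes, ens = load_run(files)
    table = occupancies(ens, groups["bodyA"], groups["bodyB"])
    cs1 = cluster_contacts(table, groups["bodyA"], groups["bodyB"])
    cs2 = cluster_contacts(table, groups["bodyA"], groups["bodyB"])
    assert cs1.membership() == cs2.membership()
    # partition: every retained residue in exactly one cluster or leftover
    seen = []
    for cl in cs1.clusters:
        seen.extend(cl.residues)
    seen.extend(cs1.leftover_group)
    assert len(seen) == len(set(seen))
    assert set(seen) == table.residues()


def test_state_order_permutation_leaves_membership_unchanged(clusterable_run):
    _, files, _ = clusterable_run
    top, groups, axes, ens = load_run(files)
    table = occupancies(ens, groups["bodyA"], groups["bodyB"])
    reordered = make_table(list(reversed(table.states)),
                           {p: dict(occ) for p, occ in table.occupancy.items()})
    cs1 = cluster_contacts(table, groups["bodyA"], groups["bodyB"])
    cs2 = cluster_contacts(reordered, groups["bodyA"], groups["bodyB"])
    as_sets = lambda cs: {frozenset(c.residues) for c in cs.clusters}
    assert as_sets(cs1) == as_sets(cs2)
    assert cs1.leftover_group == cs2.leftover_group


def test_planted_clusters_recovered_exactly(clusterable_run):
    from sklearn.metrics import adjusted_rand_score
    _, files, gt = clusterable_run
    top, groups, axes, ens = load_run(files)
    table = occupancies(ens, groups["bodyA"], groups["bodyB"])
    cs = cluster_contacts(table, groups["bodyA"], groups["bodyB"])
    pred = cs.membership()
    keys = sorted(set(pred) & set(gt.memberships))
    ari = adjusted_rand_score([gt.memberships[k] for k in keys], [pred[k] for k in keys])
    assert ari == 1.0


def _cs(*clusters):
    return ClusterSet(clusters=[Cluster(i + 1, set(A), set(B))
                                for i, (A, B) in enumerate(clusters)])


def test_prune_requires_negligible_in_every_state():
    cs = _cs(({a}, {x}), ({b}, {y}))
    ent = {1: {"s1": -100.0, "s2": -100.0},
           2: {"s1": -0.5, "s2": -3.5}}   # 0.5% in s1 but ~3.4% in s2 -> kept
    pruned, dropped = prune_by_enthalpy(cs, ent)
    assert dropped == []
    ent2 = {1: {"s1": -100.0, "s2": -100.0},
            2: {"s1": -0.5, "s2": -0.5}}  # <1% everywhere -> dropped
    pruned2, dropped2 = prune_by_enthalpy(cs, ent2)
    assert dropped2 == [2]
    assert [c.id for c in pruned2.clusters] == [1]


def test_prune_renumbers_by_interaction_strength():
    cs = _cs(({a}, {x}), ({b}, {y}), ({c}, {u}))
    ent = {1: {"s": -10.0}, 2: {"s": -300.0}, 3: {"s": -50.0}}
    pruned, _ = prune_by_enthalpy(cs, ent)
    strongest_first = [sorted(c.residues_A)[0] for c in pruned.clusters]
    assert strongest_first == [b, c, a]
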