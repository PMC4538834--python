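"""Two-stage occupancy-based clustering of interface residues.

Stage 1 works on contacts with occupancy >= 30% in a given state:

1. per state, connected components of the contact graph become state
   clusters;
2. all state clusters are pooled and sorted ascending by residue count; the
   common set is seeded with the smallest and greedily extended with the
   next cluster sharing no residue with any accepted cluster;
3. each rejected cluster overlapping exactly one common cluster is merged
   into it;
4. residues of rejected clusters overlapping two or more common clusters
   are assigned, one by one, to the common cluster they are closest to,
   where closeness(residue, cluster) = sum over states of occupancies of
   the residue's contacts with any cluster residue.

Stage 2 then iteratively sorts residues that only have sub-30% contacts
into the closest cluster (closeness recomputed after each assignment);
residues with zero closeness to every cluster end up in one leftover group.

Finally, clusters whose mean interaction enthalpy stays below a floor
fraction of the per-state total in *every* state are pruned, and surviving
clusters are renumbered by descending interaction strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .contacts import ContactTable
from .model_io import GroupDefinition, ResidueKey

DEFAULT_CLUSTER_OCC = 0.30    # stage-1 edges need occupancy "of at least 30%"
DEFAULT_ENTHALPY_FLOOR = 0.01


@dataclass(frozen=True)
class StateCluster:
    """One connected component of one state's >=30% contact graph."""

    state: str
    residues: frozenset[ResidueKey]

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Cluster:
    id: int
    residues_A: set[ResidueKey]
    residues_B: set[ResidueKey]

    @property
    def residues(self) -> set[ResidueKey]:
        return self.residues_A | self.residues_B


@dataclass
class ClusterSet:
    clusters: list[Cluster] = field(default_factory=list)
    leftover_group: set[ResidueKey] = field(default_factory=set)

    def membership(self) -> dict[ResidueKey, int]:
        """residue -> cluster id (leftover residues map to -1)."""
        out = {r: c.id for c in self.clusters for r in c.residues}
        out.update({r: -1 for r in self.leftover_group})
        return out

    def to_frame(self, sides: Mapping[ResidueKey, str] | None = None) -> pd.DataFrame:
        rows = []
        for c in self.clusters:
            for side, residues in (("A", c.residues_A), ("B", c.residues_B)):
                for chain, resid, name in sorted(residues):
                    rows.append({"cluster": c.id, "side": side, "chain": chain,
                                 "resid": resid, "resname": name})
        for chain, resid, name in sorted(self.leftover_group):
            rows.append({"cluster": -1, "side": "-", "chain": chain,
                         "resid": resid, "resname": name})
        return pd.DataFrame(rows, columns=["cluster", "side", "chain", "resid", "resname"])

    def write_tsv(self, path: str | Path, header_lines=()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ClusterSet":
        df = pd.read_csv(path, sep="\t", comment="#")
        out = cls()
        by_id: dict[int, Cluster] = {}
        for _, row in df.iterrows():
            key = (str(row.chain), int(row.resid), str(row.resname))
            cid = int(row.cluster)
            if cid == -1:
                out.leftover_group.add(key)
                continue
            c = by_id.setdefault(cid, Cluster(id=cid, residues_A=set(), residues_B=set()))
            (c.residues_A if row.side == "A" else c.residues_B).add(key)
        out.clusters = [by_id[c] for c in sorted(by_id)]
        return out


# ---------------------------------------------------------------------------
# stage 1

def state_components(table: ContactTable, state: str,
                     occ_threshold: float = DEFAULT_CLUSTER_OCC) -> list[StateCluster]:
    """Connected components of one state's >= threshold contact graph."""
    g = nx.Graph()
    for (ra, rb), occ in table.occupancy.items():
        if occ.get(state, 0.0) >= occ_threshold:
            g.add_edge(ra, rb)
    comps = [StateCluster(state=state, residues=frozenset(c))
             for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: min(c.residues))


def _sort_key(sc: StateCluster, state_order: Mapping[str, int]):
    # ascending size; ties by the lexicographically smallest member, then state order
    return (len(sc), min(sc.residues), state_order[sc.state])


def _closeness(residue: ResidueKey, cluster_residues: set[ResidueKey],
               table: ContactTable) -> float:
    """Sum over states of occupancies of this residue's contacts into the cluster."""
    total = 0.0
    for (ra, rb), occ in table.occupancy.items():
        if (ra == residue and rb in cluster_residues) or (rb == residue and ra in cluster_residues):
            total += sum(occ.values())
    return total


def build_common_clusters(per_state_clusters: Sequence[StateCluster],
                          table: ContactTable,
                          states: Sequence[str]) -> list[set[ResidueKey]]:
    """Steps 2–4: merge per-state components into one common cluster set."""
    if not per_state_clusters:
        return []
    order = {s: i for i, s in enumerate(states)}
    pool = sorted(per_state_clusters, key=lambda sc: _sort_key(sc, order))

    # step 2: greedy acceptance of non-overlapping clusters, smallest first
    common: list[set[ResidueKey]] = []
    accepted_union: set[ResidueKey] = set()
    rejected: list[StateCluster] = []
    for sc in pool:
        if sc.residues & accepted_union:
            rejected.append(sc)
        else:
            common.append(set(sc.residues))
            accepted_union |= sc.residues

    # step 3: rejected clusters overlapping exactly one common cluster merge into it
    multi: list[StateCluster] = []
    for sc in rejected:
        hits = [i for i, c in enumerate(common) if sc.residues & c]
        if len(hits) == 1:
            common[hits[0]] |= sc.residues
        else:
            multi.append(sc)

    # step 4: residues of multi-overlap clusters go to the closest common cluster
    assigned = set().union(*common) if common else set()
    for sc in multi:
        for residue in sorted(sc.residues - assigned):
            scores = [_closeness(residue, c, table) for c in common]
            best = max(scores)
            if best > 0:
                target = min(i for i, s in enumerate(scores) if s == best)
                common[target].add(residue)
                assigned.add(residue)
    return common


# ---------------------------------------------------------------------------
# stage 2

def stage2_assign(common: list[set[ResidueKey]], table: ContactTable) -> tuple[list[set[ResidueKey]], set[ResidueKey]]:
    """Iteratively sort low-occupancy-only residues into the closest cluster.

    Repeats until fixed point: among unassigned residues with positive
    closeness to any cluster, the residue with the highest closeness joins
    its closest cluster; closeness is recomputed after each assignment so a
    residue can become reachable through a newly assigned neighbour. Residues
    that never gain positive closeness form the leftover group.
    """
    clusters = [set(c) for c in common]
    assigned = set().union(*clusters) if clusters else set()
    unassigned = set(table.residues()) - assigned
    while unassigned and clusters:
        best: tuple[float, ResidueKey, int] | None = None
        for residue in sorted(unassigned):
            scores = [_closeness(residue, c, table) for c in clusters]
            top = max(scores)
            if top <= 0:
                continue
            ci = min(i for i, s in enumerate(scores) if s == top)
            if best is None or top > best[0] or (top == best[0] and residue < best[1]):
                best = (top, residue, ci)
        if best is None:
            break
        _, residue, ci = best
        clusters[ci].add(residue)
        unassigned.discard(residue)
    return clusters, unassigned


# ---------------------------------------------------------------------------
# assembly and pruning

def _split_sides(residues: set[ResidueKey], group_A: GroupDefinition,
                 group_B: GroupDefinition) -> tuple[set[ResidueKey], set[ResidueKey]]:
    return residues & group_A.members, residues & group_B.members


def cluster_contacts(table: ContactTable, group_A: GroupDefinition, group_B: GroupDefinition,
                     occ_threshold: float = DEFAULT_CLUSTER_OCC) -> ClusterSet:
    """Run both clustering stages on a retained-contact table."""
    per_state = [sc for s in table.states for sc in state_components(table, s, occ_threshold)]
    common = build_common_clusters(per_state, table, table.states)
    clusters, leftover = stage2_assign(common, table)
    ordered = sorted(range(len(clusters)), key=lambda i: min(clusters[i]))
    out = ClusterSet(leftover_group=leftover)
    for new_id, i in enumerate(ordered, start=1):
        a, b = _split_sides(clusters[i], group_A, group_B)
        out.clusters.append(Cluster(id=new_id, residues_A=a, residues_B=b))
    return out


def prune_by_enthalpy(cluster_set: ClusterSet, mean_enthalpy: Mapping[int, Mapping[str, float]],
                      floor: float = DEFAULT_ENTHALPY_FLOOR) -> tuple[ClusterSet, list[int]]:
    """Drop clusters negligible in every state; renumber by interaction strength.

    A cluster is dropped when |mean enthalpy| < floor × Σ|mean enthalpy| in
    each state (a cluster above the floor in any single state survives). The
    leftover group is always dropped from the pruned set. Survivors are
    renumbered 1..k by descending state-averaged |mean enthalpy|.
    """
    states = sorted({s for v in mean_enthalpy.values() for s in v})
    totals = {s: sum(abs(mean_enthalpy[c].get(s, 0.0)) for c in mean_enthalpy) for s in states}
    dropped: list[int] = []
    kept: list[Cluster] = []
    for c in cluster_set.clusters:
        ent = mean_enthalpy.get(c.id, {})
        negligible = all(abs(ent.get(s, 0.0)) < floor * totals[s] for s in states)
        (dropped if negligible else kept).append(c if not negligible else c.id)
    strength = {c.id: sum(abs(mean_enthalpy[c.id].get(s, 0.0)) for s in states) / max(len(states), 1)
                for c in kept}
    kept.sort(key=lambda c: (-strength[c.id], min(c.residues)))
    pruned = ClusterSet(leftover_group=set())
    for new_id, c in enumerate(kept, start=1):
        pruned.clusters.append(Cluster(id=new_id, residues_A=set(c.residues_A),
                                       residues_B=set(c.residues_B)))
    return pruned, dropped
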