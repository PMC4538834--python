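"""Intersubunit residue–residue contact detection and occupancies.

Two residues, one from each subunit group, are in contact in a frame when
the minimum distance between any two of their atoms (hydrogens included) is
strictly below the cutoff (default 3 Å). Per-state occupancy is the fraction
of that state's frames containing the contact; pairs whose occupancy never
reaches the retention threshold (default 1%) in any state are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .model_io import GroupDefinition, ResidueKey, StateEnsemble, Topology

DEFAULT_CUTOFF = 3.0          # Å, strict "<"
DEFAULT_RETENTION = 0.01      # "at least 1% of the frames from any trajectory"
DEFAULT_STABLE = 0.75         # stable contacts have occupancy strictly above this

ContactPair = tuple[ResidueKey, ResidueKey]  # canonical (subunit-A residue, subunit-B residue)


@dataclass
class ContactTable:
    """Residue-pair × state occupancy matrix (retained pairs only)."""

    states: list[str]
    occupancy: dict[ContactPair, dict[str, float]] = field(default_factory=dict)

    @property
    def pairs(self) -> list[ContactPair]:
        return list(self.occupancy)

    def occ(self, pair: ContactPair, state: str) -> float:
        return self.occupancy.get(pair, {}).get(state, 0.0)

    def residues(self) -> set[ResidueKey]:
        out: set[ResidueKey] = set()
        for a, b in self.occupancy:
            out.add(a)
            out.add(b)
        return out

    def contacts_of(self, residue: ResidueKey) -> list[ContactPair]:
        return [p for p in self.occupancy if residue in p]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (ra, rb), occ in self.occupancy.items():
            row = {
                "chainA": ra[0], "resA": ra[1], "nameA": ra[2],
                "chainB": rb[0], "resB": rb[1], "nameB": rb[2],
            }
            row.update({s: occ.get(s, 0.0) for s in self.states})
            rows.append(row)
        df = pd.DataFrame(rows, columns=["chainA", "resA", "nameA", "chainB", "resB", "nameB", *self.states])
        return df.sort_values(["chainA", "resA", "chainB", "resB"], ignore_index=True)

    def write_tsv(self, path: str | Path, header_lines: Iterable[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ContactTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        fixed = ["chainA", "resA", "nameA", "chainB", "resB", "nameB"]
        states = [c for c in df.columns if c not in fixed]
        table = cls(states=states)
        for _, row in df.iterrows():
            pair = ((str(row.chainA), int(row.resA), str(row.nameA)),
                    (str(row.chainB), int(row.resB), str(row.nameB)))
            table.occupancy[pair] = {s: float(row[s]) for s in states}
        return table


def _group_layout(topology: Topology, group: GroupDefinition):
    """Atom indices plus an atom->local-residue index for one group."""
    rmap = topology.residue_atom_map()
    residues = sorted(group.members)
    atom_idx: list[int] = []
    owner: list[int] = []
    for ri, key in enumerate(residues):
        for ai in rmap[key]:
            atom_idx.append(ai)
            owner.append(ri)
    return residues, np.array(atom_idx, dtype=int), np.array(owner, dtype=int)


def frame_contacts(frame: np.ndarray, topology: Topology,
                   group_A: GroupDefinition, group_B: GroupDefinition,
                   cutoff: float = DEFAULT_CUTOFF) -> set[ContactPair]:
    """Contacts of one frame: residue pairs with min atom distance < cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if group_A.members & group_B.members:
        raise ValueError("contact groups must be disjoint")
    if not group_A.members or not group_B.members:
        return set()
    if np.isnan(frame).any():
        raise ValueError("NaN coordinate in frame")
    mat = _contact_matrix(frame, topology, group_A, group_B, cutoff)
    res_a, _, _ = _group_layout(topology, group_A)
    res_b, _, _ = _group_layout(topology, group_B)
    ia, ib = np.nonzero(mat)
    return {(res_a[i], res_b[j]) for i, j in zip(ia, ib)}


def _contact_matrix(frame, topology, group_A, group_B, cutoff) -> np.ndarray:
    """Boolean residue_A × residue_B contact matrix for one frame."""
    res_a, idx_a, own_a = _group_layout(topology, group_A)
    res_b, idx_b, own_b = _group_layout(topology, group_B)
    d = cdist(frame[idx_a], frame[idx_b])
    dmin = np.full((len(res_a), len(res_b)), np.inf)
    np.minimum.at(dmin, (own_a[:, None], own_b[None, :]), d)
    return dmin < cutoff  # strict: the criterion is "below"


def occupancies(ensemble: StateEnsemble, group_A: GroupDefinition, group_B: GroupDefinition,
                cutoff: float = DEFAULT_CUTOFF,
                retention: float = DEFAULT_RETENTION) -> ContactTable:
    """Per-state contact occupancies with the max-over-states retention filter.

    Occupancy is exact integer frame counting divided by the state's frame
    count; a pair is retained iff its occupancy reaches ``retention`` in at
    least one state.
    """
    if group_A.members & group_B.members:
        raise ValueError("contact groups must be disjoint")
    topology = ensemble.topology
    res_a, idx_a, own_a = _group_layout(topology, group_A)
    res_b, idx_b, own_b = _group_layout(topology, group_B)
    if not res_a or not res_b:
        return ContactTable(states=list(ensemble.states))
    counts: dict[str, np.ndarray] = {}
    for state in ensemble.states:
        frames = ensemble.frames(state)
        if np.isnan(frames).any():
            raise ValueError(f"NaN coordinate in state {state!r}")
        c = np.zeros((len(res_a), len(res_b)), dtype=int)
        for frame in frames:
            c += _contact_matrix(frame, topology, group_A, group_B, cutoff)
        counts[state] = c
    n_frames = ensemble.frame_count
    occ = {s: counts[s] / n_frames[s] for s in ensemble.states}
    max_occ = np.max(np.stack([occ[s] for s in ensemble.states]), axis=0)
    table = ContactTable(states=list(ensemble.states))
    for i, j in zip(*np.nonzero(max_occ >= retention)):
        pair = (res_a[i], res_b[j])
        table.occupancy[pair] = {s: float(occ[s][i, j]) for s in ensemble.states}
    return table


@dataclass(frozen=True)
class OverlapResult:
    overlap: float | None   # percentage, None when undefined
    n_stable_1: int
    n_stable_2: int
    n_shared: int

    @property
    def defined(self) -> bool:
        return self.overlap is not None


def stable_pairs(table: ContactTable, state: str,
                 stable_threshold: float = DEFAULT_STABLE) -> set[ContactPair]:
    """Pairs with occupancy strictly above the stability threshold in one state."""
    return {p for p in table.occupancy if table.occ(p, state) > stable_threshold}


def pattern_overlap(table_1: ContactTable, state_1: str,
                    table_2: ContactTable, state_2: str,
                    stable_threshold: float = DEFAULT_STABLE) -> OverlapResult:
    """Percentage overlap of stable contacts between two single-state patterns.

    overlap = |A ∩ B| / ((|A| + |B|) / 2) × 100 for the stable sets A, B.
    When both sets are empty the overlap is undefined and flagged.
    """
    a = stable_pairs(table_1, state_1, stable_threshold)
    b = stable_pairs(table_2, state_2, stable_threshold)
    if not a and not b:
        return OverlapResult(overlap=None, n_stable_1=0, n_stable_2=0, n_shared=0)
    shared = len(a & b)
    pct = 100.0 * shared / ((len(a) + len(b)) / 2.0)
    return OverlapResult(overlap=pct, n_stable_1=len(a), n_stable_2=len(b), n_shared=shared)
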