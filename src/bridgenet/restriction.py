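"""Contact-restriction scoring.

Each retained contact is binarized over states (bit = 1 where occupancy is
strictly above 0.25). Two contacts are "restricted" together (score 1) if
they are present simultaneously in at least one state, and unrestricted
(score 0) if one is only ever present where the other is absent. A
residue's restriction R is the mean of that indicator over all unordered
pairs of its contacts; a cluster's restriction averages R over its member
residues. Low R marks residues that swap contact partners as the interface
shifts; high R marks contacts maintained by local deformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .contacts import ContactPair, ContactTable
from .model_io import ResidueKey

DEFAULT_BINARIZE = 0.25  # bits are 1 when occupancy is "above 0.25"


@dataclass(frozen=True)
class ContactVector:
    pair: ContactPair
    bits: tuple[int, ...]

    @property
    def active(self) -> bool:
        return any(self.bits)


def binarize(table: ContactTable, threshold: float = DEFAULT_BINARIZE) -> list[ContactVector]:
    """One presence/absence vector per retained pair; all-zero vectors are
    flagged inactive downstream (they carry no co-occurrence information)."""
    out = []
    for pair in table.pairs:
        bits = tuple(1 if table.occ(pair, s) > threshold else 0 for s in table.states)
        out.append(ContactVector(pair=pair, bits=bits))
    return out


def pair_restriction(c_i: ContactVector | Sequence[int], c_j: ContactVector | Sequence[int]) -> int:
    """1 if the two contacts are co-present in any state, else 0."""
    bi = c_i.bits if isinstance(c_i, ContactVector) else tuple(c_i)
    bj = c_j.bits if isinstance(c_j, ContactVector) else tuple(c_j)
    if len(bi) != len(bj):
        raise ValueError(f"contact vectors of different length: {len(bi)} vs {len(bj)}")
    return 1 if any(a and b for a, b in zip(bi, bj)) else 0


def residue_restriction(vectors: Sequence[ContactVector | Sequence[int]]) -> float:
    """Mean pairwise co-occurrence over the residue's n >= 2 active contacts."""
    if len(vectors) < 2:
        raise ValueError("restriction needs at least 2 contact vectors")
    scores = [pair_restriction(a, b) for a, b in combinations(vectors, 2)]
    return float(np.mean(scores))


@dataclass
class RestrictionTable:
    residue_R: dict[ResidueKey, float] = field(default_factory=dict)
    residue_n: dict[ResidueKey, int] = field(default_factory=dict)
    excluded: dict[ResidueKey, str] = field(default_factory=dict)
    cluster_R: dict[int, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"chain": r[0], "resid": r[1], "resname": r[2],
                 "n_contacts": self.residue_n[r], "R": self.residue_R[r]}
                for r in sorted(self.residue_R)]
        return pd.DataFrame(rows, columns=["chain", "resid", "resname", "n_contacts", "R"])

    def write_tsv(self, path: str | Path, header_lines=()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.6f")
            if self.cluster_R:
                fh.write("\n# cluster means\n")
                pd.DataFrame(
                    [{"cluster": c, "mean_R": v} for c, v in sorted(self.cluster_R.items())]
                ).to_csv(fh, sep="\t", index=False, float_format="%.6f")


def restriction_table(table: ContactTable, cluster_set=None,
                      threshold: float = DEFAULT_BINARIZE) -> RestrictionTable:
    """Per-residue and (optionally) per-cluster restriction scores.

    Inactive (all-zero) vectors are excluded before scoring; residues left
    with fewer than 2 scoreable contacts are excluded with a logged reason
    rather than given an arbitrary score.
    """
    vectors = [v for v in binarize(table, threshold)]
    by_residue: dict[ResidueKey, list[ContactVector]] = {}
    for v in vectors:
        if not v.active:
            continue
        for residue in v.pair:
            by_residue.setdefault(residue, []).append(v)
    out = RestrictionTable()
    all_residues = table.residues()
    for residue in sorted(all_residues):
        vs = by_residue.get(residue, [])
        if len(vs) < 2:
            out.excluded[residue] = (
                "no active contacts" if not vs else "single active contact"
            )
            continue
        out.residue_R[residue] = residue_restriction(vs)
        out.residue_n[residue] = len(vs)
    if cluster_set is not None:
        for cluster in cluster_set.clusters:
            rs = [out.residue_R[r] for r in cluster.residues if r in out.residue_R]
            if rs:
                out.cluster_R[cluster.id] = float(np.mean(rs))
    return out


def cluster_restriction(cluster, table: RestrictionTable) -> float:
    """Unweighted mean R over the cluster's residues with defined scores."""
    rs = [table.residue_R[r] for r in cluster.residues if r in table.residue_R]
    if not rs:
        raise ValueError(f"cluster {cluster.id}: no member has a defined restriction score")
    return float(np.mean(rs))
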