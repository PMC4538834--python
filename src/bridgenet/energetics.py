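"""Nonbonded interaction enthalpies between residue groups.

The interaction enthalpy between two disjoint atom groups is the direct sum
over cross-group atom pairs of the Coulomb term f·q_i·q_j/r_ij and the
Lennard-Jones term 4ε_ij((σ_ij/r_ij)^12 − (σ_ij/r_ij)^6), with r in nm,
f = 138.935458 kJ·mol⁻¹·nm·e⁻², Lorentz–Berthelot combination rules, no
distance cutoff and relative dielectric 1. Solvent and counter-ion
contributions are deliberately absent: this is the solute-only force-field
enthalpy, reported as enthalpy, not free energy.

Also here: the charge-sign-resolved Coulomb decomposition used to analyse
salt-bridge swapping at rotating interfaces, a pluggable hydrogen-bond
energy model, and Schlitter's upper-bound conformational entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .geometry import superpose
from .model_io import GroupDefinition, ResidueKey, StateEnsemble, Topology

#: Coulomb prefactor e²·N_A/(4πε₀), kJ·mol⁻¹·nm·e⁻²
COULOMB_CONSTANT = 138.935458
ANGSTROM_TO_NM = 0.1

# Schlitter constants (SI)
_KB = 1.380649e-23          # J/K
_HBAR = 1.054571817e-34     # J·s
_E_EULER = float(np.e)
_NA = 6.02214076e23
_AMU = 1.66053906660e-27    # kg


def _pair_terms(frame: np.ndarray, top: Topology, idx_a: np.ndarray, idx_b: np.ndarray):
    """Coulomb and LJ energies (kJ/mol) between two atom index sets."""
    r = cdist(frame[idx_a], frame[idx_b]) * ANGSTROM_TO_NM
    if np.any(r == 0.0):
        raise ValueError("overlapping atoms (r = 0) in enthalpy evaluation")
    qq = np.outer(top.charges[idx_a], top.charges[idx_b])
    coul = COULOMB_CONSTANT * np.sum(qq / r)
    sig = 0.5 * (top.sigmas[idx_a][:, None] + top.sigmas[idx_b][None, :]) * ANGSTROM_TO_NM
    eps = np.sqrt(np.outer(top.epsilons[idx_a], top.epsilons[idx_b]))
    with np.errstate(divide="ignore", invalid="ignore"):
        sr6 = np.where(eps > 0, (sig / r) ** 6, 0.0)
    lj = np.sum(4.0 * eps * (sr6 ** 2 - sr6))
    return float(coul), float(lj)


def pair_enthalpy(frame: np.ndarray, topology: Topology,
                  group_A: Iterable[ResidueKey] | GroupDefinition,
                  group_B: Iterable[ResidueKey] | GroupDefinition) -> float:
    """Interaction enthalpy (kJ/mol) between two residue groups in one frame."""
    res_a = _members(group_A)
    res_b = _members(group_B)
    if res_a & res_b:
        raise ValueError("enthalpy groups must be disjoint")
    if sorted(res_b) < sorted(res_a):  # canonical order: symmetry holds exactly
        res_a, res_b = res_b, res_a
    idx_a = topology.atom_indices(res_a)
    idx_b = topology.atom_indices(res_b)
    coul, lj = _pair_terms(frame, topology, idx_a, idx_b)
    return coul + lj


def _members(group) -> set[ResidueKey]:
    if isinstance(group, GroupDefinition):
        return set(group.members)
    return set(group)


@dataclass
class EnthalpyTable:
    """(cluster id or group-pair label) × state -> mean/std enthalpy (kJ/mol)."""

    states: list[str]
    mean: dict[object, dict[str, float]] = field(default_factory=dict)
    std: dict[object, dict[str, float]] = field(default_factory=dict)
    n_frames: dict[str, int] = field(default_factory=dict)
    absent: set = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in self.mean:
            for s in self.states:
                rows.append({"entry": str(key), "state": s,
                             "mean_kJmol": self.mean[key][s],
                             "std_kJmol": self.std[key][s],
                             "n_frames": self.n_frames.get(s, 0)})
        return pd.DataFrame(rows, columns=["entry", "state", "mean_kJmol", "std_kJmol", "n_frames"])

    def write_tsv(self, path: str | Path, header_lines=()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.6f")


def _series_over_frames(ensemble: StateEnsemble, idx_a: np.ndarray, idx_b: np.ndarray,
                        state: str) -> np.ndarray:
    top = ensemble.topology
    out = np.empty(ensemble.frame_count[state])
    for t, frame in enumerate(ensemble.frames(state)):
        coul, lj = _pair_terms(frame, top, idx_a, idx_b)
        out[t] = coul + lj
    return out


def cluster_enthalpies(ensemble: StateEnsemble, cluster_set) -> EnthalpyTable:
    """Per-cluster, per-state mean and std of the A-side/B-side enthalpy."""
    table = EnthalpyTable(states=list(ensemble.states), n_frames=dict(ensemble.frame_count))
    top = ensemble.topology
    for cluster in cluster_set.clusters:
        if not cluster.residues_A or not cluster.residues_B:
            table.absent.add(cluster.id)
            continue
        idx_a = top.atom_indices(cluster.residues_A)
        idx_b = top.atom_indices(cluster.residues_B)
        table.mean[cluster.id] = {}
        table.std[cluster.id] = {}
        for state in ensemble.states:
            e = _series_over_frames(ensemble, idx_a, idx_b, state)
            table.mean[cluster.id][state] = float(e.mean())
            table.std[cluster.id][state] = float(e.std())
    return table


def group_pair_enthalpies(ensemble: StateEnsemble,
                          pairs: Sequence[tuple[GroupDefinition, GroupDefinition]]) -> EnthalpyTable:
    """Mean/std enthalpy per state for arbitrary named group pairs."""
    table = EnthalpyTable(states=list(ensemble.states), n_frames=dict(ensemble.frame_count))
    top = ensemble.topology
    for ga, gb in pairs:
        label = f"{ga.name}-{gb.name}"
        idx_a = top.atom_indices(ga.members)
        idx_b = top.atom_indices(gb.members)
        table.mean[label] = {}
        table.std[label] = {}
        for state in ensemble.states:
            e = _series_over_frames(ensemble, idx_a, idx_b, state)
            table.mean[label][state] = float(e.mean())
            table.std[label][state] = float(e.std())
    return table


def ligand_bridging(ensemble: StateEnsemble, groups: Mapping[str, GroupDefinition],
                    ligands: Sequence[str], body_A: str = "30S", body_B: str = "50S",
                    mrna: str = "mRNA") -> EnthalpyTable:
    """Subunit-bridging enthalpies of tRNA-like ligands.

    For each ligand L the table holds E(L–body_B), E(L–body_A), E(L–mRNA)
    and E(mRNA–body_A) per state, plus the derived weakest-link "bridging"
    entry: the combined L–body_A + L–mRNA term, the side of the bridging
    chain that actually limits the ligand's contribution to holding the two
    bodies together.
    """
    pairs = []
    warn_missing = [g for g in (body_A, body_B, mrna, *ligands) if g not in groups]
    if warn_missing:
        import warnings
        warnings.warn(f"missing groups skipped: {warn_missing}")
    for lig in ligands:
        if lig not in groups:
            continue
        for other in (body_B, body_A, mrna):
            if other in groups:
                pairs.append((groups[lig], groups[other]))
    if mrna in groups and body_A in groups:
        pairs.append((groups[mrna], groups[body_A]))
    table = group_pair_enthalpies(ensemble, pairs)
    for lig in ligands:
        key_a, key_m = f"{lig}-{body_A}", f"{lig}-{mrna}"
        if key_a in table.mean and key_m in table.mean:
            label = f"{lig}-bridging"
            table.mean[label] = {s: table.mean[key_a][s] + table.mean[key_m][s]
                                 for s in table.states}
            table.std[label] = {s: float(np.hypot(table.std[key_a][s], table.std[key_m][s]))
                                for s in table.states}
    return table


# ---------------------------------------------------------------------------
# charge-sign-resolved Coulomb decomposition

DEFAULT_CHARGE_CLASSES: dict[str, int] = {
    "ARG": +1, "LYS": +1,
    "ASP": -1, "GLU": -1,
    # nucleotides carry one backbone phosphate charge
    "A": -1, "C": -1, "G": -1, "U": -1,
    "RA": -1, "RC": -1, "RG": -1, "RU": -1, "NUC": -1,
    "HIS": 0,
}


@dataclass
class ChargePairDecomposition:
    """Per-state attractive / repulsive / neutral-involving Coulomb means."""

    part_pair: tuple[str, str]
    states: list[str]
    attractive: dict[str, float] = field(default_factory=dict)   # opposite signs
    repulsive: dict[str, float] = field(default_factory=dict)    # equal nonzero signs
    neutral: dict[str, float] = field(default_factory=dict)      # at least one neutral residue
    attractive_std: dict[str, float] = field(default_factory=dict)
    repulsive_std: dict[str, float] = field(default_factory=dict)

    def total(self, state: str) -> float:
        return self.attractive[state] + self.repulsive[state] + self.neutral[state]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"state": s, "attractive_kJmol": self.attractive[s],
                 "repulsive_kJmol": self.repulsive[s], "neutral_kJmol": self.neutral[s],
                 "attractive_std": self.attractive_std[s], "repulsive_std": self.repulsive_std[s]}
                for s in self.states]
        return pd.DataFrame(rows)


def _coulomb_between(frame, top, idx_a, idx_b) -> float:
    r = cdist(frame[idx_a], frame[idx_b]) * ANGSTROM_TO_NM
    if np.any(r == 0.0):
        raise ValueError("overlapping atoms in Coulomb evaluation")
    return float(COULOMB_CONSTANT * np.sum(np.outer(top.charges[idx_a], top.charges[idx_b]) / r))


def charge_pair_coulomb(ensemble: StateEnsemble, part_1: GroupDefinition, part_2: GroupDefinition,
                        classification: Mapping[str, int] | None = None) -> ChargePairDecomposition:
    """Split cross-part Coulomb energy by residue charge signs.

    Residues are classified at residue level (+1/−1/0 by residue name);
    the per-frame Coulomb energy of each cross-part residue pair is binned
    as attractive (opposite signs), repulsive (equal nonzero signs) or
    neutral-involving, then averaged per state. The three bins sum exactly
    to the total cross-part Coulomb energy.
    """
    classes = dict(DEFAULT_CHARGE_CLASSES if classification is None else classification)
    top = ensemble.topology
    out = ChargePairDecomposition(part_pair=(part_1.name, part_2.name),
                                  states=list(ensemble.states))
    res1 = sorted(part_1.members)
    res2 = sorted(part_2.members)
    idx1 = [top.atom_indices([r]) for r in res1]
    idx2 = [top.atom_indices([r]) for r in res2]
    sign1 = [classes.get(r[2], 0) for r in res1]
    sign2 = [classes.get(r[2], 0) for r in res2]
    for state in ensemble.states:
        frames = ensemble.frames(state)
        att = np.zeros(len(frames))
        rep = np.zeros(len(frames))
        neu = np.zeros(len(frames))
        for t, frame in enumerate(frames):
            for i, ia in enumerate(idx1):
                for j, jb in enumerate(idx2):
                    e = _coulomb_between(frame, top, ia, jb)
                    s = sign1[i] * sign2[j]
                    if s < 0:
                        att[t] += e
                    elif s > 0:
                        rep[t] += e
                    else:
                        neu[t] += e
        out.attractive[state] = float(att.mean())
        out.repulsive[state] = float(rep.mean())
        out.neutral[state] = float(neu.mean())
        out.attractive_std[state] = float(att.std())
        out.repulsive_std[state] = float(rep.std())
    return out


# ---------------------------------------------------------------------------
# hydrogen-bond energy model (pluggable strategy)

@dataclass(frozen=True)
class ExponentialHBond:
    """E(d) = −E₀·exp(−(d − d₀)/λ), clamped to 0 beyond d_max.

    A simple monotone donor–acceptor-distance model: E₀ is the well depth at
    the reference distance d₀ (Å), λ the decay length, d_max the clamp.
    """

    e0: float = 10.0     # kJ/mol
    d0: float = 2.8      # Å
    lam: float = 0.5     # Å
    d_max: float = 3.5   # Å

    def __call__(self, distance: float) -> float:
        if distance <= 0:
            raise ValueError("donor–acceptor distance must be positive")
        if distance >= self.d_max:
            return 0.0
        return -self.e0 * np.exp(-(distance - self.d0) / self.lam)


def hbond_energy(donor_acceptor_distance: float,
                 model: Callable[[float], float] | None = None) -> float:
    """Hydrogen-bond energy (kJ/mol) from a donor–acceptor distance (Å)."""
    return (model or ExponentialHBond())(donor_acceptor_distance)


# ---------------------------------------------------------------------------
# Schlitter conformational entropy

def schlitter_entropy(segment: np.ndarray, masses_amu: np.ndarray,
                      temperature: float = 300.0, fit: bool = True) -> float:
    """Schlitter upper-bound conformational entropy, J/(mol·K).

    S = (k_B/2) · ln det(1 + (k_B·T·e²/ħ²) · M^{1/2} C M^{1/2}), with C the
    Cartesian covariance (m²) of the selection after rigid-body fitting each
    frame to the segment mean, and M the diagonal atomic masses (kg). The
    result is per mole.
    """
    seg = np.asarray(segment, dtype=float)
    if seg.ndim != 3 or seg.shape[0] < 2:
        raise ValueError("need a (frames >= 2, atoms, 3) segment")
    n_frames, n_atoms, _ = seg.shape
    if fit:
        ref = seg.mean(axis=0)
        fitted = np.empty_like(seg)
        for t in range(n_frames):
            rot, trans, _ = superpose(seg[t], ref)
            fitted[t] = seg[t] @ rot.T + trans
        seg = fitted
    x = seg.reshape(n_frames, 3 * n_atoms) * 1e-10  # Å -> m
    c = np.cov(x, rowvar=False, bias=True)
    c = np.atleast_2d(c)
    m = np.repeat(np.asarray(masses_amu, dtype=float) * _AMU, 3)
    msqrt = np.sqrt(m)
    inner = np.eye(3 * n_atoms) + (_KB * temperature * _E_EULER ** 2 / _HBAR ** 2) * \
        (msqrt[:, None] * c * msqrt[None, :])
    sign, logdet = np.linalg.slogdet(inner)
    if sign <= 0:
        raise FloatingPointError(
            f"Schlitter determinant not positive (sign={sign}); "
            f"condition estimate {np.linalg.cond(inner):.3e}"
        )
    return 0.5 * _KB * _NA * logdet
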