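"""Topology, trajectory, parameter-table and group-definition I/O.

The analysis operates on a *state ensemble*: one topology shared by several
named conformational states, each state backed by a multi-frame trajectory.
Coordinates are Ångström throughout the package; the per-atom Lennard-Jones
sigma is converted from the parameter table's nm to Å once, at load time.

File formats are delegated to MDAnalysis (PDB/GRO coordinates, DCD/XTC
trajectories). The parameter table is a project-defined TSV with columns
``resname  atomname  charge_e  sigma_nm  epsilon_kJmol  mass_amu``; groups,
rotation axes and the state manifest live in one YAML config.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda

#: residue identity used everywhere downstream: (chain id, 1-based resid, resname)
ResidueKey = tuple[str, int, str]

NM_TO_ANGSTROM = 10.0

PARAM_COLUMNS = ["resname", "atomname", "charge_e", "sigma_nm", "epsilon_kJmol", "mass_amu"]


class MissingParameterError(KeyError):
    """An atom in the topology has no row in the parameter table."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom with its nonbonded parameters (sigma already in Å)."""

    atom_id: int
    name: str
    residue_key: ResidueKey
    charge: float          # elementary charges
    lj_sigma: float        # Å (converted from the table's nm at load)
    lj_epsilon: float      # kJ/mol
    mass: float            # amu


class Topology:
    """Ordered atom table with vectorized parameter access.

    Atom order is the file order and is the contract shared with every
    trajectory frame of the ensemble.
    """

    def __init__(self, atoms: Sequence[AtomRecord], positions: np.ndarray | None = None):
        ids = [a.atom_id for a in atoms]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate atom_id in topology")
        self.atoms: tuple[AtomRecord, ...] = tuple(atoms)
        #: coordinates from the topology file (Å); the analysis reference geometry
        self.positions = None if positions is None else np.asarray(positions, dtype=float)
        self.charges = np.array([a.charge for a in atoms], dtype=float)
        self.sigmas = np.array([a.lj_sigma for a in atoms], dtype=float)     # Å
        self.epsilons = np.array([a.lj_epsilon for a in atoms], dtype=float)  # kJ/mol
        self.masses = np.array([a.mass for a in atoms], dtype=float)
        self.residue_keys: tuple[ResidueKey, ...] = tuple(a.residue_key for a in atoms)
        if np.any(self.sigmas < 0) or np.any(self.epsilons < 0):
            raise ValueError("lj_sigma and lj_epsilon must be non-negative")
        if np.any(self.masses <= 0):
            raise ValueError("mass must be positive")
        # residue -> atom indices, preserving atom order
        self._residue_atoms: dict[ResidueKey, list[int]] = {}
        for i, key in enumerate(self.residue_keys):
            self._residue_atoms.setdefault(key, []).append(i)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def residues(self) -> list[ResidueKey]:
        return list(self._residue_atoms)

    def atom_indices(self, residues: Iterable[ResidueKey]) -> np.ndarray:
        """Atom indices of the given residues, in topology order."""
        idx: list[int] = []
        for key in residues:
            try:
                idx.extend(self._residue_atoms[key])
            except KeyError:
                raise KeyError(f"residue {key} not in topology") from None
        return np.array(sorted(idx), dtype=int)

    def residue_atom_map(self) -> Mapping[ResidueKey, list[int]]:
        return dict(self._residue_atoms)


@dataclass(frozen=True)
class GroupDefinition:
    """A named residue selection ('30S', '50S', 'tRNA_A', 'H34_tip', ...)."""

    name: str
    members: frozenset[ResidueKey]
    side: str | None = None  # subunit_A | subunit_B | ligand | None

    def validate(self, topology: Topology) -> None:
        missing = self.members - set(topology.residue_keys)
        if missing:
            raise ValueError(f"group {self.name!r} has residues not in topology: {sorted(missing)[:5]}")


@dataclass(frozen=True)
class RotationAxis:
    """A fixed rotation axis with its fit and mobile selections."""

    name: str
    origin: np.ndarray       # Å
    direction: np.ndarray    # unit vector
    fit_group: str
    mobile_group: str

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"axis {self.name!r}: |direction| = {n}, must be 1 within 1e-9")


@dataclass
class StateEnsemble:
    """Named states sharing one topology, each a (frames, atoms, 3) Å array."""

    topology: Topology
    states: list[str]
    trajectories: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def __post_init__(self):
        n = self.topology.n_atoms
        for label in self.states:
            traj = self.trajectories[label]
            if traj.ndim != 3 or traj.shape[1] != n or traj.shape[2] != 3:
                raise ValueError(
                    f"state {label!r}: trajectory shape {traj.shape} does not match "
                    f"topology ({n} atoms)"
                )
            if traj.shape[0] < 2:
                raise ValueError(f"state {label!r}: need at least 2 frames, got {traj.shape[0]}")

    @property
    def frame_count(self) -> dict[str, int]:
        return {s: int(self.trajectories[s].shape[0]) for s in self.states}

    def frames(self, state: str) -> np.ndarray:
        return self.trajectories[state]


# ---------------------------------------------------------------------------
# loading

def read_parameter_table(path: str | Path) -> pd.DataFrame:
    """Read the TSV parameter table, indexed by (resname, atomname)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(PARAM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"parameter table {path} missing columns {sorted(missing)}")
    return df.set_index(["resname", "atomname"])


def load_topology(coordinate_file: str | Path, parameter_table: str | Path) -> Topology:
    """Build a Topology from a PDB/GRO file plus the nonbonded parameter TSV.

    Every atom must have a (resname, atomname) row in the table; a missing
    row is a hard error naming the offending atom. Sigma is converted
    nm -> Å here, once.
    """
    params = read_parameter_table(parameter_table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(coordinate_file))
    atoms = []
    for i, a in enumerate(u.atoms):
        chain = _chain_of(a)
        key: ResidueKey = (chain, int(a.resid), str(a.resname).strip())
        try:
            row = params.loc[(key[2], str(a.name).strip())]
        except KeyError:
            raise MissingParameterError(
                f"no parameters for atom {a.name!r} of residue {key}"
            ) from None
        atoms.append(
            AtomRecord(
                atom_id=i + 1,
                name=str(a.name).strip(),
                residue_key=key,
                charge=float(row["charge_e"]),
                lj_sigma=float(row["sigma_nm"]) * NM_TO_ANGSTROM,
                lj_epsilon=float(row["epsilon_kJmol"]),
                mass=float(row["mass_amu"]),
            )
        )
    return Topology(atoms, positions=u.atoms.positions.astype(float))


def _chain_of(atom) -> str:
    for attr in ("chainID", "segid"):
        v = getattr(atom, attr, "")
        v = str(v).strip()
        if v and v != "SYSTEM":
            return v
    return "A"


def load_trajectory(topology_file: str | Path, trajectory_file: str | Path,
                    n_atoms: int, stride: int = 1) -> np.ndarray:
    """Read a DCD/XTC trajectory into a (frames, atoms, 3) Å array."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(topology_file), str(trajectory_file))
    if u.atoms.n_atoms != n_atoms:
        raise ValueError(
            f"trajectory {trajectory_file}: {u.atoms.n_atoms} atoms, topology has {n_atoms}"
        )
    frames = [u.atoms.positions.copy().astype(float) for ts in u.trajectory[::stride]]
    if not frames:
        raise ValueError(f"trajectory {trajectory_file} is empty")
    return np.array(frames)


def load_ensemble(topology: Topology, topology_file: str | Path,
                  state_manifest: Sequence[Mapping], stride: int = 1) -> StateEnsemble:
    """Assemble a StateEnsemble from a manifest of {label, trajectory} entries.

    States are returned in manifest order. ``stride`` keeps every stride-th
    frame (production-scale ensembles are usually analysed at a coarser
    stride; on toy ensembles stride=1 is the default).
    """
    states, trajs = [], {}
    base = Path(topology_file).parent
    for entry in state_manifest:
        label = str(entry["label"])
        traj_path = Path(entry["trajectory"])
        if not traj_path.is_absolute():
            traj_path = base / traj_path
        trajs[label] = load_trajectory(topology_file, traj_path, topology.n_atoms, stride)
        states.append(label)
    return StateEnsemble(topology=topology, states=states, trajectories=trajs)


# ---------------------------------------------------------------------------
# group / axis / manifest YAML

def _parse_members(raw, topology: Topology | None) -> frozenset[ResidueKey]:
    """Members are [chain, resid] or [chain, resid, resname] lists."""
    lookup: dict[tuple[str, int], str] = {}
    if topology is not None:
        for c, r, n in topology.residue_keys:
            lookup[(c, r)] = n
    members = set()
    for item in raw:
        if len(item) == 3:
            members.add((str(item[0]), int(item[1]), str(item[2])))
        else:
            chain, resid = str(item[0]), int(item[1])
            if (chain, resid) not in lookup:
                raise ValueError(f"residue ({chain}, {resid}) not found in topology")
            members.add((chain, resid, lookup[(chain, resid)]))
    return frozenset(members)


def load_groups_config(path: str | Path, topology: Topology | None = None):
    """Parse the YAML config into groups, axes and the state manifest.

    Returns ``(groups, axes, manifest)`` where groups maps name ->
    GroupDefinition, axes maps name -> RotationAxis, and manifest is the
    ordered list of state entries.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    groups: dict[str, GroupDefinition] = {}
    for name, spec in (cfg.get("groups") or {}).items():
        g = GroupDefinition(
            name=name,
            members=_parse_members(spec["residues"], topology),
            side=spec.get("side"),
        )
        if topology is not None:
            g.validate(topology)
        groups[name] = g
    _check_subunits_disjoint(groups)
    axes: dict[str, RotationAxis] = {}
    for name, spec in (cfg.get("axes") or {}).items():
        axes[name] = RotationAxis(
            name=name,
            origin=np.asarray(spec["origin"], dtype=float),
            direction=np.asarray(spec["direction"], dtype=float),
            fit_group=spec["fit_group"],
            mobile_group=spec["mobile_group"],
        )
    manifest = list(cfg.get("states") or [])
    return groups, axes, manifest


def _check_subunits_disjoint(groups: Mapping[str, GroupDefinition]) -> None:
    subunit = [g for g in groups.values() if g.side in ("subunit_A", "subunit_B")]
    a = frozenset().union(*[g.members for g in subunit if g.side == "subunit_A"]) \
        if any(g.side == "subunit_A" for g in subunit) else frozenset()
    b = frozenset().union(*[g.members for g in subunit if g.side == "subunit_B"]) \
        if any(g.side == "subunit_B" for g in subunit) else frozenset()
    shared = a & b
    if shared:
        raise ValueError(f"subunit groups share residues: {sorted(shared)[:5]}")


def write_groups_config(path: str | Path, groups: Mapping[str, GroupDefinition],
                        axes: Mapping[str, RotationAxis] = (),
                        manifest: Sequence[Mapping] = ()) -> None:
    cfg: dict = {"groups": {}, "axes": {}, "states": list(manifest)}
    for name, g in groups.items():
        spec: dict = {"residues": [[c, r, n] for c, r, n in sorted(g.members)]}
        if g.side:
            spec["side"] = g.side
        cfg["groups"][name] = spec
    for name, ax in dict(axes).items():
        cfg["axes"][name] = {
            "origin": [float(x) for x in ax.origin],
            "direction": [float(x) for x in ax.direction],
            "fit_group": ax.fit_group,
            "mobile_group": ax.mobile_group,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
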