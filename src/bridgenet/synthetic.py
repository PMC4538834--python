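"""Synthetic two-body complexes with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, at toy scale: two rigid bodies (rings of pseudo-atom "core"
residues) whose mobile body is rotated per state about a declared axis;
interface residue clusters whose contact pairs are placed so that, under
Gaussian thermal jitter, the min-atom-distance-below-cutoff event has a
targeted per-state probability; charged beads whose pairings change with
the rotational state; an optional flexible arm whose tip tracks an anchor
on the opposing body; and an optional body-bridging ligand plus mRNA-like
strand. Residues are 1-atom beads ("ARG" = +1e, "NUC" = −1e, "GLY"/"COR"
neutral) — the smallest system that exercises every code path. No attempt
is made to mimic ribosome geometry or force-field realism.

Contact-probability calibration is Monte-Carlo: the generator pre-samples
the jitter distribution and bisects the pair separation until the simulated
contact probability matches the target. All outputs are ordinary
module-readable files (PDB topology, one DCD per state, TSV parameter
table, YAML groups/axis/manifest, JSON ground truth), so downstream tests
exercise the real I/O path. All randomness derives from the mandatory seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda

from .model_io import GroupDefinition, ResidueKey, RotationAxis, write_groups_config

CUTOFF = 3.0  # Å; must match the contact criterion the analysis applies

# bead parameter table: resname -> (charge_e, sigma_nm, epsilon_kJmol, mass_amu)
BEAD_PARAMS: dict[str, tuple[float, float, float, float]] = {
    "COR": (0.0, 0.30, 0.20, 12.0),   # rigid-core bead
    "GLY": (0.0, 0.30, 0.20, 12.0),   # neutral interface bead
    "ARG": (+1.0, 0.00, 0.00, 12.0),  # positive bead (pure Coulomb)
    "NUC": (-1.0, 0.00, 0.00, 12.0),  # negative "nucleotide" bead
    "INE": (0.0, 0.25, 0.01, 12.0),   # near-inert bead (negligible enthalpy)
}


class CalibrationError(RuntimeError):
    pass


@dataclass
class PlantedCluster:
    """One interface contact cluster with per-state contact targets.

    ``contacts[s]`` lists ``(iA, iB, p)`` triples: in state s, B-side bead
    iB sits near A-side bead iA at a separation calibrated so the contact
    probability under jitter is p. A B bead without an entry in a state is
    parked ``park_height`` Å above its home slot, far outside the cutoff.
    """

    name: str
    residues_A: list[str]                      # resnames, one bead each
    residues_B: list[str]
    contacts: dict[int, list[tuple[int, int, float]]]
    azimuth_deg: float = 0.0
    radius: float = 18.0
    spacing: float = 8.0                       # Å between A-side beads along the arc
    park_height: float = 12.0
    b_shift: dict[int, tuple[float, float, float]] = field(default_factory=dict)
    leftover: bool = False                     # ground-truth label -1 (no cluster link)
    #: state -> [(other_cluster_name, iA_in_other, iB_here, p)]: in that state
    #: the B bead is placed midway between its own partner and the foreign A
    #: bead, touching both — a state-specific bridge between two clusters
    foreign_contacts: dict[int, list[tuple[str, int, int, float]]] = field(default_factory=dict)


@dataclass
class ArmSpec:
    """Flexible arm on body A whose tip tracks an anchor bead on body B."""

    azimuth_deg: float = 200.0
    radius: float = 18.0
    drive_sd: float = 1.5     # Å, tangential driver amplitude
    tip_sd: float = 0.1       # Å, independent tip jitter
    anchor_sd: float = 0.1    # Å, independent anchor jitter
    tip_gap: float = 2.5      # Å, tip sits this far below the anchor
    independent: bool = False  # True: tip driven by its own driver (null model)


@dataclass
class LigandSpec:
    """A body-bridging bead (tRNA-like) plus an mRNA-like bead on body A."""

    azimuth_deg: float = 300.0
    radius: float = 18.0


@dataclass
class SyntheticSpec:
    seed: int
    n_states: int = 5
    frames_per_state: int = 200
    rotation_angles: Sequence[float] | None = None  # degrees; default spans -2.7..16.3
    clusters: list[PlantedCluster] = field(default_factory=list)
    arm: ArmSpec | None = None
    ligand: LigandSpec | None = None
    jitter_sd: float = 0.3     # Å thermal jitter per atom coordinate
    core_atoms: int = 8
    core_radius: float = 25.0
    core_gap: float = 6.0      # |z| of the two core rings

    def angles(self) -> np.ndarray:
        if self.rotation_angles is not None:
            a = np.asarray(self.rotation_angles, dtype=float)
            if len(a) != self.n_states:
                raise ValueError("rotation_angles length must equal n_states")
            return a
        return np.linspace(-2.7, 16.3, self.n_states)


@dataclass
class GroundTruth:
    state_labels: list[str]
    memberships: dict[ResidueKey, int]          # cluster id (or -1 for leftover)
    cluster_names: dict[int, str]
    axis_origin: list[float]
    axis_direction: list[float]
    rotation_angles: dict[str, float]
    target_occupancy: dict[tuple, float]        # ((pairA, pairB), state) -> p
    realized_occupancy: dict[tuple, float]
    charge_classes: dict[str, int]
    arm_driver: dict[str, list[float]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def _k(pair_state):
            (ra, rb), s = pair_state
            return f"{ra[0]}:{ra[1]}:{ra[2]}|{rb[0]}:{rb[1]}:{rb[2]}|{s}"
        payload = {
            "state_labels": self.state_labels,
            "memberships": {f"{c}:{r}:{n}": cid for (c, r, n), cid in self.memberships.items()},
            "cluster_names": self.cluster_names,
            "axis": {"origin": self.axis_origin, "direction": self.axis_direction},
            "rotation_angles": self.rotation_angles,
            "target_occupancy": {_k(k): v for k, v in self.target_occupancy.items()},
            "realized_occupancy": {_k(k): v for k, v in self.realized_occupancy.items()},
            "charge_classes": self.charge_classes,
            "arm_driver": self.arm_driver,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class GeneratedFiles:
    directory: Path
    topology: Path
    parameters: Path
    config: Path
    trajectories: dict[str, Path]
    ground_truth_json: Path


# ---------------------------------------------------------------------------
# Monte-Carlo separation calibration

def _contact_probability(gap: float, lateral: np.ndarray, noise: np.ndarray,
                         cutoff: float = CUTOFF) -> float:
    v = noise + np.array([lateral[0], lateral[1], gap])
    return float(np.mean(np.linalg.norm(v, axis=1) < cutoff))


def calibrate_gap(p: float, jitter_sd: float, rng: np.random.Generator,
                  lateral: tuple[float, float] = (0.0, 0.0),
                  cutoff: float = CUTOFF, n_mc: int = 50_000) -> float:
    """Vertical separation whose MC contact probability matches the target.

    Both beads jitter isotropically with sd ``jitter_sd``, so the relative
    displacement has sd jitter_sd·√2 per coordinate. Monotone bisection on a
    common random-number sample.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("target probability must be in [0, 1]")
    noise = rng.normal(scale=jitter_sd * np.sqrt(2.0), size=(n_mc, 3))
    lat = np.asarray(lateral, dtype=float)
    far = cutoff + 12.0 * jitter_sd + 2.0
    if p <= _contact_probability(far, lat, noise, cutoff):
        return far
    if p >= _contact_probability(0.0, lat, noise, cutoff):
        return 0.0
    lo, hi = 0.0, far
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _contact_probability(mid, lat, noise, cutoff) >= p:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# scene assembly

def _rot_z(deg: float) -> np.ndarray:
    t = np.radians(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


class _Scene:
    """Accumulates beads (chain, resname, base position rule) per state."""

    def __init__(self, spec: SyntheticSpec):
        self.spec = spec
        self.chains: list[str] = []
        self.resnames: list[str] = []
        self.base: list[dict[int, np.ndarray]] = []   # per-atom: state -> position
        self.jitter: list[float] = []                  # per-atom jitter sd
        self.ref: list[np.ndarray] = []                # zero-rotation reference geometry

    def add(self, chain: str, resname: str, pos_by_state: dict[int, np.ndarray],
            jitter_sd: float, ref: np.ndarray | None = None) -> int:
        self.chains.append(chain)
        self.resnames.append(resname)
        self.base.append(pos_by_state)
        self.jitter.append(jitter_sd)
        self.ref.append(pos_by_state[0] if ref is None else ref)
        return len(self.chains) - 1

    def residue_keys(self) -> list[ResidueKey]:
        counters: dict[str, int] = {}
        keys = []
        for chain, resname in zip(self.chains, self.resnames):
            counters[chain] = counters.get(chain, 0) + 1
            keys.append((chain, counters[chain], resname))
        return keys


def _build_scene(spec: SyntheticSpec, rng: np.random.Generator):
    """Lay out all beads; returns the scene, group membership and bookkeeping."""
    angles = spec.angles()
    n_states = spec.n_states
    scene = _Scene(spec)
    groups_members: dict[str, set[int]] = {
        "bodyA": set(), "bodyB": set(), "bodyA_core": set(), "bodyB_core": set(),
    }
    memberships: dict[int, tuple[str, bool]] = {}   # atom index -> (cluster name, leftover)
    pair_targets: dict[tuple[int, int, int], float] = {}  # (iatomA, iatomB, state) -> p

    # rigid cores
    for k in range(spec.core_atoms):
        phi = 2 * np.pi * k / spec.core_atoms
        pa = spec.core_radius * np.array([np.cos(phi), np.sin(phi), 0.0]) + [0, 0, -spec.core_gap]
        i = scene.add("A", "COR", {s: pa for s in range(n_states)}, spec.jitter_sd)
        groups_members["bodyA"].add(i)
        groups_members["bodyA_core"].add(i)
        pb0 = spec.core_radius * np.array([np.cos(phi), np.sin(phi), 0.0]) + [0, 0, spec.core_gap]
        i = scene.add("B", "COR", {s: _rot_z(angles[s]) @ pb0 for s in range(n_states)},
                      spec.jitter_sd, ref=pb0)
        groups_members["bodyB"].add(i)
        groups_members["bodyB_core"].add(i)

    # interface clusters: pass 1 places every cluster's A-side beads so that
    # pass 2 can resolve cross-cluster ("foreign") partners
    cal_rng = rng.spawn(1)[0]
    _gap_cache: dict[tuple, float] = {}

    def _gap(p: float, lateral: tuple[float, float]) -> float:
        key = (round(p, 9), (round(lateral[0], 6), round(lateral[1], 6)))
        if key not in _gap_cache:
            _gap_cache[key] = calibrate_gap(p, spec.jitter_sd, cal_rng, lateral=lateral)
        return _gap_cache[key]

    a_layout: dict[str, tuple[list[np.ndarray], list[int]]] = {}
    for cluster in spec.clusters:
        phi0 = np.radians(cluster.azimuth_deg)
        dphi = cluster.spacing / cluster.radius
        a_pos, a_idx = [], []
        for ia, resname in enumerate(cluster.residues_A):
            phi = phi0 + ia * dphi
            p = cluster.radius * np.array([np.cos(phi), np.sin(phi), 0.0]) + [0, 0, -1.0]
            a_pos.append(p)
            i = scene.add("A", resname, {s: p for s in range(n_states)}, spec.jitter_sd)
            a_idx.append(i)
            groups_members["bodyA"].add(i)
            memberships[i] = (cluster.name, cluster.leftover)
        a_layout[cluster.name] = (a_pos, a_idx)

    for cluster in spec.clusters:
        a_pos, a_idx = a_layout[cluster.name]
        # a small per-bead lateral offset keeps B beads sharing one A partner
        # from coinciding
        for ib, resname in enumerate(cluster.residues_B):
            lateral = (0.35 * ib, 0.0)
            pos_by_state: dict[int, np.ndarray] = {}
            targets: list[tuple[int, int, float]] = []  # (atomA, state, p)
            for s in range(n_states):
                own = [(ia, p) for ia, jb, p in cluster.contacts.get(s, []) if jb == ib]
                foreign = [(name, ia, p) for name, ia, jb, p
                           in cluster.foreign_contacts.get(s, []) if jb == ib]
                if len(own) > 1 or len(foreign) > 1:
                    raise ValueError(f"{cluster.name}: bead B{ib} over-constrained in state {s}")
                if own and foreign:
                    # bridge: midway between the two A beads, touching both
                    ia, p = own[0]
                    fname, fia, fp = foreign[0]
                    fpos, fidx = a_layout[fname]
                    pa, pf = a_pos[ia], fpos[fia]
                    half = 0.5 * float(np.linalg.norm(pf - pa))
                    gap = _gap(p, (half, 0.0))
                    pos = 0.5 * (pa + pf) + np.array([0.0, 0.0, max(gap, 1.0e-6)])
                    targets.append((a_idx[ia], s, p))
                    targets.append((fidx[fia], s, fp))
                elif own:
                    ia, p = own[0]
                    gap = _gap(p, lateral)
                    pos = a_pos[ia] + np.array([lateral[0], lateral[1], max(gap, 1.0e-6)])
                    targets.append((a_idx[ia], s, p))
                else:
                    pos = a_pos[min(ib, len(a_pos) - 1)] + np.array([0.0, 0.0, cluster.park_height])
                shift = np.asarray(cluster.b_shift.get(s, (0.0, 0.0, 0.0)), dtype=float)
                pos_by_state[s] = pos + shift
            i = scene.add("B", resname, pos_by_state, spec.jitter_sd)
            groups_members["bodyB"].add(i)
            memberships[i] = (cluster.name, cluster.leftover)
            for atom_a, s, p in targets:
                pair_targets[(atom_a, i, s)] = p

    arm_info = None
    if spec.arm is not None:
        arm_info = _add_arm(scene, spec, angles, groups_members, memberships)

    if spec.ligand is not None:
        _add_ligand(scene, spec, angles, groups_members)

    return scene, groups_members, memberships, pair_targets, arm_info


def _add_arm(scene: _Scene, spec: SyntheticSpec, angles, groups_members, memberships):
    arm = spec.arm
    phi = np.radians(arm.azimuth_deg)
    radial = np.array([np.cos(phi), np.sin(phi), 0.0])
    anchor0 = arm.radius * radial + np.array([0.0, 0.0, 1.0])
    anchor_by_state = {s: _rot_z(angles[s]) @ anchor0 for s in range(spec.n_states)}
    tangent_by_state = {}
    for s in range(spec.n_states):
        a = anchor_by_state[s]
        t = np.array([-a[1], a[0], 0.0])
        tangent_by_state[s] = t / np.linalg.norm(t)
    # static arm base/mid on body A, below the interface plane
    base = arm.radius * radial + np.array([0.0, 0.0, -5.0])
    mid = arm.radius * radial + np.array([0.0, 0.0, -3.5])
    for name, pos in (("GLY", base), ("GLY", mid)):
        i = scene.add("A", name, {s: pos for s in range(spec.n_states)}, spec.jitter_sd)
        groups_members["bodyA"].add(i)
    if arm.independent:
        # null model: the tip neither tracks the anchor's driver nor its
        # per-state position, so any apparent correlation is sampling noise
        tip_by_state = {s: anchor_by_state[0] - np.array([0.0, 0.0, arm.tip_gap])
                        for s in range(spec.n_states)}
    else:
        tip_by_state = {s: anchor_by_state[s] - np.array([0.0, 0.0, arm.tip_gap])
                        for s in range(spec.n_states)}
    i_tip = scene.add("A", "GLY", tip_by_state, arm.tip_sd,
                      ref=anchor0 - np.array([0.0, 0.0, arm.tip_gap]))
    groups_members["bodyA"].add(i_tip)
    groups_members["arm_tip"] = {i_tip}
    memberships[i_tip] = ("arm", False)
    i_anchor = scene.add("B", "GLY", anchor_by_state, arm.anchor_sd, ref=anchor0)
    groups_members["bodyB"].add(i_anchor)
    groups_members["anchor"] = {i_anchor}
    memberships[i_anchor] = ("arm", False)
    return {"tip": i_tip, "anchor": i_anchor, "tangent": tangent_by_state, "arm": arm}


def _add_ligand(scene: _Scene, spec: SyntheticSpec, angles, groups_members):
    lig = spec.ligand
    phi = np.radians(lig.azimuth_deg)
    radial = np.array([np.cos(phi), np.sin(phi), 0.0])
    static = lambda pos: {s: pos for s in range(spec.n_states)}
    # receptors: +1 bead on each body, mRNA bead bound to body A
    i = scene.add("B", "ARG", static(lig.radius * radial + [0, 0, 4.0]), spec.jitter_sd)
    groups_members["bodyB"].add(i)
    i = scene.add("A", "ARG", static(lig.radius * radial + [0, 0, -4.0]), spec.jitter_sd)
    groups_members["bodyA"].add(i)
    i = scene.add("L", "NUC", static(lig.radius * radial + [0, 0, 1.5]), spec.jitter_sd)
    groups_members["ligand1"] = {i}
    phi_m = phi + np.radians(25.0)
    radial_m = np.array([np.cos(phi_m), np.sin(phi_m), 0.0])
    i = scene.add("A", "ARG", static(lig.radius * radial_m + [0, 0, -4.0]), spec.jitter_sd)
    groups_members["bodyA"].add(i)
    i = scene.add("M", "NUC", static(lig.radius * radial_m + [0, 0, -1.2]), spec.jitter_sd)
    groups_members["mRNA"] = {i}


# ---------------------------------------------------------------------------
# trajectory synthesis and file emission

def _synthesize_frames(scene: _Scene, spec: SyntheticSpec, arm_info,
                       rng: np.random.Generator):
    """Per state: (frames, atoms, 3) array; returns (trajs, arm driver per state)."""
    n_atoms = len(scene.chains)
    jitter = np.array(scene.jitter)
    trajs: dict[int, np.ndarray] = {}
    drivers: dict[int, np.ndarray] = {}
    for s in range(spec.n_states):
        base = np.stack([scene.base[i][s] for i in range(n_atoms)])
        frames = base[None, :, :] + rng.normal(
            scale=1.0, size=(spec.frames_per_state, n_atoms, 3)) * jitter[None, :, None]
        if arm_info is not None:
            arm = arm_info["arm"]
            u = arm_info["tangent"][s]
            eta = rng.normal(scale=arm.drive_sd, size=spec.frames_per_state)
            drivers[s] = eta
            ia, it = arm_info["anchor"], arm_info["tip"]
            frames[:, ia, :] += eta[:, None] * u[None, :]
            if arm.independent:
                eta_tip = rng.normal(scale=arm.drive_sd, size=spec.frames_per_state)
                frames[:, it, :] += eta_tip[:, None] * u[None, :]
            else:
                frames[:, it, :] += eta[:, None] * u[None, :]
        trajs[s] = frames
    return trajs, drivers


def _realized_occupancies(scene: _Scene, trajs, pair_targets, cutoff: float = CUTOFF):
    out: dict[tuple[int, int, int], float] = {}
    for (ia, ib, s), _p in pair_targets.items():
        d = np.linalg.norm(trajs[s][:, ia, :] - trajs[s][:, ib, :], axis=1)
        out[(ia, ib, s)] = float(np.mean(d < cutoff))
    return out


def _write_pdb(path: Path, scene: _Scene, coords: np.ndarray) -> None:
    n = len(scene.chains)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n),
                               residue_segindex=np.zeros(n, dtype=int), trajectory=True)
        u.add_TopologyAttr("names", ["C1"] * n)
        u.add_TopologyAttr("resnames", scene.resnames)
        resids = []
        counters: dict[str, int] = {}
        for c in scene.chains:
            counters[c] = counters.get(c, 0) + 1
            resids.append(counters[c])
        u.add_TopologyAttr("resids", resids)
        u.add_TopologyAttr("chainIDs", scene.chains)
        u.add_TopologyAttr("elements", ["C"] * n)
        u.atoms.positions = coords.astype(np.float32)
        u.atoms.write(str(path))


def _write_dcd(path: Path, frames: np.ndarray) -> None:
    n = frames.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n, trajectory=True)
        with mda.coordinates.DCD.DCDWriter(str(path), n) as w:
            for f in frames:
                u.atoms.positions = f.astype(np.float32)
                w.write(u.atoms)


def _write_params(path: Path, resnames: set[str]) -> None:
    rows = [{"resname": rn, "atomname": "C1", "charge_e": BEAD_PARAMS[rn][0],
             "sigma_nm": BEAD_PARAMS[rn][1], "epsilon_kJmol": BEAD_PARAMS[rn][2],
             "mass_amu": BEAD_PARAMS[rn][3]} for rn in sorted(resnames)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def generate(spec: SyntheticSpec, outdir: str | Path) -> tuple[GeneratedFiles, GroundTruth]:
    """Emit topology, per-state trajectories, parameters, config and truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    scene, groups_members, memberships, pair_targets, arm_info = _build_scene(spec, rng)
    trajs, drivers = _synthesize_frames(scene, spec, arm_info, rng)

    # collision check on base geometry of every state
    for s, frames in trajs.items():
        base = np.stack([scene.base[i][s] for i in range(len(scene.chains))])
        d = np.linalg.norm(base[:, None, :] - base[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < 1e-6:
            raise ValueError(f"infeasible geometry: overlapping beads in state {s}")

    labels = [f"state{s:02d}" for s in range(spec.n_states)]
    keys = scene.residue_keys()

    topo_path = outdir / "topology.pdb"
    _write_pdb(topo_path, scene, np.stack(scene.ref))
    params_path = outdir / "parameters.tsv"
    _write_params(params_path, set(scene.resnames))

    traj_paths: dict[str, Path] = {}
    for s, label in enumerate(labels):
        p = outdir / f"{label}.dcd"
        _write_dcd(p, trajs[s])
        traj_paths[label] = p

    groups = {}
    for name, members in groups_members.items():
        side = {"bodyA": "subunit_A", "bodyB": "subunit_B",
                "ligand1": "ligand", "mRNA": "ligand"}.get(name)
        groups[name] = GroupDefinition(
            name=name, members=frozenset(keys[i] for i in members), side=side)
    axis = RotationAxis(name="body_rotation", origin=np.zeros(3),
                        direction=np.array([0.0, 0.0, 1.0]),
                        fit_group="bodyA_core", mobile_group="bodyB_core")
    manifest = [{"label": label, "trajectory": traj_paths[label].name} for label in labels]
    config_path = outdir / "config.yaml"
    write_groups_config(config_path, groups, {"body_rotation": axis}, manifest)

    cluster_ids: dict[str, int] = {}
    gt_members: dict[ResidueKey, int] = {}
    names_by_id: dict[int, str] = {}
    for i, (cname, leftover) in memberships.items():
        if leftover:
            gt_members[keys[i]] = -1
            continue
        if cname not in cluster_ids:
            cluster_ids[cname] = len(cluster_ids) + 1
            names_by_id[cluster_ids[cname]] = cname
        gt_members[keys[i]] = cluster_ids[cname]

    realized = _realized_occupancies(scene, trajs, pair_targets)
    gt = GroundTruth(
        state_labels=labels,
        memberships=gt_members,
        cluster_names=names_by_id,
        axis_origin=[0.0, 0.0, 0.0],
        axis_direction=[0.0, 0.0, 1.0],
        rotation_angles={labels[s]: float(a) for s, a in enumerate(spec.angles())},
        target_occupancy={((keys[ia], keys[ib]), labels[s]): p
                          for (ia, ib, s), p in pair_targets.items()},
        realized_occupancy={((keys[ia], keys[ib]), labels[s]): v
                            for (ia, ib, s), v in realized.items()},
        charge_classes={rn: int(BEAD_PARAMS[rn][0]) for rn in set(scene.resnames)},
        arm_driver={labels[s]: d.tolist() for s, d in drivers.items()},
    )
    gt_path = outdir / "ground_truth.json"
    gt.to_json(gt_path)
    files = GeneratedFiles(directory=outdir, topology=topo_path, parameters=params_path,
                           config=config_path, trajectories=traj_paths,
                           ground_truth_json=gt_path)
    return files, gt


def emit_occupancy_calibration(ground_truth: GroundTruth,
                               frames_per_state: int) -> pd.DataFrame:
    """Target-vs-realized occupancy table; errors if any pair misses 3σ.

    The binomial tolerance is 3·sqrt(p(1−p)/frames); degenerate targets
    (p = 0 or 1) must be realized exactly.
    """
    rows = []
    offenders = []
    for key, p in ground_truth.target_occupancy.items():
        realized = ground_truth.realized_occupancy[key]
        tol = 3.0 * np.sqrt(p * (1.0 - p) / frames_per_state)
        ok = abs(realized - p) <= tol if 0.0 < p < 1.0 else realized == p
        (pair, state) = key
        rows.append({"pair": f"{pair[0]}–{pair[1]}", "state": state,
                     "target_p": p, "realized_p": realized, "tolerance": tol, "ok": ok})
        if not ok:
            offenders.append(rows[-1])
    if offenders:
        raise CalibrationError(f"calibration failed for {len(offenders)} pair(s): {offenders}")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# presets: one per downstream analysis mechanism

def preset_clusterable(seed: int, k: int = 3, n_states: int = 3,
                       frames_per_state: int = 120) -> SyntheticSpec:
    """k planted star clusters, never linked by stable contacts across truth.

    Each cluster is a star around one A bead: an always-on strong pair, a
    satellite B bead strongly bound in the last state only (exercising the
    rejected-cluster merge of step 3) and a weakly bound bead (stage 2).
    Clusters 1 and 2 sit close enough that a bridge bead — a member of
    cluster 1 by contact weight — touches both in one middle state,
    exercising the step-4 closeness assignment. One isolated low-occupancy
    pair forms the leftover group.
    """
    if k < 2:
        raise ValueError("preset needs k >= 2")
    radius = 18.0
    bridge_delta = float(np.degrees(2.0 * np.arcsin(2.6 / radius)))
    azimuths = [0.0, bridge_delta]
    n_rest = (k - 2) + 1  # remaining clusters plus the leftover pair
    azimuths += [70.0 + 220.0 * j / max(n_rest - 1, 1) for j in range(n_rest)]

    clusters = []
    s_bridge = n_states // 2
    for j in range(k):
        contacts: dict[int, list] = {s: [(0, 0, 0.9)] for s in range(n_states)}
        contacts[n_states - 1] = contacts[n_states - 1] + [(0, 1, 0.8)]
        for s in range(n_states):
            contacts[s] = contacts[s] + [(0, 2, 0.15)]
        residues_B = ["NUC", "GLY", "GLY"]
        foreign: dict[int, list] = {}
        if j == 0:
            # bridge bead: weak link to cluster 1 in all states, strong
            # symmetric link to clusters 1 and 2 in the bridge state
            residues_B = residues_B + ["GLY"]
            for s in range(n_states):
                contacts[s] = contacts[s] + [(0, 3, 0.55 if s == s_bridge else 0.15)]
            foreign[s_bridge] = [("cluster2", 0, 3, 0.55)]
        clusters.append(PlantedCluster(
            name=f"cluster{j+1}",
            residues_A=["ARG"],
            residues_B=residues_B,
            contacts=contacts,
            foreign_contacts=foreign,
            azimuth_deg=azimuths[j],
            radius=radius,
        ))
    clusters.append(PlantedCluster(
        name="leftover_pair",
        residues_A=["GLY"], residues_B=["GLY"],
        contacts={s: [(0, 0, 0.1)] for s in range(n_states)},
        azimuth_deg=azimuths[k],
        radius=radius,
        leftover=True,
    ))
    return SyntheticSpec(seed=seed, n_states=n_states, frames_per_state=frames_per_state,
                         clusters=clusters)


def preset_calibration(seed: int, p: float = 0.6, n_pairs: int = 4,
                       n_states: int = 2, frames_per_state: int = 500) -> SyntheticSpec:
    """Independent pairs all targeting one contact probability."""
    clusters = [PlantedCluster(
        name=f"pair{j+1}",
        residues_A=["GLY"], residues_B=["GLY"],
        contacts={s: [(0, 0, p)] for s in range(n_states)},
        azimuth_deg=360.0 * j / n_pairs, radius=20.0,
    ) for j in range(n_pairs)]
    return SyntheticSpec(seed=seed, n_states=n_states, frames_per_state=frames_per_state,
                         clusters=clusters)


def preset_sliding_b1(seed: int, n_states: int = 5,
                      frames_per_state: int = 250) -> SyntheticSpec:
    """Peripheral charge-swap cluster ("sliding") plus a locked cluster.

    The sliding cluster's negative bead pairs with a positive bead in the
    end states and with a neutral bead in the mid states: attractive Coulomb
    peaks at the rotation extremes, contacts swap partners (low restriction).
    The locked cluster keeps identical partners throughout (restriction 1).
    """
    ends = {0, n_states - 1}
    sliding_contacts = {
        s: [(0, 0, 0.9)] if s in ends else [(1, 0, 0.9)] for s in range(n_states)
    }
    sliding = PlantedCluster(
        name="sliding",
        residues_A=["ARG", "GLY"],
        residues_B=["NUC", "ARG"],      # the B-side ARG stays parked: weak repulsion only
        contacts=sliding_contacts,
        azimuth_deg=0.0, park_height=20.0,
    )
    locked = PlantedCluster(
        name="locked",
        residues_A=["GLY", "GLY"],
        residues_B=["GLY", "GLY"],
        contacts={s: [(0, 0, 0.9), (0, 1, 0.9)] for s in range(n_states)},
        azimuth_deg=120.0,
        spacing=4.0,
    )
    return SyntheticSpec(seed=seed, n_states=n_states, frames_per_state=frames_per_state,
                         clusters=[sliding, locked])


def preset_tracking_arm(seed: int, n_states: int = 3, frames_per_state: int = 200,
                        independent: bool = False) -> SyntheticSpec:
    """Flexible-arm tip tracking an anchor on the rotating body.

    ``independent=True`` replaces the shared driver by two independent ones
    (the null model for the projection-correlation check).
    """
    return SyntheticSpec(seed=seed, n_states=n_states, frames_per_state=frames_per_state,
                         arm=ArmSpec(independent=independent))


def preset_bridging_ligand(seed: int, n_states: int = 3,
                           frames_per_state: int = 100) -> SyntheticSpec:
    """A charged ligand bead bound strongly to body B and weakly to body A."""
    return SyntheticSpec(seed=seed, n_states=n_states, frames_per_state=frames_per_state,
                         ligand=LigandSpec())


def preset_default(seed: int, n_states: int = 3,
                   frames_per_state: int = 100) -> SyntheticSpec:
    """Full-pipeline preset: clusterable interface + arm + bridging ligand."""
    base = preset_clusterable(seed, k=3, n_states=n_states,
                              frames_per_state=frames_per_state)
    base.arm = ArmSpec()
    base.ligand = LigandSpec()
    return base
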