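"""Rigid-body superposition, axis rotation angles and COM shifts.

The rotation angle of a mobile body about a declared axis is measured after
rigid-body fitting the frame to a reference over a fit selection (the
opposing, non-rotating body): each mobile atom's position relative to the
axis origin is projected onto the plane normal to the axis, and the angle
is the mean signed angular displacement of those projections versus the
reference (right-hand rule about the axis direction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .model_io import GroupDefinition, ResidueKey, RotationAxis, StateEnsemble

_DEGENERATE_TOL = 1e-8
_AXIS_RADIUS_TOL = 1e-6  # Å; atoms closer to the axis carry no angle information


def superpose(mobile: np.ndarray, reference: np.ndarray,
              fit_indices: np.ndarray | None = None):
    """Least-squares proper superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits the reference over the
    fit atoms (all atoms when ``fit_indices`` is None). The rotation is
    always proper (det = +1): a reflection is never returned, so purely
    mirror-related inputs keep a positive rmsd.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    idx = np.arange(len(mobile)) if fit_indices is None else np.asarray(fit_indices)
    if len(idx) < 3:
        raise ValueError("need at least 3 fit atoms")
    p = mobile[idx]
    q = reference[idx]
    pm, qm = p.mean(axis=0), q.mean(axis=0)
    pc, qc = p - pm, q - qm
    # collinearity check: rank of the centered fit cloud
    if np.linalg.matrix_rank(pc, tol=_DEGENERATE_TOL * max(1.0, np.abs(pc).max())) < 2:
        raise ValueError("degenerate (collinear) fit selection")
    h = pc.T @ qc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = qm - rot @ pm
    fitted = p @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - q) ** 2, axis=1))))
    return rot, trans, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ rotation.T + translation


def rotation_angle(frame: np.ndarray, reference: np.ndarray, axis: RotationAxis,
                   fit_indices: np.ndarray, mobile_indices: np.ndarray) -> float:
    """Signed rotation angle (degrees) of the mobile atoms about the axis.

    The frame is first superposed on the reference over the fit atoms; the
    angle is then the mean signed angular displacement of the mobile atoms'
    in-plane projections, positive by the right-hand rule about
    ``axis.direction``.
    """
    rot, trans, _ = superpose(frame, reference, fit_indices)
    fitted = apply_transform(frame, rot, trans)
    d = axis.direction / np.linalg.norm(axis.direction)
    angles = []
    for i in mobile_indices:
        v_ref = reference[i] - axis.origin
        v_frm = fitted[i] - axis.origin
        v_ref = v_ref - np.dot(v_ref, d) * d
        v_frm = v_frm - np.dot(v_frm, d) * d
        if np.linalg.norm(v_ref) < _AXIS_RADIUS_TOL or np.linalg.norm(v_frm) < _AXIS_RADIUS_TOL:
            continue
        angles.append(np.arctan2(np.dot(d, np.cross(v_ref, v_frm)), np.dot(v_ref, v_frm)))
    if not angles:
        raise ValueError("all mobile atoms lie on the rotation axis")
    return float(np.degrees(np.mean(angles)))


@dataclass
class RotationSeries:
    """Per-frame rotation angles per state with box-plot style summaries."""

    axis_name: str
    angles: dict[str, np.ndarray] = field(default_factory=dict)  # state -> per-frame degrees

    def summary(self) -> pd.DataFrame:
        rows = []
        for state, a in self.angles.items():
            rows.append({
                "state": state,
                "median": float(np.median(a)),
                "q1": float(np.percentile(a, 25)),
                "q3": float(np.percentile(a, 75)),
                "min": float(a.min()),
                "max": float(a.max()),
            })
        return pd.DataFrame(rows, columns=["state", "median", "q1", "q3", "min", "max"])

    def write_tsv(self, path: str | Path, header_lines=()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.summary().to_csv(fh, sep="\t", index=False, float_format="%.4f")


def rotation_series(ensemble: StateEnsemble, axis: RotationAxis,
                    groups: Mapping[str, GroupDefinition],
                    reference: np.ndarray | None = None) -> RotationSeries:
    """Per-frame rotation angles for every state of the ensemble.

    The reference defaults to the first frame of the first state.
    """
    top = ensemble.topology
    fit_idx = top.atom_indices(groups[axis.fit_group].members)
    mob_idx = top.atom_indices(groups[axis.mobile_group].members)
    if reference is None:
        reference = ensemble.frames(ensemble.states[0])[0]
    series = RotationSeries(axis_name=axis.name)
    for state in ensemble.states:
        frames = ensemble.frames(state)
        series.angles[state] = np.array([
            rotation_angle(f, reference, axis, fit_idx, mob_idx) for f in frames
        ])
    return series


def com_shift(ensemble: StateEnsemble, residues: Iterable[ResidueKey],
              state_1: str, state_2: str, fit_group: GroupDefinition,
              reference: np.ndarray | None = None) -> float:
    """Distance (Å) between the two states' mean-structure centers of mass.

    All frames of both states are superposed on the fit group (typically the
    opposing body's core) against one shared reference, the per-state mean
    structures are formed, and the mass-weighted COM distance of the given
    residues (a cluster's mobile side) is returned. A shared fit makes the
    result invariant to any global rigid motion applied to either state.
    """
    residues = list(residues)
    if not residues:
        raise ValueError("empty residue selection for com_shift")
    top = ensemble.topology
    sel = top.atom_indices(residues)
    fit_idx = top.atom_indices(fit_group.members)
    if reference is None:
        reference = ensemble.frames(state_1)[0]
    coms = []
    w = top.masses[sel]
    for state in (state_1, state_2):
        mean_sel = np.zeros((len(sel), 3))
        frames = ensemble.frames(state)
        for f in frames:
            rot, trans, _ = superpose(f, reference, fit_idx)
            mean_sel += apply_transform(f[sel], rot, trans)
        mean_sel /= len(frames)
        coms.append(np.average(mean_sel, axis=0, weights=w))
    return float(np.linalg.norm(coms[0] - coms[1]))
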