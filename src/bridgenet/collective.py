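"""Principal component analysis of collective motion across states.

Frames from all states are rigid-body fitted to a fit selection, the
Cartesian covariance of a chosen atom selection over the concatenated
frames is diagonalized, and per-state trajectories are projected onto the
leading eigenvectors. This is the machinery behind tracking analyses of a
flexible element (a helix arm) following a partner body: high per-state
correlation between two selections' leading-mode projections means one
follows the other.

PCA is unweighted Cartesian (no mass weighting). The fit reference is the
ensemble mean after one fit-to-first-frame / re-mean iteration, which makes
the model deterministic; eigenvector signs are fixed by making each
vector's largest-magnitude component positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .geometry import apply_transform, superpose
from .model_io import GroupDefinition, StateEnsemble


@dataclass
class ModeModel:
    selection: str
    fit_group: str
    mean: np.ndarray          # (n_sel, 3) Å
    eigenvectors: np.ndarray  # (n_modes, 3*n_sel), orthonormal rows
    eigenvalues: np.ndarray   # Å², descending
    sel_indices: np.ndarray
    fit_indices: np.ndarray
    fit_reference: np.ndarray  # full-topology reference coordinates

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# mode model: selection={self.selection} fit_group={self.fit_group}\n")
            fh.write(f"# eigenvalues_A2\t{'	'.join(f'{v:.8g}' for v in self.eigenvalues)}\n")
            np.savetxt(fh, self.mean, header="mean structure (Å)")
            np.savetxt(fh, self.eigenvectors, header="eigenvectors (rows)")


@dataclass
class ProjectionSeries:
    states: list[str]
    values: dict[str, np.ndarray] = field(default_factory=dict)  # state -> (frames, n_modes) Å

    def pooled(self) -> np.ndarray:
        return np.concatenate([self.values[s] for s in self.states], axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.states:
            for t, v in enumerate(self.values[s]):
                row = {"state": s, "frame": t}
                row.update({f"mode{k+1}": float(x) for k, x in enumerate(np.atleast_1d(v))})
                rows.append(row)
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path, header_lines=()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.6f")


def _fit_reference(ensemble: StateEnsemble, fit_idx: np.ndarray) -> np.ndarray:
    """Ensemble mean after fitting every frame to the first frame, once."""
    first = ensemble.frames(ensemble.states[0])[0]
    total = np.zeros_like(first)
    n = 0
    for state in ensemble.states:
        for frame in ensemble.frames(state):
            rot, trans, _ = superpose(frame, first, fit_idx)
            total += apply_transform(frame, rot, trans)
            n += 1
    return total / n


def _fitted_selection(ensemble: StateEnsemble, fit_idx, sel_idx, reference):
    """Yield (state, (frames, n_sel, 3)) of fit-superposed selection coords."""
    for state in ensemble.states:
        frames = ensemble.frames(state)
        out = np.empty((len(frames), len(sel_idx), 3))
        for t, frame in enumerate(frames):
            rot, trans, _ = superpose(frame, reference, fit_idx)
            out[t] = apply_transform(frame[sel_idx], rot, trans)
        yield state, out


def fit_pca(ensemble: StateEnsemble, selection: GroupDefinition,
            fit_group: GroupDefinition) -> ModeModel:
    """PCA of the selection's Cartesian coordinates over concatenated states."""
    top = ensemble.topology
    sel_idx = top.atom_indices(selection.members)
    fit_idx = top.atom_indices(fit_group.members)
    reference = _fit_reference(ensemble, fit_idx)
    blocks = [coords for _, coords in _fitted_selection(ensemble, fit_idx, sel_idx, reference)]
    x = np.concatenate(blocks, axis=0).reshape(-1, 3 * len(sel_idx))
    mean = x.mean(axis=0)
    xc = x - mean
    cov = (xc.T @ xc) / len(x)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order].T
    # deterministic sign: largest-magnitude component positive
    for v in vecs:
        if v[np.argmax(np.abs(v))] < 0:
            v *= -1.0
    return ModeModel(
        selection=selection.name, fit_group=fit_group.name,
        mean=mean.reshape(-1, 3), eigenvectors=vecs, eigenvalues=vals,
        sel_indices=sel_idx, fit_indices=fit_idx, fit_reference=reference,
    )


def project(ensemble: StateEnsemble, model: ModeModel, n_modes: int = 1) -> ProjectionSeries:
    """Per-frame projections (Å) onto the model's leading eigenvectors."""
    if n_modes > len(model.eigenvectors):
        raise ValueError(f"requested {n_modes} modes, model has {len(model.eigenvectors)}")
    series = ProjectionSeries(states=list(ensemble.states))
    mean_flat = model.mean.reshape(-1)
    v = model.eigenvectors[:n_modes]
    for state, coords in _fitted_selection(ensemble, model.fit_indices,
                                           model.sel_indices, model.fit_reference):
        flat = coords.reshape(len(coords), -1) - mean_flat
        series.values[state] = flat @ v.T
    return series


def project_coordinates(coords_flat: np.ndarray, model: ModeModel, n_modes: int = 1) -> np.ndarray:
    """Project already-fitted selection coordinates (no superposition)."""
    return (np.ravel(coords_flat) - model.mean.reshape(-1)) @ model.eigenvectors[:n_modes].T


@dataclass
class CorrelationResult:
    per_state: dict[str, float | None]
    pooled: float | None

    def to_frame(self) -> pd.DataFrame:
        rows = [{"state": s, "r": v} for s, v in self.per_state.items()]
        rows.append({"state": "pooled", "r": self.pooled})
        return pd.DataFrame(rows)


def projection_correlation(series_A: ProjectionSeries, series_B: ProjectionSeries,
                           mode: int = 0) -> CorrelationResult:
    """Pearson correlation of two projection series, per state and pooled.

    Zero-variance segments are flagged with ``None`` rather than a spurious
    coefficient.
    """
    per_state: dict[str, float | None] = {}
    for s in series_A.states:
        a = np.atleast_2d(series_A.values[s].T)[mode]
        b = np.atleast_2d(series_B.values[s].T)[mode]
        if len(a) != len(b):
            raise ValueError(f"state {s!r}: unequal frame counts {len(a)} vs {len(b)}")
        per_state[s] = _safe_pearson(a, b)
    a = np.concatenate([np.atleast_2d(series_A.values[s].T)[mode] for s in series_A.states])
    b = np.concatenate([np.atleast_2d(series_B.values[s].T)[mode] for s in series_B.states])
    return CorrelationResult(per_state=per_state, pooled=_safe_pearson(a, b))


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float | None:
    if np.std(a) == 0 or np.std(b) == 0:
        return None
    return float(pearsonr(a, b)[0])


def mode_amplitude(ensemble: StateEnsemble, model: ModeModel,
                   per_state: bool = False):
    """Range (Å) of the selection centroid's displacement along mode 1.

    The projection series is converted to centroid displacement by scaling
    with the norm of the eigenvector's mean per-atom 3-vector; the amplitude
    is max − min over the chosen frame set. With ``per_state`` a dict per
    state is returned; the pooled range is always at least each state's.
    """
    series = project(ensemble, model, n_modes=1)
    v_atoms = model.eigenvectors[0].reshape(-1, 3)
    scale = float(np.linalg.norm(v_atoms.mean(axis=0)))
    if per_state:
        return {s: float((series.values[s].max() - series.values[s].min()) * scale)
                for s in series.states}
    pooled = series.pooled()
    return float((pooled.max() - pooled.min()) * scale)


def mean_position_deviation(ensemble: StateEnsemble, model: ModeModel,
                            state_1: str, state_2: str) -> float:
    """Distance (Å) between two states' mean selection centroids (fitted)."""
    centroids: dict[str, np.ndarray] = {}
    for state, coords in _fitted_selection(ensemble, model.fit_indices,
                                           model.sel_indices, model.fit_reference):
        centroids[state] = coords.mean(axis=(0, 1))
    return float(np.linalg.norm(centroids[state_1] - centroids[state_2]))
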