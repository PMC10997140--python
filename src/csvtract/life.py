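"""Simplified linear fascicle evaluation (LiFE): streamline filtering by
non-negative least squares against the demeaned diffusion signal.

Each candidate streamline contributes, in every white-matter voxel it
traverses, a demeaned single-stick attenuation profile oriented along its
local tangent.  Solving min_w ||y - M w||_2 with w >= 0 assigns every
candidate a weight; streamlines whose weight is numerically zero did not help
predict the signal and are culled, leaving the "optimised" set.

Also hosts the ensemble pooling step: candidate batches generated under
different tracking parameter settings are unioned, with per-streamline
provenance preserved, before filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse

from .io import (
    BinaryMask,
    GradientTable,
    StreamlineSet,
    ValidationError,
    VolumeGrid,
    resample_polyline,
)


class DegenerateModelError(ValueError):
    """No candidate streamline intersects the white-matter mask."""


def pool_candidates(batches: Sequence[StreamlineSet]) -> StreamlineSet:
    """Union candidate batches from different tracking settings.

    Order is preserved (batches concatenated), per-streamline provenance tags
    travel with the streamlines, and labels are kept when every batch has
    them.  Weights are dropped: pooling happens before evaluation.
    """
    streamlines = [sl for batch in batches for sl in batch]
    labels = None
    if batches and all(b.labels is not None for b in batches):
        labels = [lab for b in batches for lab in (b.labels or [])]
    return StreamlineSet(streamlines, labels=labels)


@dataclass
class LifeModel:
    """Sparse design matrix mapping streamline weights to demeaned signal."""

    design: sparse.csc_matrix         # (n_vox * n_dw, n_streamlines)
    target: np.ndarray                # (n_vox * n_dw,)
    voxel_indices: np.ndarray         # (n_vox, 3) mask voxels, row-block order
    node_map: list[dict[tuple[int, int, int], int]]   # streamline -> voxel -> node count
    n_dw: int

    @property
    def n_streamlines(self) -> int:
        return self.design.shape[1]


def _stick_profile(gtab: GradientTable, tangent: np.ndarray, d_ax: float) -> np.ndarray:
    """Demeaned stick attenuation over the diffusion-weighted directions."""
    g = gtab.bvecs[gtab.dwi_mask]
    b = gtab.bvals[gtab.dwi_mask]
    att = np.exp(-b * d_ax * (g @ tangent) ** 2)
    return att - att.mean()


def build_life_model(candidates: StreamlineSet, signal: VolumeGrid,
                     gtab: GradientTable, wm_mask: BinaryMask,
                     d_ax: float = 1.0e-3,
                     step_mm: float | None = None) -> LifeModel:
    """Assemble the sparse LiFE system over the white-matter mask.

    Streamlines are resampled at ``step_mm`` (default: half the voxel size);
    each node deposits a demeaned stick profile for its local tangent into the
    (voxel, direction) rows of the node's voxel.  The target is the measured
    diffusion-weighted signal demeaned per voxel across directions.
    """
    if len(candidates) == 0:
        raise ValidationError("candidate set is empty")
    if signal.data.shape[:3] != wm_mask.grid.shape:
        raise ValidationError("signal and white-matter mask grids differ")
    if step_mm is None:
        step_mm = 0.5 * float(wm_mask.grid.voxel_size.min())

    mask = wm_mask.grid.data
    vox_idx = np.argwhere(mask)
    n_vox = len(vox_idx)
    row_of_voxel = {tuple(v): i for i, v in enumerate(vox_idx)}
    n_dw = int(gtab.dwi_mask.sum())

    inv = np.linalg.inv(signal.affine)
    shape = np.asarray(mask.shape)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    node_map: list[dict[tuple[int, int, int], int]] = []
    any_hit = False
    for j, sl in enumerate(candidates):
        pts = resample_polyline(sl.points, step_mm)
        mids = 0.5 * (pts[:-1] + pts[1:])
        tans = np.diff(pts, axis=0)
        norms = np.linalg.norm(tans, axis=1, keepdims=True)
        keep = norms[:, 0] > 1e-12
        mids, tans, norms = mids[keep], tans[keep], norms[keep]
        tans = tans / norms
        vox = np.rint(mids @ inv[:3, :3].T + inv[:3, 3]).astype(int)
        inside = np.all((vox >= 0) & (vox < shape), axis=1)
        sl_map: dict[tuple[int, int, int], int] = {}
        # accumulate the summed demeaned profile per traversed masked voxel
        acc: dict[int, np.ndarray] = {}
        for v, t in zip(vox[inside], tans[inside]):
            key = tuple(v)
            if key not in row_of_voxel:
                continue
            sl_map[key] = sl_map.get(key, 0) + 1
            r = row_of_voxel[key]
            prof = _stick_profile(gtab, t, d_ax)
            if r in acc:
                acc[r] += prof
            else:
                acc[r] = prof.copy()
        node_map.append(sl_map)
        if acc:
            any_hit = True
            for r, prof in acc.items():
                rows.append(np.arange(r * n_dw, (r + 1) * n_dw))
                cols.append(np.full(n_dw, j))
                vals.append(prof)
    if not any_hit:
        raise DegenerateModelError("no candidate intersects the white-matter mask")

    design = sparse.csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_vox * n_dw, len(candidates)))

    dw_signal = signal.data[mask][:, gtab.dwi_mask].astype(float)   # (n_vox, n_dw)
    target = (dw_signal - dw_signal.mean(axis=1, keepdims=True)).ravel()
    return LifeModel(design=design, target=target, voxel_indices=vox_idx,
                     node_map=node_map, n_dw=n_dw)


@dataclass
class LifeResult:
    weights: np.ndarray
    rmse: float
    kept_indices: np.ndarray
    converged: bool
    objective_history: np.ndarray = field(default_factory=lambda: np.empty(0))
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        if np.any(self.weights < 0):
            raise ValidationError("LiFE weights must be non-negative")
        if self.rmse < 0:
            raise ValidationError("rmse must be non-negative")


def solve_weights(model: LifeModel, max_iter: int = 2000, tol: float = 1e-8,
                  epsilon_rel: float = 1e-8) -> LifeResult:
    """Non-negative least squares by cyclic coordinate descent.

    Minimises 0.5 ||y - M w||^2 subject to w >= 0.  Each coordinate update is
    the exact 1-D minimiser projected to the feasible set, so the objective is
    non-increasing; iteration stops when the KKT residual
    (|grad_j| for active weights, max(0, -grad_j) for zero weights, scaled by
    the problem size) drops below ``tol``.  Non-convergence returns the best
    iterate with a warning and ``converged=False``.
    """
    M = model.design.tocsc()
    y = model.target
    n = M.shape[1]
    col_sq = np.asarray(M.multiply(M).sum(axis=0)).ravel()
    w = np.zeros(n)
    r = y.copy()                      # residual y - M w
    scale = max(float(np.abs(M.T @ y).max()), 1.0)
    history: list[float] = []
    converged = False
    indptr, indices, data = M.indptr, M.indices, M.data
    for _ in range(max_iter):
        for j in range(n):
            if col_sq[j] <= 0:
                continue
            sl = slice(indptr[j], indptr[j + 1])
            idx = indices[sl]
            col = data[sl]
            grad_j = -(col @ r[idx])
            w_new = max(0.0, w[j] - grad_j / col_sq[j])
            delta = w_new - w[j]
            if delta != 0.0:
                r[idx] -= delta * col
                w[j] = w_new
        history.append(0.5 * float(r @ r))
        grad = -(M.T @ r)
        kkt = np.where(w > 0, np.abs(grad), np.maximum(0.0, -grad))
        if kkt.max() / scale < tol:
            converged = True
            break
    if not converged:
        warnings.warn("LiFE NNLS did not reach the KKT tolerance; "
                      "returning the best iterate", RuntimeWarning)
    rmse = float(np.sqrt(np.mean((y - M @ w) ** 2)))
    eps = epsilon_rel * (w.max() if w.size and w.max() > 0 else 1.0)
    kept = np.flatnonzero(w > eps)
    return LifeResult(weights=w, rmse=rmse, kept_indices=kept,
                      converged=converged,
                      objective_history=np.asarray(history), epsilon=eps)


def cull_streamlines(candidates: StreamlineSet, result: LifeResult,
                     epsilon: float | None = None) -> StreamlineSet:
    """Keep only candidates whose weight exceeds epsilon; attach the weights."""
    if len(result.weights) != len(candidates):
        raise ValidationError("result is not aligned with the candidate set")
    eps = result.epsilon if epsilon is None else epsilon
    keep = np.flatnonzero(result.weights > eps)
    if keep.size == 0:
        warnings.warn("all streamline weights fall below epsilon; "
                      "returning an empty set", RuntimeWarning)
        return StreamlineSet([], weights=np.empty(0),
                             labels=[] if candidates.labels is not None else None)
    out = candidates.subset(keep)
    out.weights = result.weights[keep]
    return out
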