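"""Diffusion tensor fitting and the colour-coded principal-direction map.

The tensor is estimated per voxel by ordinary log-linear least squares on
ln S = ln S0 - b g^T D g, with ln S0 fitted jointly so b=0 volumes enter the
same design.  The RGB map follows the conventional directional encoding:
red = left-right (|x|), green = anterior-posterior (|y|), blue =
superior-inferior (|z|), each modulated by FA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import BinaryMask, GradientTable, ValidationError, VolumeGrid


class RankError(ValueError):
    """The gradient scheme cannot determine all six tensor components."""


@dataclass
class TensorFit:
    """Per-voxel tensor, sorted eigenvalues, principal direction and FA."""

    tensor: np.ndarray        # (X, Y, Z, 3, 3), mm^2/s
    eigenvalues: np.ndarray   # (X, Y, Z, 3), descending
    pdd: np.ndarray           # (X, Y, Z, 3), unit first eigenvector
    fa: np.ndarray            # (X, Y, Z), in [0, 1]
    mask: np.ndarray          # (X, Y, Z) bool: voxels actually fitted
    affine: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.eigenvalues[self.mask], axis=-1) > 1e-12):
            raise ValidationError("eigenvalues must be sorted descending")


def _design_matrix(gtab: GradientTable) -> np.ndarray:
    b = gtab.bvals[:, None]
    g = gtab.bvecs
    cols = np.column_stack([
        g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
        2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
    ])
    X = np.hstack([-b * cols, np.ones((len(gtab), 1))])
    return X


def fit_tensor(signal: VolumeGrid, gtab: GradientTable,
               mask: BinaryMask | None = None,
               signal_floor: float = 1e-6) -> TensorFit:
    """Ordinary log-linear least-squares tensor fit over the masked voxels.

    Non-positive signals are clamped to ``signal_floor * S0`` (per voxel)
    before the logarithm.
    """
    if signal.data.ndim != 4:
        raise ValidationError("signal must be a 4D volume")
    if signal.data.shape[3] != len(gtab):
        raise ValidationError("signal volume count does not match gradient table")
    if gtab.n_b0 < 1:
        raise ValidationError("at least one b=0 volume is required")
    dw = gtab.bvecs[gtab.dwi_mask]
    outer = np.column_stack([
        dw[:, 0] ** 2, dw[:, 1] ** 2, dw[:, 2] ** 2,
        dw[:, 0] * dw[:, 1], dw[:, 0] * dw[:, 2], dw[:, 1] * dw[:, 2],
    ])
    if np.linalg.matrix_rank(outer) < 6:
        raise RankError("need >= 6 independent diffusion-weighted directions")

    shape = signal.data.shape[:3]
    mdata = np.ones(shape, dtype=bool) if mask is None else mask.grid.data
    vox = np.argwhere(mdata)
    s = signal.data[mdata].astype(float)                    # (V, n_vol)
    s0 = s[:, gtab.b0_mask].mean(axis=1)
    s0 = np.where(s0 > 0, s0, 1.0)
    floor = signal_floor * s0[:, None]
    s = np.maximum(s, floor)

    X = _design_matrix(gtab)
    beta = np.log(s) @ np.linalg.pinv(X).T                  # (V, 7)
    d6 = beta[:, :6]
    tensors = np.empty((len(vox), 3, 3))
    tensors[:, 0, 0] = d6[:, 0]
    tensors[:, 1, 1] = d6[:, 1]
    tensors[:, 2, 2] = d6[:, 2]
    tensors[:, 0, 1] = tensors[:, 1, 0] = d6[:, 3]
    tensors[:, 0, 2] = tensors[:, 2, 0] = d6[:, 4]
    tensors[:, 1, 2] = tensors[:, 2, 1] = d6[:, 5]

    evals, evecs = np.linalg.eigh(tensors)                  # ascending
    evals = evals[:, ::-1]
    pdd = evecs[:, :, ::-1][:, :, 0]
    # deterministic sign: first non-negligible component positive
    lead = np.argmax(np.abs(pdd) > 1e-12, axis=1)
    signs = np.sign(pdd[np.arange(len(pdd)), lead])
    signs[signs == 0] = 1.0
    pdd = pdd * signs[:, None]

    mean_ev = evals.mean(axis=1, keepdims=True)
    num = ((evals - mean_ev) ** 2).sum(axis=1)
    den = (evals ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    fa = np.nan_to_num(np.clip(fa, 0.0, 1.0))

    out_tensor = np.zeros(shape + (3, 3))
    out_evals = np.zeros(shape + (3,))
    out_pdd = np.zeros(shape + (3,))
    out_fa = np.zeros(shape)
    ii, jj, kk = vox.T
    out_tensor[ii, jj, kk] = tensors
    out_evals[ii, jj, kk] = evals
    out_pdd[ii, jj, kk] = pdd
    out_fa[ii, jj, kk] = fa
    return TensorFit(tensor=out_tensor, eigenvalues=out_evals, pdd=out_pdd,
                     fa=out_fa, mask=mdata.copy(), affine=signal.affine.copy())


def pdd_rgb_map(fit: TensorFit) -> VolumeGrid:
    """FA-weighted directional colour map: (R, G, B) = FA * |pdd|, in [0, 1].

    The encoding is antipodally symmetric (absolute values), so negating the
    principal direction leaves the map unchanged.
    """
    rgb = fit.fa[..., None] * np.abs(fit.pdd)
    rgb = np.clip(rgb, 0.0, 1.0)
    rgb[~fit.mask] = 0.0
    return VolumeGrid(rgb, fit.affine)
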