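"""Core data model and I/O for volumes, streamline sets and gradient tables.

All internal computation happens in world coordinates (RAS mm, x > 0 = right);
file-format voxel/corner offset conventions are resolved at the I/O boundary
by :mod:`nibabel.streamlines`.  Voxel indices are 0-based and a voxel's centre
sits at ``affine @ (i, j, k, 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from nibabel.streamlines import Tractogram
from nibabel.streamlines.trk import TrkFile


class ValidationError(ValueError):
    """An object violates one of its declared invariants."""


class FormatError(ValueError):
    """A file on disk does not conform to its declared dialect."""


# --------------------------------------------------------------------------
# gradient table
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GradientTable:
    """Diffusion gradient scheme: unit directions and b-values (s/mm^2).

    Directions of b~0 entries may be zero vectors; all diffusion-weighted
    directions must be unit norm to 1e-6.
    """

    bvecs: np.ndarray          # (N, 3)
    bvals: np.ndarray          # (N,)
    b0_threshold: float = 50.0

    def __post_init__(self) -> None:
        bvecs = np.asarray(self.bvecs, dtype=float)
        bvals = np.asarray(self.bvals, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValidationError("bvecs must be an (N, 3) array")
        if bvals.shape != (bvecs.shape[0],):
            raise ValidationError("bvals and bvecs lengths differ")
        if np.any(bvals < 0):
            raise ValidationError("b-values must be non-negative")
        norms = np.linalg.norm(bvecs[bvals > self.b0_threshold], axis=1)
        if norms.size and np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValidationError("diffusion-weighted directions must be unit norm")
        object.__setattr__(self, "bvecs", bvecs)
        object.__setattr__(self, "bvals", bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= self.b0_threshold

    @property
    def dwi_mask(self) -> np.ndarray:
        return ~self.b0_mask

    @property
    def n_b0(self) -> int:
        return int(self.b0_mask.sum())

    def __len__(self) -> int:
        return len(self.bvals)


def read_gradient_table(bvals_path: str | Path, bvecs_path: str | Path) -> GradientTable:
    """Read an FSL-style gradient scheme (bvals: one row; bvecs: three rows)."""
    bvals = np.loadtxt(bvals_path, ndmin=1).ravel()
    bvecs = np.loadtxt(bvecs_path, ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        # ambiguous; FSL convention is three rows = x, y, z components
        bvecs = bvecs.T
    return GradientTable(bvecs=bvecs, bvals=bvals)


def write_gradient_table(gtab: GradientTable, bvals_path: str | Path,
                         bvecs_path: str | Path) -> None:
    np.savetxt(bvals_path, gtab.bvals[None, :], fmt="%.6g")
    np.savetxt(bvecs_path, gtab.bvecs.T, fmt="%.8f")


# --------------------------------------------------------------------------
# volumes and masks
# --------------------------------------------------------------------------

@dataclass
class VolumeGrid:
    """A 3D (or 4D: 3D + channel) array with a voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValidationError("affine is not invertible")
        if self.data.ndim not in (3, 4):
            raise ValidationError("data must be 3D or 4D")
        if np.any(self.voxel_size <= 0):
            raise ValidationError("voxel size derived from affine must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, ijk: Sequence[float]) -> np.ndarray:
        return voxel_to_world(self, ijk)

    def world_to_voxel(self, xyz: Sequence[float]) -> np.ndarray:
        return world_to_voxel(self, xyz)


def voxel_to_world(grid: VolumeGrid, ijk: Sequence[float]) -> np.ndarray:
    """World-mm coordinates of voxel centre(s) ``ijk`` (0-based indices)."""
    ijk = np.asarray(ijk, dtype=float)
    idx = np.atleast_2d(ijk)
    if np.any(idx < -0.5) or np.any(idx >= np.asarray(grid.shape) - 0.5):
        raise IndexError(f"voxel index {ijk} outside grid of shape {grid.shape}")
    out = idx @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    return out[0] if ijk.ndim == 1 else out


def world_to_voxel(grid: VolumeGrid, xyz: Sequence[float],
                   round_indices: bool = True) -> np.ndarray:
    """Voxel index of world point(s); rounds to the nearest lattice point."""
    xyz = np.asarray(xyz, dtype=float)
    pts = np.atleast_2d(xyz)
    inv = np.linalg.inv(grid.affine)
    idx = pts @ inv[:3, :3].T + inv[:3, 3]
    if round_indices:
        idx = np.rint(idx).astype(int)
    return idx[0] if xyz.ndim == 1 else idx


HEMISPHERES = ("left", "right", "midline")


@dataclass
class BinaryMask:
    """A named boolean ROI on a :class:`VolumeGrid`.

    For left/right masks the hemisphere label must agree with the sign of the
    mask's centre of gravity along world x (RAS: x > 0 is right).
    """

    grid: VolumeGrid
    name: str = ""
    hemisphere: str = "midline"
    allow_empty: bool = False

    def __post_init__(self) -> None:
        if self.grid.data.dtype != bool:
            self.grid = VolumeGrid(self.grid.data.astype(bool), self.grid.affine)
        if self.hemisphere not in HEMISPHERES:
            raise ValidationError(f"hemisphere must be one of {HEMISPHERES}")
        if not self.allow_empty and self.n_voxels == 0:
            raise ValidationError(f"mask {self.name!r} is empty")
        if self.n_voxels and self.hemisphere in ("left", "right"):
            cog_x = self.voxel_centres_world()[:, 0].mean()
            if self.hemisphere == "left" and cog_x > 0:
                raise ValidationError(f"mask {self.name!r} labelled left but lies at x>0")
            if self.hemisphere == "right" and cog_x < 0:
                raise ValidationError(f"mask {self.name!r} labelled right but lies at x<0")

    @property
    def n_voxels(self) -> int:
        return int(self.grid.data.sum())

    def voxel_centres_world(self) -> np.ndarray:
        """(M, 3) world-mm centres of all true voxels."""
        idx = np.argwhere(self.grid.data)
        if idx.size == 0:
            return np.empty((0, 3))
        return idx @ self.grid.affine[:3, :3].T + self.grid.affine[:3, 3]


# --------------------------------------------------------------------------
# streamlines
# --------------------------------------------------------------------------

@dataclass
class Streamline:
    """An ordered polyline of 3D world-space points (mm)."""

    points: np.ndarray          # (N, 3)
    provenance: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValidationError("a streamline needs >= 2 points of dimension 3")
        if not np.all(np.isfinite(pts)):
            raise ValidationError("streamline coordinates must be finite")
        if arc_length(pts) <= 0:
            raise ValidationError("streamline arc length must be positive")
        self.points = pts

    @property
    def length(self) -> float:
        return arc_length(self.points)


def arc_length(points: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def resample_polyline(points: np.ndarray, step_mm: float) -> np.ndarray:
    """Resample a polyline at a fixed arc-length step (endpoints preserved)."""
    if step_mm <= 0:
        raise ValidationError("step_mm must be positive")
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(int(np.ceil(total / step_mm)), 1)
    target = np.linspace(0.0, total, n + 1)
    return np.column_stack([np.interp(target, s, points[:, k]) for k in range(3)])


@dataclass
class StreamlineSet:
    """A list of streamlines with optional per-streamline weights and labels."""

    streamlines: list[Streamline] = field(default_factory=list)
    weights: np.ndarray | None = None
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (len(self.streamlines),):
                raise ValidationError("weights length must match streamline count")
            if np.any(self.weights < 0):
                raise ValidationError("weights must be non-negative")
        if self.labels is not None and len(self.labels) != len(self.streamlines):
            raise ValidationError("labels length must match streamline count")

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self) -> Iterator[Streamline]:
        return iter(self.streamlines)

    def __getitem__(self, i: int) -> Streamline:
        return self.streamlines[i]

    def subset(self, indices: Sequence[int]) -> "StreamlineSet":
        indices = list(indices)
        return StreamlineSet(
            streamlines=[self.streamlines[i] for i in indices],
            weights=None if self.weights is None else self.weights[indices],
            labels=None if self.labels is None else [self.labels[i] for i in indices],
        )


# --------------------------------------------------------------------------
# streamline file I/O (TCK / TRK)
# --------------------------------------------------------------------------

_DIALECTS = ("tck", "trk")


def _infer_dialect(path: Path, dialect: str | None) -> str:
    ext = path.suffix.lower().lstrip(".")
    if dialect is None:
        if ext not in _DIALECTS:
            raise FormatError(f"cannot infer dialect from extension {path.suffix!r}")
        return ext
    if dialect not in _DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    if ext in _DIALECTS and ext != dialect:
        raise FormatError(f"extension {path.suffix!r} conflicts with dialect {dialect!r}")
    return dialect


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".sidecar.tsv")


def write_streamlines(sset: StreamlineSet, path: str | Path,
                      dialect: str | None = None,
                      reference: VolumeGrid | None = None) -> Path:
    """Write a streamline set as TCK or TRK plus a plain-text sidecar table.

    Coordinates are handed to nibabel in RAS mm; TRK voxel/corner offsets are
    the writer's concern.  Weights, labels and provenance go to a TSV sidecar
    keyed by streamline index, so both dialects carry identical metadata.
    """
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    for sl in sset:                      # validate before touching the disk
        if not np.all(np.isfinite(sl.points)):
            raise ValidationError("non-finite coordinates in streamline set")
    tg = Tractogram([sl.points for sl in sset], affine_to_rasmm=np.eye(4))
    if dialect == "trk":
        header = TrkFile.create_empty_header()
        if reference is not None:
            header["voxel_sizes"] = reference.voxel_size.astype(np.float32)
            header["dimensions"] = np.asarray(reference.shape, dtype=np.int16)
            header["voxel_to_rasmm"] = reference.affine.astype(np.float32)
        else:
            header["voxel_sizes"] = np.ones(3, dtype=np.float32)
            header["dimensions"] = np.array([1, 1, 1], dtype=np.int16)
            header["voxel_to_rasmm"] = np.eye(4, dtype=np.float32)
        nib.streamlines.save(tg, str(path), header=header)
    else:
        nib.streamlines.save(tg, str(path))

    rows = {
        "index": np.arange(len(sset)),
        "weight": sset.weights if sset.weights is not None else np.full(len(sset), np.nan),
        "label": sset.labels if sset.labels is not None else [""] * len(sset),
        "provenance": [sl.provenance for sl in sset],
    }
    pd.DataFrame(rows).to_csv(_sidecar_path(path), sep="\t", index=False)
    return path


def read_streamlines(path: str | Path, dialect: str | None = None) -> StreamlineSet:
    """Read a TCK/TRK file back into world-mm coordinates (RAS).

    A sidecar table written by :func:`write_streamlines`, if present, restores
    weights, labels and provenance.
    """
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        tf = nib.streamlines.load(str(path))
    except Exception as exc:  # nibabel raises HeaderError/DataError/ValueError
        raise FormatError(f"malformed {dialect} file {path}: {exc}") from exc

    weights = None
    labels = None
    provenance = [""] * len(tf.streamlines)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        tab = pd.read_csv(sidecar, sep="\t", keep_default_na=False,
                          dtype={"label": str, "provenance": str})
        if len(tab) != len(tf.streamlines):
            raise FormatError(f"sidecar row count {len(tab)} != streamline count")
        w = pd.to_numeric(tab["weight"], errors="coerce").to_numpy()
        if np.isfinite(w).all():
            weights = w
        if (tab["label"] != "").any():
            labels = tab["label"].tolist()
        provenance = tab["provenance"].tolist()

    streamlines = [
        Streamline(np.asarray(pts, dtype=float), provenance=prov)
        for pts, prov in zip(tf.streamlines, provenance)
    ]
    return StreamlineSet(streamlines=streamlines, weights=weights, labels=labels)


# --------------------------------------------------------------------------
# volume file I/O (NIfTI)
# --------------------------------------------------------------------------

def write_volume(grid: VolumeGrid, path: str | Path) -> Path:
    """Write a grid as NIfTI-1; boolean data is stored as uint8."""
    path = Path(path)
    data = grid.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, grid.affine), str(path))
    return path


def read_volume(path: str | Path) -> VolumeGrid:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    return VolumeGrid(data=data, affine=np.asarray(img.affine))


def read_mask(path: str | Path, name: str = "", hemisphere: str = "midline",
              allow_empty: bool = False) -> BinaryMask:
    grid = read_volume(path)
    return BinaryMask(grid=VolumeGrid(grid.data.astype(bool), grid.affine),
                      name=name or Path(path).stem, hemisphere=hemisphere,
                      allow_empty=allow_empty)
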