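"""Waypoint-ROI tract classification of streamlines.

A streamline belongs to a tract when it passes through ALL of the tract's
waypoint ROIs (the corticospinal tract uses two ROIs, every other tract one).
Assignment is exclusive by default, resolved by a precedence order; streamlines
satisfying more than one rule are preserved in an overlap log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import BinaryMask, Streamline, StreamlineSet, ValidationError, resample_polyline, world_to_voxel

TRACTS = ("SLF_I", "SLF_II", "SLF_III", "CINGULUM", "CALLOSAL", "AF", "CST")
UNCATEGORISED = "UNCATEGORISED"

#: Default exclusive-assignment precedence (most specific rule first).
DEFAULT_PRECEDENCE = ("CST", "AF", "CALLOSAL", "CINGULUM", "SLF_I", "SLF_II", "SLF_III")


@dataclass(frozen=True)
class TractDefinition:
    """ALL-of waypoint rule: a streamline must cross every named ROI."""

    name: str
    required_rois: tuple[str, ...]
    hemisphere: str = "midline"

    def __post_init__(self) -> None:
        if not self.required_rois:
            raise ValidationError(f"tract {self.name}: required_rois is empty")
        if self.name == "CST" and len(self.required_rois) != 2:
            raise ValidationError("CST requires exactly two waypoint ROIs")
        if self.name in TRACTS and self.name != "CST" and len(self.required_rois) != 1:
            raise ValidationError(f"tract {self.name} requires exactly one waypoint ROI")


def passes_roi(streamline: Streamline, roi: BinaryMask,
               step_mm: float | None = None) -> bool:
    """True iff the streamline enters any true voxel of the ROI.

    Fast path: the polyline is resampled at ``step_mm`` (default: half the
    voxel size) and each sample is mapped to its nearest voxel.  A negative
    verdict is then confirmed by an exact segment/voxel-box intersection test,
    so a segment that merely grazes a voxel corner between two samples is
    still detected; the result equals exact geometric intersection.
    """
    if step_mm is None:
        step_mm = 0.5 * float(roi.grid.voxel_size.min())
    if step_mm <= 0:
        raise ValidationError("step_mm must be positive")
    pts = resample_polyline(streamline.points, step_mm)
    idx = world_to_voxel(roi.grid, pts)
    shape = np.asarray(roi.grid.shape)
    inside = np.all((idx >= 0) & (idx < shape), axis=1)
    if inside.any():
        ii, jj, kk = idx[inside].T
        if roi.grid.data[ii, jj, kk].any():
            return True
    return _segments_hit_mask(streamline.points, roi)


def _segments_hit_mask(points: np.ndarray, roi: BinaryMask) -> bool:
    """Exact slab-clipping test of every segment against every true voxel box.

    Assumes an axis-aligned affine (no shear/rotation), which holds for all
    grids this package constructs; falls back gracefully otherwise because the
    sampled fast path has already run.
    """
    lin = roi.grid.affine[:3, :3]
    if not np.allclose(lin, np.diag(np.diag(lin))):
        return False
    centres = roi.voxel_centres_world()
    if len(centres) == 0:
        return False
    half = 0.5 * roi.grid.voxel_size
    lo = centres - half                      # (V, 3)
    hi = centres + half
    p0 = points[:-1]                         # (S, 3)
    d = points[1:] - p0
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (lo[None, :, :] - p0[:, None, :]) / d[:, None, :]
        t2 = (hi[None, :, :] - p0[:, None, :]) / d[:, None, :]
    tmin = np.minimum(t1, t2)
    tmax = np.maximum(t1, t2)
    # axes with zero direction: inside-slab check replaces the t interval
    zero = np.abs(d)[:, None, :] < 1e-12
    in_slab = (p0[:, None, :] >= lo[None]) & (p0[:, None, :] <= hi[None])
    tmin = np.where(zero, np.where(in_slab, -np.inf, np.inf), tmin)
    tmax = np.where(zero, np.where(in_slab, np.inf, -np.inf), tmax)
    enter = np.maximum(tmin.max(axis=2), 0.0)
    leave = np.minimum(tmax.min(axis=2), 1.0)
    return bool(np.any(enter <= leave))


def classify_streamline(streamline: Streamline,
                        defs: list[TractDefinition],
                        rois: dict[str, BinaryMask],
                        precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
                        step_mm: float | None = None) -> tuple[str, list[str]]:
    """Return ``(label, matches)``: the assigned tract and all satisfied rules.

    ``label`` is the first tract in ``precedence`` whose ALL-of rule holds,
    or UNCATEGORISED when none does.
    """
    by_name = {d.name: d for d in defs}
    for name in precedence:
        if name not in by_name and name not in TRACTS:
            raise ValidationError(f"unknown tract {name!r} in precedence")
    matches = []
    for d in defs:
        missing = [r for r in d.required_rois if r not in rois]
        if missing:
            raise ValidationError(f"tract {d.name}: ROI masks missing: {missing}")
        if all(passes_roi(streamline, rois[r], step_mm) for r in d.required_rois):
            matches.append(d.name)
    for name in precedence:
        if name in matches:
            return name, matches
    return UNCATEGORISED, matches


@dataclass
class ClassificationResult:
    """Per-streamline labels plus per-tract counts for one hemisphere."""

    labels: list[str]
    counts: dict[str, int]
    hemisphere: str = "midline"
    overlap_log: list[tuple[int, tuple[str, ...]]] = field(default_factory=list)
    multi_matches: list[tuple[str, ...]] = field(default_factory=list)

    @property
    def n_streamlines(self) -> int:
        return len(self.labels)


def classify_set(sset: StreamlineSet,
                 defs: list[TractDefinition],
                 rois: dict[str, BinaryMask],
                 precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
                 hemisphere: str = "midline",
                 step_mm: float | None = None,
                 exclusive: bool = True) -> ClassificationResult:
    """Classify every streamline of a (per-hemisphere) set.

    In exclusive mode the labels partition the set (each streamline counts
    toward exactly one tract or UNCATEGORISED); multi-rule matches are
    recorded in ``overlap_log`` before precedence resolution.  With
    ``exclusive=False`` every satisfied rule counts.
    """
    labels: list[str] = []
    counts = {name: 0 for name in [d.name for d in defs] + [UNCATEGORISED]}
    overlap_log: list[tuple[int, tuple[str, ...]]] = []
    multi: list[tuple[str, ...]] = []
    for i, sl in enumerate(sset):
        label, matches = classify_streamline(sl, defs, rois, precedence, step_mm)
        labels.append(label)
        multi.append(tuple(matches))
        if len(matches) > 1:
            overlap_log.append((i, tuple(matches)))
        if exclusive:
            counts[label] += 1
        else:
            if matches:
                for m in matches:
                    counts[m] += 1
            else:
                counts[UNCATEGORISED] += 1
    return ClassificationResult(labels=labels, counts=counts, hemisphere=hemisphere,
                                overlap_log=overlap_log, multi_matches=multi)
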