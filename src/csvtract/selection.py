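"""Endpoint-proximity selection of CSv streamlines.

A streamline is a "CSv streamline" when either of its endpoints lies within a
threshold distance (default 3 mm, inclusive) of a CSv voxel centre.  Interior
points never qualify; only the two endpoints are tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .io import BinaryMask, Streamline, StreamlineSet, ValidationError


@dataclass(frozen=True)
class SelectionConfig:
    distance_mm: float = 3.0
    endpoint_rule: str = "either_endpoint"
    distance_target: str = "voxel_centres"

    def __post_init__(self) -> None:
        if self.distance_mm <= 0:
            raise ValidationError("distance_mm must be positive")
        if self.endpoint_rule != "either_endpoint":
            raise ValidationError(f"unknown endpoint rule {self.endpoint_rule!r}")
        if self.distance_target != "voxel_centres":
            raise ValidationError(f"unknown distance target {self.distance_target!r}")


def endpoint_distance(streamline: Streamline, mask: BinaryMask) -> float:
    """Minimum over both endpoints of the distance to the nearest true-voxel
    centre, in world mm."""
    centres = mask.voxel_centres_world()
    if len(centres) == 0:
        raise ValidationError(f"mask {mask.name!r} is empty")
    ends = streamline.points[[0, -1]]
    d = np.linalg.norm(ends[:, None, :] - centres[None, :, :], axis=2)
    return float(d.min())


@dataclass
class Selection:
    """Selected subset plus provenance back to the input set."""

    subset: StreamlineSet
    indices: np.ndarray          # positions in the input set
    distances: np.ndarray        # endpoint distance of each selected streamline
    hemisphere: str
    hemispheres: list[str] = field(default_factory=list)   # per selected streamline

    def __len__(self) -> int:
        return len(self.subset)


def select_csv_streamlines(sset: StreamlineSet, csv_mask: BinaryMask,
                           cfg: SelectionConfig = SelectionConfig()) -> Selection:
    """Select streamlines with an endpoint within ``cfg.distance_mm`` (<=) of
    the CSv mask; each is tagged with the mask's hemisphere."""
    centres = csv_mask.voxel_centres_world()
    if len(centres) == 0:
        raise ValidationError(f"mask {csv_mask.name!r} is empty")
    if len(sset) == 0:
        return Selection(StreamlineSet([]), np.empty(0, int), np.empty(0),
                         csv_mask.hemisphere, [])
    tree = cKDTree(centres)
    ends = np.stack([[sl.points[0], sl.points[-1]] for sl in sset])  # (N, 2, 3)
    d, _ = tree.query(ends.reshape(-1, 3))
    dmin = d.reshape(-1, 2).min(axis=1)
    keep = np.flatnonzero(dmin <= cfg.distance_mm)
    subset = sset.subset(keep)
    return Selection(subset=subset, indices=keep, distances=dmin[keep],
                     hemisphere=csv_mask.hemisphere,
                     hemispheres=[csv_mask.hemisphere] * len(keep))


def select_bilateral(sset: StreamlineSet, csv_masks: dict[str, BinaryMask],
                     cfg: SelectionConfig = SelectionConfig()) -> dict[str, Selection]:
    """Per-hemisphere selection with deterministic tie-breaking.

    A streamline qualifying at both masks is assigned to the hemisphere with
    the smaller endpoint distance; exact ties go to the left hemisphere.
    """
    per_hemi = {h: select_csv_streamlines(sset, m, cfg) for h, m in csv_masks.items()}
    claimed: dict[int, tuple[str, float]] = {}
    for hemi, sel in per_hemi.items():
        for idx, dist in zip(sel.indices, sel.distances):
            idx = int(idx)
            if idx not in claimed:
                claimed[idx] = (hemi, float(dist))
            else:
                prev_h, prev_d = claimed[idx]
                if dist < prev_d or (dist == prev_d and hemi == "left" != prev_h):
                    claimed[idx] = (hemi, float(dist))
    out: dict[str, Selection] = {}
    for hemi, sel in per_hemi.items():
        keep = [k for k, idx in enumerate(sel.indices) if claimed[int(idx)][0] == hemi]
        out[hemi] = Selection(subset=sel.subset.subset(keep),
                              indices=sel.indices[keep],
                              distances=sel.distances[keep],
                              hemisphere=hemi,
                              hemispheres=[hemi] * len(keep))
    return out
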