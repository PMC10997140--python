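"""Synthetic ground-truth scenes for the CSv streamline pipeline.

A phantom is a voxel grid carrying a small set of geometrically separated
"tract" bundles, a CSv-like seed ROI per hemisphere, box waypoint ROIs in the
roles the classification stage expects (one per tract, two for the
corticospinal tract), a per-voxel stick orientation field, and simulated
diffusion-weighted signal.  Every quantity downstream stages estimate is known
by construction, so selection, classification, streamline filtering and the
group statistics can all be tested against exact truth.

Default geometry: the seven bundles radiate like spokes from a hub placed next
to the right-hemisphere CSv blob.  A configurable fraction of each bundle's
streamlines is rerouted to terminate within the CSv selection distance; the
rest start just outside it.  Waypoint ROIs sit far enough apart that no
streamline can cross a foreign ROI, and this separation is verified (not just
assumed) at generation time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classify import TRACTS, TractDefinition, passes_roi
from .io import (
    BinaryMask,
    GradientTable,
    Streamline,
    StreamlineSet,
    ValidationError,
    VolumeGrid,
    resample_polyline,
    write_gradient_table,
    write_streamlines,
    write_volume,
)

#: Provenance tags emulating candidate generation under four curvature settings.
ANGLE_LABELS = ("angle5.7deg", "angle11.5deg", "angle23.1deg", "angle47.2deg")


class PhantomError(ValueError):
    """The requested phantom cannot be built unambiguously."""


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

@dataclass
class BundleSpec:
    """One tubular bundle: a centreline, a radius and a streamline count."""

    name: str
    centreline: np.ndarray            # (M, 3) world mm
    radius: float = 2.0
    n_streamlines: int = 30
    waypoint_arclengths: tuple[float, ...] = ()   # mm from centreline start

    def __post_init__(self) -> None:
        self.centreline = np.asarray(self.centreline, dtype=float)
        if self.radius <= 0:
            raise ValidationError("bundle radius must be positive")
        if self.n_streamlines < 0:
            raise ValidationError("n_streamlines must be >= 0")
        if self.centreline.ndim != 2 or self.centreline.shape[1] != 3:
            raise ValidationError("centreline must be an (M, 3) array")


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (56, 56, 56)
    voxel_size: float = 2.0
    bundles: list[BundleSpec] = field(default_factory=list)
    csv_centres: dict[str, np.ndarray] = field(default_factory=dict)
    snr: float = np.inf
    seed: int = 0
    reroute_fraction: float = 0.3
    csv_mask_voxels: int = 3          # CSv blob edge length in voxels
    roi_half_mm: float = 4.0          # waypoint box half-extent
    d_ax: float = 1.0e-3              # axial stick diffusivity, mm^2/s
    d_iso: float = 3.0e-3             # free-water diffusivity, mm^2/s
    s0: float = 100.0
    wm_free_water: float = 0.0        # isotropic fraction inside bundle voxels
    n_directions: int = 64
    bvalue: float = 1000.0
    n_b0: int = 6
    simulate_signal: bool = True

    def __post_init__(self) -> None:
        self.csv_centres = {h: np.asarray(c, dtype=float)
                            for h, c in self.csv_centres.items()}

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size] * 3 + [1.0])
        aff[:3, 3] = -0.5 * (np.asarray(self.grid_shape) - 1) * self.voxel_size
        return aff

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = self.affine[:3, 3] - 0.5 * self.voxel_size
        hi = lo + np.asarray(self.grid_shape) * self.voxel_size
        return lo, hi


_SPOKE_DIRECTIONS: dict[str, np.ndarray] = {
    "SLF_I": np.array([0.0, 1.0, 0.0]),        # anterior, dorsal fronto-parietal
    "SLF_II": np.array([0.0, 0.0, 1.0]),       # superior
    "SLF_III": np.array([1.0, 0.0, 0.0]),      # lateral
    "CINGULUM": np.array([0.0, -1.0, 0.0]),    # posterior, adjacent to CSv
    # toward/through the midline, tilted off -x so its far end stays clear of
    # the contralateral CSv blob
    "CALLOSAL": np.array([-4.0, 1.0, 0.0]) / np.sqrt(17.0),
    "AF": np.array([1.0, -1.0, -1.0]) / np.sqrt(3.0),
    "CST": np.array([0.0, 0.0, -1.0]),         # inferior, two waypoints
}


def default_bundles(hub: np.ndarray, n_streamlines: int = 30,
                    radius: float = 2.0) -> list[BundleSpec]:
    """Seven straight spoke bundles radiating from ``hub`` (near right CSv)."""
    hub = np.asarray(hub, dtype=float)
    bundles = []
    for name in TRACTS:
        u = _SPOKE_DIRECTIONS[name]
        s = np.arange(7.0, 35.0 + 1e-9, 1.0)
        centreline = hub + s[:, None] * u
        waypoints = (14.0, 27.0) if name == "CST" else ((24.0,) if name == "AF" else (18.0,))
        # arclengths are measured from the centreline start at s = 7 mm
        waypoints = tuple(w - 7.0 for w in waypoints)
        bundles.append(BundleSpec(name=name, centreline=centreline, radius=radius,
                                  n_streamlines=n_streamlines,
                                  waypoint_arclengths=waypoints))
    return bundles


def default_phantom_spec(seed: int = 0, n_streamlines: int = 30,
                         snr: float = np.inf, **overrides) -> PhantomSpec:
    """The default two-hemisphere scene: all bundles near the right CSv."""
    csv_centres = {"right": np.array([15.0, 1.0, 9.0]),
                   "left": np.array([-15.0, 1.0, 9.0])}
    bundles = default_bundles(csv_centres["right"], n_streamlines=n_streamlines)
    return PhantomSpec(bundles=bundles, csv_centres=csv_centres, seed=seed,
                       snr=snr, **overrides)


def make_gradient_table(n_directions: int = 64, bvalue: float = 1000.0,
                        n_b0: int = 6) -> GradientTable:
    """Deterministic quasi-uniform gradient scheme (spiral on the sphere)."""
    i = np.arange(n_directions)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - (i + 0.5) / n_directions          # upper hemisphere suffices
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    theta = golden * i
    dirs = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, bvalue)])
    return GradientTable(bvecs=bvecs, bvals=bvals)


# --------------------------------------------------------------------------
# phantom container
# --------------------------------------------------------------------------

@dataclass
class Phantom:
    spec: PhantomSpec
    grid: VolumeGrid                              # empty reference grid
    truth_streamlines: StreamlineSet              # labels = bundle names
    csv_proximal: np.ndarray                      # bool per truth streamline
    csv_masks: dict[str, BinaryMask]              # hemisphere -> mask
    waypoint_rois: dict[str, BinaryMask]          # ROI name -> mask
    roi_names_by_tract: dict[str, tuple[str, ...]]
    orientation_dirs: np.ndarray                  # (X, Y, Z, K, 3) unit sticks
    orientation_fracs: np.ndarray                 # (X, Y, Z, K)
    free_water: np.ndarray                        # (X, Y, Z) isotropic fraction
    wm_mask: BinaryMask
    gtab: GradientTable
    signal: VolumeGrid | None = None

    def tract_definitions(self, hemisphere: str = "right") -> list[TractDefinition]:
        defs = []
        for tract, roi_names in self.roi_names_by_tract.items():
            defs.append(TractDefinition(name=tract, required_rois=roi_names,
                                        hemisphere=hemisphere))
        return defs


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def _unit_perp_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


def _box_mask(spec: PhantomSpec, centre: np.ndarray, half_mm: float) -> np.ndarray:
    shape = spec.grid_shape
    aff = spec.affine
    idx = np.indices(shape).reshape(3, -1).T
    centres = idx @ aff[:3, :3].T + aff[:3, 3]
    inside = np.all(np.abs(centres - centre) <= half_mm + 1e-9, axis=1)
    return inside.reshape(shape)


def _mask_surface_distance(a: np.ndarray, b: np.ndarray, spec: PhantomSpec) -> float:
    """Minimum world distance between true-voxel centres of two masks."""
    aff = spec.affine
    pa = np.argwhere(a) @ aff[:3, :3].T + aff[:3, 3]
    pb = np.argwhere(b) @ aff[:3, :3].T + aff[:3, 3]
    from scipy.spatial import cKDTree
    return float(cKDTree(pa).query(pb)[0].min())


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Build the full scene deterministically from ``spec`` (and its seed)."""
    rng = np.random.default_rng(spec.seed)
    aff = spec.affine
    shape = tuple(spec.grid_shape)
    lo, hi = spec.world_bounds()
    grid = VolumeGrid(np.zeros(shape, dtype=np.float32), aff)

    for b in spec.bundles:
        if np.any(b.centreline < lo) or np.any(b.centreline > hi):
            raise PhantomError(f"bundle {b.name} centreline leaves the grid")
    for h, c in spec.csv_centres.items():
        if np.any(c < lo) or np.any(c > hi):
            raise PhantomError(f"CSv centre for {h} hemisphere outside the grid")

    # ---- CSv masks: small voxel blocks at the stated centres
    csv_masks: dict[str, BinaryMask] = {}
    half_block = 0.5 * (spec.csv_mask_voxels - 1) * spec.voxel_size
    for hemi, centre in spec.csv_centres.items():
        data = _box_mask(spec, centre, half_block + 1e-6)
        csv_masks[hemi] = BinaryMask(VolumeGrid(data, aff), name=f"CSv_{hemi}",
                                     hemisphere=hemi)

    # ---- waypoint ROIs, with enforced geometric separation
    waypoint_rois: dict[str, BinaryMask] = {}
    roi_names_by_tract: dict[str, tuple[str, ...]] = {}
    for b in spec.bundles:
        names = []
        for w, arclength in enumerate(b.waypoint_arclengths):
            pts = resample_polyline(b.centreline, 0.5)
            seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            s = np.concatenate([[0.0], np.cumsum(seg)])
            centre = np.array([np.interp(arclength, s, pts[:, k]) for k in range(3)])
            data = _box_mask(spec, centre, spec.roi_half_mm)
            if not data.any():
                raise PhantomError(f"waypoint ROI for {b.name} falls outside the grid")
            roi_name = b.name if len(b.waypoint_arclengths) == 1 else \
                f"{b.name}_{'inferior' if w == 1 else 'superior'}"
            waypoint_rois[roi_name] = BinaryMask(VolumeGrid(data, aff),
                                                 name=roi_name, hemisphere="midline")
            names.append(roi_name)
        if names:
            roi_names_by_tract[b.name] = tuple(names)

    min_gap = 2.0 * spec.voxel_size
    roi_items = list(waypoint_rois.items())
    for i in range(len(roi_items)):
        for j in range(i + 1, len(roi_items)):
            d = _mask_surface_distance(roi_items[i][1].grid.data,
                                       roi_items[j][1].grid.data, spec)
            if d <= min_gap:
                raise PhantomError(
                    f"waypoint ROIs {roi_items[i][0]} and {roi_items[j][0]} are "
                    f"{d:.1f} mm apart (need > {min_gap:.1f} mm)")

    # ---- streamlines
    streamlines: list[Streamline] = []
    labels: list[str] = []
    proximal_flags: list[bool] = []
    hub_by_bundle: dict[str, np.ndarray] = {}
    for b in spec.bundles:
        # hemisphere hub: the CSv centre nearest the centreline start
        start = b.centreline[0]
        hub = min(spec.csv_centres.values(),
                  key=lambda c: np.linalg.norm(start - c))
        hub_by_bundle[b.name] = hub
        centre_pts = resample_polyline(b.centreline, 1.0)
        tangent = centre_pts[-1] - centre_pts[0]
        tangent /= np.linalg.norm(tangent)
        e1, e2 = _unit_perp_basis(tangent)
        n_reroute = int(round(spec.reroute_fraction * b.n_streamlines))
        for i in range(b.n_streamlines):
            r = b.radius * np.sqrt(rng.uniform())
            phi = rng.uniform(0.0, 2.0 * np.pi)
            offset = r * (np.cos(phi) * e1 + np.sin(phi) * e2)
            pts = centre_pts + offset
            if i < n_reroute:
                # terminate at the CSv end: prepend a short tail into the blob
                q = hub + rng.normal(size=3) * 0.4
                q = hub + (q - hub) / max(np.linalg.norm(q - hub) / 1.2, 1.0)
                tail = np.linspace(q, pts[0], 8)[:-1]
                pts = np.vstack([tail, pts])
            streamlines.append(Streamline(pts, provenance="truth"))
            labels.append(b.name)
            proximal_flags.append(i < n_reroute)
    truth = StreamlineSet(streamlines, labels=labels)
    csv_proximal = np.asarray(proximal_flags, dtype=bool)

    # ---- verify the by-construction separability invariant
    for sl, label in zip(truth, truth.labels or []):
        for tract, roi_names in roi_names_by_tract.items():
            crosses = [passes_roi(sl, waypoint_rois[r]) for r in roi_names]
            if tract == label and not all(crosses):
                raise PhantomError(f"{label} streamline misses its own waypoint ROI")
            if tract != label and any(crosses):
                raise PhantomError(f"{label} streamline crosses a {tract} ROI")

    # ---- per-voxel stick orientation field from streamline tangents
    dirs_acc: dict[tuple[int, int, int], dict[str, np.ndarray]] = {}
    inv = np.linalg.inv(aff)
    for sl, label in zip(truth, truth.labels or []):
        pts = resample_polyline(sl.points, 0.5 * spec.voxel_size)
        mids = 0.5 * (pts[:-1] + pts[1:])
        tans = np.diff(pts, axis=0)
        tans /= np.linalg.norm(tans, axis=1, keepdims=True)
        vox = np.rint(mids @ inv[:3, :3].T + inv[:3, 3]).astype(int)
        ok = np.all((vox >= 0) & (vox < np.asarray(shape)), axis=1)
        for v, t in zip(vox[ok], tans[ok]):
            key = tuple(v)
            bucket = dirs_acc.setdefault(key, {})
            if label in bucket:
                prev = bucket[label]
                t = t if prev @ t >= 0 else -t   # antipodal alignment
                bucket[label] = prev + t
            else:
                bucket[label] = t.copy()

    k_max = max((len(v) for v in dirs_acc.values()), default=1)
    orientation_dirs = np.zeros(shape + (k_max, 3))
    orientation_fracs = np.zeros(shape + (k_max,))
    free_water = np.ones(shape)
    for key, bucket in dirs_acc.items():
        sticks = list(bucket.values())
        wm_frac = 1.0 - spec.wm_free_water
        for k, v in enumerate(sticks):
            orientation_dirs[key + (k,)] = v / np.linalg.norm(v)
            orientation_fracs[key + (k,)] = wm_frac / len(sticks)
        free_water[key] = spec.wm_free_water
    wm_data = orientation_fracs.sum(axis=-1) > 0
    wm_mask = BinaryMask(VolumeGrid(wm_data, aff), name="wm", hemisphere="midline")

    gtab = make_gradient_table(spec.n_directions, spec.bvalue, spec.n_b0)
    phantom = Phantom(spec=spec, grid=grid, truth_streamlines=truth,
                      csv_proximal=csv_proximal, csv_masks=csv_masks,
                      waypoint_rois=waypoint_rois,
                      roi_names_by_tract=roi_names_by_tract,
                      orientation_dirs=orientation_dirs,
                      orientation_fracs=orientation_fracs,
                      free_water=free_water, wm_mask=wm_mask, gtab=gtab)
    if spec.simulate_signal:
        phantom.signal = simulate_dwi(phantom, gtab, snr=spec.snr, seed=spec.seed)
    return phantom


# --------------------------------------------------------------------------
# diffusion signal
# --------------------------------------------------------------------------

def simulate_dwi(phantom: Phantom, gtab: GradientTable | None = None,
                 snr: float | None = None, seed: int = 0,
                 noise_model: str = "rician") -> VolumeGrid:
    """Multi-stick forward model with an isotropic free-water compartment.

    Per voxel, S(g, b) = S0 * [sum_k f_k exp(-b d_ax (g.t_k)^2)
    + f_iso exp(-b d_iso)].  Noise is Rician, |S + N(0, sigma) + i N(0, sigma)|
    with sigma = S0/snr (``noise_model="gaussian"`` adds the real part only);
    the signal is noiseless when snr is infinite.
    """
    spec = phantom.spec
    gtab = gtab or phantom.gtab
    snr = spec.snr if snr is None else snr
    fr = phantom.orientation_fracs
    total = fr.sum(axis=-1) + phantom.free_water
    if not np.allclose(total, 1.0, atol=1e-9):
        raise ValidationError("per-voxel compartment fractions must sum to 1")

    shape = fr.shape[:3]
    n_vol = len(gtab)
    signal = np.empty(shape + (n_vol,), dtype=float)
    flat_dirs = phantom.orientation_dirs.reshape(-1, fr.shape[-1], 3)
    flat_fr = fr.reshape(-1, fr.shape[-1])
    flat_fw = phantom.free_water.reshape(-1)
    for m in range(n_vol):
        b = gtab.bvals[m]
        g = gtab.bvecs[m]
        dots = flat_dirs @ g
        e = (flat_fr * np.exp(-b * spec.d_ax * dots ** 2)).sum(axis=1)
        e += flat_fw * np.exp(-b * spec.d_iso)
        signal[..., m] = (spec.s0 * e).reshape(shape)

    if np.isfinite(snr):
        if snr <= 0:
            raise ValidationError("snr must be positive")
        rng = np.random.default_rng(seed)
        sigma = spec.s0 / snr
        if noise_model == "rician":
            re = signal + rng.normal(0.0, sigma, signal.shape)
            im = rng.normal(0.0, sigma, signal.shape)
            signal = np.sqrt(re ** 2 + im ** 2)
        elif noise_model == "gaussian":
            signal = signal + rng.normal(0.0, sigma, signal.shape)
        else:
            raise ValidationError(f"unknown noise model {noise_model!r}")
    return VolumeGrid(signal, spec.affine)


# --------------------------------------------------------------------------
# candidate streamlines
# --------------------------------------------------------------------------

MIN_LENGTH_MM = 4.0
MAX_LENGTH_MM = 250.0


def generate_candidates(phantom: Phantom, n_true: int, n_spurious: int,
                        seed: int = 0, jitter_mm: float = 0.2) -> StreamlineSet:
    """A shuffled mix of jittered true-bundle members and random-walk distractors.

    True candidates are subsampled copies of the truth set with small Gaussian
    jitter; distractors are persistent random walks through the bundle region
    whose local orientations are decorrelated from the stick field.  Every
    candidate respects the [4, 250] mm length bounds, carries one of the four
    curvature-setting provenance tags, and keeps its ground-truth label
    (bundle name, or "SPURIOUS").
    """
    if n_true < 0 or n_spurious < 0:
        raise ValidationError("candidate counts must be >= 0")
    rng = np.random.default_rng(seed)
    spec = phantom.spec
    truth = phantom.truth_streamlines
    streamlines: list[Streamline] = []
    labels: list[str] = []

    if n_true > 0:
        if len(truth) == 0:
            raise ValidationError("phantom has no truth streamlines to sample")
        replace = n_true > len(truth)
        idx = rng.choice(len(truth), size=n_true, replace=replace)
        idx.sort()
        for i in idx:
            pts = truth[int(i)].points + rng.normal(0.0, jitter_mm,
                                                    truth[int(i)].points.shape)
            streamlines.append(Streamline(pts))
            labels.append((truth.labels or [""] * len(truth))[int(i)])

    lo, hi = spec.world_bounds()
    margin = 2.0 * spec.voxel_size
    csv_centres = list(spec.csv_centres.values())
    if n_spurious > 0:
        all_pts = np.vstack([sl.points for sl in truth]) if len(truth) else \
            np.array([lo + margin, hi - margin])
        bb_lo, bb_hi = all_pts.min(axis=0), all_pts.max(axis=0)
        for _ in range(n_spurious):
            for _attempt in range(200):
                pts = _random_walk(rng, bb_lo, bb_hi, lo + margin, hi - margin)
                ends = pts[[0, -1]]
                if csv_centres and min(
                        np.linalg.norm(e - c) for e in ends for c in csv_centres) < 7.0:
                    continue
                break
            else:
                raise PhantomError("could not place a distractor away from CSv")
            streamlines.append(Streamline(pts))
            labels.append("SPURIOUS")

    order = rng.permutation(len(streamlines))
    streamlines = [streamlines[i] for i in order]
    labels = [labels[i] for i in order]
    for i, sl in enumerate(streamlines):
        sl.provenance = ANGLE_LABELS[i % len(ANGLE_LABELS)]
        if not (MIN_LENGTH_MM <= sl.length <= MAX_LENGTH_MM):
            raise PhantomError("candidate violates the [4, 250] mm length bounds")
    return StreamlineSet(streamlines, labels=labels)


def _random_walk(rng: np.random.Generator, bb_lo: np.ndarray, bb_hi: np.ndarray,
                 lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Persistent random walk, 1-mm steps, reflected at the grid margins."""
    n_steps = int(rng.integers(15, 41))
    p = rng.uniform(bb_lo, bb_hi)
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    pts = [p.copy()]
    for _ in range(n_steps):
        d = d + 0.35 * rng.normal(size=3)
        d /= np.linalg.norm(d)
        p = p + d
        for ax in range(3):
            if p[ax] < lo[ax] or p[ax] > hi[ax]:
                d[ax] = -d[ax]
                p[ax] = np.clip(p[ax], lo[ax], hi[ax])
        pts.append(p.copy())
    return np.asarray(pts)


# --------------------------------------------------------------------------
# persistence
# --------------------------------------------------------------------------

def save_phantom(phantom: Phantom, out_dir: str | Path) -> Path:
    """Persist a phantom as NIfTI masks/signal + TCK truth + JSON spec."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for hemi, mask in phantom.csv_masks.items():
        write_volume(mask.grid, out / f"csv_{hemi}.nii.gz")
    for name, mask in phantom.waypoint_rois.items():
        write_volume(mask.grid, out / f"roi_{name}.nii.gz")
    write_volume(phantom.wm_mask.grid, out / "wm_mask.nii.gz")
    if phantom.signal is not None:
        write_volume(phantom.signal, out / "dwi.nii.gz")
    write_gradient_table(phantom.gtab, out / "dwi.bval", out / "dwi.bvec")
    write_streamlines(phantom.truth_streamlines, out / "truth.tck")
    spec = phantom.spec
    meta = {
        "grid_shape": list(spec.grid_shape),
        "voxel_size": spec.voxel_size,
        "seed": spec.seed,
        "snr": None if np.isinf(spec.snr) else spec.snr,
        "reroute_fraction": spec.reroute_fraction,
        "csv_centres": {h: list(map(float, c)) for h, c in spec.csv_centres.items()},
        "bundles": [{"name": b.name, "n_streamlines": b.n_streamlines,
                     "radius": b.radius} for b in spec.bundles],
        "roi_names_by_tract": {k: list(v) for k, v in phantom.roi_names_by_tract.items()},
        "csv_proximal": phantom.csv_proximal.astype(int).tolist(),
    }
    (out / "phantom.json").write_text(json.dumps(meta, indent=2))
    return out
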