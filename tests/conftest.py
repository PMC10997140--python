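import numpy as np
import pytest

import csvtract as ct


@pytest.fixture(scope="session")
def default_phantom():
    """The default 7-bundle scene, geometry only (no diffusion signal)."""
    spec = ct.default_phantom_spec(seed=0, simulate_signal=False)
    return ct.generate_phantom(spec)


@pytest.fixture(scope="session")
def signal_phantom():
    """Default scene with noiseless stick-model diffusion signal."""
    spec = ct.default_phantom_spec(seed=0)
    return ct.generate_phantom(spec)


def make_random_mask(rng, shape=(20, 20, 20), voxel=2.0, n_blobs=3):
    """A random multi-blob boolean mask on a centred axis-aligned grid."""
    affine = np.diag([voxel, voxel, voxel, 1.0])
    affine[:3, 3] = -0.5 * (np.asarray(shape) - 1) * voxel
    data = np.zeros(shape, dtype=bool)
    for _ in range(n_blobs):
        c = rng.integers(2, np.asarray(shape) - 2)
        r = int(rng.integers(1, 3))
        sl = tuple(slice(max(0, c[k] - r), c[k] + r + 1) for k in range(3))
        data[sl] = True
    return ct.BinaryMask(ct.VolumeGrid(data, affine), name="random")


def make_random_streamline(rng, span=40.0, n_points=12):
    pts = np.cumsum(rng.normal(0.0, 3.0, (n_points, 3)), axis=0)
    pts += rng.uniform(-span / 2, span / 2, 3)
    return ct.Streamline(pts)


# ---------------------------------------------------------------------------
# independent oracles (plain, loop-based; no shared code with the package)
# ---------------------------------------------------------------------------

def brute_force_endpoint_distance(streamline, mask):
    """Double loop over (endpoint, true-voxel centre) pairs."""
    import math
    best = math.inf
    aff = mask.grid.affine
    for end in (streamline.points[0], streamline.points[-1]):
        for ijk in np.argwhere(mask.grid.data):
            c = aff[:3, :3] @ ijk + aff[:3, 3]
            best = min(best, math.dist(end, c))
    return best


def _segment_hits_box(p0, p1, lo, hi):
    """Scalar slab clipping of one segment against one axis-aligned box."""
    tmin, tmax = 0.0, 1.0
    for ax in range(3):
        d = p1[ax] - p0[ax]
        if abs(d) < 1e-12:
            if p0[ax] < lo[ax] or p0[ax] > hi[ax]:
                return False
            continue
        a = (lo[ax] - p0[ax]) / d
        b = (hi[ax] - p0[ax]) / d
        if a > b:
            a, b = b, a
        tmin = max(tmin, a)
        tmax = min(tmax, b)
        if tmin > tmax:
            return False
    return True


def oracle_passes_roi(streamline, roi):
    """Exact segment/voxel-box intersection by explicit loops."""
    aff = roi.grid.affine
    half = 0.5 * roi.grid.voxel_size
    boxes = []
    for ijk in np.argwhere(roi.grid.data):
        c = aff[:3, :3] @ ijk + aff[:3, 3]
        boxes.append((c - half, c + half))
    pts = streamline.points
    for s in range(len(pts) - 1):
        for lo, hi in boxes:
            if _segment_hits_box(pts[s], pts[s + 1], lo, hi):
                return True
    return False


def oracle_nnls(design, target):
    """Exhaustive active-set enumeration: best feasible support solution."""
    import itertools
    n = design.shape[1]
    best_obj, best_w = 0.5 * float(target @ target), np.zeros(n)
    for r in range(1, n + 1):
        for support in itertools.combinations(range(n), r):
            sub = design[:, support]
            x, *_ = np.linalg.lstsq(sub, target, rcond=None)
            if np.any(x < -1e-12):
                continue
            w = np.zeros(n)
            w[list(support)] = np.clip(x, 0.0, None)
            obj = 0.5 * float(np.sum((target - design @ w) ** 2))
            if obj < best_obj - 1e-15:
                best_obj, best_w = obj, w
    return best_w, best_obj
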