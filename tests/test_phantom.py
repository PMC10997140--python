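import numpy as np
import pytest

import csvtract as ct
from csvtract.phantom import ANGLE_LABELS, Phantom, PhantomError, PhantomSpec

from conftest import oracle_passes_roi


def _one_bundle_spec(seed, n=50):
    csv_centres = {"right": np.array([15.0, 1.0, 9.0])}
    bundles = ct.default_phantom_spec().bundles[:1]
    bundles[0].n_streamlines = n
    return PhantomSpec(bundles=bundles, csv_centres=csv_centres, seed=seed,
                       simulate_signal=False)


def test_determinism_same_seed_identical():
    a = ct.generate_phantom(_one_bundle_spec(7))
    b = ct.generate_phantom(_one_bundle_spec(7))
    assert len(a.truth_streamlines) == len(b.truth_streamlines) == 50
    for sa, sb in zip(a.truth_streamlines, b.truth_streamlines):
        np.testing.assert_array_equal(sa.points, sb.points)
    np.testing.assert_array_equal(a.orientation_dirs, b.orientation_dirs)


def test_labels_partition_and_roi_exclusivity(default_phantom):
    ph = default_phantom
    labels = ph.truth_streamlines.labels
    assert len(labels) == 7 * 30
    assert sorted(set(labels)) == sorted(ct.TRACTS)
    # each bundle's streamlines intersect exactly its own ROI set (oracle check)
    for sl, label in zip(ph.truth_streamlines, labels):
        for tract, roi_names in ph.roi_names_by_tract.items():
            hits = [oracle_passes_roi(sl, ph.waypoint_rois[r]) for r in roi_names]
            if tract == label:
                assert all(hits), f"{label} streamline misses its own ROI"
            else:
                assert not any(hits), f"{label} streamline crosses a {tract} ROI"


def test_cst_two_roi_rule_by_construction(default_phantom):
    ph = default_phantom
    labels = np.asarray(ph.truth_streamlines.labels)
    cst = np.flatnonzero(labels == "CST")
    cing = np.flatnonzero(labels == "CINGULUM")
    for i in cst:
        assert ct.passes_roi(ph.truth_streamlines[i], ph.waypoint_rois["CST_superior"])
        assert ct.passes_roi(ph.truth_streamlines[i], ph.waypoint_rois["CST_inferior"])
    for i in cing:
        assert not ct.passes_roi(ph.truth_streamlines[i], ph.waypoint_rois["CST_superior"])
        assert not ct.passes_roi(ph.truth_streamlines[i], ph.waypoint_rois["CST_inferior"])


def test_roi_separation_exceeds_two_voxels(default_phantom):
    from scipy.spatial import cKDTree
    ph = default_phantom
    min_gap = 2.0 * ph.spec.voxel_size
    names = list(ph.waypoint_rois)
    for i, a in enumerate(names):
        pa = ph.waypoint_rois[a].voxel_centres_world()
        ta = cKDTree(pa)
        for b in names[i + 1:]:
            pb = ph.waypoint_rois[b].voxel_centres_world()
            assert ta.query(pb)[0].min() > min_gap


def test_reroute_fraction_controls_csv_proximity(default_phantom):
    ph = default_phantom
    assert ph.csv_proximal.sum() == 7 * round(0.3 * 30)
    mask = ph.csv_masks["right"]
    for i, sl in enumerate(ph.truth_streamlines):
        d = ct.endpoint_distance(sl, mask)
        if ph.csv_proximal[i]:
            assert d <= 3.0
        else:
            assert d > 3.0


def test_overlapping_waypoint_rois_rejected():
    spec = ct.default_phantom_spec(simulate_signal=False)
    # drag two bundles onto the same spoke so their ROIs collide
    spec.bundles[1].centreline = spec.bundles[0].centreline.copy()
    with pytest.raises(PhantomError):
        ct.generate_phantom(spec)


def _stick_phantom(sticks, fracs, free_water, d_ax=1.0e-3, d_iso=3.0e-3, s0=1.0):
    """Minimal 1-voxel phantom around a prescribed orientation field."""
    spec = PhantomSpec(grid_shape=(1, 1, 1), voxel_size=2.0, bundles=[],
                       csv_centres={}, d_ax=d_ax, d_iso=d_iso, s0=s0,
                       simulate_signal=False)
    k = len(sticks) if sticks else 1
    dirs = np.zeros((1, 1, 1, k, 3))
    fr = np.zeros((1, 1, 1, k))
    for i, (t, f) in enumerate(zip(sticks, fracs)):
        dirs[0, 0, 0, i] = t
        fr[0, 0, 0, i] = f
    fw = np.full((1, 1, 1), free_water)
    grid = ct.VolumeGrid(np.zeros((1, 1, 1), np.float32), spec.affine)
    dummy_mask = ct.BinaryMask(ct.VolumeGrid(np.ones((1, 1, 1), bool), spec.affine),
                               name="wm")
    gtab = ct.make_gradient_table(64, 1000.0, 1)
    return Phantom(spec=spec, grid=grid,
                   truth_streamlines=ct.StreamlineSet([]),
                   csv_proximal=np.zeros(0, bool), csv_masks={},
                   waypoint_rois={}, roi_names_by_tract={},
                   orientation_dirs=dirs, orientation_fracs=fr,
                   free_water=fw, wm_mask=dummy_mask, gtab=gtab)


def test_stick_model_closed_form():
    ph = _stick_phantom([(0.0, 0.0, 1.0)], [1.0], 0.0)
    gtab = ct.GradientTable(np.array([[0.0, 0, 0], [0, 0, 1.0], [1.0, 0, 0]]),
                            np.array([0.0, 1000.0, 1000.0]))
    sig = ct.simulate_dwi(ph, gtab, snr=np.inf)
    s = sig.data[0, 0, 0]
    assert s[1] == pytest.approx(np.exp(-1.0), abs=1e-12)   # parallel: exp(-b d)
    assert s[2] == pytest.approx(1.0, abs=1e-12)            # orthogonal: none


def test_isotropic_voxel_has_direction_independent_signal():
    ph = _stick_phantom([(0.0, 0.0, 1.0)], [0.0], 1.0)
    sig = ct.simulate_dwi(ph, snr=np.inf)
    dw = sig.data[0, 0, 0][ph.gtab.dwi_mask]
    assert dw.std() < 1e-12


def test_bad_fractions_rejected():
    ph = _stick_phantom([(0.0, 0.0, 1.0)], [0.7], 0.0)   # sums to 0.7
    with pytest.raises(ct.ValidationError):
        ct.simulate_dwi(ph)


def test_noise_seeded_and_rician_positive():
    ph = _stick_phantom([(0.0, 0.0, 1.0)], [1.0], 0.0, s0=100.0)
    a = ct.simulate_dwi(ph, snr=10.0, seed=5)
    b = ct.simulate_dwi(ph, snr=10.0, seed=5)
    c = ct.simulate_dwi(ph, snr=10.0, seed=6)
    np.testing.assert_array_equal(a.data, b.data)
    assert not np.array_equal(a.data, c.data)
    assert np.all(a.data >= 0)


def test_candidates_counts_lengths_and_tags(default_phantom):
    empty = ct.generate_candidates(default_phantom, 0, 0, seed=1)
    assert len(empty) == 0
    cands = ct.generate_candidates(default_phantom, 200, 200, seed=1)
    assert len(cands) == 400
    for sl in cands:
        assert 4.0 <= sl.length <= 250.0
        assert sl.provenance in ANGLE_LABELS
    labels = np.asarray(cands.labels)
    assert (labels == "SPURIOUS").sum() == 200


def test_spurious_orientations_decorrelated(default_phantom):
    """Distractor tangents align worse with the stick field than true ones."""
    ph = default_phantom
    cands = ct.generate_candidates(ph, 150, 150, seed=2)
    inv = np.linalg.inv(ph.spec.affine)
    shape = np.asarray(ph.spec.grid_shape)

    def mean_abs_cos(sl):
        pts = sl.points
        mids = 0.5 * (pts[:-1] + pts[1:])
        tans = np.diff(pts, axis=0)
        tans /= np.linalg.norm(tans, axis=1, keepdims=True)
        vox = np.rint(mids @ inv[:3, :3].T + inv[:3, 3]).astype(int)
        ok = np.all((vox >= 0) & (vox < shape), axis=1)
        vals = []
        for v, t in zip(vox[ok], tans[ok]):
            fr = ph.orientation_fracs[tuple(v)]
            if fr.sum() <= 0:
                continue
            k = int(np.argmax(fr))
            vals.append(abs(ph.orientation_dirs[tuple(v)][k] @ t))
        return np.mean(vals) if vals else np.nan

    cos_true = [mean_abs_cos(sl) for sl, lab in zip(cands, cands.labels)
                if lab != "SPURIOUS"]
    cos_spur = [mean_abs_cos(sl) for sl, lab in zip(cands, cands.labels)
                if lab == "SPURIOUS"]
    assert np.nanmean(cos_spur) < np.nanmean(cos_true)


def test_candidate_determinism(default_phantom):
    a = ct.generate_candidates(default_phantom, 50, 50, seed=9)
    b = ct.generate_candidates(default_phantom, 50, 50, seed=9)
    for sa, sb in zip(a, b):
        np.testing.assert_array_equal(sa.points, sb.points)
    assert a.labels == b.labels


def test_save_phantom_round_trips_key_artifacts(tmp_path, default_phantom):
    from csvtract.phantom import save_phantom
    out = save_phantom(default_phantom, tmp_path / "ph")
    truth = ct.read_streamlines(out / "truth.tck")
    assert len(truth) == len(default_phantom.truth_streamlines)
    mask = ct.read_volume(out / "csv_right.nii.gz")
    assert mask.data.astype(bool).sum() == default_phantom.csv_masks["right"].n_voxels
    import json
    meta = json.loads((out / "phantom.json").read_text())
    assert meta["seed"] == 0 and len(meta["bundles"]) == 7
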