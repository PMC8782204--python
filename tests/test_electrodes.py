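import numpy as np
import pytest

from seegquake.config import RunConfig
from seegquake.electrodes import (
    ElectrodeLocator,
    PointCloud,
    center_of_mass_converge,
    cluster_electrodes,
    extract_bright_voxels,
    find_head_point,
    fit_shaft_axis,
    geometry_qc,
    hough_lines_3d,
    icosphere_directions,
    resolve_threshold,
    segment_contacts,
    ContactSet,
)
from seegquake.errors import EmptyCloudError, NoMassError
from seegquake.io import Volume
from tests.conftest import gaussian_blob_volume


def _cloud(points, intensities=None):
    points = np.asarray(points, dtype=float)
    if intensities is None:
        intensities = np.ones(len(points))
    return PointCloud(coords=points, intensities=np.asarray(intensities, dtype=float),
                      affine=np.eye(4), threshold=0.0)


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------


class TestThresholding:
    def test_absolute_rule_exhaustive_scan(self):
        rng = np.random.default_rng(0)
        data = np.zeros((20, 20, 20))
        chosen = rng.choice(20 ** 3, size=10, replace=False)
        data.reshape(-1)[chosen] = 1000.0
        vol = Volume(data=data, affine=np.eye(4))
        cloud = extract_bright_voxels(vol, "abs:500")
        expected = np.argwhere(data > 500)  # independent exhaustive scan
        got = cloud.coords[np.lexsort(cloud.coords.T[::-1])]
        exp = expected[np.lexsort(expected.T[::-1])]
        np.testing.assert_array_equal(got, exp.astype(float))

    def test_strict_inequality_at_boundary(self):
        vol = Volume(data=np.full((6, 6, 6), 100.0), affine=np.eye(4))
        with pytest.raises(EmptyCloudError):
            extract_bright_voxels(vol, "abs:100")

    def test_all_zero_volume_errors(self):
        vol = Volume(data=np.zeros((6, 6, 6)), affine=np.eye(4))
        with pytest.raises(EmptyCloudError):
            extract_bright_voxels(vol, "abs:0")
        with pytest.raises(EmptyCloudError):
            extract_bright_voxels(vol, "bright")

    def test_otsu_matches_skimage_on_bimodal(self):
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.normal(100, 10, 4000), rng.normal(900, 50, 4000)])
        vals = np.clip(vals, 1, None)
        vol = Volume(data=vals.reshape(20, 20, 20), affine=np.eye(4))
        ours = resolve_threshold(vol, "otsu")
        ref = threshold_otsu(vals)
        assert abs(ours - ref) < 20  # same inter-mode gap

    def test_percentile_rule(self):
        data = np.arange(1000, dtype=float).reshape(10, 10, 10)
        vol = Volume(data=data, affine=np.eye(4))
        assert resolve_threshold(vol, "p90") == pytest.approx(np.percentile(data, 90))


# ---------------------------------------------------------------------------
# Hough transform
# ---------------------------------------------------------------------------


class TestHough:
    def test_direction_set_is_sign_deduplicated_icosphere(self):
        dirs = icosphere_directions(3)
        assert len(dirs) == 321
        np.testing.assert_allclose(np.linalg.norm(dirs, axis=1), 1.0, atol=1e-9)
        # no antipodal duplicates
        dots = dirs @ dirs.T
        np.testing.assert_array_less(-0.9999, dots[~np.eye(len(dirs), dtype=bool)])

    def test_single_collinear_line(self):
        t = np.arange(50, dtype=float)
        pts = np.stack([t, np.full(50, 10.0), np.full(50, 20.0)], 1)
        lines = hough_lines_3d(_cloud(pts))
        assert len(lines) == 1
        angle = np.degrees(np.arccos(min(1.0, abs(lines[0].direction @ np.array([1.0, 0, 0])))))
        assert angle < 4.0  # within the direction-bin half-width
        assert lines[0].inliers.size == 50

    def test_two_parallel_lines_recover_generating_sets(self):
        t = np.arange(100, dtype=float)
        a = np.stack([t, np.zeros(100), np.zeros(100)], 1)
        b = a + np.array([0.0, 20.0, 0.0])
        lines = hough_lines_3d(_cloud(np.vstack([a, b])))
        assert len(lines) == 2
        sets = [set(l.inliers.tolist()) for l in lines]
        assert {frozenset(range(100)), frozenset(range(100, 200))} == set(map(frozenset, sets))

    def test_three_nonparallel_lines_match_truth(self):
        from itertools import permutations

        t = np.linspace(0, 60, 80)
        dirs = np.array([[0.9, 0.1, 0.2], [0.1, 1.0, 0.25], [0.3, -0.15, 1.0]])
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        anchors = np.array([[0, 10, 40.0], [40, 0, 0.0], [0, 40, 0.0]])
        clouds = [anchors[i] + t[:, None] * dirs[i] for i in range(3)]
        lines = hough_lines_3d(_cloud(np.vstack(clouds)))
        assert len(lines) == 3
        # brute-force best assignment over all 3! pairings
        best = min(
            max(
                np.degrees(np.arccos(min(1.0, abs(lines[i].direction @ dirs[p[i]]))))
                for i in range(3)
            )
            for p in permutations(range(3))
        )
        assert best < 4.0

    def test_empty_cloud_rejected(self):
        with pytest.raises(EmptyCloudError):
            hough_lines_3d(_cloud(np.zeros((0, 3))))


# ---------------------------------------------------------------------------
# mixture clustering
# ---------------------------------------------------------------------------


def _two_line_cloud(rng, n=120, sep=15.0):
    t = np.linspace(0, 40, n // 2)
    a = np.stack([t, np.zeros_like(t), np.zeros_like(t)], 1) + rng.normal(0, 0.3, (n // 2, 3))
    b = a + np.array([0.0, sep, 0.0])
    labels = np.array([0] * (n // 2) + [1] * (n // 2))
    return np.vstack([a, b]), labels


class TestClustering:
    def test_two_separated_lines_fully_recovered(self):
        rng = np.random.default_rng(0)
        pts, labels = _two_line_cloud(rng)
        cloud = _cloud(pts)
        lines = hough_lines_3d(cloud)
        clusters = cluster_electrodes(cloud, lines, seed=0)
        assert len(clusters) == 2
        pred = np.empty(len(pts), dtype=int)
        for c in clusters:
            pred[c.member_indices] = c.label
        # oracle: nearest generating line
        acc = max(np.mean(pred == labels), np.mean(pred == 1 - labels))
        assert acc == 1.0

    def test_single_line_single_component(self):
        t = np.arange(30, dtype=float)
        pts = np.stack([t, t * 0.2, np.zeros(30)], 1)
        cloud = _cloud(pts)
        lines = hough_lines_3d(cloud)
        clusters = cluster_electrodes(cloud, lines[:1], seed=0)
        assert len(clusters) == 1
        assert clusters[0].member_indices.size == 30

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        pts, _ = _two_line_cloud(rng)
        cloud = _cloud(pts)
        lines = hough_lines_3d(cloud)
        c1 = cluster_electrodes(cloud, lines, seed=42)
        c2 = cluster_electrodes(cloud, lines, seed=42)
        for a, b in zip(c1, c2):
            np.testing.assert_array_equal(a.member_indices, b.member_indices)

    def test_cloud_row_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        pts, _ = _two_line_cloud(rng)
        perm = rng.permutation(len(pts))
        c_orig = cluster_electrodes(_cloud(pts), hough_lines_3d(_cloud(pts)), seed=0)
        c_perm = cluster_electrodes(_cloud(pts[perm]), hough_lines_3d(_cloud(pts[perm])), seed=0)
        sets_orig = {frozenset(c.member_indices.tolist()) for c in c_orig}
        sets_perm = {frozenset(perm[c.member_indices].tolist()) for c in c_perm}
        assert sets_orig == sets_perm


class TestShaftAxis:
    def test_exact_line_zero_residual(self):
        t = np.arange(40, dtype=float)
        pts = np.stack([t, 2 * t, -t], 1)
        cloud = _cloud(pts)
        lines = hough_lines_3d(cloud)
        clusters = cluster_electrodes(cloud, lines[:1], seed=0)
        point, direction, rms = fit_shaft_axis(clusters[0], cloud)
        assert rms < 1e-9
        truth = np.array([1.0, 2.0, -1.0]) / np.sqrt(6)
        assert abs(direction @ truth) > 1 - 1e-9

    def test_jittered_line_direction_within_one_degree(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 50, 200)
        d = np.array([0.6, 0.64, 0.48])
        d /= np.linalg.norm(d)
        pts = t[:, None] * d + rng.normal(0, 0.1, (200, 3))
        from seegquake.electrodes import _principal_axis

        _, direction, _ = _principal_axis(pts)
        angle = np.degrees(np.arccos(min(1.0, abs(direction @ d))))
        assert angle < 1.0


# ---------------------------------------------------------------------------
# center-of-mass convergence and contact walking
# ---------------------------------------------------------------------------


class TestCenterOfMass:
    def test_single_bright_voxel(self):
        data = np.zeros((16, 16, 16))
        data[8, 8, 8] = 1000.0
        vol = Volume(data=data, affine=np.eye(4))
        c = center_of_mass_converge(vol, np.array([9.0, 8.5, 8.0]), cube_mm=2.0)
        assert np.linalg.norm(c - np.array([8.0, 8.0, 8.0])) < 0.25

    def test_gaussian_blob_matches_brute_force_argmax(self):
        center = np.array([15.0, 16.0, 14.0])  # voxel-center aligned
        vol = gaussian_blob_volume(center)
        start = center + np.array([2.0, 0.0, 0.0])
        c = center_of_mass_converge(vol, start, cube_mm=2.0)
        # oracle: brightest voxel of the rendered image
        argmax = np.array(np.unravel_index(np.argmax(vol.data), vol.shape), dtype=float)
        assert np.linalg.norm(c - argmax) < 0.2

    def test_subvoxel_blob_center_recovered(self):
        center = np.array([15.3, 16.1, 13.8])
        vol = gaussian_blob_volume(center)
        c = center_of_mass_converge(vol, center + np.array([0.0, 2.0, 0.0]), cube_mm=2.0)
        assert np.linalg.norm(c - center) < 0.2

    def test_uniform_region_is_fixed_point(self):
        vol = Volume(data=np.full((20, 20, 20), 50.0), affine=np.eye(4))
        start = np.array([10.0, 10.0, 10.0])
        c = center_of_mass_converge(vol, start, cube_mm=2.0)
        np.testing.assert_allclose(c, start, atol=1e-9)

    def test_massless_region_raises(self):
        vol = Volume(data=np.zeros((16, 16, 16)), affine=np.eye(4))
        with pytest.raises(NoMassError):
            center_of_mass_converge(vol, np.array([8.0, 8.0, 8.0]), cube_mm=2.0)


class TestSegmentation:
    def test_manufacturer_defaults_in_config(self):
        cfg = RunConfig()
        assert cfg.pitch_mm == 3.5
        assert cfg.cube_mm == 2.0

    def test_single_electrode_noiseless_recovery(self):
        from seegquake.synth import ElectrodeSpec, make_volume

        spec = ElectrodeSpec(n_electrodes=1, contacts_min=8, contacts_max=8,
                             noise_sd=0.0)
        vol, truth = make_volume(spec, shape=(100, 100, 100), seed=2)
        loc = ElectrodeLocator().fit(vol)
        assert len(loc.contact_sets_) == 1
        cs = loc.contact_sets_[0]
        assert cs.n_contacts == 8
        d = np.linalg.norm(cs.contacts - truth.contacts[0], axis=1)
        assert d.max() < 0.5

    def test_single_blob_yields_one_contact(self):
        center = np.array([16.0, 16.0, 16.0])
        vol = gaussian_blob_volume(center)
        cloud = extract_bright_voxels(vol, "abs:500")
        from seegquake.electrodes import ElectrodeCluster, _principal_axis

        point, direction, _ = _principal_axis(cloud.coords)
        cluster = ElectrodeCluster(
            label=0, member_indices=np.arange(cloud.n_points),
            centroid=cloud.coords.mean(0), axis_point=point, axis_direction=direction,
        )
        cs = segment_contacts(vol, cluster, cloud)
        assert cs.n_contacts == 1
        assert np.linalg.norm(cs.contacts[0] - center) < 0.3

    def test_head_point_is_near_center_endpoint(self, noiseless_volume):
        vol, truth = noiseless_volume
        cloud = extract_bright_voxels(vol)
        lines = hough_lines_3d(cloud)
        clusters = cluster_electrodes(cloud, lines, seed=0)
        center_mm = vol.voxel_to_mm((np.asarray(vol.shape) - 1) / 2.0)
        for cl in clusters:
            head = vol.voxel_to_mm(find_head_point(cl, cloud, vol))
            # truth electrode whose head is nearest
            t = min(truth.contacts, key=lambda c: np.linalg.norm(c[0] - head))
            assert np.linalg.norm(head - t[0]) < np.linalg.norm(head - t[-1])
            assert np.linalg.norm(t[0] - center_mm) < np.linalg.norm(t[-1] - center_mm)


class TestGeometryQC:
    def test_perfect_geometry_zero_errors(self):
        d = np.array([0.0, 0.0, 1.0])
        pts = np.array([10.0, 10.0, 10.0]) + np.arange(8)[:, None] * 3.5 * d
        qc = geometry_qc([ContactSet(electrode_label=0, contacts=pts, pitch_used=3.5)])
        np.testing.assert_allclose(qc.axis_contact_distances, 0.0, atol=1e-9)
        np.testing.assert_allclose(qc.adjacent_distance_errors, 0.0, atol=1e-9)

    def test_single_displaced_contact_axis_distance(self):
        d = np.array([1.0, 0.0, 0.0])
        pts = np.arange(24, dtype=float)[:, None] * 3.5 * d
        pts[10] += np.array([0.0, 0.5, 0.0])
        qc = geometry_qc([ContactSet(electrode_label=0, contacts=pts, pitch_used=3.5)])
        # closed form: with many contacts the fitted line barely moves
        assert abs(qc.axis_contact_distances[10] - 0.5) < 0.05

    def test_spacing_errors_signed(self):
        pts = np.array([[0, 0, 0], [3.0, 0, 0], [7.0, 0, 0]], dtype=float)
        qc = geometry_qc([ContactSet(electrode_label=0, contacts=pts, pitch_used=3.5)])
        np.testing.assert_allclose(qc.adjacent_distance_errors, [-0.5, 0.5])

    def test_counts_match(self):
        pts = np.arange(5, dtype=float)[:, None] * np.array([3.5, 0, 0])
        qc = geometry_qc([ContactSet(electrode_label=0, contacts=pts, pitch_used=3.5)])
        assert len(qc.axis_contact_distances) == 5
        assert len(qc.adjacent_distance_errors) == 4


# ---------------------------------------------------------------------------
# end-to-end properties
# ---------------------------------------------------------------------------


class TestEndToEnd:
    def test_noiseless_full_recovery_within_half_mm(self, noiseless_volume):
        vol, truth = noiseless_volume
        loc = ElectrodeLocator().fit(vol)
        assert len(loc.contact_sets_) == len(truth.contacts)
        counts_found = sorted(cs.n_contacts for cs in loc.contact_sets_)
        counts_true = sorted(len(c) for c in truth.contacts)
        assert counts_found == counts_true
        truth_all = np.concatenate(truth.contacts)
        for cs in loc.contact_sets_:
            d = np.linalg.norm(cs.contacts[:, None, :] - truth_all[None, :, :], axis=-1)
            assert d.min(axis=1).max() < 0.5

    def test_monotone_projection_invariant(self, small_volume):
        vol, _ = small_volume
        loc = ElectrodeLocator().fit(vol)
        for cs in loc.contact_sets_:
            if cs.n_contacts < 2:
                continue
            d = cs.contacts[-1] - cs.contacts[0]
            d /= np.linalg.norm(d)
            along = (cs.contacts - cs.contacts[0]) @ d
            assert np.all(np.diff(along) > 0)

    def test_bent_electrode_produces_axis_distance_outliers(self):
        from seegquake.synth import ElectrodeSpec, make_volume

        spec = ElectrodeSpec(n_electrodes=2, contacts_min=10, contacts_max=12,
                             bend_amplitude_mm=1.0, noise_sd=0.0)
        vol, _ = make_volume(spec, shape=(120, 120, 120), seed=1)
        loc = ElectrodeLocator().fit(vol)
        assert (loc.qc_.axis_contact_distances > 0.1).any()
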