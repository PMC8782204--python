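"""Electrode localization and contact segmentation from a CT-like volume.

Pipeline: intensity thresholding -> voxel point cloud -> iterative 3D line
Hough transform (votes over a sign-deduplicated icosphere of directions x a
2D anchor grid in the plane orthogonal to each direction) -> Gaussian
mixture clustering seeded from the Hough lines -> per-cluster total
least-squares shaft axis -> head-voxel selection (deepest end, nearer the
brain's center of intensity mass) -> center-of-mass convergence with
fixed-pitch stepping along the shaft -> geometric QC.

All returned contact coordinates are in mm scanner space; internal work on
the cloud is in 0-based voxel indices.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import binary_dilation, map_coordinates
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

from .config import RunConfig
from .errors import (
    DegenerateClusterError,
    EmptyCloudError,
    NoContactsError,
    NoMassError,
)
from .io import Volume

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass
class PointCloud:
    """Voxels above the extraction threshold."""

    coords: np.ndarray        # (N, 3) voxel indices
    intensities: np.ndarray   # (N,)
    affine: np.ndarray        # 4x4 voxel -> mm
    threshold: float          # resolved extraction threshold

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    def to_mm(self) -> np.ndarray:
        return self.coords @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class HoughLine:
    direction: np.ndarray     # unit 3-vector, sign-normalized
    anchor: np.ndarray        # point on the line (voxel coords)
    votes: int
    inliers: np.ndarray       # indices into the PointCloud


@dataclass
class ElectrodeCluster:
    label: int
    member_indices: np.ndarray
    centroid: np.ndarray               # voxel coords
    axis_point: np.ndarray             # voxel coords, on the fitted axis
    axis_direction: np.ndarray         # unit vector (voxel space)
    rms_residual: float = 0.0


@dataclass
class ContactSet:
    electrode_label: int
    contacts: np.ndarray       # (k, 3) mm, head (deepest) first
    pitch_used: float

    @property
    def n_contacts(self) -> int:
        return self.contacts.shape[0]


@dataclass
class GeometryQC:
    """Straightness and spacing metrics of the final contact coordinates."""

    axis_contact_distances: np.ndarray      # pooled, mm
    adjacent_distance_errors: np.ndarray    # pooled, mm (distance - pitch)
    adjacent_distances: np.ndarray          # pooled, mm
    per_electrode: List[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------


def _otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu's between-class-variance maximizer on a value histogram."""
    hist, edges = np.histogram(values, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(float)
    p = w / w.sum()
    omega = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    between[~np.isfinite(between)] = -1.0
    return float(centers[int(np.argmax(between))])


def resolve_threshold(volume: Volume, rule: str) -> float:
    """Resolve a thresholding rule to an intensity value.

    Rules: 'bright' (default; midpoint between the robust background level,
    the median of nonzero voxels, and the robust maximum, their 99.99th
    percentile — electrode voxels being far brighter than everything else,
    any midpoint isolates them across intensity scales), 'otsu' (on nonzero
    voxels; appropriate when bright voxels are a sizable class),
    'p<percentile>', or 'abs:<value>'.
    """
    if rule == "bright":
        nz = volume.data[volume.data > 0]
        if nz.size == 0:
            raise EmptyCloudError("volume has no positive voxels")
        lo = float(np.median(nz))
        hi = float(np.percentile(nz, 99.999))
        if hi <= lo:
            raise EmptyCloudError("no bright voxel class above the background")
        return lo + 0.5 * (hi - lo)
    if rule == "otsu":
        nz = volume.data[volume.data > 0]
        if nz.size == 0:
            raise EmptyCloudError("volume has no positive voxels; cannot run Otsu")
        return _otsu_threshold(nz)
    if rule.startswith("p"):
        return float(np.percentile(volume.data, float(rule[1:])))
    if rule.startswith("abs:"):
        return float(rule[4:])
    raise ValueError(f"unknown threshold rule {rule!r}")


def extract_bright_voxels(volume: Volume, rule: str = "bright") -> PointCloud:
    """Voxels with intensity strictly above the resolved threshold."""
    thr = resolve_threshold(volume, rule)
    mask = volume.data > thr
    if not mask.any():
        raise EmptyCloudError(
            f"no voxel above threshold {thr:.4g}; lower the threshold rule"
        )
    coords = np.argwhere(mask)
    cloud = PointCloud(
        coords=coords.astype(float),
        intensities=volume.data[mask],
        affine=volume.affine,
        threshold=thr,
    )
    logger.info("threshold rule %s -> %.4g; %d voxels extracted", rule, thr, cloud.n_points)
    return cloud


# ---------------------------------------------------------------------------
# 3D line Hough transform
# ---------------------------------------------------------------------------


def icosphere_directions(subdivisions: int = 3) -> np.ndarray:
    """Unit directions = vertices of a repeatedly subdivided icosahedron,
    deduplicated by sign (largest-magnitude component made positive)."""
    phi = (1 + np.sqrt(5)) / 2
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts = [tuple(v) for v in verts]
    for _ in range(subdivisions):
        index = {v: i for i, v in enumerate(verts)}
        cache: dict = {}

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key in cache:
                return cache[key]
            m = np.asarray(verts[i]) + np.asarray(verts[j])
            m /= np.linalg.norm(m)
            m = tuple(m)
            if m not in index:
                index[m] = len(verts)
                verts.append(m)
            cache[key] = index[m]
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (ab, b, bc), (ca, bc, c), (ab, bc, ca)]
        faces = new_faces

    dirs = np.asarray(verts)
    # sign normalization: flip so the largest-|.| component is positive
    idx = np.argmax(np.abs(dirs), axis=1)
    signs = np.sign(dirs[np.arange(len(dirs)), idx])
    dirs = dirs * signs[:, None]
    # deduplicate antipodal pairs
    uniq = np.unique(np.round(dirs, 9), axis=0)
    return uniq


def _plane_basis(d: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def _point_line_distance(points: np.ndarray, anchor: np.ndarray, d: np.ndarray) -> np.ndarray:
    rel = points - anchor
    along = rel @ d
    return np.linalg.norm(rel - along[:, None] * d[None, :], axis=1)


def _principal_axis(points: np.ndarray) -> Tuple[np.ndarray, np.ndarray, float]:
    """Centroid, principal direction, rms perpendicular residual (TLS line)."""
    c = points.mean(axis=0)
    x = points - c
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    d = vt[0]
    i = int(np.argmax(np.abs(d)))
    if d[i] < 0:
        d = -d
    resid = _point_line_distance(points, c, d)
    return c, d, float(np.sqrt((resid ** 2).mean()))


def _trimmed_axis(
    points: np.ndarray, trim_radius: float = 3.0
) -> Tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """TLS line refit once after dropping perpendicular outliers (> trim_radius),
    so the occasional stray bright voxel cannot tilt a shaft axis or extend
    its endpoints.  Returns (point, direction, rms, keep_mask)."""
    c, d, rms = _principal_axis(points)
    keep = _point_line_distance(points, c, d) <= trim_radius
    if 2 <= keep.sum() < points.shape[0]:
        c, d, rms = _principal_axis(points[keep])
    else:
        keep = np.ones(points.shape[0], dtype=bool)
    return c, d, rms, keep


def _best_bin(points: np.ndarray, directions: np.ndarray, bin_w: float):
    """Global best (direction, anchor) accumulator cell over all directions."""
    best = (0, None, None)  # votes, direction, anchor(3,)
    for d in directions:
        u, v = _plane_basis(d)
        a = points @ u
        b = points @ v
        ia = np.floor(a / bin_w).astype(np.int64)
        ib = np.floor(b / bin_w).astype(np.int64)
        keys = (ia - ia.min()) * (ib.max() - ib.min() + 1) + (ib - ib.min())
        vals, counts = np.unique(keys, return_counts=True)
        k = int(np.argmax(counts))
        if counts[k] > best[0]:
            sel = keys == vals[k]
            anchor2d = np.array([a[sel].mean(), b[sel].mean()])
            anchor = anchor2d[0] * u + anchor2d[1] * v
            best = (int(counts[k]), d.copy(), anchor)
    return best


def hough_lines_3d(
    cloud: PointCloud,
    direction_subdivisions: int = 3,
    distance_bin: float = 1.0,
    min_votes: Optional[int] = None,
    inlier_radius: float = 2.0,
    max_lines: int = 64,
) -> List[HoughLine]:
    """Iterative-peak 3D line Hough transform on the voxel cloud.

    The global accumulator maximum defines a candidate line; its direction
    is refined by a principal-axis fit to the claimed inliers, the inliers
    are removed, and voting repeats until the next peak falls below
    ``min_votes`` (default: max(10, 25% of the first peak)).
    """
    if cloud.n_points == 0:
        raise EmptyCloudError("Hough transform requires a non-empty point cloud")
    directions = icosphere_directions(direction_subdivisions)
    remaining = np.arange(cloud.n_points)
    pts = cloud.coords
    lines: List[HoughLine] = []
    threshold = min_votes

    while remaining.size and len(lines) < max_lines:
        votes, d, anchor = _best_bin(pts[remaining], directions, distance_bin)
        if d is None:
            break
        if threshold is None:
            threshold = max(10, int(0.25 * votes))  # from the first peak
        if votes < threshold:
            break
        # refine: claim generously around the discrete-direction line, refit
        # the axis by PCA on the claimed points, and repeat until the claimed
        # set stabilizes (the first claim covers only part of the shaft when
        # the discrete direction is a few degrees off); final claim is tight.
        d_ref, anchor_ref = d, anchor
        wide = max(inlier_radius, 1.5 * distance_bin + 1.0)
        prev_size = -1
        sel = np.empty(0, dtype=int)
        for _ in range(8):
            dist = _point_line_distance(pts[remaining], anchor_ref, d_ref)
            sel = remaining[dist <= wide]
            if sel.size >= 2:
                proj = (pts[sel] - anchor_ref) @ d_ref
                keep = _contiguous_extent(proj, max_gap=5.0)
                if keep.sum() >= 2:
                    sel = sel[keep]
            if sel.size < 2 or sel.size == prev_size:
                break
            prev_size = sel.size
            anchor_ref, d_ref, _ = _principal_axis(pts[sel])
        dist = _point_line_distance(pts[remaining], anchor_ref, d_ref)
        sel = remaining[dist <= inlier_radius]
        if sel.size >= 2:
            # keep only the contiguous axial run: the infinite line extended
            # beyond the shaft can pass through another electrode, and those
            # points must not be claimed (they would starve that shaft's own
            # peak below min_votes)
            proj = (pts[sel] - anchor_ref) @ d_ref
            keep = _contiguous_extent(proj, max_gap=5.0)
            if keep.sum() >= 2:
                sel = sel[keep]
            anchor_ref, d_ref, _ = _principal_axis(pts[sel])
        if sel.size == 0:
            break
        lines.append(
            HoughLine(direction=d_ref, anchor=anchor_ref, votes=votes, inliers=sel)
        )
        remaining = np.setdiff1d(remaining, sel, assume_unique=True)

    lines.sort(key=lambda l: -l.votes)
    logger.info("Hough transform found %d line(s)", len(lines))
    return lines


# ---------------------------------------------------------------------------
# mixture clustering
# ---------------------------------------------------------------------------


def cluster_electrodes(
    cloud: PointCloud,
    lines: Sequence[HoughLine],
    seed: int = 0,
    reg_covar: float = 1e-3,
    min_members: int = 4,
) -> List[ElectrodeCluster]:
    """Assign every cloud point to one electrode with a Gaussian mixture.

    One component per Hough line; means, weights and (elongated) covariances
    are initialized from each line's inliers, so the fit starts at the
    geometric prior instead of a random draw.
    """
    if not lines:
        raise ValueError("at least one Hough line is required")
    k = len(lines)
    pts = cloud.coords

    means = np.stack([pts[l.inliers].mean(axis=0) for l in lines])
    weights = np.array([max(l.inliers.size, 1) for l in lines], dtype=float)
    weights /= weights.sum()
    precisions = []
    for l in lines:
        if l.inliers.size >= 4:
            cov = np.cov(pts[l.inliers].T) + reg_covar * np.eye(3)
        else:
            cov = np.eye(3)
        precisions.append(np.linalg.inv(cov))
    gmm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        reg_covar=reg_covar,
        weights_init=weights,
        means_init=means,
        precisions_init=np.stack(precisions),
        n_init=1,
        random_state=seed,
    )
    labels = gmm.fit_predict(pts)

    # k-lines refinement: refit each cluster's axis and re-assign every point
    # to the nearest axis.  Near shaft crossings the full-covariance Gaussians
    # overlap and the mixture responsibilities can hand a few voxels to the
    # wrong electrode; those stray voxels later corrupt endpoints and the
    # double-weight region, so the geometrically correct assignment wins.
    for _ in range(2):
        axes = []
        for j in range(k):
            members = pts[labels == j]
            if members.shape[0] >= 2 and not np.allclose(members, members[0]):
                c_j, d_j, _, _ = _trimmed_axis(members)
            else:
                c_j, d_j = means[j], np.array([1.0, 0.0, 0.0])
            axes.append((c_j, d_j))
        dist = np.stack([_point_line_distance(pts, c_j, d_j) for c_j, d_j in axes])
        labels = dist.argmin(axis=0)

    clusters: List[ElectrodeCluster] = []
    for j in range(k):
        members = np.flatnonzero(labels == j)
        if members.size < min_members:
            raise DegenerateClusterError(
                f"mixture component {j} collapsed to {members.size} member(s)"
            )
        point, direction, rms, _ = _trimmed_axis(pts[members])
        clusters.append(
            ElectrodeCluster(
                label=j,
                member_indices=members,
                centroid=pts[members].mean(axis=0),
                axis_point=point,
                axis_direction=direction,
                rms_residual=rms,
            )
        )
    return clusters


def fit_shaft_axis(
    cluster: ElectrodeCluster, cloud: PointCloud
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Total-least-squares shaft line through the cluster's member voxels."""
    pts = cloud.coords[cluster.member_indices]
    if np.allclose(pts, pts[0]):
        raise DegenerateClusterError("all cluster points identical; no axis")
    return _principal_axis(pts)


# ---------------------------------------------------------------------------
# contact segmentation
# ---------------------------------------------------------------------------


def _interp_intensity(volume: Volume, mm_points: np.ndarray) -> np.ndarray:
    vox = volume.mm_to_voxel(np.atleast_2d(mm_points))
    return map_coordinates(volume.data, vox.T, order=1, mode="constant", cval=0.0)


def intensity_center_of_mass(volume: Volume) -> np.ndarray:
    """Center of intensity mass of the whole volume, in mm (clipped-positive
    weights; falls back to the geometric grid center if massless)."""
    w = np.clip(volume.data, 0, None)
    total = w.sum()
    if total <= 0:
        center_vox = (np.asarray(volume.shape) - 1) / 2.0
        return volume.voxel_to_mm(center_vox)
    idx = [np.arange(s) for s in volume.shape]
    com_vox = np.array(
        [
            (w.sum(axis=tuple(a for a in range(3) if a != ax)) * idx[ax]).sum() / total
            for ax in range(3)
        ]
    )
    return volume.voxel_to_mm(com_vox)


def _contiguous_extent(proj: np.ndarray, max_gap: float) -> np.ndarray:
    """Mask of the contiguous run of sorted axial projections (consecutive
    gaps <= max_gap) containing the median; isolated stray points beyond a
    gap cannot fake a shaft endpoint."""
    order = np.argsort(proj)
    sorted_p = proj[order]
    gaps = np.diff(sorted_p)
    mid = len(sorted_p) // 2
    lo = mid
    while lo > 0 and gaps[lo - 1] <= max_gap:
        lo -= 1
    hi = mid
    while hi < len(sorted_p) - 1 and gaps[hi] <= max_gap:
        hi += 1
    keep = np.zeros(len(proj), dtype=bool)
    keep[order[lo:hi + 1]] = True
    return keep


def find_head_point(
    cluster: ElectrodeCluster,
    cloud: PointCloud,
    volume: Volume,
    brain_center_mm: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Deepest shaft endpoint (voxel coords): the extreme axis projection
    nearer the brain's center of intensity mass; ties break toward the
    endpoint with the lower flattened voxel index.  A single-point cluster
    returns its own centroid."""
    pts = cloud.coords[cluster.member_indices]
    if pts.shape[0] == 1 or np.allclose(pts, pts[0]):
        return pts[0].copy()
    if brain_center_mm is None:
        brain_center_mm = intensity_center_of_mass(volume)
    c, d = cluster.axis_point, cluster.axis_direction
    near = _point_line_distance(pts, c, d) <= 3.0  # ignore stray voxels
    if near.sum() >= 2:
        pts = pts[near]
    proj = (pts - c) @ d
    keep = _contiguous_extent(proj, max_gap=5.0)  # voxels; ~pitch plus slack
    if keep.sum() >= 2:
        pts, proj = pts[keep], proj[keep]
    ends = np.stack([c + proj.min() * d, c + proj.max() * d])
    ends_mm = volume.voxel_to_mm(ends)
    dist = np.linalg.norm(ends_mm - brain_center_mm, axis=1)
    if np.isclose(dist[0], dist[1]):
        flat = [
            int(np.ravel_multi_index(tuple(np.clip(np.round(e).astype(int), 0,
                  np.asarray(volume.shape) - 1)), volume.shape))
            for e in ends
        ]
        return ends[int(np.argmin(flat))]
    return ends[int(np.argmin(dist))]


def center_of_mass_converge(
    volume: Volume,
    start_mm: np.ndarray,
    cube_mm: float = 2.0,
    cluster_mask: Optional[np.ndarray] = None,
    max_iter: int = 10,
    tol_voxels: float = 0.05,
    n_grid: int = 9,
) -> np.ndarray:
    """Iterated intensity-weighted centroid of a cube_mm box (mm space).

    The box is resampled on an n_grid^3 trilinear grid each step; voxels
    inside ``cluster_mask`` get double weight.  Stops when the displacement
    drops below ``tol_voxels`` (in mean-voxel units) or after ``max_iter``
    steps; a detected two-point oscillation returns whichever candidate has
    the higher interpolated intensity.
    """
    c = np.asarray(start_mm, dtype=float).copy()
    offsets = np.linspace(-cube_mm / 2, cube_mm / 2, n_grid)
    og = np.stack(np.meshgrid(offsets, offsets, offsets, indexing="ij"), -1).reshape(-1, 3)
    mean_vox = float(volume.voxel_sizes.mean())
    history = [c.copy()]

    for _ in range(max_iter):
        sample_mm = c[None, :] + og
        vox = volume.mm_to_voxel(sample_mm)
        w = np.clip(map_coordinates(volume.data, vox.T, order=1, mode="constant"), 0, None)
        if cluster_mask is not None:
            inside = map_coordinates(
                cluster_mask.astype(np.uint8), vox.T, order=0, mode="constant"
            ).astype(bool)
            w = np.where(inside, 2.0 * w, w)
        total = w.sum()
        if total <= 0:
            raise NoMassError("center-of-mass box contains no intensity mass")
        new_c = (w[:, None] * sample_mm).sum(axis=0) / total
        step = np.linalg.norm(new_c - c) / mean_vox
        # two-cycle guard: bouncing between two bright regions
        if len(history) >= 2 and np.linalg.norm(new_c - history[-2]) / mean_vox < tol_voxels / 2:
            cands = np.stack([new_c, c])
            vals = _interp_intensity(volume, cands)
            return cands[int(np.argmax(vals))]
        c = new_c
        history.append(c.copy())
        if step < tol_voxels:
            break
    return c


def segment_contacts(
    volume: Volume,
    cluster: ElectrodeCluster,
    cloud: PointCloud,
    pitch_mm: float = 3.5,
    max_contacts: int = 16,
    cube_mm: float = 2.0,
    brain_center_mm: Optional[np.ndarray] = None,
    com_max_iter: int = 10,
    com_tol_voxels: float = 0.05,
    mask_dilation_voxels: int = 2,
) -> ContactSet:
    """Walk the shaft from the head outward, converging on one contact per
    pitch step.  Stops at max_contacts, when the step leaves the cluster's
    axial extent dilated by one pitch, or when the converged point's
    intensity falls below the extraction threshold."""
    if pitch_mm <= 0:
        raise ValueError("pitch_mm must be positive")
    if brain_center_mm is None:
        brain_center_mm = intensity_center_of_mass(volume)

    mask = np.zeros(volume.shape, dtype=bool)
    mi = cloud.coords[cluster.member_indices].astype(int)
    mask[mi[:, 0], mi[:, 1], mi[:, 2]] = True
    # The double-weighted "cluster region" is the member voxels dilated to
    # cover whole contact blobs; doubling only the supra-threshold subset
    # would bias each centroid toward an arbitrary noise-dependent voxel set.
    mask = binary_dilation(mask, iterations=mask_dilation_voxels)

    member_vox = cloud.coords[cluster.member_indices]
    near = _point_line_distance(member_vox, cluster.axis_point, cluster.axis_direction) <= 3.0
    if near.sum() >= 2:
        member_vox = member_vox[near]
    members_mm = volume.voxel_to_mm(member_vox)
    head_vox = find_head_point(cluster, cloud, volume, brain_center_mm)
    head_mm = volume.voxel_to_mm(head_vox)

    # axis in mm space, oriented away from the brain center (head -> tail)
    axis_pts = volume.voxel_to_mm(
        np.stack([cluster.axis_point, cluster.axis_point + cluster.axis_direction])
    )
    d_mm = axis_pts[1] - axis_pts[0]
    d_mm /= np.linalg.norm(d_mm)
    centroid_mm = members_mm.mean(axis=0)
    tail_sign = np.sign((centroid_mm - head_mm) @ d_mm)
    if tail_sign != 0:
        d_mm *= tail_sign  # points from head toward tail (outward)
    proj = (members_mm - head_mm) @ d_mm
    keep = _contiguous_extent(proj, max_gap=pitch_mm + 2.0)
    if keep.sum() >= 2:
        proj = proj[keep]
    proj_lo, proj_hi = float(proj.min()), float(proj.max())

    contacts: List[np.ndarray] = []
    start = head_mm.copy()
    for _ in range(max_contacts):
        p = (start - head_mm) @ d_mm
        if p < proj_lo - pitch_mm or p > proj_hi + pitch_mm:
            break
        try:
            c = center_of_mass_converge(
                volume, start, cube_mm=cube_mm, cluster_mask=mask,
                max_iter=com_max_iter, tol_voxels=com_tol_voxels,
            )
        except NoMassError:
            break
        if float(_interp_intensity(volume, c)[0]) < cloud.threshold:
            break
        if contacts and np.linalg.norm(c - contacts[-1]) < pitch_mm / 2:
            break  # converged back onto the previous contact
        contacts.append(c)
        start = c + pitch_mm * d_mm

    if not contacts:
        raise NoContactsError(f"no contacts found for electrode {cluster.label}")
    # End-contact validity: a leading/trailing contact whose spacing to its
    # neighbor is far from the pitch is a phantom — typically a crossing
    # shaft's blob reached because stray cluster voxels inflated the axial
    # extent.  Genuine spacings stay within a few tenths of a mm of pitch.
    for _ in range(2):
        if len(contacts) >= 2 and abs(
            np.linalg.norm(contacts[1] - contacts[0]) - pitch_mm
        ) > 1.0:
            contacts.pop(0)
        elif len(contacts) >= 2 and abs(
            np.linalg.norm(contacts[-1] - contacts[-2]) - pitch_mm
        ) > 1.0:
            contacts.pop()
        else:
            break
    contact_arr = np.stack(contacts)
    # monotone-projection invariant (head-first ordering, no backtracking)
    along = (contact_arr - contact_arr[0]) @ d_mm
    if contact_arr.shape[0] > 1 and not np.all(np.diff(along) > 0):
        raise NoContactsError(
            f"electrode {cluster.label}: contact projections not monotone"
        )
    return ContactSet(
        electrode_label=cluster.label, contacts=contact_arr, pitch_used=pitch_mm
    )


# ---------------------------------------------------------------------------
# geometric QC
# ---------------------------------------------------------------------------


def geometry_qc(contact_sets: Sequence[ContactSet]) -> GeometryQC:
    """Axis-contact distances (to a line re-regressed through the final
    contact coordinates) and adjacent-spacing errors, pooled and per
    electrode.  Single-contact electrodes contribute axis distance 0."""
    axis_d, adj_err, adj_d, per = [], [], [], []
    for cs in contact_sets:
        pts = cs.contacts
        if pts.shape[0] >= 2:
            c, d, _ = _principal_axis(pts)
            dist = _point_line_distance(pts, c, d)
            gaps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            errs = gaps - cs.pitch_used
        else:
            dist = np.zeros(1)
            gaps = np.zeros(0)
            errs = np.zeros(0)
        axis_d.append(dist)
        adj_d.append(gaps)
        adj_err.append(errs)
        per.append(
            {
                "electrode_label": cs.electrode_label,
                "n_contacts": pts.shape[0],
                "axis_contact_distances": dist,
                "adjacent_distance_errors": errs,
            }
        )
    return GeometryQC(
        axis_contact_distances=np.concatenate(axis_d) if axis_d else np.zeros(0),
        adjacent_distance_errors=np.concatenate(adj_err) if adj_err else np.zeros(0),
        adjacent_distances=np.concatenate(adj_d) if adj_d else np.zeros(0),
        per_electrode=per,
    )


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


class ElectrodeLocator(BaseEstimator):
    """End-to-end electrode localization, scikit-learn estimator style.

    Parameters mirror :class:`seegquake.config.RunConfig`.  ``fit`` takes a
    :class:`~seegquake.io.Volume` and exposes the fitted state as trailing-
    underscore attributes.

    Attributes
    ----------
    threshold_ : float
        Resolved voxel-extraction threshold.
    cloud_ : PointCloud
    lines_ : list of HoughLine
    clusters_ : list of ElectrodeCluster
    contact_sets_ : list of ContactSet
        Per-electrode ordered contact coordinates (mm, head first).
    qc_ : GeometryQC
    """

    def __init__(
        self,
        threshold_rule: str = "bright",
        direction_subdivisions: int = 3,
        distance_bin_voxels: float = 1.0,
        inlier_radius_voxels: float = 2.0,
        min_votes: Optional[int] = None,
        n_electrodes: Optional[int] = None,
        pitch_mm: float = 3.5,
        cube_mm: float = 2.0,
        max_contacts: int = 16,
        com_tol_voxels: float = 0.05,
        com_max_iter: int = 10,
        seed: int = 0,
    ):
        self.threshold_rule = threshold_rule
        self.direction_subdivisions = direction_subdivisions
        self.distance_bin_voxels = distance_bin_voxels
        self.inlier_radius_voxels = inlier_radius_voxels
        self.min_votes = min_votes
        self.n_electrodes = n_electrodes
        self.pitch_mm = pitch_mm
        self.cube_mm = cube_mm
        self.max_contacts = max_contacts
        self.com_tol_voxels = com_tol_voxels
        self.com_max_iter = com_max_iter
        self.seed = seed

    @classmethod
    def from_config(cls, config: RunConfig) -> "ElectrodeLocator":
        return cls(
            threshold_rule=config.threshold_rule,
            direction_subdivisions=config.direction_subdivisions,
            distance_bin_voxels=config.distance_bin_voxels,
            inlier_radius_voxels=config.inlier_radius_voxels,
            min_votes=config.min_votes,
            n_electrodes=config.n_electrodes,
            pitch_mm=config.pitch_mm,
            cube_mm=config.cube_mm,
            max_contacts=config.max_contacts,
            com_tol_voxels=config.com_tol_voxels,
            com_max_iter=config.com_max_iter,
            seed=config.gmm_seed,
        )

    def fit(self, X: Volume, y=None) -> "ElectrodeLocator":
        volume = X
        self.cloud_ = extract_bright_voxels(volume, self.threshold_rule)
        self.threshold_ = self.cloud_.threshold
        lines = hough_lines_3d(
            self.cloud_,
            direction_subdivisions=self.direction_subdivisions,
            distance_bin=self.distance_bin_voxels,
            min_votes=self.min_votes,
            inlier_radius=self.inlier_radius_voxels,
        )
        if self.n_electrodes is not None:
            lines = lines[: self.n_electrodes]
        if not lines:
            raise EmptyCloudError("no line reached the Hough vote threshold")
        self.lines_ = lines
        self.clusters_ = cluster_electrodes(self.cloud_, lines, seed=self.seed)
        center = intensity_center_of_mass(volume)
        self.contact_sets_ = []
        for cluster in self.clusters_:
            try:
                cs = segment_contacts(
                    volume,
                    cluster,
                    self.cloud_,
                    pitch_mm=self.pitch_mm,
                    max_contacts=self.max_contacts,
                    cube_mm=self.cube_mm,
                    brain_center_mm=center,
                    com_max_iter=self.com_max_iter,
                    com_tol_voxels=self.com_tol_voxels,
                )
            except NoContactsError as exc:
                logger.warning("electrode %d skipped: %s", cluster.label, exc)
                continue
            self.contact_sets_.append(cs)
        self.qc_ = geometry_qc(self.contact_sets_)
        logger.info(
            "localized %d electrode(s), %d contact(s)",
            len(self.contact_sets_),
            sum(cs.n_contacts for cs in self.contact_sets_),
        )
        return self

    def transform(self, X: Volume) -> np.ndarray:
        """Fit on the volume and return all contact coordinates (mm)."""
        self.fit(X)
        if not self.contact_sets_:
            return np.zeros((0, 3))
        return np.concatenate([cs.contacts for cs in self.contact_sets_])
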