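"""Peritumoral-vasculature radiomics.

Pipeline: multi-scale Hessian vesselness -> Otsu threshold -> morphological
cleanup -> restriction to a peritumoral cube (tumour bounding box + 25 mm per
side) -> skeleton centerlines partitioned into branches -> per-branch Frenet
curvature/torsion -> 91 features (61 morphology + 30 organization), plus the
3-SD / 20% outlier-based feature filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import splev, splprep
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import ball, skeletonize

from .image_core import ImageVolume

MORPHOLOGY_QUANTITIES = (
    "mean_curvature", "max_curvature", "mean_torsion", "max_torsion",
    "length_mm", "mean_radius_mm", "straightness", "curvature_skewness",
    "torsion_skewness", "inflection_count", "total_curvature", "total_torsion",
)
ORGANIZATION_SCALARS = (
    "branch_count", "junction_count", "branch_density_per_cm3",
    "junction_density_per_cm3", "tip_count",
)
ORGANIZATION_QUANTITIES = (
    "nearest_branch_distance_mm", "orientation_angle_rad",
    "orientation_dispersion_rad", "tumor_surface_distance_mm",
    "local_spacing_mm",
)
AGGREGATORS = ("mean", "sd", "skewness", "kurtosis", "median")


def vessel_manifest_names() -> list[str]:
    """Ordered names of the 91 vasculature features (61 morphology + 30 organization)."""
    names = [f"morph_{q}_{a}" for q in MORPHOLOGY_QUANTITIES for a in AGGREGATORS]
    names.append("morph_total_vessel_volume_mm3")
    names += [f"org_{s}" for s in ORGANIZATION_SCALARS]
    names += [f"org_{q}_{a}" for q in ORGANIZATION_QUANTITIES for a in AGGREGATORS]
    assert len(names) == 91
    return names


@dataclass
class VesselTree:
    """Centerline branches (mm coordinates), junctions, and per-point radii."""

    branches: list[np.ndarray] = field(default_factory=list)
    junctions: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    radii: list[np.ndarray] = field(default_factory=list)
    cube_bounds: tuple | None = None

    @property
    def n_branches(self) -> int:
        return len(self.branches)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def lung_mask_fallback(volume: ImageVolume, tumor_mask: np.ndarray | None = None,
                       threshold: float | None = None) -> np.ndarray:
    """Threshold-based lung segmentation for phantoms and pre-standardized CT.

    Low-intensity connected components (excluding the background component that
    touches the volume border on all sides) are labelled lung; the tumour mask,
    if given, is unioned back in since it is brighter than lung parenchyma.
    """
    vals = volume.values
    if vals.size == 0 or vals.std() == 0:
        raise ValueError("volume is empty or constant; cannot derive a lung mask")
    thr = float(np.median(vals)) if threshold is None else threshold
    low = vals < thr
    lab, n = ndimage.label(low)
    if n == 0:
        raise ValueError("no lung-like low-intensity component found")
    sizes = ndimage.sum(low, lab, index=np.arange(1, n + 1))
    lung = lab == (1 + int(np.argmax(sizes)))
    if tumor_mask is not None:
        lung = lung | np.asarray(tumor_mask, dtype=bool)
    return lung


def vesselness(volume: ImageVolume, scales_mm=(1.0, 1.5, 2.0, 3.0, 4.0),
               alpha: float = 0.5, beta: float = 0.5,
               return_scales: bool = False):
    """Frangi-style multi-scale tubularity response in [0, 1] (bright tubes).

    At each Gaussian scale the gamma-normalized (x s^2) Hessian eigenvalues
    |l1|<=|l2|<=|l3| score tube-likeness (plate and blob terms suppressed via
    alpha/beta). The structure-norm term uses a single gamma = half the
    maximal Hessian norm over ALL scales, so responses are comparable across
    scales and the per-voxel argmax scale tracks the tube radius. The output
    is the maximum over scales; optionally also the argmax scale.
    """
    scales = [float(s) for s in scales_mm]
    if not scales or any(s <= 0 for s in scales):
        raise ValueError("need at least one positive scale")
    min_sp = min(volume.spacing_mm)
    scales = [max(s, min_sp) for s in scales]
    vals = volume.values.astype(np.float64)
    per_scale = []
    gamma_max = 0.0
    for s in scales:
        sigma = [s / sp for sp in volume.spacing_mm]
        h = hessian_matrix(vals, sigma=sigma, order="rc",
                           use_gaussian_derivatives=False, mode="reflect")
        eigs = hessian_matrix_eigvals(h) * s**2
        # sort by absolute value ascending: |l1| <= |l2| <= |l3|
        idx = np.argsort(np.abs(eigs), axis=0)
        e = np.take_along_axis(eigs, idx, axis=0).astype(np.float32)
        per_scale.append(e)
        gamma_max = max(gamma_max, float(np.sqrt((e.astype(np.float64)**2).sum(axis=0)).max()))
    best = np.zeros(vals.shape)
    best_scale = np.zeros(vals.shape)
    gamma = 0.5 * gamma_max
    if gamma > 0:
        for s, e in zip(scales, per_scale):
            l1, l2, l3 = (e[0].astype(np.float64), e[1].astype(np.float64),
                          e[2].astype(np.float64))
            with np.errstate(divide="ignore", invalid="ignore"):
                ra = np.abs(l2) / np.abs(l3)
                rb = np.abs(l1) / np.sqrt(np.abs(l2 * l3))
            snorm2 = l1**2 + l2**2 + l3**2
            resp = (
                (1.0 - np.exp(-(ra**2) / (2 * alpha**2)))
                * np.exp(-(rb**2) / (2 * beta**2))
                * (1.0 - np.exp(-snorm2 / (2 * gamma**2)))
            )
            resp = np.where((l2 < 0) & (l3 < 0), resp, 0.0)  # bright tubes only
            resp = np.nan_to_num(resp, nan=0.0)
            take = resp > best
            best = np.where(take, resp, best)
            best_scale = np.where(take, s, best_scale)
    if return_scales:
        return volume.copy_with(best), best_scale
    return volume.copy_with(best)


def otsu_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Otsu's threshold maximizing between-class variance over a 256-bin histogram."""
    values = np.asarray(values, dtype=np.float64).ravel()
    if np.unique(values).size < 2:
        raise ValueError("constant input has no Otsu threshold")
    return float(threshold_otsu(values, nbins=n_bins))


def morphological_cleanup(mask: np.ndarray, spacing_mm=(1.0, 1.0, 1.0),
                          min_component_voxels: int = 27,
                          opening_radius_mm: float = 1.0) -> np.ndarray:
    """Binary opening with a ball element, then small-component removal."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    r_vox = int(round(opening_radius_mm / min(spacing_mm)))
    out = (ndimage.binary_opening(mask, structure=ball(r_vox))
           if r_vox >= 1 else mask.copy())
    lab, n = ndimage.label(out)
    if n:
        sizes = np.bincount(lab.ravel())
        keep = sizes >= min_component_voxels
        keep[0] = False
        out = keep[lab]
    return out


def peritumoral_cube(tumor_mask: np.ndarray, spacing_mm=(1.0, 1.0, 1.0),
                     extension_mm: float = 25.0) -> tuple[tuple[int, int], ...]:
    """Axis-aligned cube: tumour bounding box extended per side, clipped to grid.

    Returns per-axis half-open voxel index bounds ``((lo, hi), ...)``.
    """
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    if not tumor_mask.any():
        raise ValueError("empty tumor mask")
    idx = np.argwhere(tumor_mask)
    bounds = []
    for ax in range(3):
        ext = int(round(extension_mm / spacing_mm[ax]))
        lo = max(0, int(idx[:, ax].min()) - ext)
        hi = min(tumor_mask.shape[ax], int(idx[:, ax].max()) + ext + 1)
        bounds.append((lo, hi))
    return tuple(bounds)


# ---------------------------------------------------------------------------
# centerlines
# ---------------------------------------------------------------------------

_NEIGH = [np.array((dx, dy, dz)) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
          for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)]


def extract_centerlines(vessel_mask: np.ndarray, spacing_mm=(1.0, 1.0, 1.0)) -> VesselTree:
    """Skeletonize the vessel mask and partition the skeleton into branches.

    Uses distance-ordered medial-axis thinning; the skeleton graph is split at
    junction voxels (>= 3 skeleton neighbours); the per-point radius estimate
    is the Euclidean distance to the vessel surface.
    """
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    if not vessel_mask.any():
        return VesselTree()
    skel = skeletonize(vessel_mask)
    if not skel.any():
        # perfectly even-symmetric tubes can be annihilated by thinning (no
        # uniquely medial voxel); break the symmetry by a one-voxel erosion
        # shift along each axis in turn
        for ax in range(3):
            shifted = vessel_mask & np.roll(vessel_mask, 1, axis=ax)
            skel = skeletonize(shifted)
            if skel.any():
                break
    if not skel.any():
        return VesselTree()
    dist = ndimage.distance_transform_edt(vessel_mask, sampling=spacing_mm)
    spacing = np.asarray(spacing_mm)

    pts = [tuple(p) for p in np.argwhere(skel)]
    pset = set(pts)
    nbrs = {
        p: [q for q in (tuple(np.asarray(p) + d) for d in _NEIGH) if q in pset]
        for p in pts
    }
    deg = {p: len(n) for p, n in nbrs.items()}
    junction_pts = {p for p, d in deg.items() if d >= 3}

    visited_edges: set[frozenset] = set()
    branches, radii = [], []

    def walk(start, nxt):
        """Follow the path from a junction/tip until the next junction/tip."""
        path = [start, nxt]
        visited_edges.add(frozenset((start, nxt)))
        cur, prev = nxt, start
        while cur not in junction_pts and deg[cur] == 2:
            nn = [q for q in nbrs[cur] if q != prev]
            if not nn:
                break
            prev, cur = cur, nn[0]
            if frozenset((prev, cur)) in visited_edges:
                break
            visited_edges.add(frozenset((prev, cur)))
            path.append(cur)
        return path

    endpoints = [p for p in pts if deg[p] != 2]
    for p in endpoints:
        for q in nbrs[p]:
            if frozenset((p, q)) not in visited_edges:
                path = walk(p, q)
                if len(path) >= 2:
                    branches.append(np.asarray(path, dtype=np.float64) * spacing)
                    radii.append(np.asarray([dist[pt] for pt in path]))
    # isolated cycles (no endpoint): walk from any unvisited degree-2 voxel
    used = {pt for br in branches for pt in map(tuple, (br / spacing).round().astype(int))}
    for p in pts:
        if p not in used and deg[p] == 2:
            path = walk(p, nbrs[p][0])
            if len(path) >= 2:
                branches.append(np.asarray(path, dtype=np.float64) * spacing)
                radii.append(np.asarray([dist[pt] for pt in path]))
                used.update(map(tuple, path))

    junctions = (np.asarray(sorted(junction_pts), dtype=np.float64) * spacing
                 if junction_pts else np.zeros((0, 3)))
    return VesselTree(branches=branches, junctions=junctions, radii=radii)


# ---------------------------------------------------------------------------
# branch geometry (Frenet)
# ---------------------------------------------------------------------------

def branch_geometry(points: np.ndarray, smoothing_mm: float = 1.0,
                    step_mm: float = 2.0, curvature_floor: float = 0.04) -> dict:
    """Curvature, torsion, length and straightness of one centerline branch.

    The polyline is smoothed with a parametric cubic spline, resampled at
    ``step_mm`` arc steps, and differenced with discrete Frenet frames:
    curvature = turning angle of consecutive tangents per arc length, torsion
    = signed dihedral angle of consecutive osculating planes per arc length.
    Torsion is undefined where the curve is locally straight, so it is set to
    0 where curvature falls below ``curvature_floor`` (1/mm) — there the
    binormal direction is pure noise. The coarse step suppresses the
    voxel-level staircase of digital skeletons; length and straightness are
    measured on the smoothed curve for the same reason.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 points for curvature")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    raw_len = float(seg.sum())
    keep = np.concatenate(([True], seg > 1e-12))  # splprep rejects duplicates
    pts_u = pts[keep]

    def _flat(length: float, straight: float) -> dict:
        return {"curvature": np.zeros(1), "torsion": np.zeros(1),
                "length_mm": length, "straightness": straight,
                "arc_mm": np.zeros(1), "ds_mm": np.asarray([length])}

    if pts_u.shape[0] < 4 or raw_len <= 0:
        chord = float(np.linalg.norm(pts[-1] - pts[0]))
        return _flat(raw_len, min(1.0, chord / raw_len) if raw_len > 0 else 1.0)

    k = min(3, pts_u.shape[0] - 1)
    try:
        tck, _ = splprep(pts_u.T, s=smoothing_mm**2 * pts_u.shape[0], k=k)
    except Exception:
        tck, _ = splprep(pts_u.T, s=0, k=k)
    fine = np.asarray(splev(np.linspace(0, 1, 200), tck)).T
    arclen = float(np.linalg.norm(np.diff(fine, axis=0), axis=1).sum())
    chord = float(np.linalg.norm(fine[-1] - fine[0]))
    straightness = min(1.0, chord / arclen) if arclen > 0 else 1.0

    m = max(int(np.ceil(arclen / step_mm)) + 1, 4)
    r = np.asarray(splev(np.linspace(0, 1, m), tck)).T
    d = np.diff(r, axis=0)
    dn = np.linalg.norm(d, axis=1)
    if np.any(dn <= 1e-12):
        return _flat(arclen, straightness)
    e = d / dn[:, None]
    cosang = np.clip((e[:-1] * e[1:]).sum(axis=1), -1.0, 1.0)
    ds = 0.5 * (dn[:-1] + dn[1:])
    kappa = np.arccos(cosang) / ds

    binormal = np.cross(e[:-1], e[1:])
    bnorm = np.linalg.norm(binormal, axis=1)
    tau = np.zeros_like(kappa)
    for i in range(len(binormal) - 1):
        if (bnorm[i] > 1e-8 and bnorm[i + 1] > 1e-8
                and kappa[i] >= curvature_floor and kappa[i + 1] >= curvature_floor):
            b0 = binormal[i] / bnorm[i]
            b1 = binormal[i + 1] / bnorm[i + 1]
            ang = np.arccos(np.clip(b0 @ b1, -1.0, 1.0))
            sign = np.sign(np.cross(b0, b1) @ e[i + 1]) or 1.0
            tau[i + 1] = sign * ang / dn[i + 1]
    arc = np.concatenate(([0.0], np.cumsum(ds)))[: len(kappa)]
    return {"curvature": kappa, "torsion": tau, "length_mm": arclen,
            "straightness": straightness, "arc_mm": arc, "ds_mm": ds}


# ---------------------------------------------------------------------------
# 91-feature block
# ---------------------------------------------------------------------------

def _agg(values: np.ndarray) -> dict[str, float]:
    v = np.asarray(values, dtype=np.float64)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return {a: 0.0 for a in AGGREGATORS}
    mean = v.mean()
    sd = v.std()
    if sd > 0:
        sk = float(((v - mean) ** 3).mean() / sd**3)
        ku = float(((v - mean) ** 4).mean() / sd**4 - 3.0)
    else:
        sk = ku = 0.0
    return {"mean": float(mean), "sd": float(sd), "skewness": sk,
            "kurtosis": ku, "median": float(np.median(v))}


def _skewness(v: np.ndarray) -> float:
    v = np.asarray(v, dtype=np.float64)
    if v.size < 2:
        return 0.0
    sd = v.std()
    return float(((v - v.mean()) ** 3).mean() / sd**3) if sd > 0 else 0.0


def vessel_features(tree: VesselTree, cube_volume_mm3: float,
                    tumor_centroid_mm: np.ndarray | None = None,
                    tumor_surface_distance=None,
                    vessel_volume_mm3: float = 0.0,
                    smoothing_mm: float = 1.0,
                    min_torsion_points: int = 5) -> dict[str, float]:
    """Compute the 91 vasculature features (+ an ``empty_tree`` flag column).

    Morphology: {mean, SD, skewness, kurtosis, median} over branches of 12
    per-branch quantities (60) + total vessel volume. Organization: 5 count /
    density scalars + the same 5 aggregators over 5 per-branch spatial
    quantities. ``tumor_surface_distance`` maps an (n,3) mm coordinate array
    to distances from the tumour surface; defaults to distance from
    ``tumor_centroid_mm`` (or the origin).
    """
    names = vessel_manifest_names()
    feats = dict.fromkeys(names, 0.0)
    feats["empty_tree"] = 1.0

    usable = [i for i, b in enumerate(tree.branches) if len(b) >= 3]
    if usable:
        feats["empty_tree"] = 0.0
        geos, midpoints, orientations = [], [], []
        for i in usable:
            g = branch_geometry(tree.branches[i], smoothing_mm=smoothing_mm)
            if len(tree.branches[i]) < min_torsion_points:
                g["torsion"] = np.zeros_like(g["torsion"])
            geos.append((i, g))
            midpoints.append(tree.branches[i].mean(axis=0))
            d = tree.branches[i][-1] - tree.branches[i][0]
            n = np.linalg.norm(d)
            orientations.append(d / n if n > 0 else np.array([1.0, 0.0, 0.0]))
        midpoints = np.asarray(midpoints)
        orientations = np.asarray(orientations)

        per_branch: dict[str, list[float]] = {q: [] for q in MORPHOLOGY_QUANTITIES}
        for i, g in geos:
            kappa, tau, ds = g["curvature"], g["torsion"], g["ds_mm"]
            per_branch["mean_curvature"].append(kappa.mean())
            per_branch["max_curvature"].append(kappa.max())
            per_branch["mean_torsion"].append(np.abs(tau).mean())
            per_branch["max_torsion"].append(np.abs(tau).max())
            per_branch["length_mm"].append(g["length_mm"])
            per_branch["mean_radius_mm"].append(float(np.mean(tree.radii[i]))
                                                if len(tree.radii) > i and len(tree.radii[i]) else 0.0)
            per_branch["straightness"].append(g["straightness"])
            per_branch["curvature_skewness"].append(_skewness(kappa))
            per_branch["torsion_skewness"].append(_skewness(tau))
            signs = np.sign(tau[np.abs(tau) > 1e-8])
            per_branch["inflection_count"].append(float((np.diff(signs) != 0).sum()))
            per_branch["total_curvature"].append(float((kappa * ds).sum()))
            per_branch["total_torsion"].append(float((np.abs(tau) * ds).sum()))
        for q in MORPHOLOGY_QUANTITIES:
            for a, v in _agg(np.asarray(per_branch[q])).items():
                feats[f"morph_{q}_{a}"] = v

        nb = len(usable)
        cm3 = max(cube_volume_mm3 / 1000.0, 1e-9)
        njunc = len(tree.junctions)
        feats["org_branch_count"] = float(nb)
        feats["org_junction_count"] = float(njunc)
        feats["org_branch_density_per_cm3"] = nb / cm3
        feats["org_junction_density_per_cm3"] = njunc / cm3
        # tips: branch endpoints not coincident with a junction
        tips = 0
        for i in usable:
            for end in (tree.branches[i][0], tree.branches[i][-1]):
                if njunc == 0 or np.min(
                        np.linalg.norm(tree.junctions - end, axis=1)) > 2.0:
                    tips += 1
        feats["org_tip_count"] = float(tips)

        centroid = (np.asarray(tumor_centroid_mm, dtype=np.float64)
                    if tumor_centroid_mm is not None else np.zeros(3))
        if nb > 1:
            dmat = np.linalg.norm(midpoints[:, None] - midpoints[None, :], axis=2)
            np.fill_diagonal(dmat, np.inf)
            nearest = dmat.min(axis=1)
        else:
            nearest = np.zeros(nb)
        rays = midpoints - centroid
        raynorm = np.linalg.norm(rays, axis=1)
        rays = np.where(raynorm[:, None] > 0, rays / np.maximum(raynorm[:, None], 1e-12),
                        np.array([1.0, 0.0, 0.0]))
        cosang = np.clip(np.abs((orientations * rays).sum(axis=1)), 0, 1)
        angles = np.arccos(cosang)
        dispersion = []
        for i in usable:
            b = tree.branches[i]
            segd = np.diff(b, axis=0)
            segn = np.linalg.norm(segd, axis=1)
            segd = segd[segn > 0] / segn[segn > 0, None]
            if len(segd) < 2:
                dispersion.append(0.0)
            else:
                mdir = segd.mean(axis=0)
                mnorm = np.linalg.norm(mdir)
                if mnorm == 0:
                    dispersion.append(np.pi / 2)
                else:
                    cs = np.clip(np.abs(segd @ (mdir / mnorm)), 0, 1)
                    dispersion.append(float(np.arccos(cs).std() + np.arccos(cs).mean()))
        if tumor_surface_distance is not None:
            surf = np.asarray(tumor_surface_distance(midpoints), dtype=np.float64)
        else:
            surf = np.linalg.norm(midpoints - centroid, axis=1)
        spacing_local = nearest if nb > 1 else np.zeros(nb)
        org_vals = {
            "nearest_branch_distance_mm": nearest,
            "orientation_angle_rad": angles,
            "orientation_dispersion_rad": np.asarray(dispersion),
            "tumor_surface_distance_mm": surf,
            "local_spacing_mm": spacing_local,
        }
        for q, vals in org_vals.items():
            for a, v in _agg(vals).items():
                feats[f"org_{q}_{a}"] = v

    feats["morph_total_vessel_volume_mm3"] = float(vessel_volume_mm3)
    ordered = {k: feats[k] for k in names}
    ordered["empty_tree"] = feats["empty_tree"]
    return ordered


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------

def extract_peritumoral(volume: ImageVolume, tumor_mask: np.ndarray,
                        lung_mask: np.ndarray | None = None,
                        vessel_mask: np.ndarray | None = None,
                        scales_mm=(1.0, 1.5, 2.0, 3.0, 4.0),
                        extension_mm: float = 25.0,
                        min_component_voxels: int = 27,
                        opening_radius_mm: float = 1.0) -> dict[str, float]:
    """Segment peritumoral vessels and compute the 91 vasculature features.

    A precomputed ``vessel_mask`` (e.g. from a phantom's ground truth) skips
    the vesselness/Otsu/cleanup stages; otherwise vesselness is computed on
    the full volume and thresholded, then restricted to
    (lung mask ∩ peritumoral cube) minus the tumour.
    """
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    spacing = volume.spacing_mm
    if vessel_mask is None:
        if lung_mask is None:
            lung_mask = lung_mask_fallback(volume, tumor_mask)
        v = vesselness(volume, scales_mm)
        pos = v.values[v.values > 0]
        if pos.size < 2:
            vessel_mask = np.zeros(volume.shape, dtype=bool)
        else:
            thr = otsu_threshold(pos)
            vessel_mask = morphological_cleanup(
                v.values > thr, spacing, min_component_voxels, opening_radius_mm)
        vessel_mask = vessel_mask & np.asarray(lung_mask, dtype=bool) & ~tumor_mask
    else:
        vessel_mask = np.asarray(vessel_mask, dtype=bool) & ~tumor_mask

    bounds = peritumoral_cube(tumor_mask, spacing, extension_mm)
    sl = tuple(slice(lo, hi) for lo, hi in bounds)
    cube_vessels = np.zeros_like(vessel_mask)
    cube_vessels[sl] = vessel_mask[sl]

    tree = extract_centerlines(cube_vessels, spacing)
    voxvol = float(np.prod(spacing))
    cube_volume = float(np.prod([hi - lo for lo, hi in bounds])) * voxvol
    centroid = np.argwhere(tumor_mask).mean(axis=0) * np.asarray(spacing)
    dist_out = ndimage.distance_transform_edt(~tumor_mask, sampling=spacing)

    def surface_distance(pts_mm: np.ndarray) -> np.ndarray:
        idx = np.round(pts_mm / np.asarray(spacing)).astype(int)
        idx = np.clip(idx, 0, np.asarray(tumor_mask.shape) - 1)
        return dist_out[idx[:, 0], idx[:, 1], idx[:, 2]]

    return vessel_features(
        tree, cube_volume,
        tumor_centroid_mm=centroid,
        tumor_surface_distance=surface_distance,
        vessel_volume_mm3=float(cube_vessels.sum()) * voxvol,
    )


# ---------------------------------------------------------------------------
# outlier-based feature filter
# ---------------------------------------------------------------------------

class OutlierFeatureFilter:
    """Remove features whose 3-SD outlier fraction exceeds 20% of the dataset.

    Per feature, mean and SD come from the reference rows (the training split);
    the outlier fraction is counted over *all* rows passed to
    :meth:`fit`/:meth:`transform`. A feature is removed when the fraction
    strictly exceeds ``max_fraction``; zero-SD reference features are removed
    and reported. Follows the sklearn transformer protocol.
    """

    def __init__(self, z_threshold: float = 3.0, max_fraction: float = 0.20):
        self.z_threshold = z_threshold
        self.max_fraction = max_fraction

    def get_params(self, deep: bool = True) -> dict:
        return {"z_threshold": self.z_threshold, "max_fraction": self.max_fraction}

    def set_params(self, **params) -> "OutlierFeatureFilter":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, reference_index=None) -> "OutlierFeatureFilter":
        """Learn reference statistics and decide removals.

        ``X`` is the full dataset; ``reference_index`` selects the reference
        rows (defaults to all rows).
        """
        X = pd.DataFrame(X)
        ref = X.loc[reference_index] if reference_index is not None else X
        if len(ref) == 0:
            raise ValueError("reference rows must be nonempty")
        mean = ref.mean(axis=0)
        sd = ref.std(axis=0, ddof=0)
        removed, report = [], {}
        for col in X.columns:
            if sd[col] == 0 or not np.isfinite(sd[col]):
                removed.append(col)
                report[col] = {"fraction": 1.0, "reason": "zero reference SD"}
                continue
            z = (X[col] - mean[col]).abs() / sd[col]
            frac = float((z > self.z_threshold).mean())
            if frac > self.max_fraction:
                removed.append(col)
                report[col] = {"fraction": frac, "reason": "outlier fraction"}
        self.reference_mean_ = mean
        self.reference_sd_ = sd
        self.removed_features_ = removed
        self.removal_report_ = report
        self.kept_features_ = [c for c in X.columns if c not in set(removed)]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "kept_features_"):
            raise ValueError("filter not fitted")
        return pd.DataFrame(X)[self.kept_features_]

    def fit_transform(self, X: pd.DataFrame, reference_index=None) -> pd.DataFrame:
        return self.fit(X, reference_index=reference_index).transform(X)
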