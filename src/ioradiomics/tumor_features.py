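"""Intratumoral radiomics: 593 features over the original image and 8 wavelet subbands.

Per image set (original + LLL...HHH): 14 histogram, 22 GLCM, 11 GLRLM and 17
local-binary-pattern features computed inside the tumour ROI (9 x 64 = 576),
plus 17 mask-only geometry features = 593. Texture matrices are 3D: GLCM and
GLRLM accumulate over the 13 unique direction offsets at distance 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage.measure import marching_cubes, mesh_surface_area

from .image_core import ImageVolume, WAVELET_LABELS, wavelet_decompose

#: The 13 unique 3D direction offsets at Chebyshev distance 1 (up to sign).
DIRECTIONS_3D = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

HISTOGRAM_NAMES = (
    "mean", "sd", "variance", "skewness", "kurtosis", "median", "min", "max",
    "range", "iqr", "energy", "entropy", "p10", "p90",
)
GEOMETRY_NAMES = (
    "volume_mm3", "voxel_count", "surface_area_mm2", "surface_to_volume",
    "sphericity", "compactness", "spherical_disproportion", "max_diameter_3d_mm",
    "extent_x_mm", "extent_y_mm", "extent_z_mm", "major_axis_mm",
    "minor_axis_mm", "least_axis_mm", "elongation", "flatness",
    "equivalent_diameter_mm",
)
GLCM_NAMES = (
    "energy", "contrast", "correlation", "variance", "homogeneity",
    "inverse_difference", "inverse_variance", "entropy", "dissimilarity",
    "max_probability", "autocorrelation", "cluster_tendency", "cluster_shade",
    "cluster_prominence", "sum_average", "sum_variance", "sum_entropy",
    "difference_average", "difference_variance", "difference_entropy",
    "imc1", "imc2",
)
GLRLM_NAMES = (
    "sre", "lre", "gln", "rln", "rp", "lgre", "hgre", "srlge", "srhge",
    "lrlge", "lrhge",
)
LBP_NAMES = tuple(f"bin_{i:02d}" for i in range(16)) + ("entropy",)

IMAGE_SETS = ("original",) + WAVELET_LABELS


@dataclass(frozen=True)
class ManifestEntry:
    name: str
    family: str  # histogram | geometry | glcm | glrlm | lbp
    image_set: str  # original | LLL..HHH | n/a


def feature_manifest() -> list[ManifestEntry]:
    """Ordered manifest of the 593 intratumoral features."""
    entries = [ManifestEntry(f"geometry_{n}", "geometry", "n/a") for n in GEOMETRY_NAMES]
    for img in IMAGE_SETS:
        entries += [ManifestEntry(f"{img}_histogram_{n}", "histogram", img) for n in HISTOGRAM_NAMES]
        entries += [ManifestEntry(f"{img}_glcm_{n}", "glcm", img) for n in GLCM_NAMES]
        entries += [ManifestEntry(f"{img}_glrlm_{n}", "glrlm", img) for n in GLRLM_NAMES]
        entries += [ManifestEntry(f"{img}_lbp_{n}", "lbp", img) for n in LBP_NAMES]
    return entries


def manifest_names() -> list[str]:
    return [e.name for e in feature_manifest()]


def save_manifest(path: str) -> None:
    with open(path, "w") as fh:
        json.dump(
            [{"name": e.name, "family": e.family, "image_set": e.image_set}
             for e in feature_manifest()],
            fh, indent=1,
        )


# ---------------------------------------------------------------------------
# quantization and histogram statistics
# ---------------------------------------------------------------------------

def quantize(values: np.ndarray, n_bins: int = 64) -> np.ndarray:
    """Fixed-bin-count quantization of ROI intensities to labels 1..n_bins.

    Bins cover the min-max range of the supplied values; a constant input maps
    everything to bin 1.
    """
    if values.size == 0:
        raise ValueError("empty ROI")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    values = np.asarray(values, dtype=np.float64)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.ones(values.shape, dtype=np.int64)
    q = np.floor((values - lo) / (hi - lo) * n_bins).astype(np.int64) + 1
    return np.clip(q, 1, n_bins)


def _shannon_entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


def histogram_features(volume: ImageVolume, mask: np.ndarray, n_bins: int = 64) -> dict[str, float]:
    """First-order intensity statistics over the ROI (population conventions).

    Skewness and (excess) kurtosis of a constant region are defined as 0 so a
    degenerate ROI never propagates NaN into the model.
    """
    vals = volume.values[mask]
    if vals.size == 0:
        raise ValueError("empty mask")
    vals = vals.astype(np.float64)
    mean = vals.mean()
    var = vals.var()
    sd = np.sqrt(var)
    centred = vals - mean
    if sd > 0:
        skew = float((centred**3).mean() / sd**3)
        kurt = float((centred**4).mean() / sd**4 - 3.0)
    else:
        skew = kurt = 0.0
    q = quantize(vals, n_bins)
    counts = np.bincount(q, minlength=n_bins + 1)[1:]
    p = counts / counts.sum()
    out = {
        "mean": float(mean),
        "sd": float(sd),
        "variance": float(var),
        "skewness": skew,
        "kurtosis": kurt,
        "median": float(np.median(vals)),
        "min": float(vals.min()),
        "max": float(vals.max()),
        "range": float(vals.max() - vals.min()),
        "iqr": float(np.percentile(vals, 75) - np.percentile(vals, 25)),
        "energy": float((vals**2).sum()),
        "entropy": _shannon_entropy(p),
        "p10": float(np.percentile(vals, 10)),
        "p90": float(np.percentile(vals, 90)),
    }
    return out


# ---------------------------------------------------------------------------
# geometry (mask-only)
# ---------------------------------------------------------------------------

def geometry_features(mask: np.ndarray, spacing_mm) -> dict[str, float]:
    """17 shape descriptors of the binary tumour mask in physical units.

    Surface area comes from a marching-cubes mesh; the maximum 3D diameter is
    the largest distance between voxel corners (a single voxel therefore has
    diameter equal to its diagonal); axis lengths are the PCA axes of the
    voxel-centre cloud (4*sqrt(eigenvalue), IBSI-style).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    spacing = np.asarray(spacing_mm, dtype=np.float64)
    voxvol = float(spacing.prod())
    nvox = int(mask.sum())
    volume = nvox * voxvol

    # light Gaussian pre-smoothing regularizes the voxel staircase so the mesh
    # area of a digitized ball is unbiased; tiny masks fall back to the raw grid
    padded = np.pad(mask, 1).astype(np.float64)
    smoothed = ndimage.gaussian_filter(padded, 0.8)
    surf_src = smoothed if smoothed.max() > 0.5 else padded
    verts, faces, _, _ = marching_cubes(surf_src, level=0.5, spacing=tuple(spacing))
    area = float(mesh_surface_area(verts, faces))

    coords = np.argwhere(mask).astype(np.float64)
    phys = coords * spacing

    # corner cloud for the max diameter (convex hull keeps it O(hull^2))
    corners = []
    for d in ((0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1),
              (1, 1, 0), (1, 0, 1), (0, 1, 1), (1, 1, 1)):
        corners.append((coords + np.asarray(d) - 0.5) * spacing)
    corners = np.unique(np.concatenate(corners), axis=0)
    if len(corners) > 4:
        try:
            corners = corners[ConvexHull(corners).vertices]
        except Exception:  # degenerate (coplanar) cloud
            pass
    max_diam = float(pdist(corners).max())

    extents = (coords.max(axis=0) - coords.min(axis=0) + 1) * spacing

    if nvox > 1:
        cov = np.cov(phys.T)
        eig = np.sort(np.linalg.eigvalsh(np.atleast_2d(cov)))[::-1]
        eig = np.clip(eig, 0, None)
    else:
        eig = np.zeros(3)
    axes = 4.0 * np.sqrt(eig)
    elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0
    flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 1.0

    r_eq = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    sphericity = np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area
    return {
        "volume_mm3": volume,
        "voxel_count": float(nvox),
        "surface_area_mm2": area,
        "surface_to_volume": area / volume,
        "sphericity": float(sphericity),
        "compactness": float(volume / (np.sqrt(np.pi) * area**1.5)),
        "spherical_disproportion": float(area / (4.0 * np.pi * r_eq**2)),
        "max_diameter_3d_mm": max_diam,
        "extent_x_mm": float(extents[0]),
        "extent_y_mm": float(extents[1]),
        "extent_z_mm": float(extents[2]),
        "major_axis_mm": float(axes[0]),
        "minor_axis_mm": float(axes[1]),
        "least_axis_mm": float(axes[2]),
        "elongation": elongation,
        "flatness": flatness,
        "equivalent_diameter_mm": float(2.0 * r_eq),
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrix(quantized: np.ndarray, mask: np.ndarray, n_bins: int,
                offsets=DIRECTIONS_3D) -> np.ndarray:
    """Symmetrized, direction-merged co-occurrence matrix, normalized to sum 1."""
    q = np.where(mask, quantized, 0)
    counts = np.zeros((n_bins + 1, n_bins + 1), dtype=np.float64)
    for off in offsets:
        a, b = _shifted_pairs(q, off)
        np.add.at(counts, (a, b), 1.0)
        np.add.at(counts, (b, a), 1.0)
    mat = counts[1:, 1:]
    total = mat.sum()
    if total == 0:
        raise ValueError("fewer than 2 in-mask voxel pairs")
    return mat / total


def _shifted_pairs(q: np.ndarray, off) -> tuple[np.ndarray, np.ndarray]:
    """Aligned (center, neighbour) label arrays for one offset, zeros = outside."""
    sl_a, sl_b = [], []
    for o, n in zip(off, q.shape):
        if o >= 0:
            sl_a.append(slice(0, n - o))
            sl_b.append(slice(o, n))
        else:
            sl_a.append(slice(-o, n))
            sl_b.append(slice(0, n + o))
    a = q[tuple(sl_a)].ravel()
    b = q[tuple(sl_b)].ravel()
    keep = (a > 0) & (b > 0)
    return a[keep], b[keep]


def glcm_features(quantized: np.ndarray, mask: np.ndarray, n_bins: int = 64,
                  offsets=DIRECTIONS_3D) -> dict[str, float]:
    """22 Haralick-style features of the merged 3D co-occurrence matrix."""
    p = glcm_matrix(quantized, mask, n_bins, offsets)
    i = np.arange(1, n_bins + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())
    sigma = np.sqrt(sigma2)

    diff = np.abs(ii - jj)
    # p_{x+y}(k), k = 2..2N  and  p_{x-y}(k), k = 0..N-1
    ks = np.arange(2, 2 * n_bins + 1)
    pxy_sum = np.array([p[(ii + jj) == k].sum() for k in ks])
    kd = np.arange(0, n_bins)
    pxy_diff = np.array([p[diff == k].sum() for k in kd])

    if sigma > 0:
        correlation = float(((ii - mu) * (jj - mu) * p).sum() / sigma2)
    else:
        correlation = 1.0

    hx = _shannon_entropy(px)
    hxy = _shannon_entropy(p.ravel())
    pxpy = np.outer(px, px)
    nz = (p > 0) & (pxpy > 0)
    hxy1 = float(-(p[nz] * np.log2(pxpy[nz])).sum())
    nz2 = pxpy > 0
    hxy2 = float(-(pxpy[nz2] * np.log2(pxpy[nz2])).sum())
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    da = float((kd * pxy_diff).sum())
    off_diag = diff > 0
    return {
        "energy": float((p**2).sum()),
        "contrast": float(((ii - jj) ** 2 * p).sum()),
        "correlation": correlation,
        "variance": sigma2,
        "homogeneity": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "inverse_difference": float((p / (1.0 + diff)).sum()),
        "inverse_variance": float((p[off_diag] / diff[off_diag] ** 2).sum()),
        "entropy": hxy,
        "dissimilarity": float((diff * p).sum()),
        "max_probability": float(p.max()),
        "autocorrelation": float((ii * jj * p).sum()),
        "cluster_tendency": float(((ii + jj - 2 * mu) ** 2 * p).sum()),
        "cluster_shade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "cluster_prominence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
        "sum_average": float((ks * pxy_sum).sum()),
        "sum_variance": float((((ks - (ks * pxy_sum).sum()) ** 2) * pxy_sum).sum()),
        "sum_entropy": _shannon_entropy(pxy_sum),
        "difference_average": da,
        "difference_variance": float(((kd - da) ** 2 * pxy_diff).sum()),
        "difference_entropy": _shannon_entropy(pxy_diff),
        "imc1": float(imc1),
        "imc2": imc2,
    }


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def glrlm_matrix(quantized: np.ndarray, mask: np.ndarray, n_bins: int,
                 directions=DIRECTIONS_3D) -> np.ndarray:
    """Run-length matrix averaged over directions; rows = gray level, cols = length."""
    q = np.where(mask, quantized, 0).astype(np.int64)
    max_len = max(q.shape)
    acc = np.zeros((n_bins, max_len), dtype=np.float64)
    shape = q.shape
    for d in directions:
        mat = np.zeros_like(acc)
        starts = _run_starts(q, d)
        for x, y, z in starts:
            g = q[x, y, z]
            length = 1
            nx, ny, nz = x + d[0], y + d[1], z + d[2]
            while (0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]
                   and q[nx, ny, nz] == g):
                length += 1
                nx, ny, nz = nx + d[0], ny + d[1], nz + d[2]
            mat[g - 1, length - 1] += 1
        acc += mat
    return acc / len(directions)


def _run_starts(q: np.ndarray, d) -> np.ndarray:
    """Voxels that begin a run along direction d (predecessor absent or differs)."""
    prev = np.zeros_like(q)
    sl_dst, sl_src = [], []
    for o, n in zip(d, q.shape):
        if o >= 0:
            sl_dst.append(slice(o, n))
            sl_src.append(slice(0, n - o))
        else:
            sl_dst.append(slice(0, n + o))
            sl_src.append(slice(-o, n))
    prev[tuple(sl_dst)] = q[tuple(sl_src)]
    start = (q > 0) & (prev != q)
    return np.argwhere(start)


def glrlm_features(quantized: np.ndarray, mask: np.ndarray, n_bins: int = 64,
                   directions=DIRECTIONS_3D) -> dict[str, float]:
    """11 run-length features of the direction-averaged 3D run matrix."""
    if not np.asarray(mask).any():
        raise ValueError("empty mask")
    r = glrlm_matrix(quantized, mask, n_bins, directions)
    nr = r.sum()
    npix = float(np.asarray(mask).sum())
    g = np.arange(1, r.shape[0] + 1, dtype=np.float64)[:, None]
    l = np.arange(1, r.shape[1] + 1, dtype=np.float64)[None, :]
    rg = r.sum(axis=1)  # per gray level
    rl = r.sum(axis=0)  # per run length
    return {
        "sre": float((r / l**2).sum() / nr),
        "lre": float((r * l**2).sum() / nr),
        "gln": float((rg**2).sum() / nr),
        "rln": float((rl**2).sum() / nr),
        "rp": float(nr / npix),
        "lgre": float((r / g**2).sum() / nr),
        "hgre": float((r * g**2).sum() / nr),
        "srlge": float((r / (g**2 * l**2)).sum() / nr),
        "srhge": float((r * g**2 / l**2).sum() / nr),
        "lrlge": float((r * l**2 / g**2).sum() / nr),
        "lrhge": float((r * l**2 * g**2).sum() / nr),
    }


# ---------------------------------------------------------------------------
# 3D LBP
# ---------------------------------------------------------------------------

def lbp_codes(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Rotation-pooled 3D LBP code per interior ROI voxel.

    The code is the count of the 26 neighbours whose intensity strictly
    exceeds the centre (0..26) — invariant under any rotation of the
    neighbourhood — pooled onto 16 bins by fixed uniform binning.
    """
    mask = np.asarray(mask, dtype=bool)
    interior = mask.copy()
    interior[0, :, :] = interior[-1, :, :] = False
    interior[:, 0, :] = interior[:, -1, :] = False
    interior[:, :, 0] = interior[:, :, -1] = False
    if not interior.any():
        raise ValueError("mask has no interior voxel")
    count = np.zeros(values.shape, dtype=np.int64)
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                shifted = np.roll(values, (-dx, -dy, -dz), axis=(0, 1, 2))
                count += shifted > values
    codes = count[interior]
    return np.minimum(15, codes * 16 // 27)


def lbp_features(volume: ImageVolume, mask: np.ndarray) -> dict[str, float]:
    """Normalized 16-bin LBP code histogram plus its entropy (17 values)."""
    codes = lbp_codes(volume.values, mask)
    counts = np.bincount(codes, minlength=16).astype(np.float64)
    p = counts / counts.sum()
    out = {f"bin_{i:02d}": float(p[i]) for i in range(16)}
    out["entropy"] = _shannon_entropy(p)
    return out


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------

def _crop_for_mask(volume: ImageVolume, mask: np.ndarray, margin: int = 4):
    """Crop to the mask bounding box (+margin) at even start indices.

    Even alignment keeps the decimated wavelet pairing identical to the
    full-volume decomposition for short (Haar-length) filters.
    """
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    lo -= lo % 2
    hi = np.minimum(idx.max(axis=0) + margin + 1, mask.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return volume.copy_with(volume.values[sl]), mask[sl]


def extract_intratumoral(volume: ImageVolume, tumor_mask: np.ndarray,
                         n_bins: int = 64, wavelet: str = "haar") -> dict[str, float]:
    """All 593 intratumoral features, keyed by the manifest names.

    Expects an isotropically resampled, Z-score-standardized volume and a
    nonempty tumour mask on the same grid.
    """
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    if tumor_mask.shape != volume.shape:
        raise ValueError("mask shape does not match volume")
    if not tumor_mask.any():
        raise ValueError("empty tumor mask")
    features: dict[str, float] = {}
    for name, val in geometry_features(tumor_mask, volume.spacing_mm).items():
        features[f"geometry_{name}"] = val

    vol_c, mask_c = _crop_for_mask(volume, tumor_mask)
    wset = wavelet_decompose(vol_c, wavelet=wavelet)
    for img_name, img in wset.images().items():
        q = np.zeros(img.shape, dtype=np.int64)
        q[mask_c] = quantize(img.values[mask_c], n_bins)
        for n, v in histogram_features(img, mask_c, n_bins).items():
            features[f"{img_name}_histogram_{n}"] = v
        for n, v in glcm_features(q, mask_c, n_bins).items():
            features[f"{img_name}_glcm_{n}"] = v
        for n, v in glrlm_features(q, mask_c, n_bins).items():
            features[f"{img_name}_glrlm_{n}"] = v
        for n, v in lbp_features(img, mask_c).items():
            features[f"{img_name}_lbp_{n}"] = v
    order = manifest_names()
    assert set(features) == set(order)
    return {k: features[k] for k in order}
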