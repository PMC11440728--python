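"""Volume container, NIfTI I/O, resampling, standardization and wavelet decomposition.

Shared preprocessing for both the intratumoral and the peritumoral-vasculature
feature extractors: CT volumes are resampled to isotropic 1 mm voxels,
intensity-standardized by a whole-volume Z-score, and decomposed into the eight
single-level 3D wavelet subbands (LLL ... HHH).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
import SimpleITK as sitk

#: Canonical subband labels: one low/high-pass choice per axis (x, y, z).
WAVELET_LABELS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


@dataclass
class ImageVolume:
    """A 3D scalar grid with physical voxel spacing and origin (millimetres).

    ``values`` is indexed ``[x, y, z]``; ``spacing_mm`` and ``origin_mm`` are
    per-axis in the same order.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D volume, got {self.values.ndim}D")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def copy_with(self, values: np.ndarray) -> "ImageVolume":
        return ImageVolume(values, self.spacing_mm, self.origin_mm)


@dataclass
class WaveletSet:
    """Original volume plus its 8 single-level wavelet subband images.

    Each subband is the inverse reconstruction of one coefficient band with all
    other bands zeroed, so all nine grids share shape and spacing and the sum
    of the eight subbands reproduces the original (orthogonal decomposition).
    """

    original: ImageVolume
    subbands: dict[str, ImageVolume] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.subbands) != set(WAVELET_LABELS):
            raise ValueError(f"subband labels must be exactly {WAVELET_LABELS}")
        for label, sub in self.subbands.items():
            if sub.shape != self.original.shape:
                raise ValueError(f"subband {label} shape {sub.shape} != {self.original.shape}")

    def images(self) -> dict[str, ImageVolume]:
        """Return the 9 labelled images ('original' first)."""
        out = {"original": self.original}
        out.update({k: self.subbands[k] for k in WAVELET_LABELS})
        return out


def _to_sitk(volume: ImageVolume) -> sitk.Image:
    # SimpleITK arrays are indexed [z, y, x]; ImageVolume is [x, y, z].
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.values.T.astype(np.float32)))
    img.SetSpacing(volume.spacing_mm)
    img.SetOrigin(volume.origin_mm)
    return img


def _from_sitk(img: sitk.Image) -> ImageVolume:
    arr = sitk.GetArrayFromImage(img).T
    return ImageVolume(arr, tuple(img.GetSpacing()), tuple(img.GetOrigin()))


def read_volume(path: str) -> ImageVolume:
    """Read a 3D NIfTI volume (values + spacing + origin)."""
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"expected a 3D image, got {img.GetDimension()}D: {path}")
    return _from_sitk(img)


def write_volume(volume: ImageVolume, path: str) -> None:
    """Write a volume as NIfTI; float32 values, exact spacing/origin."""
    sitk.WriteImage(_to_sitk(volume), str(path))


def resample_isotropic(
    volume: ImageVolume, target_mm: float = 1.0, is_mask: bool = False
) -> ImageVolume:
    """Resample to isotropic voxels (trilinear; nearest-neighbour for masks).

    Physical extent is preserved to within one voxel per axis.
    """
    if target_mm <= 0:
        raise ValueError("target spacing must be positive")
    if volume.spacing_mm == (target_mm,) * 3:
        return volume.copy_with(volume.values.copy())
    img = _to_sitk(volume)
    new_size = [
        max(1, int(round(n * s / target_mm)))
        for n, s in zip(volume.shape, volume.spacing_mm)
    ]
    interp = sitk.sitkNearestNeighbor if is_mask else sitk.sitkLinear
    out = sitk.Resample(
        img,
        new_size,
        sitk.Transform(),
        interp,
        img.GetOrigin(),
        (target_mm,) * 3,
        img.GetDirection(),
        0.0,
        img.GetPixelID(),
    )
    res = _from_sitk(out)
    if is_mask:
        res = ImageVolume(res.values > 0.5, res.spacing_mm, res.origin_mm)
    return res


def zscore_standardize(volume: ImageVolume) -> ImageVolume:
    """Standardize intensities to zero mean, unit SD over the whole volume."""
    vals = volume.values.astype(np.float64)
    sd = vals.std()
    if sd == 0:
        raise ValueError("degenerate intensity: volume has zero variance")
    return volume.copy_with((vals - vals.mean()) / sd)


def wavelet_decompose(volume: ImageVolume, wavelet: str = "haar") -> WaveletSet:
    """Single-level separable 3D wavelet decomposition into 8 labelled subbands.

    Low (L) and high (H) pass filters are applied along each axis; the label's
    characters correspond to axes (x, y, z). Each subband image is the inverse
    transform of that band alone, so it has the original shape and the eight
    subbands sum to the input exactly (up to float round-off) for an
    orthogonal wavelet.
    """
    if any(n < 2 for n in volume.shape):
        raise ValueError(f"each axis must have length >= 2, got {volume.shape}")
    vals = volume.values.astype(np.float64)
    coeffs = pywt.dwtn(vals, wavelet, mode="symmetric")
    subbands: dict[str, ImageVolume] = {}
    for label in WAVELET_LABELS:
        # pywt keys use a/d per axis: L -> a (approximation), H -> d (detail)
        key = label.lower().replace("l", "a").replace("h", "d")
        solo = {k: (v if k == key else np.zeros_like(v)) for k, v in coeffs.items()}
        rec = pywt.idwtn(solo, wavelet, mode="symmetric")
        rec = rec[tuple(slice(0, n) for n in vals.shape)]
        subbands[label] = volume.copy_with(rec)
    return WaveletSet(original=volume, subbands=subbands)


def wavelet_coefficients(volume: ImageVolume, wavelet: str = "haar") -> dict[str, np.ndarray]:
    """Raw decimated coefficient arrays keyed by the canonical labels."""
    coeffs = pywt.dwtn(volume.values.astype(np.float64), wavelet, mode="symmetric")
    out = {}
    for label in WAVELET_LABELS:
        key = label.lower().replace("l", "a").replace("h", "d")
        out[label] = coeffs[key]
    return out
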