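"""Image preprocessing retained in the pipeline's scope.

The pipeline assumes its inputs are already co-registered, bias-field-free
volumes (classical tools such as N4 bias correction, skull stripping and
rigid registration are deliberately out of scope and expected upstream).
What remains here is isotropic resampling, histogram-matching intensity
normalization, and per-region gray-level quantization for the texture
matrices.

Coordinate convention: voxel indices are 0-based and world coordinates are
``index * spacing`` per axis; no orientation matrix beyond identity is
supported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Tuple

import numpy as np
from scipy import ndimage
from skimage.exposure import match_histograms as _sk_match_histograms

#: Label codes of the segmentation mask.
LABEL_NECROSIS = 1
LABEL_ENHANCEMENT = 2
LABEL_EDEMA = 3

#: Region codes -> constituent label sets.  SN = necrosis, SNE = tumor core
#: (necrosis + enhancement), ST = whole tumor (all three labels).
REGION_LABELS = {
    "SN": (LABEL_NECROSIS,),
    "ENH": (LABEL_ENHANCEMENT,),
    "ED": (LABEL_EDEMA,),
    "SNE": (LABEL_NECROSIS, LABEL_ENHANCEMENT),
    "ST": (LABEL_NECROSIS, LABEL_ENHANCEMENT, LABEL_EDEMA),
}

REGION_CODES = tuple(REGION_LABELS)


@dataclass
class SubregionMask:
    """Labeled tumor subregion mask.

    ``labels`` holds 0 = background, 1 = necrosis, 2 = enhancement,
    3 = edema on the same grid (and spacing) as the modality volumes.
    Derived regions are unions of the base labels (see ``REGION_LABELS``).
    """

    labels: np.ndarray
    spacing: Tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.labels.ndim != 3:
            raise ValueError("mask labels must be a 3D grid")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive components")
        bad = np.setdiff1d(np.unique(self.labels), [0, 1, 2, 3])
        if bad.size:
            raise ValueError(f"mask contains invalid label codes {bad.tolist()}")

    def region(self, code: str) -> np.ndarray:
        """Boolean voxel mask of a derived region (``SN``/``ENH``/``ED``/``SNE``/``ST``)."""
        if code not in REGION_LABELS:
            raise KeyError(f"unknown region code {code!r}; expected one of {REGION_CODES}")
        return np.isin(self.labels, REGION_LABELS[code])

    def region_voxel_count(self, code: str) -> int:
        return int(self.region(code).sum())

    def is_valid_tumor(self) -> bool:
        """True when each of the three base labels is nonempty."""
        return all((self.labels == lab).any() for lab in (1, 2, 3))

    def copy(self) -> "SubregionMask":
        return SubregionMask(self.labels.copy(), self.spacing)


def _resampled_shape(shape: Iterable[int], spacing: Iterable[float], target: float) -> Tuple[int, ...]:
    # sample world positions j*target for j = 0..floor((n-1)*spacing/target)
    out = []
    for n, s in zip(shape, spacing):
        out.append(int(np.floor((n - 1) * s / target + 1e-9)) + 1)
    return tuple(out)


def resample_isotropic(
    volume: np.ndarray,
    spacing: Tuple[float, float, float],
    target_spacing: float = 1.0,
    order: int = 1,
) -> Tuple[np.ndarray, Tuple[float, float, float]]:
    """Resample a scalar volume to isotropic voxels.

    Scalar volumes use trilinear interpolation (``order=1``); label masks
    must use ``order=0`` (see :func:`resample_mask`).  Output sample ``j``
    on each axis sits at world coordinate ``j * target_spacing``, so a
    volume already on the target grid is returned unchanged.
    """
    volume = np.asarray(volume)
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing) or target_spacing <= 0:
        raise ValueError("voxel spacings must be positive")
    new_shape = _resampled_shape(volume.shape, spacing, target_spacing)
    if new_shape == volume.shape and all(abs(s - target_spacing) < 1e-12 for s in spacing):
        return volume.copy(), (target_spacing,) * 3
    grids = np.meshgrid(
        *[np.arange(n) * target_spacing / s for n, s in zip(new_shape, spacing)],
        indexing="ij",
    )
    out = ndimage.map_coordinates(
        volume.astype(float, copy=False), np.stack(grids), order=order, mode="nearest"
    )
    if order == 0:
        out = out.astype(volume.dtype)
    return out, (target_spacing,) * 3


def resample_mask(mask: SubregionMask, target_spacing: float = 1.0) -> SubregionMask:
    """Nearest-neighbor resampling of a label mask to isotropic voxels."""
    labels, spacing = resample_isotropic(mask.labels, mask.spacing, target_spacing, order=0)
    return SubregionMask(labels.astype(mask.labels.dtype), spacing)


def histogram_match(volume: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Quantile-map ``volume`` intensities onto the distribution of ``reference``.

    Raises on a constant reference, for which the inverse CDF is undefined.
    """
    volume = np.asarray(volume, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if volume.size == 0 or reference.size == 0:
        raise ValueError("histogram matching requires nonempty volumes")
    if np.ptp(reference) == 0:
        raise ValueError("reference volume is constant; histogram matching undefined")
    return _sk_match_histograms(volume, reference)


def quantize_gray_levels(volume: np.ndarray, region: np.ndarray, n_levels: int = 32) -> np.ndarray:
    """Quantize region intensities to levels ``1..n_levels`` by equal-width bins.

    Returns an integer grid of the volume's shape with 0 outside the region.
    Bins span the region's min-max range; the maximum maps to ``n_levels``.
    A constant region maps entirely to level 1 (documented convention).
    """
    volume = np.asarray(volume, dtype=float)
    region = np.asarray(region, dtype=bool)
    if n_levels < 2:
        raise ValueError("n_levels must be at least 2")
    if volume.shape != region.shape:
        raise ValueError("volume and region must share a shape")
    if not region.any():
        raise ValueError("region is empty")
    out = np.zeros(volume.shape, dtype=np.int32)
    vals = volume[region]
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        out[region] = 1
        return out
    width = (hi - lo) / n_levels
    levels = np.floor((vals - lo) / width).astype(np.int32) + 1
    out[region] = np.clip(levels, 1, n_levels)
    return out
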