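"""Handcrafted radiomics features: geometry, first-order intensity, texture.

The extractor produces 1403 named features per patient: a 23-descriptor 3D
shape set computed once from the segmentation mask, and per region-modality
(5 subregions x 4 modalities = 20 combinations) 17 first-order intensity
descriptors plus 52 texture descriptors from four matrix families — 22 GLCM,
13 GLRLM, 12 GLSZM and 5 NGTDM — giving 23 + 340 + 1040 = 1403.

Texture matrices are computed in 3D over the 13 unique direction offsets of
the 26-neighborhood at distance 1 and merged (summed) across directions
before descriptor evaluation, the most common radiomics convention.  Gray
levels are quantized per region per modality into a fixed number of
equal-width bins (default 32).

Degenerate inputs (single-voxel regions, constant regions) return
documented conventional values with a warning rather than raising, so
cohort-level extraction never aborts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

from radsurv.phantom import MODALITIES, PatientRecord
from radsurv.preprocess import REGION_CODES, SubregionMask, quantize_gray_levels

N_GRAY_LEVELS = 32

#: The 13 unique direction offsets of the 3D 26-neighborhood at distance 1.
OFFSETS_13: Tuple[Tuple[int, int, int], ...] = (
    (0, 0, 1),
    (0, 1, 0),
    (1, 0, 0),
    (0, 1, 1),
    (0, 1, -1),
    (1, 0, 1),
    (1, 0, -1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)

NGTDM_COARSENESS_CAP = 1e6

GEOMETRY_FEATURES = (
    "volume",
    "surface_area",
    "surface_volume_ratio",
    "compactness1",
    "compactness2",
    "sphericity",
    "spherical_disproportion",
    "max_diameter_3d",
    "major_axis_length",
    "minor_axis_length",
    "least_axis_length",
    "elongation",
    "flatness",
    "bbox_extent_x",
    "bbox_extent_y",
    "bbox_extent_z",
    "extent_fraction",
    "necrosis_volume",
    "enhancement_volume",
    "edema_volume",
    "necrosis_fraction",
    "enhancement_fraction",
    "edema_fraction",
)

INTENSITY_FEATURES = (
    "mean",
    "median",
    "minimum",
    "maximum",
    "range",
    "variance",
    "std",
    "skewness",
    "kurtosis",
    "energy",
    "entropy",
    "rms",
    "mean_abs_dev",
    "uniformity",
    "p10",
    "p90",
    "iqr",
)

GLCM_FEATURES = (
    "contrast",
    "correlation",
    "energy",
    "entropy",
    "homogeneity1",
    "homogeneity2",
    "dissimilarity",
    "autocorrelation",
    "cluster_shade",
    "cluster_prominence",
    "cluster_tendency",
    "max_probability",
    "sum_average",
    "sum_entropy",
    "sum_variance",
    "difference_entropy",
    "difference_variance",
    "imc1",
    "imc2",
    "idmn",
    "idn",
    "inverse_variance",
)

GLRLM_FEATURES = (
    "sre",
    "lre",
    "gln",
    "rln",
    "rp",
    "lglre",
    "hglre",
    "srlgle",
    "srhgle",
    "lrlgle",
    "lrhgle",
    "glv",
    "rlv",
)

GLSZM_FEATURES = (
    "sae",
    "lae",
    "gln",
    "szn",
    "zp",
    "lglze",
    "hglze",
    "salgle",
    "sahgle",
    "lalgle",
    "lahgle",
    "zv",
)

NGTDM_FEATURES = ("coarseness", "contrast", "busyness", "complexity", "strength")

TEXTURE_FAMILIES = {
    "GLCM": GLCM_FEATURES,
    "GLRLM": GLRLM_FEATURES,
    "GLSZM": GLSZM_FEATURES,
    "NGTDM": NGTDM_FEATURES,
}


@dataclass
class TextureMatrix:
    """A texture matrix with its aggregation metadata.

    GLCM stores symmetrized, direction-merged co-occurrence counts; GLRLM
    and GLSZM store raw run / zone counts; NGTDM stores per-level counts
    ``n_i`` and summed absolute neighborhood differences ``s_i``.
    """

    kind: str
    matrix: np.ndarray
    n_levels: int
    directions: Tuple[Tuple[int, int, int], ...]
    n_voxels: int
    extra: Optional[np.ndarray] = None  # NGTDM s_i column


@dataclass(frozen=True)
class CatalogEntry:
    name: str
    region: Optional[str]  # None for geometry's subregion-spanning set
    modality: Optional[str]  # None for geometry
    family: str


class FeatureCatalog:
    """Ordered catalog of the 1403 handcrafted feature names.

    Enforces the documented composition at construction: 23 geometry +
    340 intensity + 1040 texture.
    """

    def __init__(self, entries: Sequence[CatalogEntry]):
        names = [e.name for e in entries]
        if len(set(names)) != len(names):
            raise ValueError("catalog feature names must be unique")
        counts = {"geometry": 0, "intensity": 0, "texture": 0}
        for e in entries:
            if e.family == "geometry":
                counts["geometry"] += 1
            elif e.family == "intensity":
                counts["intensity"] += 1
            elif e.family in TEXTURE_FAMILIES:
                counts["texture"] += 1
            else:
                raise ValueError(f"unknown feature family {e.family!r}")
        if counts != {"geometry": 23, "intensity": 340, "texture": 1040}:
            raise ValueError(f"catalog composition {counts} violates the 23/340/1040 contract")
        self.entries: List[CatalogEntry] = list(entries)
        self.names: List[str] = names

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.__dict__ for e in self.entries])


def default_catalog() -> FeatureCatalog:
    """The package's frozen 1403-feature catalog.

    Composition per region-modality: 17 intensity + 22 GLCM + 13 GLRLM +
    12 GLSZM + 5 NGTDM; geometry is modality-independent.  Names follow
    ``MODALITY_REGION_FAMILY_name`` (geometry: ``GEOM_name``).
    """
    entries: List[CatalogEntry] = [
        CatalogEntry(f"GEOM_{f}", None, None, "geometry") for f in GEOMETRY_FEATURES
    ]
    for modality in MODALITIES:
        for region in REGION_CODES:
            entries.extend(
                CatalogEntry(f"{modality}_{region}_INT_{f}", region, modality, "intensity")
                for f in INTENSITY_FEATURES
            )
            for family, feats in TEXTURE_FAMILIES.items():
                entries.extend(
                    CatalogEntry(f"{modality}_{region}_{family}_{f}", region, modality, family)
                    for f in feats
                )
    return FeatureCatalog(entries)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def compute_geometry_features(mask: SubregionMask, spacing: Optional[Sequence[float]] = None) -> Dict[str, float]:
    """The 23-descriptor 3D shape set.

    Shape descriptors are computed on the whole tumor (ST); subregion
    volumes and volume fractions cover necrosis / enhancement / edema.
    Surface area comes from a marching-cubes mesh of the binary mask.
    """
    spacing = tuple(spacing) if spacing is not None else mask.spacing
    whole = mask.region("ST")
    if not whole.any():
        raise ValueError("whole-tumor region ST is empty")
    voxvol = float(np.prod(spacing))
    n_voxels = int(whole.sum())
    volume = n_voxels * voxvol

    padded = np.pad(whole.astype(float), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    surface = float(measure.mesh_surface_area(verts, faces))

    idx = np.argwhere(whole)
    coords = idx * np.asarray(spacing)
    if len(coords) > 3:
        try:
            hull = ConvexHull(coords)
            hull_pts = coords[hull.vertices]
        except Exception:  # degenerate (coplanar) point sets
            hull_pts = coords
    else:
        hull_pts = coords
    max_diam = float(pdist(hull_pts).max()) if len(hull_pts) > 1 else 0.0

    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(coords)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eig = np.clip(eig, 0.0, None)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()
    elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0
    flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0

    extents = [(idx[:, a].max() - idx[:, a].min() + 1) * spacing[a] for a in range(3)]
    bbox_volume = float(np.prod(extents))

    r_equiv = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    sphericity = (36.0 * np.pi * volume**2) ** (1.0 / 3.0) / surface
    out = {
        "volume": volume,
        "surface_area": surface,
        "surface_volume_ratio": surface / volume,
        "compactness1": volume / (np.sqrt(np.pi) * surface ** 1.5),
        "compactness2": 36.0 * np.pi * volume**2 / surface**3,
        "sphericity": sphericity,
        "spherical_disproportion": surface / (4.0 * np.pi * r_equiv**2),
        "max_diameter_3d": max_diam,
        "major_axis_length": major,
        "minor_axis_length": minor,
        "least_axis_length": least,
        "elongation": elongation,
        "flatness": flatness,
        "bbox_extent_x": extents[0],
        "bbox_extent_y": extents[1],
        "bbox_extent_z": extents[2],
        "extent_fraction": volume / bbox_volume,
    }
    for name, label in (("necrosis", 1), ("enhancement", 2), ("edema", 3)):
        subvol = float((mask.labels == label).sum()) * voxvol
        out[f"{name}_volume"] = subvol
        out[f"{name}_fraction"] = subvol / volume
    return out


# ---------------------------------------------------------------------------
# first-order intensity
# ---------------------------------------------------------------------------


def compute_intensity_features(volume: np.ndarray, region: np.ndarray, n_bins: int = N_GRAY_LEVELS) -> Dict[str, float]:
    """17 first-order statistics of the region's voxel intensities.

    Entropy and uniformity use an equal-width ``n_bins`` histogram over the
    region's intensity range; a constant region has entropy 0, uniformity 1.
    """
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("intensity region is empty")
    v = np.asarray(volume, dtype=float)[region]
    rng = float(v.max() - v.min())
    if rng > 0:
        hist, _ = np.histogram(v, bins=n_bins, range=(v.min(), v.max()))
        p = hist / hist.sum()
        p = p[p > 0]
    else:
        p = np.array([1.0])
    skew = stats.skew(v) if rng > 0 else 0.0
    kurt = stats.kurtosis(v, fisher=False) if rng > 0 else 0.0
    return {
        "mean": float(v.mean()),
        "median": float(np.median(v)),
        "minimum": float(v.min()),
        "maximum": float(v.max()),
        "range": rng,
        "variance": float(v.var(ddof=0)),
        "std": float(v.std(ddof=0)),
        "skewness": float(skew),
        "kurtosis": float(kurt),
        "energy": float((v**2).sum()),
        "entropy": float(-(p * np.log2(p)).sum()),
        "rms": float(np.sqrt((v**2).mean())),
        "mean_abs_dev": float(np.abs(v - v.mean()).mean()),
        "uniformity": float((p**2).sum()),
        "p10": float(np.percentile(v, 10)),
        "p90": float(np.percentile(v, 90)),
        "iqr": float(np.percentile(v, 75) - np.percentile(v, 25)),
    }


# ---------------------------------------------------------------------------
# texture matrix helpers
# ---------------------------------------------------------------------------


def _shifted_pair(arr: np.ndarray, off: Sequence[int]) -> Tuple[np.ndarray, np.ndarray]:
    """Views (a, b) with b displaced from a by ``off``."""
    sl_a, sl_b = [], []
    for o, dim in zip(off, arr.shape):
        if o >= 0:
            sl_a.append(slice(0, dim - o))
            sl_b.append(slice(o, dim))
        else:
            sl_a.append(slice(-o, dim))
            sl_b.append(slice(0, dim + o))
    return arr[tuple(sl_a)], arr[tuple(sl_b)]


def _crop_to_region(levels: np.ndarray) -> np.ndarray:
    nz = np.argwhere(levels > 0)
    lo = nz.min(axis=0)
    hi = nz.max(axis=0) + 1
    return levels[tuple(slice(a, b) for a, b in zip(lo, hi))]


def _as_levels_3d(levels: np.ndarray) -> np.ndarray:
    levels = np.asarray(levels)
    if levels.ndim == 2:
        levels = levels[..., np.newaxis]
    if levels.ndim != 3:
        raise ValueError("level grid must be 2D or 3D")
    return levels


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------


def compute_glcm(
    levels: np.ndarray,
    n_levels: int = N_GRAY_LEVELS,
    offsets: Optional[Sequence[Sequence[int]]] = None,
) -> TextureMatrix:
    """Gray-level co-occurrence counts, symmetrized and merged over directions.

    ``levels`` is an integer grid with 0 outside the region and values
    ``1..n_levels`` inside; pairs are counted at distance 1 along each
    offset (default: all 13 unique 26-neighborhood directions).
    """
    levels = _as_levels_3d(levels)
    if not (levels > 0).any():
        raise ValueError("region is empty")
    levels = _crop_to_region(levels)
    offsets = tuple(tuple(o) for o in (offsets if offsets is not None else OFFSETS_13))
    mat = np.zeros((n_levels, n_levels), dtype=float)
    for off in offsets:
        a, b = _shifted_pair(levels, off)
        valid = (a > 0) & (b > 0)
        if valid.any():
            ia = a[valid] - 1
            ib = b[valid] - 1
            np.add.at(mat, (ia, ib), 1.0)
    mat = mat + mat.T
    if mat.sum() == 0:
        warnings.warn("no co-occurrence pairs in region; GLCM features default to 0", stacklevel=2)
    return TextureMatrix("GLCM", mat, n_levels, offsets, int((levels > 0).sum()))


def glcm_features(tm: TextureMatrix) -> Dict[str, float]:
    """The 22 co-occurrence descriptors of a (merged) GLCM."""
    total = tm.matrix.sum()
    n = tm.n_levels
    if total == 0:
        return {f: 0.0 for f in GLCM_FEATURES}
    p = tm.matrix / total
    i = np.arange(1, n + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mux = float((i * px).sum())
    muy = float((i * py).sum())
    sigx = float(np.sqrt(((i - mux) ** 2 * px).sum()))
    sigy = float(np.sqrt(((i - muy) ** 2 * py).sum()))
    nz = p > 0

    def _ent(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    # p_{x+y}(k), k = 2..2n and p_{x-y}(k), k = 0..n-1
    ksum = ii + jj
    kdiff = np.abs(ii - jj)
    pxy_sum = np.array([p[ksum == k].sum() for k in range(2, 2 * n + 1)])
    pxy_diff = np.array([p[kdiff == k].sum() for k in range(0, n)])
    sa = float((np.arange(2, 2 * n + 1) * pxy_sum).sum())
    da = float((np.arange(0, n) * pxy_diff).sum())

    hxy = _ent(p)
    pxpy = np.outer(px, py)
    with np.errstate(divide="ignore", invalid="ignore"):
        hxy1 = float(-np.nansum(np.where(nz & (pxpy > 0), p * np.log2(pxpy), 0.0)))
        hxy2 = _ent(pxpy)
    hx, hy = _ent(px), _ent(py)
    denom_imc1 = max(hx, hy)
    imc1 = (hxy - hxy1) / denom_imc1 if denom_imc1 > 0 else 0.0
    arg = 1.0 - np.exp(-2.0 * max(hxy2 - hxy, 0.0))
    imc2 = float(np.sqrt(max(arg, 0.0)))

    if sigx * sigy > 0:
        correlation = float((p * (ii - mux) * (jj - muy)).sum() / (sigx * sigy))
    else:
        correlation = 0.0
    offdiag = kdiff > 0
    return {
        "contrast": float((p * (ii - jj) ** 2).sum()),
        "correlation": correlation,
        "energy": float((p**2).sum()),
        "entropy": hxy,
        "homogeneity1": float((p / (1.0 + kdiff)).sum()),
        "homogeneity2": float((p / (1.0 + kdiff**2)).sum()),
        "dissimilarity": float((p * kdiff).sum()),
        "autocorrelation": float((p * ii * jj).sum()),
        "cluster_shade": float((p * (ii + jj - mux - muy) ** 3).sum()),
        "cluster_prominence": float((p * (ii + jj - mux - muy) ** 4).sum()),
        "cluster_tendency": float((p * (ii + jj - mux - muy) ** 2).sum()),
        "max_probability": float(p.max()),
        "sum_average": sa,
        "sum_entropy": _ent(pxy_sum),
        "sum_variance": float(((np.arange(2, 2 * n + 1) - sa) ** 2 * pxy_sum).sum()),
        "difference_entropy": _ent(pxy_diff),
        "difference_variance": float(((np.arange(0, n) - da) ** 2 * pxy_diff).sum()),
        "imc1": float(imc1),
        "imc2": imc2,
        "idmn": float((p / (1.0 + (kdiff / n) ** 2)).sum()),
        "idn": float((p / (1.0 + kdiff / n)).sum()),
        "inverse_variance": float((p[offdiag] / kdiff[offdiag] ** 2).sum()),
    }


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------


def _runs_for_offset(levels: np.ndarray, off: Sequence[int]) -> Tuple[np.ndarray, np.ndarray]:
    """(gray level, run length) of every maximal run along one direction.

    Run lengths are computed by fixed-point propagation of "continuation
    length" along the offset; convergence takes as many sweeps as the
    longest run.
    """
    in_region = levels > 0
    # same-level link from x to x + off
    link = np.zeros(levels.shape, dtype=bool)
    a, b = _shifted_pair(levels, off)
    la, _ = _shifted_pair(link, off)
    la[...] = (a > 0) & (a == b)

    runlen = in_region.astype(np.int64)
    while True:
        nxt = np.zeros(levels.shape, dtype=np.int64)
        na, nb = _shifted_pair(nxt, off)
        _, rb = _shifted_pair(runlen, off)
        na[...] = rb
        new = np.where(link, 1 + nxt, in_region.astype(np.int64))
        if np.array_equal(new, runlen):
            break
        runlen = new

    # run starts: in-region voxels with no same-level predecessor at x - off
    neg = tuple(-o for o in off)
    pred_link = np.zeros(levels.shape, dtype=bool)
    a2, b2 = _shifted_pair(levels, neg)
    pa, _ = _shifted_pair(pred_link, neg)
    pa[...] = (a2 > 0) & (a2 == b2)
    starts = in_region & ~pred_link
    return levels[starts], runlen[starts]


def compute_glrlm(
    levels: np.ndarray,
    n_levels: int = N_GRAY_LEVELS,
    offsets: Optional[Sequence[Sequence[int]]] = None,
) -> TextureMatrix:
    """Gray-level run-length counts summed over directions (default 13)."""
    levels = _as_levels_3d(levels)
    if not (levels > 0).any():
        raise ValueError("region is empty")
    levels = _crop_to_region(levels)
    offsets = tuple(tuple(o) for o in (offsets if offsets is not None else OFFSETS_13))
    max_len = int(np.ceil(np.sqrt(sum(d**2 for d in levels.shape))))
    mat = np.zeros((n_levels, max_len), dtype=np.int64)
    for off in offsets:
        g, r = _runs_for_offset(levels, off)
        np.add.at(mat, (g - 1, r - 1), 1)
    # trim trailing all-zero run-length columns
    max_r = int(np.max(np.nonzero(mat.sum(axis=0))[0])) + 1 if mat.any() else 1
    return TextureMatrix("GLRLM", mat[:, :max_r], n_levels, offsets, int((levels > 0).sum()))


def _rlm_style_features(mat: np.ndarray, n_voxels: int, n_directions: int, names, size_word: str) -> Dict[str, float]:
    """Shared run-length / size-zone descriptor arithmetic."""
    total = mat.sum()
    out = {f: 0.0 for f in names}
    if total == 0:
        return out
    p = mat / total
    g = np.arange(1, mat.shape[0] + 1, dtype=float)
    r = np.arange(1, mat.shape[1] + 1, dtype=float)
    gg, rr = np.meshgrid(g, r, indexing="ij")
    pg = p.sum(axis=1)
    pr = p.sum(axis=0)
    mu_g = float((g * pg).sum())
    mu_r = float((r * pr).sum())
    vals = {
        "short": float((p / rr**2).sum()),
        "long": float((p * rr**2).sum()),
        "gln": float((mat.sum(axis=1) ** 2).sum() / total),
        "sizen": float((mat.sum(axis=0) ** 2).sum() / total),
        "pct": float(total / (n_voxels * n_directions)),
        "lgl": float((p / gg**2).sum()),
        "hgl": float((p * gg**2).sum()),
        "slgl": float((p / (gg**2 * rr**2)).sum()),
        "shgl": float((p * gg**2 / rr**2).sum()),
        "llgl": float((p * rr**2 / gg**2).sum()),
        "lhgl": float((p * gg**2 * rr**2).sum()),
        "glv": float((p * (gg - mu_g) ** 2).sum()),
        "sizev": float((p * (rr - mu_r) ** 2).sum()),
    }
    if size_word == "run":
        keys = ["short", "long", "gln", "sizen", "pct", "lgl", "hgl", "slgl", "shgl", "llgl", "lhgl", "glv", "sizev"]
    else:
        keys = ["short", "long", "gln", "sizen", "pct", "lgl", "hgl", "slgl", "shgl", "llgl", "lhgl", "sizev"]
    return dict(zip(names, (vals[k] for k in keys)))


def glrlm_features(tm: TextureMatrix) -> Dict[str, float]:
    """13 run-length descriptors; run percentage is normalized per direction."""
    return _rlm_style_features(tm.matrix, tm.n_voxels, len(tm.directions), GLRLM_FEATURES, "run")


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------


def compute_glszm(levels: np.ndarray, n_levels: int = N_GRAY_LEVELS) -> TextureMatrix:
    """Size-zone counts: 26-connected components of equal gray level."""
    levels = _as_levels_3d(levels)
    if not (levels > 0).any():
        raise ValueError("region is empty")
    levels = _crop_to_region(levels)
    structure = np.ones((3, 3, 3), dtype=bool)
    zones: List[Tuple[int, int]] = []
    max_size = 1
    for g in range(1, n_levels + 1):
        binary = levels == g
        if not binary.any():
            continue
        lab, n_comp = ndimage.label(binary, structure=structure)
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            zones.append((g, int(s)))
            max_size = max(max_size, int(s))
    mat = np.zeros((n_levels, max_size), dtype=np.int64)
    for g, s in zones:
        mat[g - 1, s - 1] += 1
    return TextureMatrix("GLSZM", mat, n_levels, (), int((levels > 0).sum()))


def glszm_features(tm: TextureMatrix) -> Dict[str, float]:
    """12 size-zone descriptors; zone percentage = zones / region voxels."""
    return _rlm_style_features(tm.matrix, tm.n_voxels, 1, GLSZM_FEATURES, "zone")


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------


def compute_ngtdm(levels: np.ndarray, n_levels: int = N_GRAY_LEVELS) -> TextureMatrix:
    """Neighborhood gray-tone difference table: per-level counts and sums.

    For every region voxel with at least one in-region 26-neighbor, the
    absolute difference between its level and the mean level of those
    neighbors is accumulated into ``s_i``; ``n_i`` counts the contributing
    voxels per level.
    """
    levels = _as_levels_3d(levels)
    if not (levels > 0).any():
        raise ValueError("region is empty")
    levels = _crop_to_region(levels)
    in_region = levels > 0
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nb_sum = ndimage.convolve((levels * in_region).astype(float), kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(in_region.astype(float), kernel, mode="constant", cval=0.0)
    valid = in_region & (nb_cnt > 0)
    n_i = np.zeros(n_levels, dtype=np.int64)
    s_i = np.zeros(n_levels, dtype=float)
    lv = levels[valid]
    diff = np.abs(lv - nb_sum[valid] / nb_cnt[valid])
    np.add.at(n_i, lv - 1, 1)
    np.add.at(s_i, lv - 1, diff)
    return TextureMatrix("NGTDM", n_i[:, None].astype(float), n_levels, (), int(valid.sum()), extra=s_i)


def ngtdm_features(tm: TextureMatrix) -> Dict[str, float]:
    """Coarseness, contrast, busyness, complexity, strength.

    A region with zero total difference (e.g. constant) hits the documented
    coarseness cap of 1e6.
    """
    n_i = tm.matrix[:, 0]
    s_i = tm.extra
    nv = n_i.sum()
    out = {f: 0.0 for f in NGTDM_FEATURES}
    if nv == 0:
        return out
    p_i = n_i / nv
    present = p_i > 0
    levels = np.arange(1, tm.n_levels + 1, dtype=float)
    ngp = int(present.sum())

    denom = float((p_i * s_i).sum())
    out["coarseness"] = min(1.0 / denom, NGTDM_COARSENESS_CAP) if denom > 0 else NGTDM_COARSENESS_CAP

    ip = levels[present]
    pp = p_i[present]
    sp = s_i[present]
    if ngp > 1:
        di = ip[:, None] - ip[None, :]
        pij = pp[:, None] * pp[None, :]
        out["contrast"] = float((pij * di**2).sum() / (ngp * (ngp - 1)) * (s_i.sum() / nv))
        busy_denom = float(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :]).sum())
        out["busyness"] = denom / busy_denom if busy_denom > 0 else 0.0
        pair_sum = pp[:, None] + pp[None, :]
        comp = np.abs(di) * (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :]) / pair_sum
        out["complexity"] = float(comp.sum() / nv)
        s_total = float(s_i.sum())
        out["strength"] = float((pair_sum * di**2).sum() / s_total) if s_total > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------


def _region_features(volume: np.ndarray, region: np.ndarray, n_levels: int) -> Dict[str, Dict[str, float]]:
    levels = quantize_gray_levels(volume, region, n_levels)
    return {
        "INT": compute_intensity_features(volume, region),
        "GLCM": glcm_features(compute_glcm(levels, n_levels)),
        "GLRLM": glrlm_features(compute_glrlm(levels, n_levels)),
        "GLSZM": glszm_features(compute_glszm(levels, n_levels)),
        "NGTDM": ngtdm_features(compute_ngtdm(levels, n_levels)),
    }


def extract_handcrafted(
    patient: PatientRecord,
    catalog: Optional[FeatureCatalog] = None,
    n_levels: int = N_GRAY_LEVELS,
) -> pd.Series:
    """Extract the full 1403-feature handcrafted vector for one patient.

    Features are returned as a Series in catalog order.  An empty subregion
    yields NaN for its features with a warning; cohort-level handling of
    missing values belongs to the selection stage.
    """
    catalog = catalog if catalog is not None else default_catalog()
    values: Dict[str, float] = {}
    try:
        geom = compute_geometry_features(patient.mask)
        for f in GEOMETRY_FEATURES:
            values[f"GEOM_{f}"] = geom[f]
    except ValueError as exc:
        warnings.warn(f"geometry features unavailable: {exc}", stacklevel=2)
        for f in GEOMETRY_FEATURES:
            values[f"GEOM_{f}"] = np.nan

    region_masks = {code: patient.mask.region(code) for code in REGION_CODES}
    for modality in MODALITIES:
        vol = patient.volumes[modality]
        for code, region in region_masks.items():
            prefix = f"{modality}_{code}"
            if not region.any():
                warnings.warn(f"empty region {code} for patient {patient.patient_id}", stacklevel=2)
                for fam, feats in (("INT", INTENSITY_FEATURES),) + tuple(TEXTURE_FAMILIES.items()):
                    for f in feats:
                        values[f"{prefix}_{fam}_{f}"] = np.nan
                continue
            fams = _region_features(vol, region, n_levels)
            for f in INTENSITY_FEATURES:
                values[f"{prefix}_INT_{f}"] = fams["INT"][f]
            for family, feats in TEXTURE_FAMILIES.items():
                for f in feats:
                    values[f"{prefix}_{family}_{f}"] = fams[family][f]
    return pd.Series([values[name] for name in catalog.names], index=catalog.names, dtype=float)
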