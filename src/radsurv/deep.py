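"""Deep-feature extraction through a pluggable pre-trained backbone.

For each of the four MR modalities and three input subregions (necrosis
SN, tumor core SNE, whole tumor ST) the pipeline picks the transverse
slice with the largest region area, min-max rescales it to [0, 255],
crops the region's tight bounding box, resizes it to 224x224 with bicubic
interpolation, and feeds the grayscale patch through the backbone's
forward pass, harvesting the activation vectors of the named
fully-connected layers F6 and F7.  With 4096-wide layers this yields
4 x 3 x 2 x 4096 = 98304 named features per patient.

The backbone is an injected component satisfying :class:`BackboneContract`:
any network exposing deterministic F6/F7 activation vectors for a
single-channel 224x224 [0, 255] image qualifies.  The repo ships
:class:`RandomConvBackbone`, a small fixed-seed random convolutional
network, so the extraction mechanics are fully testable without external
weight files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Protocol, Tuple, runtime_checkable

import numpy as np
import pandas as pd
from skimage.transform import resize

from radsurv.phantom import MODALITIES, PatientRecord
from radsurv.preprocess import SubregionMask

DEEP_REGION_CODES = ("SN", "SNE", "ST")
DEEP_LAYERS = ("F6", "F7")
PATCH_SIZE = 224


class BackboneContractError(TypeError):
    """The injected backbone does not satisfy the required contract."""


@runtime_checkable
class BackboneContract(Protocol):
    """Contract for injected backbones.

    ``layer_widths`` names the harvestable layers and their activation
    widths (both ``F6`` and ``F7`` must resolve); ``activations`` maps a
    single-channel 224x224 image with values in [0, 255] to the named
    activation vectors, deterministically.
    """

    descriptor: str
    layer_widths: Mapping[str, int]

    def activations(self, image: np.ndarray) -> Dict[str, np.ndarray]: ...


@dataclass(frozen=True)
class DeepFeatureName:
    """Structured deep-feature name, rendered MODALITY_REGION_LAYER_INDEX.

    Neuron indices are 1-based: ``T1C_SNE_F7_1508`` is the 1508th neuron
    of fully-connected layer 7 computed on the tumor core in T1C.
    """

    modality: str
    region: str
    layer: str
    index: int

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.region not in DEEP_REGION_CODES:
            raise ValueError(f"unknown deep-feature region {self.region!r}")
        if self.layer not in DEEP_LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.index < 1:
            raise ValueError("neuron index is 1-based")

    def render(self) -> str:
        return f"{self.modality}_{self.region}_{self.layer}_{self.index}"

    @classmethod
    def parse(cls, name: str) -> "DeepFeatureName":
        parts = name.split("_")
        if len(parts) != 4:
            raise ValueError(f"cannot parse deep feature name {name!r}")
        modality, region, layer, idx = parts
        return cls(modality, region, layer, int(idx))


def select_largest_slice(mask: SubregionMask, region_code: str) -> int:
    """Index of the transverse (last-axis) slice maximizing region area.

    Ties break to the lowest index.
    """
    region = mask.region(region_code)
    counts = region.sum(axis=(0, 1))
    if counts.sum() == 0:
        raise ValueError(f"region {region_code} is empty")
    return int(np.argmax(counts))


def prepare_patch(slice2d: np.ndarray, region2d: np.ndarray) -> np.ndarray:
    """Normalize, crop and resize one slice into a 224x224 [0, 255] patch.

    Steps: (1) linear min-max rescale of the whole slice to [0, 255]
    (a constant slice maps to 0 with a warning); (2) crop the region's
    tight bounding box; (3) bicubic resize to 224x224.
    """
    slice2d = np.asarray(slice2d, dtype=float)
    region2d = np.asarray(region2d, dtype=bool)
    if slice2d.shape != region2d.shape:
        raise ValueError("slice and region mask must share a shape")
    if not region2d.any():
        raise ValueError("region is empty in the selected slice")
    lo, hi = slice2d.min(), slice2d.max()
    if hi == lo:
        warnings.warn("constant slice maps to 0 under min-max rescaling", stacklevel=2)
        scaled = np.zeros_like(slice2d)
    else:
        scaled = (slice2d - lo) * (255.0 / (hi - lo))
    rows = np.any(region2d, axis=1)
    cols = np.any(region2d, axis=0)
    r0, r1 = np.where(rows)[0][[0, -1]]
    c0, c1 = np.where(cols)[0][[0, -1]]
    crop = scaled[r0 : r1 + 1, c0 : c1 + 1]
    patch = resize(
        crop,
        (PATCH_SIZE, PATCH_SIZE),
        order=3,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return np.clip(patch, 0.0, 255.0)


class RandomConvBackbone:
    """Fixed-seed random convolutional stand-in backbone.

    A small deterministic network — two strided convolutions with ReLU
    followed by two fully-connected layers F6 and F7 — whose weights are
    drawn once from the given seed (He-scaled normal, float32).  The input
    patch is presented on the network's first channel (the remaining color
    channels carry zero weight, i.e. are turned off), after the documented
    normalization ``x / 255 - 0.5``.

    ``width`` sets the F6/F7 activation width; 4096 mirrors a classic
    ImageNet-scale fully-connected layer, while small widths make tests
    cheap.  Activations are harvested after the ReLU.
    """

    def __init__(self, seed: int = 0, width: int = 4096):
        if width < 1:
            raise ValueError("layer width must be positive")
        self.seed = int(seed)
        self.width = int(width)
        self.descriptor = f"random-conv(seed={seed}, width={width})"
        self.layer_widths = {"F6": self.width, "F7": self.width}
        rng = np.random.default_rng(np.random.SeedSequence(self.seed))

        def he(shape, fan_in):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)

        self._w1 = he((7, 7, 8), 49)  # 7x7 stride 4, 1 -> 8 channels
        self._w2 = he((5, 5, 8, 16), 200)  # 5x5 stride 3, 8 -> 16 channels
        flat = 17 * 17 * 16
        self._w6 = he((flat, self.width), flat)
        self._w7 = he((self.width, self.width), self.width)

    @staticmethod
    def _conv(x: np.ndarray, w: np.ndarray, stride: int) -> np.ndarray:
        k = w.shape[0]
        if x.ndim == 2:
            win = np.lib.stride_tricks.sliding_window_view(x, (k, k))[::stride, ::stride]
            return np.tensordot(win, w, axes=([2, 3], [0, 1]))
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(0, 1))[::stride, ::stride]
        # win: (H', W', C, k, k); w: (k, k, C, C_out)
        return np.tensordot(win, w, axes=([3, 4, 2], [0, 1, 2]))

    def activations(self, image: np.ndarray) -> Dict[str, np.ndarray]:
        image = np.asarray(image, dtype=np.float32)
        if image.shape != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError(f"backbone expects a {PATCH_SIZE}x{PATCH_SIZE} single-channel image")
        x = image / 255.0 - 0.5
        h1 = np.maximum(self._conv(x, self._w1, 4), 0.0)  # (55, 55, 8)
        h2 = np.maximum(self._conv(h1, self._w2, 3), 0.0)  # (17, 17, 16)
        flat = h2.reshape(-1).astype(np.float32)
        f6 = np.maximum(flat @ self._w6, 0.0)
        f7 = np.maximum(f6 @ self._w7, 0.0)
        return {"F6": f6.astype(np.float64), "F7": f7.astype(np.float64)}


def _check_contract(backbone) -> None:
    widths = getattr(backbone, "layer_widths", None)
    if widths is None or not callable(getattr(backbone, "activations", None)):
        raise BackboneContractError("backbone must expose layer_widths and activations()")
    for layer in DEEP_LAYERS:
        if layer not in widths:
            raise BackboneContractError(f"backbone does not resolve layer {layer!r}")


def extract_deep(patient: PatientRecord, backbone: BackboneContract) -> pd.Series:
    """Extract the full deep-feature vector for one patient.

    For every modality x region (SN, SNE, ST): select the largest-area
    transverse slice of that region, prepare the patch, run the forward
    pass and harvest F6/F7 activations.  Output length is
    ``4 * 3 * 2 * layer_width``.
    """
    _check_contract(backbone)
    names = []
    values = []
    for modality in MODALITIES:
        vol = patient.volumes[modality]
        for region_code in DEEP_REGION_CODES:
            z = select_largest_slice(patient.mask, region_code)
            patch = prepare_patch(vol[:, :, z], patient.mask.region(region_code)[:, :, z])
            acts = backbone.activations(patch)
            for layer in DEEP_LAYERS:
                vec = np.asarray(acts[layer], dtype=float)
                if vec.shape != (backbone.layer_widths[layer],):
                    raise BackboneContractError(
                        f"layer {layer} returned shape {vec.shape}, expected ({backbone.layer_widths[layer]},)"
                    )
                names.extend(
                    DeepFeatureName(modality, region_code, layer, i + 1).render()
                    for i in range(vec.size)
                )
                values.append(vec)
    return pd.Series(np.concatenate(values), index=names, dtype=float)
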