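"""Synthetic multi-modality MR tumor cohorts with planted prognostic structure.

Each phantom is a set of four co-registered modality volumes (T1, T1C, T2,
FLAIR) carrying three nested ellipsoidal tumor subregions — necrosis inside
an enhancing rim inside edema — on a background of smooth textured noise.
Modality contrasts follow the qualitative radiology of glioblastoma:
necrosis hypointense in T1C and hyperintense in T2/FLAIR, enhancement
bright in T1C, edema bright in T2/FLAIR.

Prognostic structure is planted through standardized latent patient traits
(necrosis burden, texture contrast, tumor size, age, performance score).
Each latent is mapped monotonically into the rendered image (or clinical
field) and may carry a log-hazard coefficient in the survival generator,
so that downstream feature extraction and selection can be asked to
recover the planted effects.  Survival times come from an exponential
proportional-hazards baseline with independent uniform censoring.

All randomness flows from explicit integer seeds; no global random state
is touched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from radsurv.preprocess import SubregionMask

MODALITIES = ("T1", "T1C", "T2", "FLAIR")

#: Mean intensities per modality and tissue class (arbitrary MR-like units).
MODALITY_INTENSITY = {
    "T1": {"background": 90.0, "necrosis": 45.0, "enhancement": 80.0, "edema": 70.0},
    "T1C": {"background": 90.0, "necrosis": 35.0, "enhancement": 150.0, "edema": 75.0},
    "T2": {"background": 80.0, "necrosis": 160.0, "enhancement": 100.0, "edema": 140.0},
    "FLAIR": {"background": 70.0, "necrosis": 120.0, "enhancement": 100.0, "edema": 150.0},
}

#: Latent patient traits available as planted prognostic properties.  Each is
#: a standard-normal draw mapped monotonically into the phantom, so rank
#: statistics (C-index) on the trait equal those on the rendered property.
PLANTED_PROPERTIES = ("necrosis_fraction", "tumor_volume", "texture_contrast", "age", "kps")

#: Strong planted-effect condition used by the recovery experiments: large
#: necrosis-burden and texture-contrast log-hazard coefficients plus a
#: moderate age effect.
STRONG_PLANTED_BETAS = {"necrosis_fraction": 1.2, "texture_contrast": 0.9, "age": 0.5}


class ConfigurationError(ValueError):
    """Invalid generator configuration; the message names the offending field."""


@dataclass
class PhantomSpec:
    """Geometry, texture and noise parameters of the phantom generator."""

    grid_shape: Tuple[int, int, int] = (48, 48, 48)
    voxel_spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    #: mm radii of the nested necrosis / enhancement / edema ellipsoids
    subregion_radii: Mapping[str, float] = field(
        default_factory=lambda: {"necrosis": 6.0, "enhancement": 11.0, "edema": 16.0}
    )
    #: per-modality texture: gray-field contrast (intensity units) and
    #: correlation length (mm) of the smoothed Gaussian random field
    texture_params: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            m: {"contrast": 12.0, "correlation_length": 3.0} for m in MODALITIES
        }
    )
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        radii = self.subregion_radii
        for key in ("necrosis", "enhancement", "edema"):
            if key not in radii or radii[key] <= 0:
                raise ConfigurationError(f"subregion_radii[{key!r}] must be positive")
        if not radii["necrosis"] < radii["enhancement"] < radii["edema"]:
            raise ConfigurationError("subregion_radii must be strictly nested (necrosis < enhancement < edema)")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ConfigurationError("voxel_spacing components must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        # largest ellipsoid (with axis-ratio and size jitter) must fit the grid
        max_radius = radii["edema"] * 1.15 * 1.30
        for n, s in zip(self.grid_shape, self.voxel_spacing):
            if n * s / 2.0 < max_radius:
                raise ConfigurationError(
                    f"grid_shape extent {n * s:.1f}mm cannot accommodate edema radius {max_radius:.1f}mm"
                )


@dataclass
class SurvivalGenConfig:
    """Proportional-hazards survival generator configuration.

    ``betas`` maps planted property names (see ``PLANTED_PROPERTIES``) to
    log-hazard coefficients on the standardized latent scale.  The baseline
    is exponential with the given mean survival scale in days; censoring is
    uniform on ``[0, F]`` with the horizon ``F`` solved so that the expected
    censored fraction at the baseline hazard equals ``censor_rate``.
    """

    baseline: Tuple[str, float] = ("exponential", 500.0)
    betas: Mapping[str, float] = field(
        default_factory=lambda: {"necrosis_fraction": 0.8, "texture_contrast": 0.6, "age": 0.4}
    )
    censor_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        family, scale = self.baseline
        if family != "exponential":
            raise ConfigurationError(f"baseline family {family!r} not supported (use 'exponential')")
        if scale <= 0:
            raise ConfigurationError("baseline scale must be positive")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ConfigurationError("censor_rate must lie in [0, 1)")
        for name in self.betas:
            if name not in PLANTED_PROPERTIES:
                raise ConfigurationError(
                    f"betas key {name!r} is not a planted property {PLANTED_PROPERTIES}"
                )


@dataclass
class PatientRecord:
    """One synthetic subject: four modality volumes, mask, clinical fields."""

    patient_id: str
    volumes: Dict[str, np.ndarray]
    mask: SubregionMask
    age: float
    kps: int
    os_days: float
    event: int

    def __post_init__(self) -> None:
        missing = [m for m in MODALITIES if m not in self.volumes]
        if missing:
            raise ValueError(f"patient {self.patient_id} missing modalities {missing}")
        shapes = {v.shape for v in self.volumes.values()}
        if len(shapes) != 1 or next(iter(shapes)) != self.mask.labels.shape:
            raise ValueError("all modality volumes and the mask must share one grid shape")
        if self.os_days <= 0:
            raise ValueError("os_days must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")

    @property
    def spacing(self) -> Tuple[float, float, float]:
        return self.mask.spacing


def _smooth_field(rng: np.random.Generator, shape, spacing, correlation_length_mm: float) -> np.ndarray:
    """Unit-variance Gaussian random field with the given correlation length."""
    sigma = [max(correlation_length_mm / s, 1e-6) for s in spacing]
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def _ellipsoid(shape, spacing, radii_mm) -> np.ndarray:
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * s
        for n, s in zip(shape, spacing)
    ]
    grids = np.meshgrid(*axes, indexing="ij")
    q = sum((g / r) ** 2 for g, r in zip(grids, radii_mm))
    return q <= 1.0


def _build_mask(spec: PhantomSpec, ratios, size_scale: float, nec_scale: float) -> SubregionMask:
    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    r = spec.subregion_radii
    for label, base, extra in (
        (3, r["edema"], 1.0),
        (2, r["enhancement"], 1.0),
        (1, r["necrosis"], nec_scale),
    ):
        radii = [base * size_scale * extra * rt for rt in ratios]
        labels[_ellipsoid(spec.grid_shape, spec.voxel_spacing, radii)] = label
    return SubregionMask(labels, spec.voxel_spacing)


def _render_volumes(
    spec: PhantomSpec, mask: SubregionMask, rng: np.random.Generator, texture_gain: float
) -> Dict[str, np.ndarray]:
    volumes: Dict[str, np.ndarray] = {}
    labels = mask.labels
    tumor = labels > 0
    for modality in MODALITIES:
        base = MODALITY_INTENSITY[modality]
        vol = np.full(spec.grid_shape, base["background"], dtype=float)
        vol[labels == 1] = base["necrosis"]
        vol[labels == 2] = base["enhancement"]
        vol[labels == 3] = base["edema"]
        tex = spec.texture_params.get(modality, {"contrast": 0.0, "correlation_length": 3.0})
        fld = _smooth_field(rng, spec.grid_shape, spec.voxel_spacing, tex["correlation_length"])
        contrast = tex["contrast"] * (texture_gain if modality == "T1C" else 1.0)
        vol[tumor] += contrast * fld[tumor]
        if spec.noise_sd > 0:
            vol += rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)
        volumes[modality] = vol
    return volumes


def _censor_horizon(scale: float, censor_rate: float) -> float:
    """Horizon F with P(C < T) = censor_rate for T ~ Exp(scale), C ~ U(0, F)."""
    if censor_rate <= 0:
        return np.inf

    def frac(ratio):  # ratio = F / scale
        return (1.0 - np.exp(-ratio)) / ratio - censor_rate

    ratio = optimize.brentq(frac, 1e-9, 1e6)
    return ratio * scale


def generate_cohort(
    n: int,
    phantom: Optional[PhantomSpec] = None,
    surv: Optional[SurvivalGenConfig] = None,
    return_properties: bool = False,
):
    """Generate ``n`` synthetic patients.

    Per-patient phantom parameters are drawn reproducibly from the spec
    seeds; patient ``i``'s hazard is ``baseline_rate * exp(sum_k beta_k *
    x_ik)`` with ``x_ik`` the planted standardized latent traits.  With
    ``return_properties=True`` the planted trait table is returned
    alongside the records.
    """
    if n < 0:
        raise ConfigurationError("patient count n must be non-negative")
    phantom = phantom if phantom is not None else PhantomSpec()
    surv = surv if surv is not None else SurvivalGenConfig()

    records: List[PatientRecord] = []
    rows = []
    if n == 0:
        props = pd.DataFrame(columns=list(PLANTED_PROPERTIES))
        return (records, props) if return_properties else records

    ph_streams = np.random.SeedSequence(phantom.seed).spawn(n)
    sv_streams = np.random.SeedSequence(surv.seed).spawn(n)
    scale = surv.baseline[1]
    horizon = _censor_horizon(scale, surv.censor_rate)

    for i in range(n):
        prng = np.random.default_rng(ph_streams[i])
        srng = np.random.default_rng(sv_streams[i])

        z = {
            "necrosis_fraction": prng.standard_normal(),
            "tumor_volume": prng.standard_normal(),
            "texture_contrast": prng.standard_normal(),
            "age": srng.standard_normal(),
            "kps": srng.standard_normal(),
        }
        ratios = prng.uniform(0.85, 1.15, size=3)
        size_scale = 1.0 + 0.10 * np.tanh(z["tumor_volume"] / 1.5)
        nec_scale = 1.0 + 0.35 * np.tanh(z["necrosis_fraction"] / 1.5)
        texture_gain = float(np.exp(0.45 * z["texture_contrast"]))

        mask = _build_mask(phantom, ratios, size_scale, nec_scale)
        volumes = _render_volumes(phantom, mask, prng, texture_gain)

        age = float(np.clip(55.0 + 12.0 * z["age"], 18.0, 88.0))
        kps = int(np.clip(np.round((80.0 + 10.0 * (-z["kps"])) / 10.0) * 10.0, 40, 100))

        lp = sum(surv.betas.get(k, 0.0) * z[k] for k in PLANTED_PROPERTIES)
        rate = np.exp(lp) / scale
        t_event = srng.exponential(1.0 / rate)
        c = srng.uniform(0.0, horizon) if np.isfinite(horizon) else np.inf
        os_days = max(min(t_event, c), 1.0)
        event = int(t_event <= c)

        records.append(
            PatientRecord(
                patient_id=f"P{i:04d}",
                volumes=volumes,
                mask=mask,
                age=age,
                kps=kps,
                os_days=float(os_days),
                event=event,
            )
        )
        rows.append({k: z[k] for k in PLANTED_PROPERTIES})

    props = pd.DataFrame(rows, index=[r.patient_id for r in records])
    return (records, props) if return_properties else records


def perturb_segmentation(mask: SubregionMask, magnitude: float, seed: int = 0) -> SubregionMask:
    """Displace subregion boundaries by a smooth random field of given mm magnitude.

    Emulates intra-/inter-rater contour variation.  A single smooth
    displacement field warps the whole label map (nearest-neighbor
    sampling), so label nesting is preserved by construction.  The same
    seed at increasing magnitudes scales one fixed unit field, making the
    perturbation monotone in ``magnitude``.
    """
    if magnitude < 0:
        raise ValueError("perturbation magnitude must be non-negative")
    if magnitude == 0:
        return mask.copy()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    shape = mask.labels.shape
    spacing = mask.spacing
    disp = np.stack(
        [_smooth_field(rng, shape, spacing, correlation_length_mm=6.0) for _ in range(3)]
    )
    vec_mag = np.sqrt((disp**2).sum(axis=0))
    mean_mag = vec_mag.mean()
    if mean_mag == 0:
        return mask.copy()
    disp *= magnitude / mean_mag  # mean displacement magnitude = `magnitude` mm
    coords = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")).astype(float)
    for ax in range(3):
        coords[ax] += disp[ax] / spacing[ax]
    warped = ndimage.map_coordinates(mask.labels, coords, order=0, mode="nearest")
    out = SubregionMask(warped.astype(mask.labels.dtype), spacing)
    if not out.is_valid_tumor():
        warnings.warn("perturbation removed a subregion entirely", stacklevel=2)
    return out


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean masks (1.0 when both empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
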