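"""End-to-end orchestration: discovery training and independent validation.

``run_discovery`` executes the full workflow on a discovery cohort —
feature extraction (handcrafted + deep), z-scoring, robustness pair
generation, four-step selection, LASSO-Cox signature fitting, optimal
cutpoint, combined clinical Cox model and nomogram — and returns the
trained artifacts.  ``run_validation`` scores an independent cohort with
the *discovery* normalization statistics, signature and cutoff; nothing
is refitted, so no information flows from validation back into the
artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from radsurv.cohort_io import clinical_frame
from radsurv.deep import RandomConvBackbone, extract_deep
from radsurv.handcrafted import FeatureCatalog, default_catalog, extract_handcrafted
from radsurv.nomogram import DEFAULT_HORIZONS, NomogramModel, build_nomogram, calibration_curve
from radsurv.phantom import PatientRecord, perturb_segmentation
from radsurv.selection import (
    SelectionConfig,
    SelectionReport,
    apply_zscore,
    run_selection,
    zscore_normalize,
)
from radsurv.survival import (
    CombinedCoxResults,
    CoxSignature,
    SignatureModel,
    SignatureResults,
    StratificationResult,
    SurvivalData,
    harrell_cindex,
)


@dataclass
class RunConfig:
    """Options of one end-to-end run; every seed is explicit."""

    selection: SelectionConfig = field(default_factory=SelectionConfig)
    backbone_seed: int = 0
    backbone_width: int = 8
    n_folds: int = 10
    seed: int = 0
    perturb_magnitude_mm: float = 1.0
    min_group_frac: float = 0.10
    horizons: Tuple[float, ...] = DEFAULT_HORIZONS
    include_deep: bool = True
    include_handcrafted: bool = True


def extract_features(
    records: List[PatientRecord],
    catalog: Optional[FeatureCatalog] = None,
    backbone=None,
    include_handcrafted: bool = True,
    include_deep: bool = True,
) -> pd.DataFrame:
    """Patients x features table (handcrafted then deep, in catalog order)."""
    rows = []
    for rec in records:
        parts = []
        if include_handcrafted:
            parts.append(extract_handcrafted(rec, catalog))
        if include_deep:
            if backbone is None:
                raise ValueError("deep extraction requested but no backbone supplied")
            parts.append(extract_deep(rec, backbone))
        rows.append(pd.concat(parts))
    return pd.DataFrame(rows, index=pd.Index([r.patient_id for r in records], name="patient_id"))


def make_robustness_pairs(
    records: List[PatientRecord],
    base_features: pd.DataFrame,
    subset_ids: List[str],
    magnitude_mm: float,
    seed: int,
    catalog: Optional[FeatureCatalog],
    backbone,
    include_handcrafted: bool = True,
    include_deep: bool = True,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """(first, second) feature measurements for a robustness analysis.

    The first measurement reuses the cohort extraction; the second comes
    from re-extraction after smooth random contour perturbation of each
    patient's mask, emulating a repeated segmentation.
    """
    by_id = {r.patient_id: r for r in records}
    second_rows = []
    for i, pid in enumerate(subset_ids):
        rec = by_id[pid]
        pmask = perturb_segmentation(rec.mask, magnitude_mm, seed=seed + i)
        prec = dataclasses.replace(rec, mask=pmask)
        parts = []
        if include_handcrafted:
            parts.append(extract_handcrafted(prec, catalog))
        if include_deep:
            parts.append(extract_deep(prec, backbone))
        second_rows.append(pd.concat(parts))
    second = pd.DataFrame(second_rows, index=pd.Index(subset_ids, name="patient_id"))
    return base_features.loc[subset_ids], second


@dataclass
class DiscoveryArtifacts:
    """Everything trained on the discovery cohort."""

    catalog: Optional[FeatureCatalog]
    backbone: object
    zstats: pd.DataFrame
    report: SelectionReport
    signature: CoxSignature
    signature_results: SignatureResults
    cutoff: float
    combined: CombinedCoxResults
    nomogram: NomogramModel
    covariate_ranges: Dict[str, Tuple[float, float]]
    discovery_scores: pd.Series
    stratification: StratificationResult
    log: List[Dict] = field(default_factory=list)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.zstats.to_csv(directory / "zscore_stats.csv")
        self.report.to_json(directory / "selection_report.json")
        self.signature.to_json(directory / "signature.json")
        self.nomogram.to_json(directory / "nomogram.json")
        summary = {
            "cutoff": self.cutoff,
            "combined_coefficients": {k: float(v) for k, v in self.combined.params_.items()},
            "covariate_ranges": {k: list(v) for k, v in self.covariate_ranges.items()},
            "backbone": getattr(self.backbone, "descriptor", str(self.backbone)),
            "stage_counts": self.report.stage_counts,
        }
        with open(directory / "artifacts.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        with open(directory / "run_log.json", "w") as fh:
            json.dump(self.log, fh, indent=1)


@dataclass
class ValidationReport:
    """Held-out validation of the discovery artifacts."""

    n: int
    cindex: float
    cindex_ci: Tuple[float, float]
    logrank_statistic: float
    logrank_p: float
    hazard_ratio: float
    hr_ci: Tuple[float, float]
    combined_cindex: float
    combined_ci: Tuple[float, float]
    calibration: pd.DataFrame

    def to_json(self, path) -> None:
        payload = {
            "n": self.n,
            "cindex": self.cindex,
            "cindex_ci": list(self.cindex_ci),
            "logrank_statistic": self.logrank_statistic,
            "logrank_p": self.logrank_p,
            "hazard_ratio": self.hazard_ratio,
            "hr_ci": list(self.hr_ci),
            "combined_cindex": self.combined_cindex,
            "combined_ci": list(self.combined_ci),
            "calibration": self.calibration.reset_index().to_dict(orient="records"),
        }

        def _finite(obj):
            if isinstance(obj, float) and not np.isfinite(obj):
                return None
            if isinstance(obj, dict):
                return {k: _finite(v) for k, v in obj.items()}
            if isinstance(obj, list):
                return [_finite(v) for v in obj]
            return obj

        with open(path, "w") as fh:
            json.dump(_finite(payload), fh, indent=1, sort_keys=True)


def _combined_covariates(scores: pd.Series, clinical: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {"rad_score": scores, "age": clinical["age"], "kps": clinical["kps"].astype(float)}
    )


def run_discovery(records: List[PatientRecord], config: Optional[RunConfig] = None) -> DiscoveryArtifacts:
    """Train all artifacts on the discovery cohort.

    Stages: extract -> z-score -> robustness pairs -> four-step selection
    -> LASSO-Cox -> optimal cutpoint -> combined Cox -> nomogram.  The log
    records per-stage feature counts and seeds.
    """
    config = config or RunConfig()
    if not records:
        raise ValueError("empty discovery cohort")
    catalog = default_catalog() if config.include_handcrafted else None
    backbone = (
        RandomConvBackbone(seed=config.backbone_seed, width=config.backbone_width)
        if config.include_deep
        else None
    )
    log: List[Dict] = []

    features = extract_features(
        records,
        catalog,
        backbone,
        include_handcrafted=config.include_handcrafted,
        include_deep=config.include_deep,
    )
    features = features.fillna(0.0)
    log.append({"stage": "extract", "n_patients": len(records), "n_features": features.shape[1]})

    ztable, zstats = zscore_normalize(features)
    clinical = clinical_frame(records)
    survival = SurvivalData.from_dataframe(clinical)

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    ids = list(features.index)
    retest_ids = list(rng.choice(ids, size=min(config.selection.retest_size, len(ids)), replace=False))
    interrater_ids = list(
        rng.choice(ids, size=min(config.selection.interrater_size, len(ids)), replace=False)
    )
    retest_pairs = make_robustness_pairs(
        records, features, retest_ids, config.perturb_magnitude_mm, config.seed + 1000,
        catalog, backbone, config.include_handcrafted, config.include_deep,
    )
    interrater_pairs = make_robustness_pairs(
        records, features, interrater_ids, config.perturb_magnitude_mm, config.seed + 2000,
        catalog, backbone, config.include_handcrafted, config.include_deep,
    )
    retest_pairs = (retest_pairs[0].fillna(0.0), retest_pairs[1].fillna(0.0))
    interrater_pairs = (interrater_pairs[0].fillna(0.0), interrater_pairs[1].fillna(0.0))

    report = run_selection(
        ztable, survival.time, survival.event, retest_pairs, interrater_pairs, config.selection
    )
    log.append({"stage": "select", "counts": report.stage_counts})
    selected = report.selected
    if not selected:
        raise RuntimeError("feature selection returned an empty set; cannot fit a signature")

    model = SignatureModel(ztable[selected], survival)
    results = model.fit(n_folds=min(config.n_folds, survival.n_events), seed=config.seed, allow_empty=False)
    log.append({"stage": "fit", "lambda": results.signature.lambda_, "n_active": len(results.signature)})

    scores = results.score()
    cutoff = results.fit_cutoff(config.min_group_frac)
    strat = results.stratify(cutoff=cutoff, rho=1.0)
    log.append({"stage": "cutpoint", "cutoff": cutoff, "p": strat.p_value})

    covariates = _combined_covariates(scores, clinical)
    from radsurv.survival import CombinedCoxModel

    combined = CombinedCoxModel(covariates, survival).fit()
    ranges = {
        name: (float(covariates[name].min()), float(covariates[name].max()))
        for name in combined.covariate_names
    }
    nomo = build_nomogram(combined, ranges, horizons=config.horizons)
    log.append({"stage": "nomogram", "covariates": combined.covariate_names})

    return DiscoveryArtifacts(
        catalog=catalog,
        backbone=backbone,
        zstats=zstats,
        report=report,
        signature=results.signature,
        signature_results=results,
        cutoff=cutoff,
        combined=combined,
        nomogram=nomo,
        covariate_ranges=ranges,
        discovery_scores=scores,
        stratification=strat,
        log=log,
    )


def run_validation(
    records: List[PatientRecord],
    artifacts: DiscoveryArtifacts,
    config: Optional[RunConfig] = None,
) -> ValidationReport:
    """Score an independent cohort with the frozen discovery artifacts.

    Validation patients are normalized with discovery z-score statistics
    and stratified at the discovery cutoff; the signature and combined
    model are applied, never refitted.
    """
    config = config or RunConfig()
    if not records:
        raise ValueError("empty validation cohort")
    features = extract_features(
        records,
        artifacts.catalog,
        artifacts.backbone,
        include_handcrafted=config.include_handcrafted,
        include_deep=config.include_deep,
    ).fillna(0.0)
    missing = [n for n in artifacts.signature.names if n not in features.columns]
    if missing:
        raise KeyError(f"validation cohort is missing signature feature(s) {missing}")
    ztable = apply_zscore(features, artifacts.zstats)
    clinical = clinical_frame(records)
    survival = SurvivalData.from_dataframe(clinical)

    scores = pd.Series(
        np.asarray(artifacts.signature.score(ztable), dtype=float), index=ztable.index
    )
    cindex, ci = harrell_cindex(scores.to_numpy(), survival)
    from radsurv.survival import stratify_by_score

    try:
        strat = stratify_by_score(scores.to_numpy(), survival, artifacts.cutoff, rho=1.0)
        strat_fields = (strat.statistic, strat.p_value, strat.hazard_ratio, strat.hr_ci)
    except ValueError as exc:
        # the frozen discovery cutoff may not split a small held-out cohort;
        # stratification is then undefined rather than refitted
        warnings.warn(f"validation stratification degenerate: {exc}", stacklevel=2)
        strat_fields = (float("nan"), float("nan"), float("nan"), (float("nan"), float("nan")))

    covariates = _combined_covariates(scores, clinical)
    combined_c, combined_ci = artifacts.combined.concordance(covariates, survival)

    horizon = float(config.horizons[0])
    predicted = artifacts.nomogram.predict_survival(covariates, horizon)
    calib = calibration_curve(np.asarray(predicted, dtype=float), survival, horizon)

    return ValidationReport(
        n=len(records),
        cindex=cindex,
        cindex_ci=ci,
        logrank_statistic=strat_fields[0],
        logrank_p=strat_fields[1],
        hazard_ratio=strat_fields[2],
        hr_ci=strat_fields[3],
        combined_cindex=combined_c,
        combined_ci=combined_ci,
        calibration=calib,
    )
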