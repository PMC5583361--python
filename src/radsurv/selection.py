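"""Four-step feature selection for high-dimensional radiomics tables.

All features are first z-scored (discovery statistics are stored so that
validation data can be transformed with them).  Selection then proceeds in
the fixed order: (1) segmentation-robustness filter — keep features with
intraclass correlation coefficient >= 0.85 in BOTH a test-retest and an
inter-rater analysis; (2) discard features with zero median absolute
deviation; (3) keep features whose univariate concordance index (direction
free, max(C, 1-C)) >= 0.580; (4) greedy correlation pruning — for every
feature pair with |Pearson r| >= 0.90 the less prognostic member is
dropped.

The ICC variant is the two-way mixed-effects, absolute-agreement,
single-measurement form, the standard choice for radiomics
segmentation-robustness studies.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sksurv.metrics import concordance_index_censored

__all__ = [
    "SelectionConfig",
    "SelectionReport",
    "zscore_normalize",
    "apply_zscore",
    "compute_icc",
    "robustness_filter",
    "mad_filter",
    "univariate_cindex",
    "directional_cindex",
    "cindex_filter",
    "correlation_prune",
    "run_selection",
]


@dataclass
class SelectionConfig:
    """Thresholds of the four selection stages (all overridable)."""

    icc_threshold: float = 0.85
    cindex_threshold: float = 0.580
    corr_threshold: float = 0.90
    #: sizes of the random patient subsets used for the robustness analyses
    retest_size: int = 30
    interrater_size: int = 30

    def __post_init__(self) -> None:
        for name in ("icc_threshold", "cindex_threshold", "corr_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class SelectionReport:
    """Per-stage surviving feature sets, counts and per-feature statistics."""

    stage_survivors: Dict[str, List[str]] = field(default_factory=dict)
    icc_retest: Dict[str, float] = field(default_factory=dict)
    icc_interrater: Dict[str, float] = field(default_factory=dict)
    mad: Dict[str, float] = field(default_factory=dict)
    cindex: Dict[str, float] = field(default_factory=dict)
    notes: List[str] = field(default_factory=list)

    @property
    def stage_counts(self) -> Dict[str, int]:
        return {stage: len(names) for stage, names in self.stage_survivors.items()}

    @property
    def selected(self) -> List[str]:
        if not self.stage_survivors:
            return []
        last_stage = list(self.stage_survivors)[-1]
        return self.stage_survivors[last_stage]

    def to_json(self, path) -> None:
        payload = {
            "stage_survivors": self.stage_survivors,
            "stage_counts": self.stage_counts,
            "icc_retest": self.icc_retest,
            "icc_interrater": self.icc_interrater,
            "mad": self.mad,
            "cindex": self.cindex,
            "notes": self.notes,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SelectionReport":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            stage_survivors=payload["stage_survivors"],
            icc_retest=payload["icc_retest"],
            icc_interrater=payload["icc_interrater"],
            mad=payload["mad"],
            cindex=payload["cindex"],
            notes=payload.get("notes", []),
        )


def zscore_normalize(table: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score every feature column; return the table and its (mean, sd) stats.

    The sd uses the n-1 denominator.  Zero-variance columns are flagged
    (``zero_variance`` column of the stats frame) and passed through as
    zeros; the MAD stage removes them.
    """
    if len(table) < 2:
        raise ValueError("z-scoring requires at least 2 patients")
    mean = table.mean(axis=0)
    sd = table.std(axis=0, ddof=1)
    zero = sd == 0
    safe_sd = sd.replace(0.0, 1.0)
    z = (table - mean) / safe_sd
    z.loc[:, zero[zero].index] = 0.0
    stats = pd.DataFrame({"mean": mean, "sd": sd, "zero_variance": zero})
    return z, stats


def apply_zscore(table: pd.DataFrame, stats: pd.DataFrame) -> pd.DataFrame:
    """Transform a table with previously stored (discovery) statistics."""
    missing = stats.index.difference(table.columns)
    if len(missing):
        raise KeyError(f"table is missing features {missing[:5].tolist()}...")
    table = table[stats.index]
    safe_sd = stats["sd"].replace(0.0, 1.0)
    z = (table - stats["mean"]) / safe_sd
    z.loc[:, stats.index[stats["zero_variance"]]] = 0.0
    return z


def compute_icc(m1: np.ndarray, m2: np.ndarray) -> np.ndarray:
    """Two-way mixed-effects absolute-agreement single-measurement ICC.

    ``m1``/``m2`` are (patients, features) arrays of the two measurements.
    ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E)) with
    k = 2 raters.  Zero between-patient variance yields ICC 0 with a
    warning.
    """
    m1 = np.atleast_2d(np.asarray(m1, dtype=float))
    m2 = np.atleast_2d(np.asarray(m2, dtype=float))
    if m1.shape != m2.shape:
        raise ValueError("both measurement matrices must share a shape")
    n = m1.shape[0]
    if n < 3:
        raise ValueError("ICC requires at least 3 patients")
    k = 2
    data = np.stack([m1, m2], axis=1)  # (n, k, features)
    grand = data.mean(axis=(0, 1))
    row_mean = data.mean(axis=1)  # (n, features)
    col_mean = data.mean(axis=0)  # (k, features)
    ss_rows = k * ((row_mean - grand) ** 2).sum(axis=0)
    ss_cols = n * ((col_mean - grand) ** 2).sum(axis=0)
    ss_total = ((data - grand) ** 2).sum(axis=(0, 1))
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = np.clip(ss_err / ((n - 1) * (k - 1)), 0.0, None)
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = np.where(denom > 0, (ms_r - ms_e) / np.where(denom == 0, 1.0, denom), 0.0)
    degenerate = ms_r <= 0
    if degenerate.any():
        warnings.warn("zero between-patient variance; ICC set to 0", stacklevel=2)
        icc = np.where(degenerate, 0.0, icc)
    return icc


def _icc_series(pair: Tuple[pd.DataFrame, pd.DataFrame]) -> pd.Series:
    a, b = pair
    common = a.columns.intersection(b.columns)
    a = a[common]
    b = b.loc[a.index, common]
    return pd.Series(compute_icc(a.to_numpy(), b.to_numpy()), index=common)


def robustness_filter(
    table: pd.DataFrame,
    retest_pairs: Tuple[pd.DataFrame, pd.DataFrame],
    interrater_pairs: Tuple[pd.DataFrame, pd.DataFrame],
    config: Optional[SelectionConfig] = None,
) -> Tuple[List[str], pd.Series, pd.Series]:
    """Keep features with ICC >= threshold in BOTH robustness analyses."""
    config = config or SelectionConfig()
    icc_rt = _icc_series(retest_pairs)
    icc_ir = _icc_series(interrater_pairs)
    survivors = []
    for name in table.columns:
        if name not in icc_rt.index or name not in icc_ir.index:
            warnings.warn(f"feature {name!r} missing from robustness pair data; excluded", stacklevel=2)
            continue
        if icc_rt[name] >= config.icc_threshold and icc_ir[name] >= config.icc_threshold:
            survivors.append(name)
    return survivors, icc_rt, icc_ir


def mad_filter(table: pd.DataFrame) -> Tuple[List[str], pd.Series]:
    """Keep features with nonzero median absolute deviation."""
    if table.shape[1] == 0:
        return [], pd.Series(dtype=float)
    med = table.median(axis=0)
    mad = (table - med).abs().median(axis=0)
    return list(table.columns[mad > 0]), mad


def univariate_cindex(values: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Harrell's C of a feature treated as a risk score.

    Over pairs whose ordering is determinable (the earlier time carries an
    event), the fraction concordant with higher feature value predicting
    shorter survival; score ties count 1/2.
    """
    values = np.asarray(values, dtype=float)
    event = np.asarray(event).astype(bool)
    time = np.asarray(time, dtype=float)
    c, concordant, discordant, tied_risk, _ = concordance_index_censored(event, time, values)
    if concordant + discordant + tied_risk == 0:
        raise ValueError("no comparable pairs for C-index")
    return float(c)


def directional_cindex(values: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Sign-free predictiveness max(C, 1-C), so protective features count too."""
    c = univariate_cindex(values, time, event)
    return max(c, 1.0 - c)


def cindex_filter(
    table: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    config: Optional[SelectionConfig] = None,
) -> Tuple[List[str], pd.Series]:
    """Keep features whose directional C-index meets the threshold."""
    config = config or SelectionConfig()
    cvals = pd.Series(
        {name: directional_cindex(table[name].to_numpy(), time, event) for name in table.columns}
    )
    survivors = list(cvals.index[cvals >= config.cindex_threshold])
    return survivors, cvals


def correlation_prune(
    table: pd.DataFrame,
    cindex: pd.Series,
    config: Optional[SelectionConfig] = None,
) -> List[str]:
    """Greedy redundancy removal.

    Feature pairs with |Pearson r| >= threshold are visited in descending
    |r| (ties by name order); in each still-active pair the feature with
    the lower directional C-index is dropped (C ties by name order, the
    lexicographically later name dropped).
    """
    config = config or SelectionConfig()
    names = list(table.columns)
    if len(names) < 2:
        return names
    corr = np.corrcoef(table.to_numpy(), rowvar=False)
    corr = np.nan_to_num(np.abs(corr), nan=0.0)
    iu, ju = np.triu_indices(len(names), k=1)
    hits = [(corr[i, j], names[i], names[j]) for i, j in zip(iu, ju) if corr[i, j] >= config.corr_threshold]
    hits.sort(key=lambda t: (-t[0], t[1], t[2]))
    active = set(names)
    for _, a, b in hits:
        if a in active and b in active:
            ca, cb = cindex.get(a, 0.0), cindex.get(b, 0.0)
            if ca > cb:
                active.discard(b)
            elif cb > ca:
                active.discard(a)
            else:
                active.discard(max(a, b))
    return [n for n in names if n in active]


def run_selection(
    table: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    retest_pairs: Tuple[pd.DataFrame, pd.DataFrame],
    interrater_pairs: Tuple[pd.DataFrame, pd.DataFrame],
    config: Optional[SelectionConfig] = None,
) -> SelectionReport:
    """Apply the four stages in order and collect a report.

    ``table`` is the (already z-scored) discovery feature table.  An empty
    survivor set at any stage short-circuits with a note rather than an
    exception.
    """
    config = config or SelectionConfig()
    report = SelectionReport()
    report.stage_survivors["input"] = list(table.columns)

    surv, icc_rt, icc_ir = robustness_filter(table, retest_pairs, interrater_pairs, config)
    report.icc_retest = icc_rt.to_dict()
    report.icc_interrater = icc_ir.to_dict()
    report.stage_survivors["robustness"] = surv
    if not surv:
        report.notes.append("empty survivor set after robustness stage")
        report.stage_survivors["mad"] = []
        report.stage_survivors["cindex"] = []
        report.stage_survivors["correlation"] = []
        return report

    surv2, mad = mad_filter(table[surv])
    report.mad = mad.to_dict()
    report.stage_survivors["mad"] = surv2
    if not surv2:
        report.notes.append("empty survivor set after MAD stage")
        report.stage_survivors["cindex"] = []
        report.stage_survivors["correlation"] = []
        return report

    surv3, cvals = cindex_filter(table[surv2], time, event, config)
    report.cindex = cvals.to_dict()
    report.stage_survivors["cindex"] = surv3
    if not surv3:
        report.notes.append("empty survivor set after C-index stage")
        report.stage_survivors["correlation"] = []
        return report

    surv4 = correlation_prune(table[surv3], cvals, config)
    report.stage_survivors["correlation"] = surv4
    return report
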