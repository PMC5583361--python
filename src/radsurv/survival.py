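"""Survival modelling: LASSO-Cox signature, stratification, validation.

The central object is :class:`SignatureModel`, a statsmodels-style model
built from a (z-scored) feature table and right-censored survival data.
``fit()`` runs L1-penalized Cox regression over a regularization path,
selects the penalty by 10-fold cross-validated partial-likelihood deviance
(minimum criterion), and returns :class:`SignatureResults` carrying the
sparse signature, the CV path, scoring, stratification and validation
helpers.  :class:`CombinedCoxModel` fits the unpenalized multivariate Cox
model that joins the radiomics score with clinical covariates (age, KPS)
and feeds the nomogram.

Tied event times are handled with the Breslow approximation throughout
(the synthetic generator produces continuous times, for which Breslow and
Efron coincide).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats as sstats
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.metrics import concordance_index_censored
from sksurv.util import Surv

__all__ = [
    "SurvivalData",
    "CoxSignature",
    "KMCurve",
    "StratificationResult",
    "SignatureModel",
    "SignatureResults",
    "CombinedCoxModel",
    "CombinedCoxResults",
    "fit_lasso_cox",
    "radiomics_score",
    "optimal_cutpoint",
    "km_estimate",
    "weighted_logrank",
    "harrell_cindex",
    "hazard_ratio",
    "stratify_by_score",
    "fit_combined_cox",
]


@dataclass
class SurvivalData:
    """Right-censored survival outcomes: positive times, 0/1 event flags."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape or self.time.ndim != 1:
            raise ValueError("time and event must be matching 1D arrays")
        if (self.time <= 0).any():
            raise ValueError("survival times must be positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event flags must be 0 or 1")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, time_col: str = "os_days", event_col: str = "event") -> "SurvivalData":
        return cls(df[time_col].to_numpy(), df[event_col].to_numpy())

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, idx) -> "SurvivalData":
        return SurvivalData(self.time[idx], self.event[idx])

    def to_sksurv(self):
        return Surv.from_arrays(self.event.astype(bool), self.time)


@dataclass
class CoxSignature:
    """Sparse linear radiomics signature: named nonzero Cox coefficients.

    The score is the pure linear combination (no intercept):
    ``score = sum_k coef_k * x_k``.
    """

    features: List[Tuple[str, float]]
    lambda_: float = float("nan")
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.features = [(str(n), float(c)) for n, c in self.features if c != 0.0]

    @property
    def names(self) -> List[str]:
        return [n for n, _ in self.features]

    @property
    def coefficients(self) -> pd.Series:
        return pd.Series(dict(self.features), dtype=float)

    def __len__(self) -> int:
        return len(self.features)

    def score(self, values: Union[Mapping[str, float], pd.Series, pd.DataFrame]):
        return radiomics_score(values, self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"features": self.features, "lambda": self.lambda_, "seed": self.seed},
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "CoxSignature":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            [(n, c) for n, c in payload["features"]],
            lambda_=payload.get("lambda", float("nan")),
            seed=payload.get("seed"),
        )


def radiomics_score(values, signature: CoxSignature):
    """Linear radiomics score ``sum_k coef_k * value_k``.

    Accepts a mapping / Series (returns a float) or a DataFrame (returns a
    Series per patient).  A missing signature feature raises, naming it.
    """
    if isinstance(values, pd.DataFrame):
        missing = [n for n in signature.names if n not in values.columns]
        if missing:
            raise KeyError(f"missing signature feature(s) {missing}")
        if not signature.features:
            return pd.Series(0.0, index=values.index)
        coef = signature.coefficients
        return values[coef.index].to_numpy() @ coef.to_numpy() + pd.Series(0.0, index=values.index)
    total = 0.0
    for name, coef in signature.features:
        if name not in values:
            raise KeyError(f"missing signature feature {name!r}")
        total += coef * float(values[name])
    return total


# ---------------------------------------------------------------------------
# Cox partial likelihood and penalized fitting
# ---------------------------------------------------------------------------


def _cox_partial_loglik(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow partial log-likelihood of a linear predictor."""
    order = np.argsort(time, kind="stable")
    lp = np.asarray(lp, dtype=float)[order]
    time = np.asarray(time, dtype=float)[order]
    ev = np.asarray(event).astype(bool)[order]
    lp = lp - lp.max()  # numerical stabilization; PL is shift-invariant
    explp = np.exp(lp)
    rev_cum = np.cumsum(explp[::-1])[::-1]
    first_idx = np.searchsorted(time, time, side="left")
    risk = rev_cum[first_idx]
    return float((lp[ev] - np.log(risk[ev])).sum())


def fit_lasso_cox(
    table: pd.DataFrame,
    survival: SurvivalData,
    n_folds: int = 10,
    seed: int = 0,
    n_alphas: int = 64,
    alpha_min_ratio: float = 0.05,
    allow_empty: bool = True,
) -> Tuple[CoxSignature, Dict[str, np.ndarray]]:
    """L1-penalized Cox regression with cross-validated penalty selection.

    The full regularization path is fitted on all data; the penalty
    ``lambda*`` minimizes the mean cross-validated partial-likelihood
    deviance (Verweij & van Houwelingen form, ``-2 (pl(beta; all) -
    pl(beta; train))``) over event-stratified folds.  Returns the sparse
    signature at ``lambda*`` plus path diagnostics (``alphas``,
    ``mean_deviance``, ``n_active``).
    """
    if survival.n_events < n_folds:
        raise ValueError(f"need at least {n_folds} events for {n_folds}-fold CV")
    X = table.to_numpy(dtype=float)
    y = survival.to_sksurv()

    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_alphas, alpha_min_ratio=alpha_min_ratio)
    path.fit(X, y)
    alphas = np.asarray(path.alphas_)

    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    dev = np.zeros((n_folds, alphas.size))
    for k, (tr, _te) in enumerate(cv.split(X, survival.event)):
        fold = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas)
        fold.fit(X[tr], y[tr])
        coefs = fold.coef_  # (n_features, n_alphas_fit)
        fitted = np.asarray(fold.alphas_)
        for a_idx, alpha in enumerate(alphas):
            j = int(np.argmin(np.abs(fitted - alpha)))
            beta = coefs[:, j]
            pl_all = _cox_partial_loglik(X @ beta, survival.time, survival.event)
            pl_tr = _cox_partial_loglik(X[tr] @ beta, survival.time[tr], survival.event[tr])
            dev[k, a_idx] = -2.0 * (pl_all - pl_tr)
    mean_dev = dev.mean(axis=0)
    best = int(np.argmin(mean_dev))
    n_active_path = (path.coef_ != 0).sum(axis=0)
    if not allow_empty and n_active_path[best] == 0:
        # deviance-minimal penalty among those with at least one active
        # feature, so downstream stages stay exercised on weak-signal data
        candidates = np.where(n_active_path > 0)[0]
        if candidates.size:
            best = int(candidates[np.argmin(mean_dev[candidates])])
            warnings.warn(
                "CV-minimum penalty gave an empty signature; using the best non-empty penalty",
                stacklevel=2,
            )
    lambda_star = float(alphas[best])

    coef = path.coef_[:, best]
    features = [(name, float(c)) for name, c in zip(table.columns, coef) if c != 0.0]
    if not features:
        warnings.warn("all coefficients zero at the selected penalty; empty signature", stacklevel=2)
    signature = CoxSignature(features, lambda_=lambda_star, seed=seed)
    info = {
        "alphas": alphas,
        "mean_deviance": mean_dev,
        "n_active": n_active_path,
        "best_index": best,
    }
    return signature, info


# ---------------------------------------------------------------------------
# Kaplan-Meier, log-rank family, concordance, hazard ratio
# ---------------------------------------------------------------------------


@dataclass
class KMCurve:
    """Product-limit survival curve with at-risk counts at event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int

    def survival_at(self, t) -> np.ndarray:
        """Step-function evaluation S(t) (right-continuous)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return out if out.size > 1 else float(out[0])

    @property
    def median(self) -> float:
        below = self.survival <= 0.5
        return float(self.times[below][0]) if below.any() else float("nan")


def km_estimate(survival: SurvivalData) -> KMCurve:
    """Kaplan-Meier product-limit estimator (censoring shrinks the risk set)."""
    if survival.n == 0:
        raise ValueError("empty survival data")
    kmf = KaplanMeierFitter()
    kmf.fit(survival.time, survival.event)
    tbl = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 else kmf.event_table
    times = tbl.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy()
    at_risk = tbl["at_risk"].to_numpy()
    return KMCurve(times=times, survival=surv, at_risk=at_risk, n=survival.n)


@dataclass
class WeightedLogrankResult:
    statistic: float  # chi-square with 1 df
    p_value: float
    z: float
    rho: float


def weighted_logrank(
    survival: SurvivalData,
    group: np.ndarray,
    rho: float = 1.0,
) -> WeightedLogrankResult:
    """G-rho family weighted log-rank test between two groups.

    Weights are ``S(t-)^rho`` with ``S`` the pooled left-continuous
    Kaplan-Meier estimate; ``rho=0`` reduces to the standard log-rank test,
    ``rho=1`` emphasizes early survival differences.  The statistic is
    compared to a chi-square with 1 df.
    """
    group = np.asarray(group)
    labels = np.unique(group)
    if labels.size != 2:
        raise ValueError("weighted log-rank requires exactly two nonempty groups")
    if survival.n_events == 0:
        raise ValueError("weighted log-rank requires at least one event")
    time, event = survival.time, survival.event
    g1 = group == labels[0]

    order = np.argsort(time, kind="stable")
    t_s, e_s, g1_s = time[order], event[order], g1[order]
    event_times = np.unique(t_s[e_s == 1])

    n_total = time.size
    z_num = 0.0
    var = 0.0
    s_pooled = 1.0  # left-continuous pooled KM, S(t-)
    prev_idx = 0
    for t in event_times:
        at_risk = t_s >= t
        n_j = int(at_risk.sum())
        n1_j = int((at_risk & g1_s).sum())
        died = (t_s == t) & (e_s == 1)
        d_j = int(died.sum())
        d1_j = int((died & g1_s).sum())
        w = s_pooled**rho
        e1 = d_j * n1_j / n_j
        z_num += w * (d1_j - e1)
        if n_j > 1:
            var += w**2 * d_j * (n1_j / n_j) * (1 - n1_j / n_j) * (n_j - d_j) / (n_j - 1)
        s_pooled *= 1.0 - d_j / n_j
    if var <= 0:
        return WeightedLogrankResult(0.0, 1.0, 0.0, rho)
    chi2 = z_num**2 / var
    p = float(sstats.chi2.sf(chi2, df=1))
    return WeightedLogrankResult(float(chi2), p, float(z_num / np.sqrt(var)), rho)


def harrell_cindex(scores: np.ndarray, survival: SurvivalData) -> Tuple[float, Tuple[float, float]]:
    """Harrell's C with a Noether-type 95% CI.

    Pairs are comparable when the earlier time carries an event; score ties
    count 1/2.  The standard error is ``sqrt(C(1-C)/m)`` over the ``m``
    comparable pairs (a Noether-style large-sample approximation).
    """
    scores = np.asarray(scores, dtype=float)
    c, conc, disc, tied, _ = concordance_index_censored(
        survival.event.astype(bool), survival.time, scores
    )
    m = conc + disc + tied
    if m == 0:
        raise ValueError("no comparable pairs for C-index")
    se = np.sqrt(max(c * (1.0 - c), 1e-12) / m)
    lo, hi = max(0.0, c - 1.96 * se), min(1.0, c + 1.96 * se)
    return float(c), (float(lo), float(hi))


def hazard_ratio(group: np.ndarray, survival: SurvivalData) -> Tuple[float, Tuple[float, float], float]:
    """Univariate Cox fit on a two-group indicator: HR, Wald 95% CI, p."""
    group = np.asarray(group)
    labels = np.unique(group)
    if labels.size != 2:
        raise ValueError("hazard_ratio requires exactly two groups")
    indicator = (group == labels[1]).astype(float)
    for lab in labels:
        if survival.event[group == lab].sum() == 0:
            raise ValueError(f"group {lab!r} has no events; hazard ratio undefined")
    df = pd.DataFrame({"group": indicator, "time": survival.time, "event": survival.event})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    beta = float(cph.params_["group"])
    se = float(cph.standard_errors_["group"])
    p = float(cph.summary.loc["group", "p"])
    return float(np.exp(beta)), (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se))), p


def optimal_cutpoint(
    scores: np.ndarray,
    survival: SurvivalData,
    min_group_frac: float = 0.10,
) -> float:
    """Optimal score cutpoint by exhaustive log-rank scanning.

    Candidate cuts are midpoints between consecutive sorted unique scores;
    cuts leaving fewer than ``min_group_frac`` of patients on either side
    are inadmissible.  The returned cut maximizes the standard (rho=0)
    log-rank chi-square.  This is a transparent stand-in for X-tile-style
    optimal cutpoint analysis.
    """
    scores = np.asarray(scores, dtype=float)
    uniq = np.unique(scores)
    if uniq.size < 2:
        raise ValueError("optimal cutpoint requires at least 2 distinct scores")
    n = scores.size
    min_group = max(1, int(np.ceil(min_group_frac * n)))
    best_cut, best_stat = None, -np.inf
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        cut = 0.5 * (lo + hi)
        high = scores > cut
        if high.sum() < min_group or (~high).sum() < min_group:
            continue
        if survival.event[high].sum() == 0 and survival.event[~high].sum() == 0:
            continue
        res = weighted_logrank(survival, high.astype(int), rho=0.0)
        if res.statistic > best_stat:
            best_stat, best_cut = res.statistic, cut
    if best_cut is None:
        raise ValueError("no admissible cutpoint under the minimum-group constraint")
    return float(best_cut)


@dataclass
class StratificationResult:
    """High/low risk stratification of a cohort at a score cutoff."""

    cutoff: float
    labels: np.ndarray  # 'high' / 'low'
    km_high: KMCurve
    km_low: KMCurve
    statistic: float
    p_value: float
    hazard_ratio: float
    hr_ci: Tuple[float, float]
    rho: float = 1.0

    @property
    def n_high(self) -> int:
        return int((self.labels == "high").sum())

    @property
    def n_low(self) -> int:
        return int((self.labels == "low").sum())


def stratify_by_score(
    scores: np.ndarray,
    survival: SurvivalData,
    cutoff: float,
    rho: float = 1.0,
) -> StratificationResult:
    """Split at the cutoff (score > cutoff = high risk) and test separation."""
    scores = np.asarray(scores, dtype=float)
    high = scores > cutoff
    if high.sum() in (0, scores.size):
        raise ValueError("cutoff leaves an empty risk group")
    labels = np.where(high, "high", "low")
    test = weighted_logrank(survival, high.astype(int), rho=rho)
    hr, hr_ci, _ = hazard_ratio(high.astype(int), survival)
    return StratificationResult(
        cutoff=float(cutoff),
        labels=labels,
        km_high=km_estimate(survival.subset(high)),
        km_low=km_estimate(survival.subset(~high)),
        statistic=test.statistic,
        p_value=test.p_value,
        hazard_ratio=hr,
        hr_ci=hr_ci,
        rho=rho,
    )


# ---------------------------------------------------------------------------
# statsmodels-style model / results surface
# ---------------------------------------------------------------------------


class SignatureModel:
    """LASSO-Cox radiomics signature model.

    Parameters
    ----------
    table:
        Patients x features matrix (z-scored with discovery statistics).
    survival:
        Matching :class:`SurvivalData`.
    """

    def __init__(self, table: pd.DataFrame, survival: SurvivalData):
        if len(table) != survival.n:
            raise ValueError("feature table and survival data disagree on patient count")
        self.table = table
        self.survival = survival

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        feature_cols: Sequence[str],
        time_col: str = "os_days",
        event_col: str = "event",
    ) -> "SignatureModel":
        return cls(df[list(feature_cols)], SurvivalData.from_dataframe(df, time_col, event_col))

    def fit(self, n_folds: int = 10, seed: int = 0, **kwargs) -> "SignatureResults":
        signature, info = fit_lasso_cox(self.table, self.survival, n_folds=n_folds, seed=seed, **kwargs)
        return SignatureResults(self, signature, info)


@dataclass
class SignatureResults:
    """Fitted radiomics signature with scoring and validation helpers."""

    model: SignatureModel
    signature: CoxSignature
    cv_path: Dict[str, np.ndarray] = field(default_factory=dict)
    _cutoff: Optional[float] = None

    def score(self, table: Optional[pd.DataFrame] = None) -> pd.Series:
        table = table if table is not None else self.model.table
        scores = radiomics_score(table, self.signature)
        return pd.Series(np.asarray(scores, dtype=float), index=table.index, name="rad_score")

    def fit_cutoff(self, min_group_frac: float = 0.10) -> float:
        """Optimal cutpoint on the model's own (discovery) cohort."""
        self._cutoff = optimal_cutpoint(self.score().to_numpy(), self.model.survival, min_group_frac)
        return self._cutoff

    @property
    def cutoff(self) -> float:
        if self._cutoff is None:
            self.fit_cutoff()
        return self._cutoff

    def stratify(
        self,
        table: Optional[pd.DataFrame] = None,
        survival: Optional[SurvivalData] = None,
        cutoff: Optional[float] = None,
        rho: float = 1.0,
    ) -> StratificationResult:
        table = table if table is not None else self.model.table
        survival = survival if survival is not None else self.model.survival
        cutoff = cutoff if cutoff is not None else self.cutoff
        return stratify_by_score(self.score(table).to_numpy(), survival, cutoff, rho=rho)

    def concordance(
        self,
        table: Optional[pd.DataFrame] = None,
        survival: Optional[SurvivalData] = None,
    ) -> Tuple[float, Tuple[float, float]]:
        table = table if table is not None else self.model.table
        survival = survival if survival is not None else self.model.survival
        return harrell_cindex(self.score(table).to_numpy(), survival)

    def summary(self) -> str:
        c, (lo, hi) = self.concordance()
        lines = [
            "Radiomics signature (LASSO Cox, CV-minimum penalty)",
            f"  n = {self.model.survival.n}, events = {self.model.survival.n_events}",
            f"  lambda* = {self.signature.lambda_:.6g}, active features = {len(self.signature)}",
            f"  discovery C-index = {c:.3f} (95% CI {lo:.3f}, {hi:.3f})",
            "",
            "  coefficients:",
        ]
        for name, coef in self.signature.features:
            lines.append(f"    {name:40s} {coef:+.8f}")
        return "\n".join(lines)


def fit_combined_cox(covariates: pd.DataFrame, survival: SurvivalData) -> "CombinedCoxResults":
    """Unpenalized multivariate Cox fit of score + clinical covariates.

    Constant covariates are excluded with a warning; non-convergence
    surfaces as an error with lifelines' diagnostics attached.
    """
    return CombinedCoxModel(covariates, survival).fit()


class CombinedCoxModel:
    """Multivariate Cox proportional-hazards model (score + clinical factors)."""

    def __init__(self, covariates: pd.DataFrame, survival: SurvivalData):
        if len(covariates) != survival.n:
            raise ValueError("covariate table and survival data disagree on patient count")
        if survival.n_events < 3:
            raise ValueError("combined Cox model requires at least 3 events")
        keep = []
        for col in covariates.columns:
            if covariates[col].nunique() <= 1:
                warnings.warn(f"constant covariate {col!r} excluded from Cox model", stacklevel=2)
            else:
                keep.append(col)
        if not keep:
            raise ValueError("no non-constant covariates to fit")
        self.covariates = covariates[keep]
        self.survival = survival

    def fit(self) -> "CombinedCoxResults":
        df = self.covariates.copy()
        df["__time"] = self.survival.time
        df["__event"] = self.survival.event
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="__time", event_col="__event")
        except Exception as exc:  # pragma: no cover - convergence diagnostics path
            raise RuntimeError(f"combined Cox model failed to converge: {exc}") from exc
        return CombinedCoxResults(self, cph)


class CombinedCoxResults:
    """Fitted combined Cox model: coefficients, uncertainty, prediction."""

    def __init__(self, model: CombinedCoxModel, fitter: CoxPHFitter):
        self.model = model
        self._cph = fitter
        self.params_ = fitter.params_.copy()
        self.standard_errors_ = fitter.standard_errors_.copy()
        self.p_values_ = fitter.summary["p"].copy()

    @property
    def covariate_names(self) -> List[str]:
        return list(self.params_.index)

    def linear_predictor(self, covariates: Optional[pd.DataFrame] = None) -> pd.Series:
        cov = covariates if covariates is not None else self.model.covariates
        lp = cov[self.covariate_names].to_numpy() @ self.params_.to_numpy()
        return pd.Series(lp, index=cov.index, name="lp")

    def predict_survival(self, covariates: pd.DataFrame, horizons: Sequence[float]) -> pd.DataFrame:
        """S(t | x) at the requested horizons via the Breslow-type baseline."""
        sf = self._cph.predict_survival_function(covariates[self.covariate_names], times=list(horizons))
        out = sf.T
        out.index = covariates.index
        out.columns = list(horizons)
        return out

    def concordance(
        self,
        covariates: Optional[pd.DataFrame] = None,
        survival: Optional[SurvivalData] = None,
    ) -> Tuple[float, Tuple[float, float]]:
        cov = covariates if covariates is not None else self.model.covariates
        surv = survival if survival is not None else self.model.survival
        return harrell_cindex(self.linear_predictor(cov).to_numpy(), surv)

    def summary(self) -> pd.DataFrame:
        s = self._cph.summary[["coef", "exp(coef)", "se(coef)", "z", "p"]].copy()
        s.index.name = "covariate"
        return s
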