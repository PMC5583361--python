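"""Points-based prognostic nomogram and calibration curves.

A nomogram renders a multivariate Cox model as additive point scales: each
covariate's contribution ``|beta_i| * (x_i - x_i,ref)`` is mapped linearly
to points, with the reference at that covariate's lowest-risk range end
and the largest single-covariate contribution spanning exactly 100 points.
Total points map affinely back onto the Cox linear predictor, so
nomogram-predicted survival ``S0(t)^exp(lp)`` at the 1/2/3-year horizons
is an exact round-trip of the Cox prediction.

Calibration groups patients by predicted-probability quantiles and
compares the group's mean prediction with the Kaplan-Meier estimate (and
Greenwood CI) at the horizon.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from radsurv.survival import CombinedCoxResults, SurvivalData

DEFAULT_HORIZONS = (365.0, 730.0, 1095.0)  # 1, 2, 3 years in days


@dataclass
class NomogramEntry:
    name: str
    beta: float
    low: float
    high: float
    ref: float  # range end of lowest risk

    def points(self, x) -> np.ndarray:
        # filled in by the parent model with the global scale
        raise NotImplementedError


@dataclass
class NomogramModel:
    """Additive point scales plus total-points -> survival maps."""

    entries: List[Dict[str, float]]
    max_span: float  # largest |beta| * range, mapped to 100 points
    lp_ref: float  # linear predictor at the all-reference (lowest-risk) patient
    horizons: Tuple[float, ...]
    baseline_survival: Dict[float, float]  # S(t | reference patient) per horizon

    def covariate_points(self, name: str, x) -> np.ndarray:
        entry = next(e for e in self.entries if e["name"] == name)
        x = np.asarray(x, dtype=float)
        # beta * (x - ref) is non-negative for in-range x by the reference
        # choice; keeping the sign (rather than taking |.|) makes the
        # points -> linear-predictor map exact even out of range
        pts = 100.0 * entry["beta"] * (x - entry["ref"]) / self.max_span
        return pts

    def total_points(self, covariates: Mapping[str, float] | pd.DataFrame) -> np.ndarray:
        if isinstance(covariates, pd.DataFrame):
            total = np.zeros(len(covariates))
            for e in self.entries:
                total += self.covariate_points(e["name"], covariates[e["name"]].to_numpy())
            return total
        return float(sum(self.covariate_points(e["name"], covariates[e["name"]]) for e in self.entries))

    def linear_predictor_from_points(self, total_points) -> np.ndarray:
        """Affine inverse map: lp = lp_ref + max_span * points / 100."""
        return self.lp_ref + self.max_span * np.asarray(total_points, dtype=float) / 100.0

    def predict_survival(self, covariates, horizon: float) -> np.ndarray:
        """Nomogram-predicted S(t|x) = S_ref(t)^exp(lp - lp_ref)."""
        if horizon not in self.baseline_survival:
            raise KeyError(f"horizon {horizon} not tabulated; available: {sorted(self.baseline_survival)}")
        pts = self.total_points(covariates)
        lp = self.linear_predictor_from_points(pts)
        s_ref = self.baseline_survival[horizon]
        return s_ref ** np.exp(lp - self.lp_ref)

    def to_json(self, path) -> None:
        payload = {
            "entries": self.entries,
            "max_span": self.max_span,
            "lp_ref": self.lp_ref,
            "horizons": list(self.horizons),
            "baseline_survival": {str(k): v for k, v in self.baseline_survival.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "NomogramModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            entries=payload["entries"],
            max_span=payload["max_span"],
            lp_ref=payload["lp_ref"],
            horizons=tuple(payload["horizons"]),
            baseline_survival={float(k): v for k, v in payload["baseline_survival"].items()},
        )

    def plot(self, ax=None):
        """Static nomogram figure: per-covariate point scales, total points,
        per-horizon survival-probability scales."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 2 + len(self.entries) + len(self.horizons)))
        n_rows = 1 + len(self.entries) + 1 + len(self.horizons)
        y = n_rows
        ax.hlines(y, 0, 100, color="k")
        for p in range(0, 101, 10):
            ax.plot([p, p], [y - 0.08, y + 0.08], color="k", lw=0.8)
            ax.text(p, y + 0.18, f"{p}", ha="center", fontsize=7)
        ax.text(-4, y, "Points", ha="right", va="center")
        y -= 1
        for e in self.entries:
            span = self.covariate_points(e["name"], e["high"] if e["ref"] == e["low"] else e["low"])
            lo_pt, hi_pt = 0.0, float(span)
            ax.hlines(y, lo_pt, hi_pt, color="tab:blue")
            for frac in np.linspace(0, 1, 5):
                x_val = e["ref"] + frac * ((e["high"] if e["ref"] == e["low"] else e["low"]) - e["ref"])
                p = self.covariate_points(e["name"], x_val)
                ax.plot([p, p], [y - 0.08, y + 0.08], color="tab:blue", lw=0.8)
                ax.text(p, y - 0.3, f"{x_val:.2g}", ha="center", fontsize=7)
            ax.text(-4, y, e["name"], ha="right", va="center")
            y -= 1
        max_total = sum(
            self.covariate_points(e["name"], e["high"] if e["ref"] == e["low"] else e["low"])
            for e in self.entries
        )
        ax.hlines(y, 0, max_total, color="k")
        ax.text(-4, y, "Total points", ha="right", va="center")
        for p in np.linspace(0, max_total, 11):
            ax.plot([p, p], [y - 0.08, y + 0.08], color="k", lw=0.8)
            ax.text(p, y + 0.15, f"{p:.0f}", ha="center", fontsize=7)
        y -= 1
        for h in self.horizons:
            probs = self.predict_survival_from_points(np.linspace(0, max_total, 200), h)
            ax.hlines(y, 0, max_total, color="tab:green", lw=0.8)
            for target in (0.9, 0.7, 0.5, 0.3, 0.1):
                idx = int(np.argmin(np.abs(probs - target)))
                p = np.linspace(0, max_total, 200)[idx]
                ax.plot([p, p], [y - 0.08, y + 0.08], color="tab:green", lw=0.8)
                ax.text(p, y - 0.3, f"{target:.1f}", ha="center", fontsize=7)
            ax.text(-4, y, f"S({h:.0f}d)", ha="right", va="center")
            y -= 1
        ax.set_ylim(y, n_rows + 1)
        ax.axis("off")
        return ax

    def predict_survival_from_points(self, total_points, horizon: float) -> np.ndarray:
        lp = self.linear_predictor_from_points(total_points)
        s_ref = self.baseline_survival[horizon]
        return s_ref ** np.exp(lp - self.lp_ref)


def build_nomogram(
    results: CombinedCoxResults,
    covariate_ranges: Mapping[str, Tuple[float, float]],
    horizons: Sequence[float] = DEFAULT_HORIZONS,
) -> NomogramModel:
    """Build the point-scale nomogram from a fitted combined Cox model.

    ``covariate_ranges`` gives the finite (low, high) display range per
    covariate; the reference is the lowest-risk range end (low for a
    positive coefficient, high for a negative one).  Zero-range covariates
    are excluded with a warning.
    """
    entries: List[Dict[str, float]] = []
    fixed: Dict[str, float] = {}  # zero-range covariates, held at their value
    for name in results.covariate_names:
        if name not in covariate_ranges:
            raise KeyError(f"no display range given for covariate {name!r}")
        lo, hi = (float(v) for v in covariate_ranges[name])
        if not np.isfinite([lo, hi]).all() or hi <= lo:
            if hi == lo and np.isfinite(lo):
                warnings.warn(f"zero-range covariate {name!r} excluded from nomogram", stacklevel=2)
                fixed[name] = lo
                continue
            raise ValueError(f"invalid range for covariate {name!r}: ({lo}, {hi})")
        beta = float(results.params_[name])
        ref = lo if beta >= 0 else hi
        entries.append({"name": name, "beta": beta, "low": lo, "high": hi, "ref": ref})
    if not entries:
        raise ValueError("no usable covariates for the nomogram")
    max_span = max(abs(e["beta"]) * (e["high"] - e["low"]) for e in entries)
    lp_ref = float(sum(e["beta"] * e["ref"] for e in entries))

    ref_values = {e["name"]: [e["ref"]] for e in entries}
    ref_values.update({name: [val] for name, val in fixed.items()})
    ref_row = pd.DataFrame(ref_values, index=["__ref"])
    s_ref = results.predict_survival(ref_row, horizons).iloc[0]
    baseline = {float(h): float(s_ref[h]) for h in horizons}
    return NomogramModel(
        entries=entries,
        max_span=float(max_span),
        lp_ref=lp_ref,
        horizons=tuple(float(h) for h in horizons),
        baseline_survival=baseline,
    )


def calibration_curve(
    predicted: np.ndarray,
    survival: SurvivalData,
    horizon: float,
    n_groups: int = 3,
) -> pd.DataFrame:
    """Predicted vs observed survival probability at a horizon.

    Patients are grouped by predicted-probability quantiles; per group the
    mean prediction is paired with the Kaplan-Meier estimate (Greenwood
    95% CI) at the horizon.  Groups with no patient at risk through the
    horizon are flagged.
    """
    predicted = np.asarray(predicted, dtype=float)
    if predicted.size != survival.n:
        raise ValueError("predictions and survival data disagree on patient count")
    if predicted.size < n_groups:
        raise ValueError("need at least n_groups patients")
    try:
        groups = np.asarray(pd.qcut(predicted, q=n_groups, labels=False, duplicates="drop"), dtype=float)
        groups = np.where(np.isnan(groups), 0.0, groups).astype(int)
    except ValueError:
        groups = np.zeros(predicted.size, dtype=int)
    if np.unique(groups).size < n_groups:
        warnings.warn("fewer effective calibration groups than requested (tied predictions)", stacklevel=2)
    rows = []
    for g in np.unique(groups):
        sel = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(survival.time[sel], survival.event[sel])
        obs = float(kmf.survival_function_at_times(horizon).iloc[0])
        ci = kmf.confidence_interval_survival_function_
        tidx = ci.index.searchsorted(horizon, side="right") - 1
        if tidx >= 0:
            lo, hi = float(ci.iloc[tidx, 0]), float(ci.iloc[tidx, 1])
        else:
            lo, hi = 0.0, 1.0
        at_risk_through = bool((survival.time[sel] >= horizon).any())
        rows.append(
            {
                "group": int(g),
                "n": int(sel.sum()),
                "mean_predicted": float(predicted[sel].mean()),
                "km_observed": obs,
                "ci_low": lo,
                "ci_high": hi,
                "flagged": not at_risk_through,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def plot_calibration(curve: pd.DataFrame, ax=None):
    """Calibration plot: mean predicted vs KM-observed with CIs and diagonal."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="ideal")
    ax.errorbar(
        curve["mean_predicted"],
        curve["km_observed"],
        yerr=[curve["km_observed"] - curve["ci_low"], curve["ci_high"] - curve["km_observed"]],
        fmt="o-",
        capsize=3,
    )
    ax.set_xlabel("Nomogram-predicted survival probability")
    ax.set_ylabel("Observed (Kaplan-Meier)")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    return ax
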