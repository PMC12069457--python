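"""Survival analysis linking spatial features to outcome.

Kaplan-Meier estimation (Greenwood variance, log-log confidence bands),
log-rank comparison, and univariate Cox proportional-hazards models with
cluster-robust (sandwich) variance. Clustering is by patient: in
tissue-microarray cohorts a patient can contribute several cores, and score
residuals are aggregated within patient before the outer product so repeated
cores do not spuriously shrink standard errors. Ties use the Efron
approximation. Fits are delegated to lifelines behind this module surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times

from .composition import bh_adjust, significance_tier

__all__ = [
    "KMEstimate",
    "CoxFit",
    "km_estimate",
    "logrank_test",
    "fit_cox_univariate",
    "spatial_survival_scan",
]


@dataclass
class KMEstimate:
    """Product-limit survival curve with median and fixed-horizon summaries."""

    times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    median: float  # NaN when the curve never reaches 0.5
    median_ci: tuple
    survival_at: dict
    n: int
    n_events: int

    def at(self, t: float) -> float:
        """Step-function evaluation Ŝ(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[idx]) if idx >= 0 else 1.0


def km_estimate(times, events, horizons=(60.0, 120.0), alpha: float = 0.05) -> KMEstimate:
    """Kaplan-Meier estimator with Greenwood-based log-log 95% CI.

    ``median`` is the earliest time at which the curve drops to <= 0.5 (NaN
    if never reached, e.g. under heavy censoring); ``survival_at`` reports
    Ŝ at the given horizons (months).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("need at least one record")
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    kmf = KaplanMeierFitter(alpha=alpha).fit(times, events)
    sf = kmf.survival_function_
    ci = kmf.confidence_interval_
    med = kmf.median_survival_time_
    med_ci_df = median_survival_times(kmf.confidence_interval_)
    med_ci = (float(med_ci_df.iloc[0, 0]), float(med_ci_df.iloc[0, 1]))
    surv_at = {float(h): float(kmf.predict(h)) for h in horizons}
    return KMEstimate(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(),
        ci_lower=ci.iloc[:, 0].to_numpy(),
        ci_upper=ci.iloc[:, 1].to_numpy(),
        median=float(med) if np.isfinite(med) else float("nan"),
        median_ci=med_ci,
        survival_at=surv_at,
        n=len(times),
        n_events=int(events.sum()),
    )


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-or-more-sample log-rank test; returns (chi-square statistic, p)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 non-empty groups")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxFit:
    """Univariate Cox fit: log hazard ratio with naive and cluster-robust SE."""

    coef: float
    se_naive: float
    se_robust: float
    z: float
    p: float
    n: int
    n_events: int
    n_clusters: int
    converged: bool


def fit_cox_univariate(feature, times, events, clusters=None) -> CoxFit:
    """Cox partial-likelihood fit of a single feature, Efron ties.

    ``clusters`` groups observations (samples) by patient; the robust
    variance sums score residuals within cluster before the outer product.
    Without clusters every observation is its own cluster, which reduces the
    estimator to the ordinary robust sandwich. Inference (z, p) uses the
    robust SE.
    """
    feature = np.asarray(feature, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if np.ptp(feature[~np.isnan(feature)]) == 0:
        raise ValueError("feature is constant; hazard ratio not identifiable")
    if events.sum() < 2:
        raise ValueError("need at least 2 events")
    if clusters is None:
        clusters = np.arange(len(times))
    clusters = np.asarray(clusters)
    df = pd.DataFrame(
        {"T": times, "E": events, "x": feature, "cluster": clusters}
    ).dropna(subset=["x"])
    robust = CoxPHFitter().fit(df, "T", "E", cluster_col="cluster")
    naive = CoxPHFitter().fit(df[["T", "E", "x"]], "T", "E")
    coef = float(robust.params_.iloc[0])
    se_r = float(robust.standard_errors_.iloc[0])
    z = coef / se_r
    from scipy.stats import norm

    return CoxFit(
        coef=coef,
        se_naive=float(naive.standard_errors_.iloc[0]),
        se_robust=se_r,
        z=z,
        p=float(2 * norm.sf(abs(z))),
        n=len(df),
        n_events=int(df["E"].sum()),
        n_clusters=int(pd.unique(df["cluster"]).size),
        converged=True,
    )


def spatial_survival_scan(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    feature_cols: list[str] | None = None,
    family: str = "scan",
    adjust: bool = False,
    min_events: int = 2,
) -> pd.DataFrame:
    """One clustered univariate Cox fit per spatial feature.

    ``features`` carries one row per sample with a ``patient_id`` column and
    scalar spatial features (G-cross values at fixed radii, AUCs,
    proportions); ``clinical`` one row per patient with ``time_months`` and
    ``event``. Sample rows are joined to their patient's outcome and kept as
    separate observations with patient-level clustering. Samples with a
    missing feature (e.g. an excluded type pair) are dropped per fit, not
    imputed. Raw p-value tiers are reported by default; ``adjust=True`` adds
    BH q-values across the scanned family instead.
    """
    if feature_cols is None:
        feature_cols = [
            c for c in features.columns
            if c not in ("sample_id", "patient_id") and features[c].dtype.kind == "f"
        ]
    feats = features.reset_index() if features.index.name == "sample_id" else features.copy()
    merged = feats.merge(
        clinical[["patient_id", "time_months", "event"]], on="patient_id", how="inner"
    )
    rows = []
    for col in feature_cols:
        sub = merged.dropna(subset=[col])
        rec = {
            "family": family,
            "feature": col,
            "log_HR": np.nan,
            "robust_se": np.nan,
            "p": np.nan,
            "n": len(sub),
            "n_clusters": int(sub["patient_id"].nunique()),
            "skip_reason": "",
        }
        if len(sub) == 0 or sub["event"].sum() < min_events:
            rec["skip_reason"] = "fewer than 2 events"
            rows.append(rec)
            continue
        try:
            fit = fit_cox_univariate(
                sub[col], sub["time_months"], sub["event"], sub["patient_id"]
            )
        except Exception as exc:
            rec["skip_reason"] = f"fit failed: {exc}"
            rows.append(rec)
            continue
        rec.update(log_HR=fit.coef, robust_se=fit.se_robust, p=fit.p,
                   n=fit.n, n_clusters=fit.n_clusters)
        rows.append(rec)
    out = pd.DataFrame(rows)
    ok = out["skip_reason"] == ""
    if adjust:
        out["q"] = np.nan
        if ok.any():
            out.loc[ok, "q"] = bh_adjust(out.loc[ok, "p"].to_numpy())
        out["tier"] = [significance_tier(q) if o else "" for o, q in zip(ok, out["q"])]
    else:
        out["tier"] = [significance_tier(p) if o else "" for o, p in zip(ok, out["p"])]
    return out
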