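"""Compositional comparison of proportion-valued features between cohorts.

Each feature (a cell-type proportion, a neighborhood proportion, or a nested
fraction) is compared between groups with beta regression — the response is
beta-distributed with mean modelled through a logit link and a single
precision parameter φ — so the group coefficient β is the change in log-odds
of the mean proportion. P-values across a feature family are adjusted with
Benjamini-Hochberg FDR, and significance tiers follow the */**/***
convention at q < 0.05 / 0.01 / 0.001.

Exact 0/1 proportions are incompatible with the beta likelihood; they are
compressed with the Smithson–Verkuilen transform y' = (y·(n−1)+0.5)/n,
applied to every response for estimator continuity. Features constant within
a group (zero variance) are excluded before fitting, as are non-converged
fits, and neither enters the FDR family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.othermod.betareg import BetaModel
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BetaRegFit",
    "boundary_adjust",
    "fit_beta_regression",
    "bh_adjust",
    "significance_tier",
    "compare_cohorts",
]


@dataclass
class BetaRegFit:
    """Beta-regression fit: mean-model coefficients on the logit scale plus a
    fitted constant precision φ."""

    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    phi: float
    converged: bool
    nobs: int

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse, "upper": self.params + z * self.bse}
        )


def boundary_adjust(y, n: int | None = None) -> np.ndarray:
    """Smithson–Verkuilen compression of [0,1] proportions into (0,1).

    y' = (y·(n−1) + 0.5) / n with n the sample count; order-preserving and a
    fixed point at 0.5.
    """
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    if n is None:
        n = y.size
    if n < 2:
        raise ValueError("need n >= 2 for boundary adjustment")
    return (y * (n - 1) + 0.5) / n


def fit_beta_regression(y, X) -> BetaRegFit:
    """Maximum-likelihood beta regression with logit mean link and constant
    precision (log link).

    ``y`` must already lie strictly inside (0,1) — apply
    :func:`boundary_adjust` first. ``X`` is a design matrix *without*
    intercept column; one is prepended (named ``intercept``).
    """
    y = np.asarray(y, dtype=float)
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("responses must lie strictly in (0, 1); boundary-adjust first")
    if isinstance(X, pd.Series):
        X = X.to_frame()
    if isinstance(X, pd.DataFrame):
        names = ["intercept", *X.columns.astype(str)]
        Xmat = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    else:
        Xmat = np.asarray(X, dtype=float)
        if Xmat.ndim == 1:
            Xmat = Xmat[:, None]
        names = ["intercept"] + [f"x{k}" for k in range(Xmat.shape[1])]
        Xmat = np.column_stack([np.ones(len(Xmat)), Xmat])
    for k in range(1, Xmat.shape[1]):
        if np.ptp(Xmat[:, k]) == 0:
            raise ValueError("design contains a constant (non-identifiable) predictor")
    model = BetaModel(y, Xmat)
    res = model.fit(disp=0)
    converged = bool(res.mle_retvals.get("converged", False))
    p = len(names)
    idx = pd.Index(names)
    return BetaRegFit(
        params=pd.Series(res.params[:p], index=idx),
        bse=pd.Series(res.bse[:p], index=idx),
        zvalues=pd.Series(res.tvalues[:p], index=idx),
        pvalues=pd.Series(res.pvalues[:p], index=idx),
        phi=float(np.exp(res.params[-1])),
        converged=converged,
        nobs=len(y),
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def significance_tier(q: float) -> str:
    if q < 0.001:
        return "***"
    if q < 0.01:
        return "**"
    if q < 0.05:
        return "*"
    return ""


def compare_cohorts(
    features: pd.DataFrame,
    groups: pd.Series,
    family: str = "features",
    reference: str | None = None,
) -> pd.DataFrame:
    """One beta regression per feature column, BH-adjusted across the family.

    ``features`` has one row per sample and one proportion column per
    feature; ``groups`` the cohort label per sample (2+ levels; the fitted
    coefficient is for the non-reference level — with two levels and
    ``reference`` unset, the lexicographically first level is the
    reference). Features that are constant within any group, raise at fit
    time, or do not converge are reported with ``skip_reason`` set and are
    excluded from the FDR family.
    """
    groups = pd.Series(groups).reindex(features.index)
    levels = sorted(groups.dropna().unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 cohorts")
    if reference is not None:
        levels = [reference] + [l for l in levels if l != reference]
    dummies = pd.get_dummies(groups, dtype=float).reindex(columns=levels)
    X = dummies[levels[1:]]
    rows = []
    for feat in features.columns:
        y_raw = features[feat]
        keep = y_raw.notna() & groups.notna()
        y = y_raw[keep]
        g = groups[keep]
        rec = {
            "feature": feat,
            "family": family,
            "n": int(keep.sum()),
            "beta": np.nan,
            "se": np.nan,
            "p": np.nan,
            "skip_reason": "",
        }
        if any((y[g == lv].var(ddof=0) == 0) or (len(y[g == lv]) < 2) for lv in levels):
            rec["skip_reason"] = "zero variance or too few samples in a group"
            rows.append(rec)
            continue
        try:
            fit = fit_beta_regression(boundary_adjust(y.to_numpy()), X[keep])
        except Exception as exc:  # non-identifiable / optimizer failure
            rec["skip_reason"] = f"fit failed: {exc}"
            rows.append(rec)
            continue
        if not fit.converged:
            rec["skip_reason"] = "did not converge"
            rows.append(rec)
            continue
        coef_name = str(levels[1]) if len(levels) == 2 else None
        if coef_name is None:
            coef_name = fit.params.index[1]
        rec.update(
            beta=float(fit.params[coef_name]),
            se=float(fit.bse[coef_name]),
            p=float(fit.pvalues[coef_name]),
            phi=float(fit.phi),
        )
        rows.append(rec)
    out = pd.DataFrame(rows)
    fitted = out["skip_reason"] == ""
    out["q"] = np.nan
    if fitted.any():
        out.loc[fitted, "q"] = bh_adjust(out.loc[fitted, "p"].to_numpy())
    out["tier"] = ["" if not ok else significance_tier(q)
                   for ok, q in zip(fitted, out["q"])]
    return out
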