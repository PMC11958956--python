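"""Urinary-exposure preprocessing.

Raw analyte concentrations become analysis exposures through a fixed
pipeline order:

* main path:        LOD-impute -> creatinine-correct -> natural log
* sensitivity path: LOD-impute -> covariate-adjusted standardize -> ln

LOD imputation codes below-detection values as LOD/sqrt(2) on the measured
concentration scale.  Creatinine correction divides the concentration
(ug/L) by urinary creatinine expressed in g/L (1 mg/dL = 0.01 g/L),
yielding ug/g creatinine.  The covariate-adjusted standardization fits a
linear model of ln creatinine on covariates and scales each analyte by the
ratio of predicted to measured creatinine, decoupling dilution adjustment
from covariates that drive creatinine itself.  Quartile categories use
survey-weighted percentile cut points by default (an unweighted switch is
provided; the weighted/unweighted choice is an analysis assumption).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "impute_lod",
    "creatinine_correct",
    "covariate_adjusted_standardize",
    "weighted_quantile",
    "quartile_categorize",
    "build_exposures",
]

_SQRT2 = np.sqrt(2.0)


def impute_lod(raw, flag, lod):
    """Replace below-LOD values by LOD/sqrt(2); pass detected values through.

    ``raw`` may be NaN where ``flag`` is set (the generator withholds
    censored values).  A flagged row with a missing LOD is an error.
    """
    raw = np.asarray(raw, dtype=float)
    flag = np.asarray(flag).astype(bool)
    lod = np.asarray(lod, dtype=float)
    lod = np.broadcast_to(lod, raw.shape)
    bad = flag & (~np.isfinite(lod) | (lod <= 0))
    if np.any(bad):
        rows = np.flatnonzero(bad)[:10].tolist()
        raise ValueError(f"below-LOD rows with missing/invalid LOD: {rows}")
    return np.where(flag, lod / _SQRT2, raw)


def creatinine_correct(analyte, creatinine_mg_dl):
    """ug/L divided by urinary creatinine in g/L -> ug/g creatinine."""
    analyte = np.asarray(analyte, dtype=float)
    creat = np.asarray(creatinine_mg_dl, dtype=float)
    bad = ~(creat > 0)
    if np.any(bad):
        rows = np.flatnonzero(bad)[:10].tolist()
        raise ValueError(f"non-positive urinary creatinine at rows: {rows}")
    return analyte / (creat * 0.01)


def _categorical_design(covariates: pd.DataFrame):
    """Intercept + dummy/numeric design matrix; rejects singular designs."""
    parts = [pd.Series(1.0, index=covariates.index, name="const")]
    for col in covariates.columns:
        s = covariates[col]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.astype(float))
        else:
            dummies = pd.get_dummies(s.astype(str), prefix=col, drop_first=True)
            parts.append(dummies.astype(float))
    X = pd.concat(parts, axis=1)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the offending columns via QR pivoting
        _, R = np.linalg.qr(X.to_numpy())
        small = np.abs(np.diag(R)) < 1e-8 * np.abs(np.diag(R)).max()
        names = [c for c, s in zip(X.columns, small) if s]
        raise ValueError(f"singular covariate design; collinear columns: {names}")
    return X


def covariate_adjusted_standardize(analyte, creatinine_mg_dl, covariates: pd.DataFrame):
    """Standardize analytes by predicted-to-measured creatinine ratio.

    Fits ln(creatinine) ~ covariates by OLS, predicts creatinine
    ``C_hat = exp(fit)``, and returns ``analyte / (C / C_hat)`` (ug/L on the
    standardized scale) together with the fitted coefficients for audit.
    """
    analyte = np.asarray(analyte, dtype=float)
    creat = np.asarray(creatinine_mg_dl, dtype=float)
    if np.any(~(creat > 0)):
        raise ValueError("urinary creatinine must be positive")
    X = _categorical_design(covariates)
    coefs, *_ = np.linalg.lstsq(X.to_numpy(), np.log(creat), rcond=None)
    pred = np.exp(X.to_numpy() @ coefs)
    standardized = analyte * pred / creat
    return standardized, dict(zip(X.columns, coefs))


def weighted_quantile(values, probs, weights=None):
    """Inverse weighted empirical CDF with linear interpolation.

    Plotting positions ``p_i = (C_i - w_i) / (W - w_n)`` over the sorted
    sample (``C_i`` the cumulative weight, ``w_n`` the last sorted weight)
    reduce to the standard type-7 definition under equal weights.
    """
    values = np.asarray(values, dtype=float)
    probs = np.atleast_1d(np.asarray(probs, dtype=float))
    if weights is None:
        weights = np.ones_like(values)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    denom = cw[-1] - w[-1]
    if denom <= 0:
        # all weight on one observation: every quantile is that value
        return np.full(probs.shape, v[np.argmax(w)])
    p = (cw - w) / denom
    return np.interp(probs, p, v)


def quartile_categorize(values, weights=None):
    """Survey-weighted quartiles: returns (cut points, labels 1..4).

    Cut points are the weighted 25th/50th/75th percentiles; labels use
    half-open intervals with the lowest quartile as reference category 1.
    """
    values = np.asarray(values, dtype=float)
    if len(np.unique(values)) < 8:
        raise ValueError("need at least 8 distinct values to form quartiles")
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        ess = w.sum() ** 2 / (w**2).sum()
        if ess < 8:
            warnings.warn(
                f"effective sample size {ess:.1f} < 8 (weights concentrated "
                "on few points); quartile cut points are tie-prone",
                stacklevel=2,
            )
    cuts = weighted_quantile(values, [0.25, 0.50, 0.75], weights)
    if len(np.unique(cuts)) < 3:
        warnings.warn(
            "tied quartile cut points (heavy ties or degenerate weights); "
            "labels remain exhaustive and exclusive",
            stacklevel=2,
        )
    labels = 1 + np.searchsorted(cuts, values, side="left").astype(int)
    return cuts, labels


def build_exposures(
    table: pd.DataFrame,
    analytes,
    creatinine_col: str = "urinary_creatinine",
    weight_col: str | None = "weight",
    standardize_covariates: list[str] | None = None,
    weighted_quartiles: bool = True,
) -> pd.DataFrame:
    """Append the derived exposure columns for each analyte.

    Adds ``{a}_lodimp`` (ug/L after LOD imputation), ``{a}_cc`` (ug/g
    creatinine), ``{a}_ln`` (ln of corrected value), ``{a}_q`` (quartile
    1-4) and, when ``standardize_covariates`` is given, the sensitivity-path
    ``{a}_std`` / ``{a}_std_ln`` columns.
    """
    out = table.copy()
    weights = None
    if weighted_quartiles and weight_col is not None and weight_col in out:
        weights = out[weight_col].to_numpy(dtype=float)
    for a in analytes:
        imputed = impute_lod(
            out[f"{a}_conc"], out[f"{a}_below_lod"], out[f"{a}_lod"]
        )
        corrected = creatinine_correct(imputed, out[creatinine_col])
        out[f"{a}_lodimp"] = imputed
        out[f"{a}_cc"] = corrected
        out[f"{a}_ln"] = np.log(corrected)
        _, labels = quartile_categorize(corrected, weights)
        out[f"{a}_q"] = labels
        if standardize_covariates:
            std, _ = covariate_adjusted_standardize(
                imputed, out[creatinine_col], out[standardize_covariates]
            )
            out[f"{a}_std"] = std
            out[f"{a}_std_ln"] = np.log(std)
    return out
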