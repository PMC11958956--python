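"""Biological-age clocks: phenotypic age and Klemera-Doubal biological age.

Two outcome scores are computed from routine clinical biomarkers:

* **Phenotypic age** maps nine blood biomarkers plus chronological age
  through a fixed-coefficient linear predictor ``xb``, a Gompertz-based
  10-year mortality score, and a log-log transform back onto an age scale
  (years).  The coefficients are frozen constants shipped with the package
  (``phenoage_coefficients.txt``); they are unit-bound, so inputs must be in
  the documented units.

* **KDM biological age** (Klemera-Doubal) combines per-biomarker ordinary
  regressions of biomarker on chronological age -- slope ``k_j``, intercept
  ``q_j``, residual RMSE ``s_j`` -- into a precision-weighted age estimate
  with a variance-correction term ``s_BA^2``.  Unlike phenotypic age it is
  trained on the analysis sample itself and the fitted parameters are
  serializable so scoring is reproducible.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PhenoAgeCoefficients",
    "load_phenoage_coefficients",
    "phenoage",
    "phenoage_table",
    "KDMTraining",
    "fit_kdm",
    "kdm_ba_e",
    "kdm_biological_age",
    "PHENOAGE_BIOMARKERS",
    "DEFAULT_PHENOAGE_COLUMNS",
]

# Order of the nine biomarker terms in the linear predictor (age is appended).
PHENOAGE_BIOMARKERS = (
    "albumin",
    "creatinine",
    "glucose",
    "ln_crp",
    "lymphocyte_pct",
    "mcv",
    "rdw",
    "alp",
    "wbc",
)

# Default mapping from linear-predictor terms to cohort-table columns.
DEFAULT_PHENOAGE_COLUMNS = {
    "albumin": "ph_albumin",
    "creatinine": "ph_creatinine",
    "glucose": "ph_glucose",
    "crp": "ph_crp",          # mg/dL; log taken internally with a floor
    "lymphocyte_pct": "ph_lymphpct",
    "mcv": "ph_mcv",
    "rdw": "ph_rdw",
    "alp": "ph_alp",
    "wbc": "ph_wbc",
    "age": "age",
}

# Broad plausibility screens (unit sanity, not clinical reference ranges).
_PLAUSIBLE = {
    "albumin": (20.0, 60.0),        # g/L
    "creatinine": (20.0, 1000.0),   # umol/L
    "glucose": (2.0, 30.0),         # mmol/L
    "lymphocyte_pct": (1.0, 80.0),
    "mcv": (60.0, 120.0),           # fL
    "rdw": (10.0, 30.0),            # %
    "alp": (5.0, 500.0),            # U/L
    "wbc": (1.0, 40.0),             # 1000 cells/uL
}


@dataclass(frozen=True)
class PhenoAgeCoefficients:
    """Immutable phenotypic-age constants (linear predictor + transforms)."""

    intercept: float
    terms: dict[str, float]      # biomarker name -> coefficient, plus "age"
    gompertz_a: float
    gompertz_b: float
    pa_c1: float
    pa_c2: float
    pa_c3: float


def _parse_kv_text(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out


def load_phenoage_coefficients() -> PhenoAgeCoefficients:
    """Load the versioned phenotypic-age constants shipped with the package."""
    text = (
        importlib.resources.files("bioaging_mixtures")
        .joinpath("phenoage_coefficients.txt")
        .read_text(encoding="utf-8")
    )
    kv = {k: float(v) for k, v in _parse_kv_text(text).items()}
    terms = {name: kv[name] for name in PHENOAGE_BIOMARKERS}
    terms["age"] = kv["age"]
    return PhenoAgeCoefficients(
        intercept=kv["intercept"],
        terms=terms,
        gompertz_a=kv["gompertz_a"],
        gompertz_b=kv["gompertz_b"],
        pa_c1=kv["pa_c1"],
        pa_c2=kv["pa_c2"],
        pa_c3=kv["pa_c3"],
    )


_DEFAULT_COEFFS: PhenoAgeCoefficients | None = None


def _default_coeffs() -> PhenoAgeCoefficients:
    global _DEFAULT_COEFFS
    if _DEFAULT_COEFFS is None:
        _DEFAULT_COEFFS = load_phenoage_coefficients()
    return _DEFAULT_COEFFS


def phenoage(
    biomarkers: dict[str, np.ndarray],
    age,
    coeffs: PhenoAgeCoefficients | None = None,
):
    """Compute (xb, mortality score, phenotypic age) from the nine biomarkers.

    Parameters
    ----------
    biomarkers
        Mapping with keys :data:`PHENOAGE_BIOMARKERS` (``ln_crp`` is the
        natural log of C-reactive protein in mg/dL).  Values are scalars or
        equal-length arrays.
    age
        Chronological age in years.

    Returns
    -------
    xb, mortality_score, phenotypic_age
        ``mortality_score`` is the Gompertz 10-year mortality probability in
        (0, 1); ``phenotypic_age`` is in years.  Vectorized over rows.
    """
    coeffs = coeffs or _default_coeffs()
    missing = [b for b in PHENOAGE_BIOMARKERS if b not in biomarkers]
    if missing:
        raise ValueError(f"missing phenotypic-age biomarkers: {missing}")
    age = np.asarray(age, dtype=float)
    xb = np.full(age.shape, coeffs.intercept, dtype=float)
    for name in PHENOAGE_BIOMARKERS:
        vals = np.asarray(biomarkers[name], dtype=float)
        if not np.all(np.isfinite(vals)):
            bad = np.flatnonzero(~np.isfinite(np.atleast_1d(vals)))
            raise ValueError(
                f"non-finite value in biomarker {name!r} at rows {bad[:10].tolist()}"
            )
        xb = xb + coeffs.terms[name] * vals
    if not np.all(np.isfinite(age)):
        raise ValueError("non-finite chronological age")
    xb = xb + coeffs.terms["age"] * age
    # 10-year mortality under the Gompertz hazard; strictly in (0,1) for
    # finite xb, so the log-log transform below is always defined.
    mortality = 1.0 - np.exp(-coeffs.gompertz_a * np.exp(xb) / coeffs.gompertz_b)
    pheno = coeffs.pa_c1 + np.log(coeffs.pa_c2 * np.log1p(-mortality)) / coeffs.pa_c3
    return xb, mortality, pheno


def phenoage_table(
    table: pd.DataFrame,
    columns: dict[str, str] | None = None,
    coeffs: PhenoAgeCoefficients | None = None,
    crp_floor: float = 0.01,
    warn_implausible: bool = True,
) -> pd.DataFrame:
    """Score a cohort table, returning xb / mortality_score / phenotypic_age.

    CRP is read on the concentration scale (mg/dL) from ``columns['crp']``
    and floored at ``crp_floor`` before the natural log, so non-positive
    laboratory values do not produce -inf.  Implausible units trigger a
    warning, never a rejection.
    """
    columns = dict(DEFAULT_PHENOAGE_COLUMNS if columns is None else columns)
    crp = table[columns.pop("crp")].to_numpy(dtype=float)
    if np.any(~np.isfinite(crp)):
        raise ValueError("non-finite CRP values")
    n_floored = int(np.sum(crp < crp_floor))
    if n_floored:
        warnings.warn(
            f"{n_floored} CRP values below {crp_floor} mg/dL floored before ln",
            stacklevel=2,
        )
    biomarkers = {"ln_crp": np.log(np.maximum(crp, crp_floor))}
    for name in PHENOAGE_BIOMARKERS:
        if name == "ln_crp":
            continue
        biomarkers[name] = table[columns[name]].to_numpy(dtype=float)
        if warn_implausible and name in _PLAUSIBLE:
            lo, hi = _PLAUSIBLE[name]
            frac = np.mean((biomarkers[name] < lo) | (biomarkers[name] > hi))
            if frac > 0.05:
                warnings.warn(
                    f"{frac:.0%} of {columns[name]!r} outside plausible range "
                    f"[{lo}, {hi}] -- check units",
                    stacklevel=2,
                )
    age = table[columns["age"]].to_numpy(dtype=float)
    xb, mortality, pheno = phenoage(biomarkers, age, coeffs)
    return pd.DataFrame(
        {"xb": xb, "mortality_score": mortality, "phenotypic_age": pheno},
        index=table.index,
    )


# ---------------------------------------------------------------------------
# Klemera-Doubal biological age
# ---------------------------------------------------------------------------


@dataclass
class KDMTraining:
    """Fitted Klemera-Doubal clock parameters.

    ``k``, ``q``, ``s`` are the slope, intercept and residual RMSE of each
    biomarker's regression on chronological age; ``r2`` the variance
    explained.  ``r_char`` is the characteristic biomarker-age correlation
    (weighted average of signed ``r_j`` with weights ``k_j/s_j``) and
    ``s_ba2`` the variance-correction term (years^2) entering the final
    estimator.
    """

    biomarkers: list[str]
    k: np.ndarray
    q: np.ndarray
    s: np.ndarray
    r2: np.ndarray
    r_char: float
    s_ba2: float
    ca_min: float
    ca_max: float
    n_train: int = 0

    @property
    def m(self) -> int:
        return len(self.biomarkers)

    def validate(self) -> None:
        if self.m < 1:
            raise ValueError("KDM training needs at least one biomarker")
        if np.any(self.s <= 0):
            raise ValueError("residual RMSE values must be positive")
        if np.any((self.r2 < 0) | (self.r2 > 1)):
            raise ValueError("r2 values must lie in [0, 1]")
        if not self.ca_max > self.ca_min:
            raise ValueError("CA_max must exceed CA_min")
        if not self.s_ba2 > 0:
            raise ValueError("s_BA^2 must be positive")

    def to_text(self) -> str:
        lines = [
            "# KDM biological-age training parameters",
            f"biomarkers = {','.join(self.biomarkers)}",
            f"r_char = {self.r_char!r}",
            f"s_ba2 = {self.s_ba2!r}",
            f"ca_min = {self.ca_min!r}",
            f"ca_max = {self.ca_max!r}",
            f"n_train = {self.n_train}",
        ]
        for i, name in enumerate(self.biomarkers):
            lines.append(f"k.{name} = {float(self.k[i])!r}")
            lines.append(f"q.{name} = {float(self.q[i])!r}")
            lines.append(f"s.{name} = {float(self.s[i])!r}")
            lines.append(f"r2.{name} = {float(self.r2[i])!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "KDMTraining":
        kv = _parse_kv_text(text)
        names = kv["biomarkers"].split(",")
        get = lambda pre: np.array([float(kv[f"{pre}.{n}"]) for n in names])
        return cls(
            biomarkers=names,
            k=get("k"),
            q=get("q"),
            s=get("s"),
            r2=get("r2"),
            r_char=float(kv["r_char"]),
            s_ba2=float(kv["s_ba2"]),
            ca_min=float(kv["ca_min"]),
            ca_max=float(kv["ca_max"]),
            n_train=int(kv["n_train"]),
        )


def _as_matrix(biomarkers, names: list[str] | None):
    if isinstance(biomarkers, pd.DataFrame):
        names = list(biomarkers.columns) if names is None else names
        X = biomarkers[names].to_numpy(dtype=float)
    else:
        X = np.asarray(biomarkers, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if names is None:
            names = [f"biomarker_{j}" for j in range(X.shape[1])]
    return X, names


def fit_kdm(
    biomarkers,
    age,
    names: list[str] | None = None,
    min_s_ba2: float = 1e-8,
) -> KDMTraining:
    """Train the Klemera-Doubal clock by regressing biomarkers on age.

    Each biomarker is regressed on chronological age by OLS, giving slope
    ``k_j``, intercept ``q_j``, residual RMSE ``s_j`` (denominator n-2) and
    ``r_j^2``.  ``r_char`` averages the signed correlations ``r_j`` with
    weights ``k_j/s_j``, and ``s_BA^2`` is the variance of the precision-
    weighted estimate's residual against age minus the sampling-noise term
    ``(1-r_char^2)/r_char^2 * (CA_max-CA_min)^2 / (12 m)``.  A non-positive
    ``s_BA^2`` (possible in near-noiseless data where the correction term
    dominates) is floored at ``min_s_ba2`` with a warning.
    """
    X, names = _as_matrix(biomarkers, names)
    age = np.asarray(age, dtype=float)
    n, m = X.shape
    if n < m + 2:
        raise ValueError(f"need at least m+2={m + 2} rows, got {n}")
    if np.any(~np.isfinite(X)) or np.any(~np.isfinite(age)):
        raise ValueError("missing or non-finite entries in training data")
    if np.var(age) == 0:
        raise ValueError("chronological age is constant; KDM fit undefined")

    age_c = age - age.mean()
    sxx = float(age_c @ age_c)
    k = (X.T @ age_c) / sxx
    q = X.mean(axis=0) - k * age.mean()
    resid = X - (q[None, :] + np.outer(age, k))
    sse = np.einsum("ij,ij->j", resid, resid)
    sst = np.einsum("ij,ij->j", X - X.mean(axis=0), X - X.mean(axis=0))
    s = np.sqrt(sse / (n - 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(sst > 0, 1.0 - sse / sst, 0.0)
    r2 = np.clip(r2, 0.0, 1.0)

    zero = np.flatnonzero(np.abs(k) < 1e-12)
    if zero.size:
        bad = [names[j] for j in zero]
        raise ValueError(
            f"biomarker(s) {bad} have (near-)zero age slope; the KDM "
            "estimator divides by k_j -- drop them from the panel"
        )
    if np.any(s <= 0):
        bad = [names[j] for j in np.flatnonzero(s <= 0)]
        raise ValueError(f"biomarker(s) {bad} have zero residual RMSE")

    w = k / s  # weights for the characteristic correlation
    r = np.sign(k) * np.sqrt(r2)
    r_char = float((w * r).sum() / w.sum())

    ca_min, ca_max = float(age.min()), float(age.max())
    partial = KDMTraining(
        biomarkers=names, k=k, q=q, s=s, r2=r2,
        r_char=r_char, s_ba2=1.0, ca_min=ca_min, ca_max=ca_max, n_train=n,
    )
    ba_e = kdm_ba_e(X, partial)
    diff = ba_e - age
    var_diff = float(np.mean((diff - diff.mean()) ** 2))
    if r_char <= 0:
        raise ValueError("characteristic correlation r_char is non-positive")
    correction = (1.0 - r_char**2) / r_char**2 * (ca_max - ca_min) ** 2 / (12.0 * m)
    s_ba2 = var_diff - correction
    if s_ba2 <= 0:
        warnings.warn(
            f"s_BA^2 = {s_ba2:.3g} non-positive (noise correction exceeds "
            f"residual variance); floored at {min_s_ba2}",
            stacklevel=2,
        )
        s_ba2 = min_s_ba2
    partial.s_ba2 = float(s_ba2)
    partial.validate()
    return partial


def kdm_ba_e(biomarkers, training: KDMTraining) -> np.ndarray:
    """Precision-weighted age estimate BA_E (no chronological-age shrinkage)."""
    X, _ = _as_matrix(biomarkers, training.biomarkers)
    if np.any(~np.isfinite(X)):
        raise ValueError("missing biomarker values; no silent imputation")
    w = training.k / training.s**2
    num = (X - training.q[None, :]) @ w
    den = float((training.k**2 / training.s**2).sum())
    return num / den


def kdm_biological_age(biomarkers, age, training: KDMTraining) -> np.ndarray:
    """Klemera-Doubal biological age in years.

    ``BA = [sum_j (x_j - q_j) k_j / s_j^2 + CA / s_BA^2] /
    [sum_j k_j^2 / s_j^2 + 1 / s_BA^2]`` -- BA_E shrunk toward chronological
    age with weight 1/s_BA^2.
    """
    training.validate()
    X, _ = _as_matrix(biomarkers, training.biomarkers)
    if np.any(~np.isfinite(X)):
        raise ValueError("missing biomarker values; no silent imputation")
    age = np.asarray(age, dtype=float)
    w = training.k / training.s**2
    num = (X - training.q[None, :]) @ w + age / training.s_ba2
    den = float((training.k**2 / training.s**2).sum()) + 1.0 / training.s_ba2
    return num / den
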