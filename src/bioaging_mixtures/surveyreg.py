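"""Design-based weighted regression for stratified, clustered survey samples.

Point estimates are weighted least squares; variances are the
Taylor-linearization (linearized sandwich) estimator: weighted score
vectors are totaled within primary sampling units (PSUs), centered within
stratum, and combined as ``sum_h n_h/(n_h-1) sum_i (z_hi - zbar_h)(.)'``,
pre/post-multiplied by ``(X'WX)^-1``.  Design degrees of freedom are
``#PSU - #strata``; single-coefficient inference is t-based and joint Wald
tests use an F reference with ``df - q + 1`` denominator degrees of freedom.

The module also provides the three covariate adjustment sets used
throughout the analysis (model1/2/3), quartile trend tests (quartile index
refit as a continuous score), restricted cubic splines with nonlinearity
tests, subgroup/interaction analysis, and weighted descriptive statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurveyDesign",
    "RegressionResult",
    "WaldTest",
    "COVARIATE_SETS",
    "design_matrix",
    "fit_weighted_lm",
    "wald_test",
    "quartile_trend_test",
    "rcs_basis",
    "rcs_fit",
    "RCSFit",
    "run_model",
    "ModelFit",
    "subgroup_interaction",
    "SubgroupResult",
    "weighted_descriptives",
]

# Covariate sets for the three adjustment models.  model1: demographics;
# model2: + socioeconomic and lifestyle; model3: + comorbidity, diet and
# survey cycle.
COVARIATE_SETS = {
    "model1": ["age", "sex", "race"],
    "model2": ["age", "sex", "race", "pir", "bmi_cat", "marital", "home",
               "education", "activity", "smoke", "drinks"],
    "model3": ["age", "sex", "race", "pir", "bmi_cat", "marital", "home",
               "education", "activity", "smoke", "drinks", "hypertension",
               "dm", "cvd", "cancer", "energy_kcal", "diet_score", "cycle"],
}


@dataclass
class SurveyDesign:
    """Stratum labels, PSU labels and examination weights, one per row."""

    strata: np.ndarray
    psu: np.ndarray
    weights: np.ndarray
    lonely_psu: str = "adjacent-collapse"  # or "certainty" or "fail"

    def __post_init__(self):
        self.strata = np.asarray(self.strata)
        self.psu = np.asarray(self.psu)
        self.weights = np.asarray(self.weights, dtype=float)
        if not (len(self.strata) == len(self.psu) == len(self.weights)):
            raise ValueError("design columns must have equal length")
        if np.any(~(self.weights > 0)):
            raise ValueError("examination weights must be positive")
        if self.lonely_psu not in ("adjacent-collapse", "certainty", "fail"):
            raise ValueError(f"unknown lonely-PSU rule {self.lonely_psu!r}")

    @classmethod
    def from_table(cls, table: pd.DataFrame, strata="stratum", psu="psu",
                   weights="weight", **kw) -> "SurveyDesign":
        return cls(table[strata].to_numpy(), table[psu].to_numpy(),
                   table[weights].to_numpy(), **kw)

    def subset(self, mask) -> "SurveyDesign":
        mask = np.asarray(mask)
        return SurveyDesign(self.strata[mask], self.psu[mask],
                            self.weights[mask], self.lonely_psu)

    def _collapsed_strata(self) -> np.ndarray:
        """Apply the lonely-PSU rule, returning effective stratum labels."""
        strata = self.strata
        labels = pd.unique(strata)
        lonely = [
            s for s in labels
            if len(pd.unique(self.psu[strata == s])) < 2
        ]
        if not lonely:
            return strata
        if self.lonely_psu == "fail":
            raise ValueError(
                f"strata {lonely} contain a single PSU; Taylor variance is "
                "undefined -- set lonely_psu to 'adjacent-collapse' or "
                "'certainty'"
            )
        if self.lonely_psu == "certainty":
            return strata
        # adjacent-collapse: merge each lonely stratum with its neighbor in
        # sorted label order (previous neighbor for the first label)
        order = sorted(labels.tolist())
        mapping = {s: s for s in order}
        for s in lonely:
            i = order.index(s)
            target = order[i + 1] if i + 1 < len(order) else order[i - 1]
            mapping[s] = mapping.get(target, target)
        collapsed = np.array([mapping[s] for s in strata])
        # iterate in case collapsing still leaves a lonely merged stratum
        d = SurveyDesign(collapsed, self.psu, self.weights, self.lonely_psu)
        still = [
            s for s in pd.unique(collapsed)
            if len(pd.unique(self.psu[collapsed == s])) < 2
        ]
        if still and len(pd.unique(collapsed)) > 1:
            return d._collapsed_strata()
        return collapsed

    def degrees_of_freedom(self) -> int:
        strata = self._collapsed_strata()
        keys = pd.MultiIndex.from_arrays([strata, self.psu])
        n_psu = len(keys.drop_duplicates())
        n_strata = len(pd.unique(strata))
        return n_psu - n_strata


def _taylor_cov(z: np.ndarray, design: SurveyDesign) -> np.ndarray:
    """Design-based covariance of the column totals of ``z`` (n x p)."""
    strata = design._collapsed_strata()
    df_keys = pd.DataFrame({"_s": strata, "_p": design.psu})
    groups = df_keys.groupby(["_s", "_p"], sort=True).indices
    # PSU totals per stratum
    psu_totals: dict = {}
    for (s, p), idx in groups.items():
        psu_totals.setdefault(s, []).append(z[idx].sum(axis=0))
    V = np.zeros((z.shape[1], z.shape[1]))
    for s, totals in psu_totals.items():
        n_h = len(totals)
        if n_h < 2:
            continue  # certainty stratum: no between-PSU contribution
        T = np.asarray(totals)
        D = T - T.mean(axis=0)
        V += n_h / (n_h - 1) * (D.T @ D)
    return V


@dataclass
class WaldTest:
    statistic: float
    df_num: int
    df_den: int
    pvalue: float


@dataclass
class RegressionResult:
    """Weighted-LS fit with design-based (Taylor) covariance."""

    terms: list
    beta: np.ndarray
    cov: np.ndarray
    df: int
    n: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def conf_int(self, level: float = 0.95):
        tcrit = stats.t.ppf(0.5 + level / 2, self.df)
        return (self.beta - tcrit * self.se, self.beta + tcrit * self.se)

    def pvalues(self) -> np.ndarray:
        t = self.beta / self.se
        return 2 * stats.t.sf(np.abs(t), self.df)

    def table(self) -> pd.DataFrame:
        lo, hi = self.conf_int()
        return pd.DataFrame(
            {"beta": self.beta, "se": self.se, "ci_low": lo, "ci_high": hi,
             "p": self.pvalues()},
            index=pd.Index(self.terms, name="term"),
        )

    def __getitem__(self, term: str) -> pd.Series:
        return self.table().loc[term]


def design_matrix(df: pd.DataFrame, columns, add_const: bool = True) -> pd.DataFrame:
    """Numeric columns pass through; categoricals become drop-first dummies."""
    parts = []
    if add_const:
        parts.append(pd.Series(1.0, index=df.index, name="const"))
    for col in columns:
        s = df[col]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.astype(float))
        else:
            dummies = pd.get_dummies(s.astype(str), prefix=col, drop_first=True)
            parts.append(dummies.astype(float))
    return pd.concat(parts, axis=1)


def fit_weighted_lm(y, X, design: SurveyDesign) -> RegressionResult:
    """Design-based weighted linear regression.

    ``beta = (X'WX)^-1 X'Wy`` with Taylor-linearized covariance and
    ``df = #PSU - #strata``.
    """
    if isinstance(X, pd.DataFrame):
        terms = list(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        terms = [f"x{j}" for j in range(Xm.shape[1])]
    y = np.asarray(y, dtype=float)
    w = design.weights
    n, p = Xm.shape
    if n != len(y) or n != len(w):
        raise ValueError("y, X and design must align row-wise")
    A = Xm.T @ (w[:, None] * Xm)
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        _, R = np.linalg.qr(np.sqrt(w)[:, None] * Xm)
        diag = np.abs(np.diag(R))
        bad = [terms[j] for j in np.flatnonzero(diag < 1e-8 * diag.max())]
        raise ValueError(f"singular weighted design matrix; dependent columns: {bad}")
    Ainv = np.linalg.inv(A)
    beta = Ainv @ (Xm.T @ (w * y))
    resid = y - Xm @ beta
    z = Xm * (w * resid)[:, None]
    V = _taylor_cov(z, design)
    cov = Ainv @ V @ Ainv
    df = design.degrees_of_freedom()
    if df < 1:
        raise ValueError("design degrees of freedom < 1; add strata/PSUs")
    if df <= p:
        warnings.warn(
            f"design df ({df}) <= number of parameters ({p}); "
            "inference may be unreliable",
            stacklevel=2,
        )
    return RegressionResult(terms=terms, beta=beta, cov=cov, df=df, n=n)


def wald_test(result: RegressionResult, terms) -> WaldTest:
    """Design-based joint Wald test that the named coefficients are zero.

    The quadratic form uses the Hotelling T-squared reference for a
    covariance estimated with ``df`` design degrees of freedom:
    ``T2 * (df - q + 1) / (df * q) ~ F(q, df - q + 1)``.  For q = 1 this
    reduces to the squared t statistic against F(1, df).
    """
    idx = [result.terms.index(t) for t in terms]
    b = result.beta[idx]
    Vrr = result.cov[np.ix_(idx, idx)]
    q = len(idx)
    t2 = float(b @ np.linalg.solve(Vrr, b))
    df_den = max(result.df - q + 1, 1)
    stat = t2 * df_den / (max(result.df, 1) * q)
    p = float(stats.f.sf(stat, q, df_den))
    return WaldTest(statistic=stat, df_num=q, df_den=df_den, pvalue=p)


# ---------------------------------------------------------------------------
# model runner: continuous / quartile exposure forms
# ---------------------------------------------------------------------------


@dataclass
class ModelFit:
    """Tidy summary of one outcome ~ exposure (+ covariates) survey fit."""

    outcome: str
    exposure: str
    form: str
    covariate_set: str
    result: RegressionResult
    exposure_terms: list
    p_trend: float | None = None
    n: int = 0

    def tidy(self) -> pd.DataFrame:
        tab = self.result.table().loc[self.exposure_terms].reset_index()
        tab.insert(0, "outcome", self.outcome)
        tab.insert(1, "exposure", self.exposure)
        tab.insert(2, "form", self.form)
        tab.insert(3, "covariate_set", self.covariate_set)
        tab["p_trend"] = self.p_trend
        tab["n"] = self.n
        return tab


def _complete_mask(df: pd.DataFrame, columns) -> np.ndarray:
    sub = df[list(columns)]
    numeric = sub.select_dtypes(include=[np.number])
    mask = ~sub.isna().any(axis=1)
    if not numeric.empty:
        mask &= np.isfinite(numeric).all(axis=1)
    return mask.to_numpy()


def run_model(
    df: pd.DataFrame,
    outcome: str,
    exposure: str,
    form: str,
    covariate_set: str,
    design: SurveyDesign | None = None,
    trend_coding: str = "index",
) -> ModelFit:
    """Fit one adjustment model with a continuous or quartile exposure.

    ``exposure`` names the ln-transformed column for ``form='continuous'``
    or the quartile-label column (values 1-4) for ``form='quartiles'``.
    Complete-case per model; the analyzed n is recorded on the fit.
    """
    covars = COVARIATE_SETS[covariate_set]
    needed = [outcome, exposure] + covars
    mask = _complete_mask(df, needed)
    data = df.loc[mask]
    if design is None:
        design = SurveyDesign.from_table(df)
    design = design.subset(mask)

    Xc = design_matrix(data, covars)
    y = data[outcome].to_numpy(dtype=float)
    if form == "continuous":
        X = pd.concat([Xc, data[exposure].astype(float)], axis=1)
        res = fit_weighted_lm(y, X, design)
        return ModelFit(outcome, exposure, form, covariate_set, res,
                        [exposure], n=int(mask.sum()))
    if form == "quartiles":
        q = data[exposure].astype(int)
        dummies = pd.get_dummies(q, prefix=exposure, drop_first=True).astype(float)
        X = pd.concat([Xc, dummies], axis=1)
        res = fit_weighted_lm(y, X, design)
        p_trend = quartile_trend_test(y, q.to_numpy(), Xc, design,
                                      coding=trend_coding,
                                      raw=data[exposure.rsplit("_", 1)[0] + "_cc"]
                                      if trend_coding == "median" else None,
                                      )
        return ModelFit(outcome, exposure, form, covariate_set, res,
                        list(dummies.columns), p_trend=p_trend,
                        n=int(mask.sum()))
    raise ValueError(f"unknown exposure form {form!r}")


def quartile_trend_test(y, quartiles, covariate_design: pd.DataFrame,
                        design: SurveyDesign, coding: str = "index",
                        raw=None) -> float:
    """P-for-trend: refit with the quartile score as a continuous term.

    Default coding is the quartile index 1..4; ``coding='median'`` uses the
    weighted within-quartile median of the raw exposure instead.
    """
    quartiles = np.asarray(quartiles)
    occupied = np.unique(quartiles)
    if len(occupied) < 2:
        raise ValueError("fewer than 2 occupied quartiles; trend undefined")
    if coding == "index":
        score = quartiles.astype(float)
    elif coding == "median":
        if raw is None:
            raise ValueError("median coding requires the raw exposure values")
        raw = np.asarray(raw, dtype=float)
        score = np.empty(len(quartiles))
        from .exposure import weighted_quantile
        for qv in occupied:
            m = quartiles == qv
            score[m] = weighted_quantile(raw[m], 0.5, design.weights[m])
    else:
        raise ValueError(f"unknown trend coding {coding!r}")
    X = covariate_design.copy()
    X["_trend"] = score
    res = fit_weighted_lm(np.asarray(y, dtype=float), X, design)
    return float(res["_trend"]["p"])


# ---------------------------------------------------------------------------
# restricted cubic splines
# ---------------------------------------------------------------------------

_DEFAULT_KNOT_PCTS = {3: (10, 50, 90), 4: (5, 35, 65, 95),
                      5: (5, 27.5, 50, 72.5, 95)}


def rcs_basis(x, knots) -> np.ndarray:
    """Harrell truncated-power restricted cubic spline basis.

    Returns ``len(knots) - 1`` columns: the linear term and the
    ``len(knots) - 2`` nonlinear terms, each exactly linear beyond the
    boundary knots.  Normalization divides by ``(t_last - t_first)^2``.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    k = len(t)
    if k < 3:
        raise ValueError("restricted cubic splines need at least 3 knots")
    if len(np.unique(t)) < k:
        raise ValueError(
            "coincident knots (heavy ties in the exposure); use fewer knots"
        )
    norm = (t[-1] - t[0]) ** 2
    cols = [x]
    pos3 = lambda u: np.maximum(u, 0.0) ** 3
    for j in range(k - 2):
        term = (
            pos3(x - t[j])
            - pos3(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + pos3(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        ) / norm
        cols.append(term)
    return np.column_stack(cols)


@dataclass
class RCSFit:
    knots: np.ndarray
    curve: pd.DataFrame  # grid, estimate, ci_low, ci_high (vs reference)
    p_overall: float
    p_nonlinear: float
    result: RegressionResult = field(repr=False, default=None)


def rcs_fit(
    y,
    x,
    covariates: pd.DataFrame | None,
    design: SurveyDesign,
    n_knots: int = 4,
    grid: np.ndarray | None = None,
    reference: float | None = None,
) -> RCSFit:
    """Dose-response via restricted cubic spline in a design-based fit.

    ``p_nonlinear`` is the joint Wald test that all nonlinear basis
    coefficients are zero; ``p_overall`` tests all spline coefficients.  The
    returned curve is the contrast against the reference value (default:
    median of ``x``) with t-based confidence bands.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pcts = _DEFAULT_KNOT_PCTS.get(n_knots)
    if pcts is None:
        raise ValueError("n_knots must be 3, 4 or 5")
    knots = np.percentile(x, pcts)
    basis = rcs_basis(x, knots)
    names = ["rcs_lin"] + [f"rcs_nl{j}" for j in range(1, n_knots - 1)]
    parts = [pd.DataFrame(basis, columns=names)]
    if covariates is not None:
        parts.append(covariates.reset_index(drop=True))
    X = pd.concat(parts, axis=1)
    X.insert(0, "const", 1.0)
    res = fit_weighted_lm(y, X, design)
    p_overall = wald_test(res, names).pvalue
    p_nonlinear = wald_test(res, names[1:]).pvalue

    if grid is None:
        grid = np.linspace(np.percentile(x, 1), np.percentile(x, 99), 100)
    if reference is None:
        reference = float(np.median(x))
    bg = rcs_basis(grid, knots)
    bref = rcs_basis(np.array([reference]), knots)
    contrast = bg - bref
    idx = [res.terms.index(nm) for nm in names]
    b = res.beta[idx]
    V = res.cov[np.ix_(idx, idx)]
    est = contrast @ b
    se = np.sqrt(np.einsum("ij,jk,ik->i", contrast, V, contrast))
    tcrit = stats.t.ppf(0.975, res.df)
    curve = pd.DataFrame(
        {"x": grid, "estimate": est, "ci_low": est - tcrit * se,
         "ci_high": est + tcrit * se}
    )
    return RCSFit(knots=knots, curve=curve, p_overall=p_overall,
                  p_nonlinear=p_nonlinear, result=res)


# ---------------------------------------------------------------------------
# subgroup / interaction analysis
# ---------------------------------------------------------------------------


@dataclass
class SubgroupResult:
    modifier: str
    table: pd.DataFrame       # per-level beta, se, ci, p, n
    p_interaction: float


def subgroup_interaction(
    df: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariate_set: str,
    modifier: str,
    design: SurveyDesign | None = None,
) -> SubgroupResult:
    """Stratified exposure effects plus a product-term interaction test.

    The modifier is removed from the covariate set when present.  The
    P-for-interaction is the design-based joint Wald test of all
    exposure x modifier product terms in the pooled model.
    """
    covars = [c for c in COVARIATE_SETS[covariate_set] if c != modifier]
    needed = [outcome, exposure, modifier] + covars
    mask = _complete_mask(df, needed)
    data = df.loc[mask]
    if design is None:
        design = SurveyDesign.from_table(df)
    design_full = design.subset(mask)

    levels = [l for l in pd.unique(data[modifier]) if not pd.isna(l)]
    levels = sorted(levels, key=str)
    if len(levels) < 2:
        raise ValueError(f"modifier {modifier!r} has fewer than 2 levels")

    rows = []
    for level in levels:
        m = (data[modifier] == level).to_numpy()
        if m.sum() < len(covars) + 5:
            warnings.warn(f"subgroup {modifier}={level} too small; skipped",
                          stacklevel=2)
            continue
        sub = data.loc[m]
        X = pd.concat([design_matrix(sub, covars), sub[exposure].astype(float)],
                      axis=1)
        res = fit_weighted_lm(sub[outcome].to_numpy(dtype=float), X,
                              design_full.subset(m))
        row = res[exposure]
        rows.append({"level": level, "beta": row["beta"], "se": row["se"],
                     "ci_low": row["ci_low"], "ci_high": row["ci_high"],
                     "p": row["p"], "n": int(m.sum())})

    # pooled fit with product terms
    Xc = design_matrix(data, covars + [modifier])
    mod_dummies = pd.get_dummies(data[modifier].astype(str), prefix=modifier,
                                 drop_first=True).astype(float)
    inter = mod_dummies.mul(data[exposure].astype(float), axis=0)
    inter.columns = [f"{exposure}:{c}" for c in mod_dummies.columns]
    X = pd.concat([Xc, data[exposure].astype(float), inter], axis=1)
    res = fit_weighted_lm(data[outcome].to_numpy(dtype=float), X, design_full)
    p_int = wald_test(res, list(inter.columns)).pvalue
    return SubgroupResult(modifier=modifier, table=pd.DataFrame(rows),
                          p_interaction=p_int)


# ---------------------------------------------------------------------------
# weighted descriptive statistics
# ---------------------------------------------------------------------------


def _mean_with_se(y, mask, design: SurveyDesign):
    """Weighted domain mean and Taylor SE (influence-function based)."""
    w = design.weights
    wm = w * mask
    W = wm.sum()
    mean = float((wm * y).sum() / W)
    u = (wm * (y - mean) / W)[:, None]
    var = _taylor_cov(u, design)[0, 0]
    return mean, float(np.sqrt(var))


def weighted_descriptives(
    df: pd.DataFrame,
    continuous: list,
    categorical: list,
    design: SurveyDesign | None = None,
    by: str = "sex",
) -> pd.DataFrame:
    """Weighted means (SE) and percentages (SE), overall and by group.

    Group differences are assessed by design-based Wald tests: a t-test on
    the two-group mean difference for continuous variables, a joint F test
    on the vector of category-proportion differences for categoricals.
    """
    if design is None:
        design = SurveyDesign.from_table(df)
    groups = sorted([g for g in pd.unique(df[by]) if not pd.isna(g)], key=str)
    rows = []

    def _domain_diff_test(cols_influence, d_vec):
        V = _taylor_cov(np.column_stack(cols_influence), design)
        q = len(d_vec)
        t2 = float(np.asarray(d_vec) @ np.linalg.solve(V, np.asarray(d_vec)))
        df = max(design.degrees_of_freedom(), 1)
        df_den = max(df - q + 1, 1)
        stat = t2 * df_den / (df * q)
        return float(stats.f.sf(stat, q, df_den))

    w = design.weights
    for col in continuous:
        y = df[col].to_numpy(dtype=float)
        ok = np.isfinite(y)
        if not ok.any():
            warnings.warn(f"column {col!r} all-missing; skipped", stacklevel=2)
            continue
        entry = {"variable": col, "level": ""}
        mean, se = _mean_with_se(np.where(ok, y, 0.0), ok.astype(float), design)
        entry["overall"], entry["overall_se"] = mean, se
        infl, diffs = [], []
        for g in groups:
            m = ((df[by] == g).to_numpy() & ok).astype(float)
            gm, gse = _mean_with_se(np.where(ok, y, 0.0), m, design)
            entry[f"{g}"], entry[f"{g}_se"] = gm, gse
            W = (w * m).sum()
            infl.append(w * m * (np.where(ok, y, 0.0) - gm) / W)
            diffs.append(gm)
        if len(groups) == 2:
            entry["p"] = _domain_diff_test([infl[0] - infl[1]],
                                           [diffs[0] - diffs[1]])
        rows.append(entry)

    for col in categorical:
        vals = df[col]
        levels = sorted([l for l in pd.unique(vals) if not pd.isna(l)], key=str)
        lev_infl, lev_diff = [], []
        for li, level in enumerate(levels):
            ind = (vals == level).to_numpy().astype(float)
            entry = {"variable": col, "level": str(level)}
            p_all, se_all = _mean_with_se(ind, np.ones(len(ind)), design)
            entry["overall"], entry["overall_se"] = 100 * p_all, 100 * se_all
            ginfl, gprop = [], []
            for g in groups:
                m = (df[by] == g).to_numpy().astype(float)
                gp, gse = _mean_with_se(ind, m, design)
                entry[f"{g}"], entry[f"{g}_se"] = 100 * gp, 100 * gse
                W = (w * m).sum()
                ginfl.append(w * m * (ind - gp) / W)
                gprop.append(gp)
            if len(groups) == 2 and li < len(levels) - 1:
                lev_infl.append(ginfl[0] - ginfl[1])
                lev_diff.append(gprop[0] - gprop[1])
            rows.append(entry)
        if len(groups) == 2 and lev_infl:
            p = _domain_diff_test(lev_infl, lev_diff)
            for r in rows[-len(levels):]:
                r["p"] = p
    return pd.DataFrame(rows)
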