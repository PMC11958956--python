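"""Weighted Quantile Sum (WQS) regression for chemical mixtures.

The outcome is regressed on a single mixture index ``sum_m w_m q_m`` where
``q_m`` are within-sample quantile scores of each exposure and the weights
``w`` lie on the probability simplex.  The index coefficient is
sign-constrained (``direction``) during weight estimation.  Weights are
estimated by bootstrap on a random training split: each resample maximizes
the Gaussian likelihood via the unconstrained reparameterization
``w = softmax(theta)``, ``beta1 = sign * exp(phi)`` (covariate coefficients
are profiled out exactly by residualization), and the final weight vector
averages the bootstrap draws whose index t-statistic satisfies |t| >= 1
(plain mean available).  Inference is on the held-out test split, where the
index coefficient is left unconstrained: a negative fitted coefficient for
a positively-constrained index is therefore possible and reported as-is.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .surveyreg import SurveyDesign, design_matrix, fit_weighted_lm

__all__ = ["WQSConfig", "WQSResult", "quantile_score", "fit_wqs",
           "run_both_directions"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WQSConfig:
    n_quantiles: int = 4
    train_fraction: float = 0.40
    n_bootstrap: int = 200       # published analyses typically use 10,000
    direction: str = "negative"  # or "positive"
    seed: int = 0
    covariate_set: str = "model3"
    signal_filter: bool = True   # average only bootstraps with |t| >= 1
    use_survey_design: bool = False
    resample: bool = True        # False: every "bootstrap" uses the full train set

    def validate(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_quantiles < 2:
            raise ValueError("n_quantiles must be >= 2")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if self.direction not in ("positive", "negative"):
            raise ValueError("direction must be 'positive' or 'negative'")


@dataclass
class WQSResult:
    direction: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    weights: pd.Series
    bootstrap_weights: np.ndarray = field(repr=False)
    n_train: int = 0
    n_test: int = 0
    n_dropped: int = 0
    cut_points: dict = field(default_factory=dict, repr=False)


def quantile_score(exposures, n_quantiles: int = 4, cuts: dict | None = None):
    """Integer quantile scores in {0, ..., n_quantiles - 1} per exposure.

    Cut points come from the (training) sample passed in unless ``cuts`` is
    provided, in which case they are reused (test rows below the lowest cut
    score 0, above the highest score n_quantiles - 1).
    Returns ``(scores DataFrame, cuts dict)``.
    """
    X = pd.DataFrame(exposures)
    out = {}
    cut_out = {}
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        if cuts is None:
            if len(np.unique(v)) < n_quantiles:
                raise ValueError(
                    f"exposure {col!r} has fewer than {n_quantiles} distinct "
                    "values; quantile scoring undefined"
                )
            c = np.quantile(v, np.arange(1, n_quantiles) / n_quantiles)
        else:
            c = np.asarray(cuts[col], dtype=float)
        out[col] = np.searchsorted(c, v, side="left").astype(int)
        cut_out[col] = c
    return pd.DataFrame(out, index=X.index), cut_out


def _softmax(theta: np.ndarray) -> np.ndarray:
    e = np.exp(theta - theta.max())
    return e / e.sum()


def _fit_one_resample(y, Q, Xc, sign: float):
    """Constrained Gaussian-ML fit on one (resampled) training set.

    Covariates are profiled out by residualizing y and the quantile scores
    on [1, Xc] (Frisch-Waugh), leaving a (phi, theta) optimization of
    ||y~ - sign*exp(phi) * (Q~ w)||^2 with w = softmax(theta).
    Returns (weights, beta1, t_stat, converged).
    """
    n, M = Q.shape
    H = np.column_stack([np.ones(n), Xc])
    coef, *_ = np.linalg.lstsq(H, np.column_stack([y, Q]), rcond=None)
    resid = np.column_stack([y, Q]) - H @ coef
    yt, Qt = resid[:, 0], resid[:, 1:]

    # crude initialization: magnitude of the equal-weight index coefficient
    u0 = Qt @ np.full(M, 1.0 / M)
    denom = float(u0 @ u0)
    b0 = float(u0 @ yt) / denom if denom > 0 else 0.0
    phi0 = np.log(max(abs(b0), 1e-3))
    x0 = np.concatenate([[phi0], np.zeros(M)])

    def objective(params):
        phi, theta = params[0], params[1:]
        w = _softmax(theta)
        b = sign * np.exp(phi)
        u = Qt @ w
        r = yt - b * u
        f = float(r @ r)
        dphi = -2.0 * b * float(u @ r)
        dw = -2.0 * b * (Qt.T @ r)
        dtheta = w * (dw - float(w @ dw))
        return f, np.concatenate([[dphi], dtheta])

    res = optimize.minimize(objective, x0, jac=True, method="L-BFGS-B",
                            options={"maxiter": 500})
    phi, theta = res.x[0], res.x[1:]
    w = _softmax(theta)
    b = sign * np.exp(phi)
    u = Qt @ w
    dof = n - H.shape[1] - 1
    sse = float(np.sum((yt - b * u) ** 2))
    uu = float(u @ u)
    if uu > 0 and dof > 0:
        t = b / np.sqrt(sse / dof / uu)
    else:
        t = 0.0
    return w, b, t, bool(res.success)


def fit_wqs(
    table: pd.DataFrame,
    outcome: str,
    exposures: list,
    config: WQSConfig,
    design: SurveyDesign | None = None,
) -> WQSResult:
    """Full WQS fit: split, bootstrap weight estimation, test-split inference.

    ``exposures`` name continuous exposure columns (typically ln-transformed
    concentrations; quantile scoring makes the fit invariant to monotone
    transforms).  ``design`` supplies survey weights for the test-split
    regression when ``config.use_survey_design`` is set; weight estimation
    itself is unweighted.
    """
    config.validate()
    from .surveyreg import COVARIATE_SETS, _complete_mask

    covars = COVARIATE_SETS[config.covariate_set]
    needed = [outcome] + list(exposures) + covars
    mask = _complete_mask(table, needed)
    data = table.loc[mask].reset_index(drop=True)
    if design is not None:
        design = design.subset(mask)

    rng = np.random.default_rng(config.seed)
    n = len(data)
    perm = rng.permutation(n)
    n_train = int(round(config.train_fraction * n))
    train_idx, test_idx = perm[:n_train], perm[n_train:]

    # training cut points, reused on the test split
    scores_train, cuts = quantile_score(
        data.loc[train_idx, exposures], config.n_quantiles
    )
    scores_test, _ = quantile_score(
        data.loc[test_idx, exposures], config.n_quantiles, cuts=cuts
    )

    Xc_all = design_matrix(data, covars, add_const=False)
    y = data[outcome].to_numpy(dtype=float)
    sign = 1.0 if config.direction == "positive" else -1.0
    M = len(exposures)

    if M == 1:
        boot_w = np.ones((config.n_bootstrap, 1))
        final_w = np.ones(1)
        n_dropped = 0
    else:
        Qtr = scores_train.to_numpy(dtype=float)
        Xtr = Xc_all.to_numpy(dtype=float)[train_idx]
        ytr = y[train_idx]
        draws, tstats = [], []
        n_dropped = 0
        for _ in range(config.n_bootstrap):
            if config.resample:
                bidx = rng.integers(0, n_train, size=n_train)
            else:
                bidx = np.arange(n_train)
            w, b, t, ok = _fit_one_resample(ytr[bidx], Qtr[bidx], Xtr[bidx], sign)
            if not ok:
                n_dropped += 1
                continue
            draws.append(w)
            tstats.append(t)
        if n_dropped > 0.2 * config.n_bootstrap:
            raise RuntimeError(
                f"{n_dropped}/{config.n_bootstrap} bootstrap resamples failed "
                "to converge"
            )
        if n_dropped:
            logger.info("dropped %d non-converged bootstrap resamples", n_dropped)
        boot_w = np.asarray(draws)
        tstats = np.asarray(tstats)
        if config.signal_filter:
            keep = np.abs(tstats) >= 1.0
            if not keep.any():
                warnings.warn(
                    "no bootstrap draw reached |t| >= 1; falling back to the "
                    "plain mean of all draws",
                    stacklevel=2,
                )
                keep = np.ones(len(boot_w), dtype=bool)
        else:
            keep = np.ones(len(boot_w), dtype=bool)
        final_w = boot_w[keep].mean(axis=0)
        final_w = final_w / final_w.sum()

    # test-split regression of outcome on index + covariates; the index
    # coefficient here is unconstrained
    index_test = scores_test.to_numpy(dtype=float) @ final_w
    Xtest = Xc_all.iloc[test_idx].reset_index(drop=True).copy()
    Xtest.insert(0, "const", 1.0)
    Xtest["wqs_index"] = index_test
    ytest = y[test_idx]
    if config.use_survey_design and design is not None:
        res = fit_weighted_lm(ytest, Xtest, design.subset(
            np.isin(np.arange(n), test_idx)))
        row = res["wqs_index"]
        beta, se = float(row["beta"]), float(row["se"])
        lo, hi, p = float(row["ci_low"]), float(row["ci_high"]), float(row["p"])
    else:
        Xm = Xtest.to_numpy(dtype=float)
        coef, *_ = np.linalg.lstsq(Xm, ytest, rcond=None)
        resid = ytest - Xm @ coef
        dof = len(ytest) - Xm.shape[1]
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(Xm.T @ Xm)
        j = Xtest.columns.get_loc("wqs_index")
        beta = float(coef[j])
        se = float(np.sqrt(cov[j, j]))
        tcrit = stats.t.ppf(0.975, dof)
        lo, hi = beta - tcrit * se, beta + tcrit * se
        p = float(2 * stats.t.sf(abs(beta / se), dof))

    return WQSResult(
        direction=config.direction, beta=beta, se=se, ci_low=lo, ci_high=hi,
        pvalue=p, weights=pd.Series(final_w, index=list(exposures)),
        bootstrap_weights=boot_w, n_train=n_train, n_test=n - n_train,
        n_dropped=n_dropped, cut_points=cuts,
    )


def run_both_directions(table, outcome, exposures, config: WQSConfig,
                        design: SurveyDesign | None = None):
    """Fit the positive- and negative-direction indices with a shared split."""
    from dataclasses import replace

    pos = fit_wqs(table, outcome, exposures,
                  replace(config, direction="positive"), design)
    neg = fit_wqs(table, outcome, exposures,
                  replace(config, direction="negative"), design)
    return pos, neg
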