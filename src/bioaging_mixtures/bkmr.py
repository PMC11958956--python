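"""Bayesian kernel machine regression (BKMR) for a small exposure mixture.

Model: ``y = h(z) + X beta + eps`` with Gaussian noise ``eps ~ N(0, sigma^2)``
and a Gaussian-process prior on the exposure-response surface ``h`` with
kernel ``Cov(h_i, h_j) = lambda * sigma^2 * K_ij``,
``K_ij = exp(-sum_m r_m (z_im - z_jm)^2)``.  Component-wise variable
selection places a spike-and-slab prior on each kernel scale:
``r_m = 0`` (exposure excluded) with prior probability ``1 - pi``, else an
Exponential slab.  The conditional posterior inclusion probability
(conPIP) of exposure ``m`` is the posterior mean of its inclusion
indicator.

Sampling is Metropolis-within-Gibbs on the marginal likelihood with ``h``
integrated out (``y - X beta ~ N(0, sigma^2 (I + lambda K))``): conjugate
Gibbs updates for ``beta`` (Gaussian prior) and ``sigma^2``
(inverse-gamma), Metropolis log-random-walk for ``lambda``, and per-
component birth/death/jitter moves for ``(delta_m, r_m)``.  Posterior
draws of ``h`` at new points are recovered from the GP conditional.

The kernel matrix is n x n, so fits are capped at a documented ``n_cap``
(larger inputs are subsampled with a warning).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "BKMRConfig",
    "BKMRPosterior",
    "fit_bkmr",
    "univariate_response",
    "overall_effect",
    "single_exposure_effect",
    "bivariate_response",
]


@dataclass(frozen=True)
class BKMRConfig:
    n_iterations: int = 2000      # published analyses typically run 10,000
    burn_fraction: float = 0.5
    seed: int = 0
    inclusion_prior: float = 0.5  # P(delta_m = 1)
    slab_rate: float = 1.0        # Exponential slab for r_m | delta_m = 1
    lambda_shape: float = 1.0     # Gamma prior on lambda
    lambda_rate: float = 0.1
    sigma2_shape: float = 2.0     # inverse-gamma prior on sigma^2
    sigma2_scale: float = 1.0
    beta_prior_sd: float = 100.0  # N(0, sd^2) prior on covariate effects
    standardize: bool = True      # center/scale exposures before the kernel
    n_cap: int = 1000
    prop_sd_lambda: float = 1.3
    prop_sd_r: float = 1.3

    def validate(self) -> None:
        if not 0 < self.burn_fraction < 1:
            raise ValueError("burn_fraction must be in (0, 1)")
        if self.n_iterations * (1 - self.burn_fraction) < 2:
            raise ValueError("n_iterations must exceed the burn-in")
        for name in ("slab_rate", "lambda_shape", "lambda_rate",
                     "sigma2_shape", "sigma2_scale", "beta_prior_sd",
                     "prop_sd_lambda", "prop_sd_r"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.inclusion_prior <= 1:
            raise ValueError("inclusion_prior must be in [0, 1]")


@dataclass
class BKMRPosterior:
    """Retained post-burn-in MCMC draws plus the data they condition on."""

    exposures: list
    Z: np.ndarray                # standardized exposures used in the kernel
    Z_raw: np.ndarray            # original scale, for percentile grids
    X: np.ndarray
    y: np.ndarray
    z_mean: np.ndarray
    z_sd: np.ndarray
    r: np.ndarray                # (S, M)
    delta: np.ndarray            # (S, M)
    beta: np.ndarray             # (S, p)
    sigma2: np.ndarray
    lam: np.ndarray
    accept_rates: dict = field(default_factory=dict)
    config: BKMRConfig = None

    @property
    def conpip(self) -> pd.Series:
        return pd.Series(self.delta.mean(axis=0), index=self.exposures,
                         name="conPIP")

    def n_draws(self) -> int:
        return len(self.sigma2)


def _sq_dists(Z: np.ndarray) -> np.ndarray:
    """Per-component squared distance matrices, shape (M, n, n)."""
    n, M = Z.shape
    D = np.empty((M, n, n))
    for m in range(M):
        d = Z[:, m][:, None] - Z[:, m][None, :]
        D[m] = d * d
    return D


def _kernel_from_r(D: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Gaussian kernel; with every component excluded (all r_m = 0) the
    exposure surface is dropped entirely (K = 0), so the all-excluded state
    is exactly linear regression rather than a free random intercept."""
    if not np.any(r > 0):
        return np.zeros(D.shape[1:])
    return np.exp(-np.tensordot(r, D, axes=1))


class _MarginalState:
    """Cached Cholesky of V = I + lambda*K for the current (r, lambda)."""

    def __init__(self, D, r, lam):
        self.D = D
        self.set(r, lam)

    def set(self, r, lam, K=None):
        self.r = np.asarray(r, dtype=float).copy()
        self.lam = float(lam)
        self.K = _kernel_from_r(self.D, self.r) if K is None else K
        n = self.K.shape[0]
        V = self.lam * self.K
        V[np.diag_indices(n)] += 1.0
        self.chol = linalg.cho_factor(V, lower=True, check_finite=False)
        self.logdet = 2.0 * np.sum(np.log(np.diag(self.chol[0])))

    def solve(self, B):
        return linalg.cho_solve(self.chol, B, check_finite=False)

    def loglik(self, e, sigma2):
        quad = float(e @ self.solve(e))
        return -0.5 * self.logdet - 0.5 * quad / sigma2


def marginal_loglik(y, X, beta, sigma2, lam, K):
    """Direct dense evaluation of the integrated-h log-likelihood.

    Reference implementation (explicit determinant/solve on sigma^2 V);
    the sampler's cached-Cholesky path must agree with it.
    """
    n = len(y)
    V = sigma2 * (np.eye(n) + lam * K)
    e = y - X @ beta
    sign, logdet = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    return float(-0.5 * n * np.log(2 * np.pi) - 0.5 * logdet
                 - 0.5 * e @ np.linalg.solve(V, e))


def fit_bkmr(
    Z,
    X,
    y,
    config: BKMRConfig | None = None,
) -> BKMRPosterior:
    """Run the Metropolis-within-Gibbs sampler.

    ``Z`` is the n x M exposure matrix (DataFrame column names become the
    exposure labels), ``X`` the covariate design (an intercept column is
    appended if absent) and ``y`` the outcome.
    """
    config = config or BKMRConfig()
    config.validate()
    if isinstance(Z, pd.DataFrame):
        names = list(Z.columns)
        Z = Z.to_numpy(dtype=float)
    else:
        Z = np.asarray(Z, dtype=float)
        names = [f"z{m}" for m in range(Z.shape[1])]
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.any(np.all(X == 1.0, axis=0)):
        X = np.column_stack([np.ones(len(X)), X])
    y = np.asarray(y, dtype=float)
    n, M = Z.shape

    rng = np.random.default_rng(config.seed)
    if n > config.n_cap:
        warnings.warn(
            f"n={n} exceeds the kernel cap ({config.n_cap}); fitting on a "
            "random subsample",
            stacklevel=2,
        )
        keep = np.sort(rng.choice(n, size=config.n_cap, replace=False))
        Z, X, y = Z[keep], X[keep], y[keep]
        n = config.n_cap

    Z_raw = Z.copy()
    if config.standardize:
        z_mean, z_sd = Z.mean(axis=0), Z.std(axis=0)
        z_sd[z_sd == 0] = 1.0
        Z = (Z - z_mean) / z_sd
    else:
        z_mean, z_sd = np.zeros(M), np.ones(M)

    D = _sq_dists(Z)
    p = X.shape[1]

    # initial state
    pi = config.inclusion_prior
    delta = np.ones(M, dtype=int) if pi > 0 else np.zeros(M, dtype=int)
    r = np.where(delta == 1, 0.2, 0.0)
    lam = 1.0
    sigma2 = float(np.var(y)) or 1.0
    beta = np.zeros(p)
    state = _MarginalState(D, r, lam)
    e = y - X @ beta

    n_keep = config.n_iterations - int(config.n_iterations * config.burn_fraction)
    store = {
        "r": np.empty((n_keep, M)), "delta": np.empty((n_keep, M), dtype=int),
        "beta": np.empty((n_keep, p)), "sigma2": np.empty(n_keep),
        "lam": np.empty(n_keep),
    }
    counts = {k: [0, 0] for k in ("lambda", "r_jitter", "birth", "death")}
    log_pi_odds = (np.log(pi) - np.log1p(-pi)) if 0 < pi < 1 else None

    slab = config.slab_rate
    burn = config.n_iterations - n_keep
    for it in range(config.n_iterations):
        cur_ll = state.loglik(e, sigma2)
        if not np.isfinite(cur_ll):
            raise RuntimeError(f"non-finite marginal likelihood at iteration {it}")

        # lambda: log random walk, Gamma prior
        lam_prop = lam * np.exp(config.prop_sd_lambda * rng.standard_normal())
        trial = _MarginalState.__new__(_MarginalState)
        trial.D = D
        trial.set(state.r, lam_prop, K=state.K)
        logr = (trial.loglik(e, sigma2) - cur_ll
                + stats.gamma.logpdf(lam_prop, config.lambda_shape,
                                     scale=1.0 / config.lambda_rate)
                - stats.gamma.logpdf(lam, config.lambda_shape,
                                     scale=1.0 / config.lambda_rate)
                + np.log(lam_prop) - np.log(lam))
        counts["lambda"][1] += 1
        if np.log(rng.uniform()) < logr:
            lam = lam_prop
            state = trial
            cur_ll = state.loglik(e, sigma2)
            counts["lambda"][0] += 1

        # component-wise spike-and-slab moves
        for m in range(M):
            r_prop = state.r.copy()
            if delta[m] == 1 and pi < 1.0 and rng.uniform() < 0.5:
                # death: exclude component m
                r_prop[m] = 0.0
                move = "death"
                logq = -log_pi_odds + np.log(2.0) if log_pi_odds is not None else None
            elif delta[m] == 1:
                # jitter the slab value on the log scale
                r_prop[m] = state.r[m] * np.exp(
                    config.prop_sd_r * rng.standard_normal())
                move = "r_jitter"
                logq = (stats.expon.logpdf(r_prop[m], scale=1.0 / slab)
                        - stats.expon.logpdf(state.r[m], scale=1.0 / slab)
                        + np.log(r_prop[m]) - np.log(state.r[m]))
            else:
                # birth: propose inclusion with r from the slab prior
                if pi == 0.0:
                    continue
                r_prop[m] = rng.exponential(1.0 / slab)
                move = "birth"
                logq = log_pi_odds - np.log(2.0) if log_pi_odds is not None else np.inf
            trial = _MarginalState.__new__(_MarginalState)
            trial.D = D
            trial.set(r_prop, lam)
            logr = trial.loglik(e, sigma2) - cur_ll + (logq if logq is not None else 0.0)
            counts[move][1] += 1
            if np.log(rng.uniform()) < logr:
                delta[m] = int(r_prop[m] > 0)
                state = trial
                cur_ll = state.loglik(e, sigma2)
                counts[move][0] += 1

        # beta: Gaussian conjugate update on the marginal (h integrated out)
        ViX = state.solve(X)
        Viy = state.solve(y)
        A = X.T @ ViX / sigma2 + np.eye(p) / config.beta_prior_sd**2
        b = X.T @ Viy / sigma2
        cholA = linalg.cho_factor(A, lower=True, check_finite=False)
        mean = linalg.cho_solve(cholA, b, check_finite=False)
        z = rng.standard_normal(p)
        beta = mean + linalg.solve_triangular(
            cholA[0], z, lower=True, trans="T", check_finite=False)
        e = y - X @ beta

        # sigma^2: inverse-gamma conjugate update
        quad = float(e @ state.solve(e))
        shape = config.sigma2_shape + 0.5 * n
        scale = config.sigma2_scale + 0.5 * quad
        sigma2 = scale / rng.gamma(shape)

        if it >= burn:
            j = it - burn
            store["r"][j] = state.r
            store["delta"][j] = delta
            store["beta"][j] = beta
            store["sigma2"][j] = sigma2
            store["lam"][j] = lam

    rates = {k: (c[0] / c[1] if c[1] else np.nan) for k, c in counts.items()}
    return BKMRPosterior(
        exposures=names, Z=Z, Z_raw=Z_raw, X=X, y=y, z_mean=z_mean,
        z_sd=z_sd, r=store["r"], delta=store["delta"], beta=store["beta"],
        sigma2=store["sigma2"], lam=store["lam"], accept_rates=rates,
        config=config,
    )


# ---------------------------------------------------------------------------
# posterior summaries of the exposure-response surface
# ---------------------------------------------------------------------------


def _draw_indices(post: BKMRPosterior, max_draws: int) -> np.ndarray:
    S = post.n_draws()
    if S <= max_draws:
        return np.arange(S)
    return np.unique(np.linspace(0, S - 1, max_draws).astype(int))


def _train_sq_dists(post: BKMRPosterior) -> np.ndarray:
    cached = getattr(post, "_D_cache", None)
    if cached is None:
        cached = _sq_dists(post.Z)
        post._D_cache = cached
    return cached


def _h_conditional(post: BKMRPosterior, Znew_std: np.ndarray, j: int):
    """GP conditional mean and covariance of h at new points, for draw j."""
    r, lam, s2, beta = post.r[j], post.lam[j], post.sigma2[j], post.beta[j]
    n = len(post.y)
    g = Znew_std.shape[0]
    if not np.any(r > 0):
        # all components excluded: h == 0 identically
        return np.zeros(g), np.zeros((g, g))
    diff = post.Z[:, None, :] - Znew_std[None, :, :]
    Kstar = np.exp(-np.einsum("m,ijm->ij", r, diff**2))
    dd = Znew_std[:, None, :] - Znew_std[None, :, :]
    Kss = np.exp(-np.einsum("m,ijm->ij", r, dd**2))
    V = lam * _kernel_from_r(_train_sq_dists(post), r)
    V[np.diag_indices(n)] += 1.0
    chol = linalg.cho_factor(V, lower=True, check_finite=False)
    e = post.y - post.X @ beta
    Vie = linalg.cho_solve(chol, e, check_finite=False)
    mean = lam * (Kstar.T @ Vie)
    ViK = linalg.cho_solve(chol, Kstar, check_finite=False)
    cov = s2 * (lam * Kss - lam**2 * (Kstar.T @ ViK))
    return mean, cov


def _h_samples(post: BKMRPosterior, Znew_raw: np.ndarray, rng,
               max_draws: int = 250):
    """Pointwise posterior samples and means of h at new (raw-scale) points."""
    Znew = (np.asarray(Znew_raw, dtype=float) - post.z_mean) / post.z_sd
    idx = _draw_indices(post, max_draws)
    g = Znew.shape[0]
    means = np.empty((len(idx), g))
    samples = np.empty((len(idx), g))
    for a, j in enumerate(idx):
        mu, cov = _h_conditional(post, Znew, j)
        var = np.clip(np.diag(cov), 0.0, None)
        means[a] = mu
        samples[a] = mu + np.sqrt(var) * rng.standard_normal(g)
    return means, samples


def _contrast_samples(post: BKMRPosterior, points_raw, pairs, rng,
                      max_draws=250):
    """Posterior samples of ``h(points[a]) - h(points[b])`` per ``(a, b)`` pair.

    All points are stacked so one GP conditional (one Cholesky) per retained
    draw serves every contrast; a pair of identical points yields exactly
    zero (zero mean, zero variance).
    """
    Zstd = (np.asarray(points_raw, dtype=float) - post.z_mean) / post.z_sd
    idx = _draw_indices(post, max_draws)
    out = np.empty((len(idx), len(pairs)))
    for d, j in enumerate(idx):
        mu, cov = _h_conditional(post, Zstd, j)
        for c, (a, b) in enumerate(pairs):
            d_mean = mu[a] - mu[b]
            d_var = max(cov[a, a] + cov[b, b] - 2 * cov[a, b], 0.0)
            out[d, c] = d_mean + np.sqrt(d_var) * rng.standard_normal()
    return out


def _percentile_point(post: BKMRPosterior, pcts) -> np.ndarray:
    """Raw-scale point with each exposure at its own percentile."""
    pcts = np.broadcast_to(np.asarray(pcts, dtype=float), (post.Z_raw.shape[1],))
    return np.array([np.percentile(post.Z_raw[:, m], pcts[m])
                     for m in range(post.Z_raw.shape[1])])


def univariate_response(
    post: BKMRPosterior,
    exposure: str,
    grid: np.ndarray | None = None,
    others_at: float = 50.0,
    max_draws: int = 250,
    seed: int = 0,
) -> pd.DataFrame:
    """Posterior mean and 95% credible band of h along one exposure.

    The other exposures are fixed at their ``others_at`` percentile.  Grid
    points outside the observed range are flagged ``extrapolated``.
    """
    m = post.exposures.index(exposure)
    zcol = post.Z_raw[:, m]
    if grid is None:
        grid = np.linspace(np.percentile(zcol, 2), np.percentile(zcol, 98), 50)
    grid = np.asarray(grid, dtype=float)
    extrap = (grid < zcol.min()) | (grid > zcol.max())
    if extrap.any():
        warnings.warn("grid extends beyond the observed exposure range",
                      stacklevel=2)
    base = _percentile_point(post, others_at)
    Znew = np.tile(base, (len(grid), 1))
    Znew[:, m] = grid
    rng = np.random.default_rng(seed)
    means, samples = _h_samples(post, Znew, rng, max_draws)
    return pd.DataFrame({
        "exposure": exposure, "x": grid,
        "estimate": means.mean(axis=0),
        "ci_low": np.percentile(samples, 2.5, axis=0),
        "ci_high": np.percentile(samples, 97.5, axis=0),
        "extrapolated": extrap,
    })


def overall_effect(
    post: BKMRPosterior,
    percentiles=tuple(range(25, 80, 5)),
    reference: float = 50.0,
    max_draws: int = 250,
    seed: int = 0,
) -> pd.DataFrame:
    """Joint-mixture contrast: h(all exposures at p) - h(all at reference)."""
    rng = np.random.default_rng(seed)
    points = [_percentile_point(post, p) for p in percentiles]
    points.append(_percentile_point(post, reference))
    pairs = [(i, len(points) - 1) for i in range(len(percentiles))]
    draws = _contrast_samples(post, np.asarray(points), pairs, rng, max_draws)
    rows = []
    for c, p in enumerate(percentiles):
        rows.append({
            "percentile": p, "estimate": float(draws[:, c].mean()),
            "ci_low": float(np.percentile(draws[:, c], 2.5)),
            "ci_high": float(np.percentile(draws[:, c], 97.5)),
        })
    return pd.DataFrame(rows)


def single_exposure_effect(
    post: BKMRPosterior,
    exposure: str,
    others_at=(25.0, 50.0, 75.0),
    contrast=(75.0, 25.0),
    max_draws: int = 250,
    seed: int = 0,
) -> pd.DataFrame:
    """h with one exposure at its 75th vs 25th percentile, others fixed."""
    m = post.exposures.index(exposure)
    rng = np.random.default_rng(seed)
    hi = np.percentile(post.Z_raw[:, m], contrast[0])
    lo = np.percentile(post.Z_raw[:, m], contrast[1])
    points, pairs = [], []
    for q in others_at:
        base = _percentile_point(post, q)
        z_a, z_b = base.copy(), base.copy()
        z_a[m], z_b[m] = hi, lo
        pairs.append((len(points), len(points) + 1))
        points.extend([z_a, z_b])
    draws = _contrast_samples(post, np.asarray(points), pairs, rng, max_draws)
    rows = []
    for c, q in enumerate(others_at):
        rows.append({
            "exposure": exposure, "others_at": q,
            "estimate": float(draws[:, c].mean()),
            "ci_low": float(np.percentile(draws[:, c], 2.5)),
            "ci_high": float(np.percentile(draws[:, c], 97.5)),
        })
    return pd.DataFrame(rows)


def bivariate_response(
    post: BKMRPosterior,
    pair,
    second_at=(25.0, 50.0, 75.0),
    third_at: float = 50.0,
    n_grid: int = 30,
    max_draws: int = 250,
    seed: int = 0,
) -> pd.DataFrame:
    """h vs the first exposure of ``pair`` at quantiles of the second.

    Non-parallel curves across the quantiles of the second exposure
    indicate interaction; any remaining exposure is fixed at ``third_at``.
    """
    m1 = post.exposures.index(pair[0])
    m2 = post.exposures.index(pair[1])
    rng = np.random.default_rng(seed)
    zcol = post.Z_raw[:, m1]
    grid = np.linspace(np.percentile(zcol, 2), np.percentile(zcol, 98), n_grid)
    frames = []
    for q in second_at:
        base = _percentile_point(post, third_at)
        base[m2] = np.percentile(post.Z_raw[:, m2], q)
        Znew = np.tile(base, (n_grid, 1))
        Znew[:, m1] = grid
        means, samples = _h_samples(post, Znew, rng, max_draws)
        frames.append(pd.DataFrame({
            "exposure_x": pair[0], "exposure_quantile": pair[1],
            "quantile": q, "x": grid,
            "estimate": means.mean(axis=0),
            "ci_low": np.percentile(samples, 2.5, axis=0),
            "ci_high": np.percentile(samples, 97.5, axis=0),
        }))
    return pd.concat(frames, ignore_index=True)
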