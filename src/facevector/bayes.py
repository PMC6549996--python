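"""Bayesian validation analyses: linear regression on manipulation level,
Pearson-correlation estimation, and MCMC diagnostics.

The regression model is y ~ Normal(b0 + beta*x, sigma^2) with weakly
informative priors: Normal(0, 10^2) on the intercept and slope and
half-Cauchy(0, 5) on sigma.  Correlations are estimated under a bivariate or
trivariate normal likelihood with flat priors on the means, half-Cauchy(0, 5)
on the standard deviations and a uniform prior over valid correlation
matrices; the contrast delta_rho = rho_12 - rho_13 is summarized from the
joint posterior draws so it accounts for the shared condition.

Sampling is adaptive random-walk Metropolis within Gibbs: one Gaussian
proposal per parameter per sweep, proposal scales tuned toward a 30-50%
acceptance rate during burn-in only (adaptation frozen afterwards, so the
retained chains are valid MCMC), chains started from dispersed points and
run in parallel as vectorized numpy operations.  Convergence is checked with
the split-chain potential scale reduction factor (Rhat).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raters import RatingMatrix, mean_scores, standardize_ratings

__all__ = [
    "McmcSettings",
    "PosteriorSummary",
    "RegressionResult",
    "CorrelationResult",
    "bayes_linear_regression",
    "bayes_correlation",
    "split_rhat",
    "validate_model",
]


@dataclass(frozen=True)
class McmcSettings:
    """Sampler configuration (defaults: 5000 iterations, 500 burn-in, 4 chains)."""

    iterations: int = 5000
    burn_in: int = 500
    chains: int = 4
    seed: int = 0
    proposal_scales: tuple | None = None

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.chains < 2:
            raise ValueError("need at least 2 chains")
        if self.iterations < 4:
            raise ValueError("too few iterations")


@dataclass
class PosteriorSummary:
    """EAP, central 95% credible interval, split-Rhat and retained draws."""

    name: str
    eap: float
    cri_low: float
    cri_high: float
    rhat: float
    chains: np.ndarray  # (n_chains, n_retained)

    def to_dict(self) -> dict:
        return {
            "eap": self.eap,
            "cri": [self.cri_low, self.cri_high],
            "rhat": self.rhat,
            "n_draws": int(self.chains.size),
        }

    def cri_contains(self, value: float) -> bool:
        return self.cri_low <= value <= self.cri_high


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain Gelman-Rubin potential scale reduction factor.

    Each chain is halved (the trailing draw is dropped when the length is
    odd), then Rhat = sqrt(((n-1)/n * W + B/n) / W) with W the mean
    within-half variance and B/n the variance of the half means.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need draws from at least 2 chains")
    m, n = chains.shape
    if n < 4:
        raise ValueError("need at least 4 draws per chain")
    half = n // 2
    splits = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    w = splits.var(axis=1, ddof=1).mean()
    if w <= 0:
        raise ValueError("zero within-chain variance: Rhat undefined")
    b_over_n = splits.mean(axis=1).var(ddof=1)
    var_hat = (half - 1) / half * w + b_over_n
    return float(np.sqrt(var_hat / w))


def _half_cauchy_logpdf(sigma: np.ndarray, scale: float = 5.0) -> np.ndarray:
    return -np.log1p((sigma / scale) ** 2)


def _run_rwm(logpost, init: np.ndarray, scales: np.ndarray, settings: McmcSettings,
             rng: np.random.Generator) -> np.ndarray:
    """Componentwise random-walk Metropolis, vectorized over chains.

    Returns retained draws of shape (n_retained, n_chains, n_params).
    Proposal scales adapt every 50 sweeps during burn-in (toward 30-50%
    acceptance) and are frozen afterwards.
    """
    iters, burn = settings.iterations, settings.burn_in
    m, p = init.shape
    noise = rng.standard_normal((iters, p, m))
    logu = np.log(rng.random((iters, p, m)))
    n_joint = 4  # joint refreshes per sweep once the covariance is learned
    joint_noise = rng.standard_normal((iters, n_joint, m, p))
    joint_logu = np.log(rng.random((iters, n_joint, m)))
    scales = np.asarray(scales, dtype=float).copy()
    params = init.copy()
    lp = logpost(params)
    if not np.isfinite(lp).all():
        raise RuntimeError("invalid starting point for MCMC")
    draws = np.empty((iters - burn, m, p))
    acc = np.zeros(p)
    window = 50
    since = 0
    # adaptive joint step: proposal covariance learned from burn-in history
    # (frozen afterwards); handles ridge-shaped posteriors that defeat
    # purely componentwise moves
    history = np.empty((burn, m, p))
    chol = None
    for it in range(iters):
        for j in range(p):
            cand = params.copy()
            cand[:, j] += scales[j] * noise[it, j]
            lp_new = logpost(cand)
            accept = logu[it, j] < (lp_new - lp)
            params[accept] = cand[accept]
            lp = np.where(accept, lp_new, lp)
            acc[j] += accept.mean()
        if it < burn:
            history[it] = params
        if chol is not None:
            for k in range(n_joint):
                cand = params + joint_noise[it, k] @ chol.T
                lp_new = logpost(cand)
                accept = joint_logu[it, k] < (lp_new - lp)
                params[accept] = cand[accept]
                lp = np.where(accept, lp_new, lp)
        since += 1
        if it < burn and since == window:
            rates = acc / window
            scales[rates > 0.5] *= 1.4
            scales[rates < 0.3] *= 0.7
            acc[:] = 0.0
            since = 0
            if it >= 2 * window:
                flat = history[: it + 1].reshape(-1, p)
                cov = np.cov(flat, rowvar=False).reshape(p, p)
                cov += 1e-10 * np.eye(p) * max(cov.diagonal().max(), 1e-12)
                chol = np.linalg.cholesky(cov) * (2.38 / np.sqrt(p))
        if it >= burn:
            draws[it - burn] = params
    return draws


def _summarize(name: str, draws_param: np.ndarray) -> PosteriorSummary:
    """draws_param: (n_retained, n_chains) draws of one parameter."""
    by_chain = draws_param.T  # (chains, retained)
    pooled = by_chain.ravel()
    lo, hi = np.percentile(pooled, [2.5, 97.5])
    return PosteriorSummary(
        name=name,
        eap=float(pooled.mean()),
        cri_low=float(lo),
        cri_high=float(hi),
        rhat=split_rhat(by_chain),
        chains=by_chain,
    )


# ---------------------------------------------------------------------------
# Linear regression
# ---------------------------------------------------------------------------


@dataclass
class RegressionResult:
    beta: PosteriorSummary
    intercept: PosteriorSummary
    sigma: PosteriorSummary
    n: int
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "beta": self.beta.to_dict(),
            "intercept": self.intercept.to_dict(),
            "sigma": self.sigma.to_dict(),
            "n": self.n,
        }


def bayes_linear_regression(x, y, settings: McmcSettings) -> RegressionResult:
    """Posterior for y ~ Normal(b0 + beta*x, sigma^2).

    Priors: Normal(0, 10^2) on b0 and beta, half-Cauchy(0, 5) on sigma
    (sampled on the log scale with the Jacobian included).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("x and y must be the same length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite inputs")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: slope not identifiable")

    n = float(len(x))
    sx, sy = x.sum(), y.sum()
    sxx, sxy, syy = (x * x).sum(), (x * y).sum(), (y * y).sum()

    def logpost(params: np.ndarray) -> np.ndarray:
        b0, b1, ls = params[:, 0], params[:, 1], params[:, 2]
        sigma = np.exp(ls)
        ssr = (
            syy - 2 * b0 * sy - 2 * b1 * sxy + 2 * b0 * b1 * sx
            + n * b0**2 + b1**2 * sxx
        )
        loglik = -n * ls - ssr / (2 * sigma**2)
        prior = -(b0**2 + b1**2) / 200.0 + _half_cauchy_logpdf(sigma) + ls
        return loglik + prior

    # dispersed starts around the least-squares fit
    xbar, ybar = sx / n, sy / n
    sxx_c = sxx - n * xbar**2
    b1_ols = (sxy - n * xbar * ybar) / sxx_c
    b0_ols = ybar - b1_ols * xbar
    resid_sd = max(
        float(np.sqrt(np.mean((y - b0_ols - b1_ols * x) ** 2))), 1e-8 * max(y.std(), 1.0), 1e-12
    )
    sd_x = x.std()
    rng = np.random.default_rng(settings.seed)
    m = settings.chains
    init = np.column_stack(
        [
            b0_ols + 2 * resid_sd / np.sqrt(n) * rng.standard_normal(m),
            b1_ols + 2 * resid_sd / (sd_x * np.sqrt(n)) * rng.standard_normal(m),
            np.log(resid_sd) + 0.5 * rng.standard_normal(m),
        ]
    )
    scales = settings.proposal_scales or (
        3 * resid_sd / np.sqrt(n),
        3 * resid_sd / (sd_x * np.sqrt(n)),
        0.2,
    )
    draws = _run_rwm(logpost, init, np.asarray(scales), settings, rng)
    return RegressionResult(
        beta=_summarize("beta", draws[:, :, 1]),
        intercept=_summarize("intercept", draws[:, :, 0]),
        sigma=_summarize("sigma", np.exp(draws[:, :, 2])),
        n=int(n),
    )


# ---------------------------------------------------------------------------
# Correlation estimation
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    rho: dict  # pair name -> PosteriorSummary
    delta_rho: PosteriorSummary | None
    n: int
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {name: s.to_dict() for name, s in self.rho.items()}
        if self.delta_rho is not None:
            out["delta_rho"] = self.delta_rho.to_dict()
        out["n"] = self.n
        return out


def _corr_loglik_factory(ybar, sds, a, n, d):
    """Closed-form multivariate-normal log-likelihood from sufficient stats.

    ``a`` is the sample covariance (denominator n) pre-divided by the sample
    s.d. products; parameter s.d.s rescale it per draw.
    """
    if d == 2:
        def loglik(mu, ls, r):
            s0, s1 = np.exp(ls[:, 0]), np.exp(ls[:, 1])
            r01 = r[:, 0]
            det = 1.0 - r01**2
            bad = (np.abs(r01) >= 1.0) | (det <= 1e-12)
            det = np.where(bad, 1.0, det)
            a00 = a[0, 0] * (sds[0] / s0) ** 2
            a11 = a[1, 1] * (sds[1] / s1) ** 2
            a01 = a[0, 1] * sds[0] * sds[1] / (s0 * s1)
            m0 = (ybar[0] - mu[:, 0]) / s0
            m1 = (ybar[1] - mu[:, 1]) / s1
            quad = (a00 + a11 - 2 * r01 * a01 + m0**2 + m1**2 - 2 * r01 * m0 * m1) / det
            ll = -n / 2 * (np.log(det) + 2 * (ls[:, 0] + ls[:, 1]) + quad)
            return np.where(bad, -np.inf, ll)
        return loglik

    def loglik(mu, ls, r):  # d == 3, inverse via the adjugate
        s = np.exp(ls)
        p, q, t = r[:, 0], r[:, 1], r[:, 2]  # r12, r13, r23
        det = 1.0 + 2 * p * q * t - p**2 - q**2 - t**2
        bad = (np.abs(r) >= 1.0).any(axis=1) | (det <= 1e-12)
        det = np.where(bad, 1.0, det)
        c00, c11, c22 = 1 - t**2, 1 - q**2, 1 - p**2
        c01, c02, c12 = q * t - p, p * t - q, p * q - t
        aa = [[None] * 3 for _ in range(3)]
        mm = []
        for i in range(3):
            mm.append((ybar[i] - mu[:, i]) / s[:, i])
            for j in range(i, 3):
                aa[i][j] = a[i, j] * sds[i] * sds[j] / (s[:, i] * s[:, j])
        quad = (
            c00 * (aa[0][0] + mm[0] * mm[0])
            + c11 * (aa[1][1] + mm[1] * mm[1])
            + c22 * (aa[2][2] + mm[2] * mm[2])
            + 2 * c01 * (aa[0][1] + mm[0] * mm[1])
            + 2 * c02 * (aa[0][2] + mm[0] * mm[2])
            + 2 * c12 * (aa[1][2] + mm[1] * mm[2])
        ) / det
        ll = -n / 2 * (np.log(det) + 2 * ls.sum(axis=1) + quad)
        return np.where(bad, -np.inf, ll)

    return loglik


def bayes_correlation(ys, settings: McmcSettings) -> CorrelationResult:
    """Bayesian Pearson correlations under a 2- or 3-variate normal model.

    With three vectors (y1, y2, y3) the pairwise correlations rho_12,
    rho_13, rho_23 are estimated jointly and the contrast
    delta_rho = rho_12 - rho_13 is summarized from the same draws.
    """
    ys = [np.asarray(v, dtype=float).ravel() for v in ys]
    d = len(ys)
    if d not in (2, 3):
        raise ValueError("provide 2 or 3 item-aligned vectors")
    n = len(ys[0])
    if any(len(v) != n for v in ys):
        raise ValueError("vectors must be item-aligned (equal length)")
    if n < 3:
        raise ValueError("need at least 3 items")
    for i, v in enumerate(ys):
        if not np.isfinite(v).all():
            raise ValueError("non-finite inputs")
        if np.ptp(v) == 0:
            raise ValueError(f"vector {i} is constant: correlation undefined")

    ymat = np.column_stack(ys)
    ybar = ymat.mean(axis=0)
    yc = ymat - ybar
    cov = yc.T @ yc / n
    sds = np.sqrt(np.diag(cov))
    a = cov / np.outer(sds, sds)  # sample correlation matrix
    loglik = _corr_loglik_factory(ybar, sds, a, n, d)

    n_r = d * (d - 1) // 2
    pairs = [(i, j) for i in range(d) for j in range(i + 1, d)]

    # correlations are sampled on the Fisher-z scale (r = tanh z) so chains
    # mix well near the +/-1 boundary; the Jacobian keeps the prior uniform
    # over the positive-definite region
    def logpost(params: np.ndarray) -> np.ndarray:
        mu, ls, z = params[:, :d], params[:, d : 2 * d], params[:, 2 * d :]
        r = np.tanh(z)
        prior = (_half_cauchy_logpdf(np.exp(ls)) + ls).sum(axis=1)
        prior = prior + np.log1p(-(r**2)).sum(axis=1)
        return loglik(mu, ls, r) + prior

    rng = np.random.default_rng(settings.seed)
    m = settings.chains
    r_sample = np.array([a[i, j] for i, j in pairs])
    init = np.column_stack(
        [ybar[i] + 2 * sds[i] / np.sqrt(n) * rng.standard_normal(m) for i in range(d)]
        + [np.log(sds[i]) + 0.3 * rng.standard_normal(m) for i in range(d)]
        + [
            np.arctanh(
                np.clip(0.8 * r_sample[k] + 0.1 * rng.standard_normal(m), -0.95, 0.95)
            )
            for k in range(n_r)
        ]
    )
    scales = settings.proposal_scales or np.concatenate(
        [3 * sds / np.sqrt(n), np.full(d, 0.2), np.full(n_r, 3.0 / np.sqrt(n))]
    )
    # repair any start whose correlation block is outside the PD region
    for _ in range(60):
        bad = ~np.isfinite(logpost(init))
        if not bad.any():
            break
        init[np.ix_(bad, range(2 * d, 2 * d + n_r))] *= 0.7
    draws = _run_rwm(logpost, init, np.asarray(scales), settings, rng)

    r_draws = np.tanh(draws[:, :, 2 * d :])
    rho = {}
    for k, (i, j) in enumerate(pairs):
        rho[f"rho_{i + 1}{j + 1}"] = _summarize(f"rho_{i + 1}{j + 1}", r_draws[:, :, k])
    delta = None
    if d == 3:
        delta = _summarize("delta_rho", r_draws[:, :, 0] - r_draws[:, :, 1])
    return CorrelationResult(rho=rho, delta_rho=delta, n=n)


# ---------------------------------------------------------------------------
# End-to-end validation analysis
# ---------------------------------------------------------------------------

_CONDITION_ORDER = ("shape_and_reflectance", "shape_only", "reflectance_only")


def _stable_seed(*parts) -> int:
    import hashlib

    h = hashlib.blake2b("|".join(map(str, parts)).encode(), digest_size=4)
    return int.from_bytes(h.digest(), "little") % (2**31)


def validate_model(
    ratings_by_condition: dict,
    settings: McmcSettings,
    delta_rho_method: str = "joint",
) -> dict:
    """Run the full validation analysis on per-condition rating matrices.

    ``ratings_by_condition`` maps (sex, condition) to a RatingMatrix whose
    columns are validation stimuli (item = face x manipulation level, with
    ``delta_levels`` set).  Per sex and condition, ratings are standardized
    per rater, averaged to item-level means, and regressed on the level; per
    sex, the three conditions' item-aligned means enter a trivariate
    correlation model reporting rho(combined, shape-only),
    rho(combined, reflectance-only) and their contrast delta_rho.
    """
    if delta_rho_method not in ("joint", "two_fit"):
        raise ValueError("delta_rho_method must be 'joint' or 'two_fit'")
    sexes = sorted({sex for sex, _ in ratings_by_condition})
    report = {
        "item_unit": "face x delta level",
        "delta_rho_method": delta_rho_method,
        "conditions": list(_CONDITION_ORDER),
        "per_sex": {},
    }
    results = {"report": report, "regressions": {}, "correlations": {}}
    for sex in sexes:
        sex_report = {"regression": {}, "correlation": {}}
        item_means = {}
        item_ids = None
        for cond in _CONDITION_ORDER:
            matrix = ratings_by_condition.get((sex, cond))
            if matrix is None:
                raise ValueError(f"missing condition {cond!r} for sex {sex!r}")
            if matrix.delta_levels is None:
                raise ValueError(f"{sex}/{cond}: delta_levels required")
            y = mean_scores(standardize_ratings(matrix)).to_numpy()
            x = np.asarray(matrix.delta_levels, dtype=float)
            if item_ids is None:
                item_ids = list(matrix.face_ids)
            elif list(matrix.face_ids) != item_ids:
                raise ValueError(f"{sex}/{cond}: item ordering differs across conditions")
            fit = bayes_linear_regression(
                x, y, McmcSettings(
                    settings.iterations, settings.burn_in, settings.chains,
                    seed=_stable_seed(settings.seed, sex, cond),
                )
            )
            results["regressions"][(sex, cond)] = fit
            sex_report["regression"][cond] = fit.to_dict()
            item_means[cond] = y
        triple = [item_means[c] for c in _CONDITION_ORDER]
        corr_settings = McmcSettings(
            settings.iterations, settings.burn_in, settings.chains,
            seed=_stable_seed(settings.seed, sex, "correlation"),
        )
        if delta_rho_method == "joint":
            corr = bayes_correlation(triple, corr_settings)
            delta = corr.delta_rho
            rho_shape, rho_refl = corr.rho["rho_12"], corr.rho["rho_13"]
        else:
            fit_s = bayes_correlation([triple[0], triple[1]], corr_settings)
            fit_r = bayes_correlation(
                [triple[0], triple[2]],
                McmcSettings(
                    settings.iterations, settings.burn_in, settings.chains,
                    seed=_stable_seed(settings.seed, sex, "correlation2"),
                ),
            )
            rho_shape, rho_refl = fit_s.rho["rho_12"], fit_r.rho["rho_12"]
            delta = _summarize("delta_rho", (rho_shape.chains - rho_refl.chains).T)
            corr = CorrelationResult(
                rho={"rho_12": rho_shape, "rho_13": rho_refl}, delta_rho=delta,
                n=len(triple[0]),
            )
        results["correlations"][sex] = corr
        sex_report["correlation"] = {
            "rho_shape": rho_shape.to_dict(),
            "rho_reflectance": rho_refl.to_dict(),
            "delta_rho": delta.to_dict(),
            "n_items": corr.n,
        }
        report["per_sex"][sex] = sex_report
    return results
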