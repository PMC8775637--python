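"""Hierarchical Bayesian random-parameter binary logit.

Model
-----
Each observed cyclist i occupies the motor lane with probability

    y_i ~ Bernoulli(p_i),    logit(p_i) = beta_i . x_i,

where x_i is the treatment-coded covariate row (leading 1 for the
intercept).  Coefficients declared *random* vary across observations,

    beta_{i,k} ~ N(mu_k, Sigma_k),

with diagonal mixing covariance; the rest are fixed, beta_{i,k} = mu_k.
Hierarchical priors are conjugate where possible:

    mu_k ~ N(a, b),    Sigma_k ~ InverseGamma(c, d),

with vague defaults a=0, b=1e6, c=d=0.001.  The fixed-parameter
("standard") logit is the special case with an empty random set.

Sampler
-------
Metropolis-within-Gibbs.  Per iteration: a vectorised per-observation
random-walk Metropolis sweep over each random coefficient column (the full
conditionals of the beta_i factorise over observations), conjugate Gibbs
draws for mu_k (random set) and Sigma_k, a block random-walk Metropolis for
the fixed-coefficient mu (proposal preconditioned by the inverse observed
information at the maximum-likelihood fit), and two joint "group" moves per
random coordinate — a translation of (mu_k, beta_{.,k}) and a rescaling of
(Sigma_k, centred beta residuals) — which leave the posterior invariant and
repair the slow mixing of the centred parameterisation when Sigma_k is
weakly identified.  Proposal scales adapt toward acceptance rates in
[0.2, 0.5] during burn-in only, so the post-burn-in kernel is a fixed,
valid MH kernel.

Model comparison uses the conditional DIC (deviance evaluated at the
posterior means of the parameters that actually enter the likelihood:
beta_{i,k} for random coefficients, mu_k for fixed ones), mirroring the
convention of the BUGS family of samplers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .encoding import DesignMatrix

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "PosteriorDraws",
    "DICResult",
    "log_likelihood",
    "log_posterior",
    "mu_conditional",
    "gibbs_update_mu",
    "sigma_conditional",
    "gibbs_update_sigma",
    "metropolis_update_beta",
    "run_chain",
    "fit_fixed_logit",
    "gelman_rubin",
    "dic",
    "maximum_likelihood_logit",
]

SIGMA_FLOOR = 1e-8  # variance draws below this are rejected states


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the hierarchical priors and the random set.

    ``mean_loc``/``mean_var`` are the normal prior location/variance on every
    mu_k; ``var_shape``/``var_rate`` the inverse-gamma shape/rate on each
    random coefficient's mixing variance; ``random_set`` lists the design
    columns whose coefficients vary across observations.
    """

    mean_loc: float = 0.0
    mean_var: float = 1e6
    var_shape: float = 0.001
    var_rate: float = 0.001
    random_set: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.mean_var <= 0 or self.var_shape <= 0 or self.var_rate <= 0:
            raise ValueError("prior variance, shape and rate must all be positive")


@dataclass(frozen=True)
class MCMCConfig:
    chains: int = 2
    iterations: int = 20_000
    burnin: int = 10_000
    thin: int = 1
    seed: int = 0
    adapt_interval: int = 50
    accept_window: tuple[float, float] = (0.2, 0.5)
    initial_values: tuple[dict | None, ...] | None = None  # per-chain {"mu": ..., "sigma2": ...}

    def __post_init__(self) -> None:
        if self.iterations <= self.burnin or self.burnin < 0:
            raise ValueError("need iterations > burnin >= 0")
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class DICResult:
    """Deviance information criterion: DIC = Dbar + pD = 2*Dbar - Dhat."""

    dbar: float
    dhat: float
    fingerprint: str = ""

    @property
    def pd(self) -> float:
        return self.dbar - self.dhat

    @property
    def dic(self) -> float:
        return self.dbar + self.pd


@dataclass
class PosteriorDraws:
    """Post-burn-in MCMC draws, one block per chain.

    ``mu`` has shape (chains, draws, k+1); ``sigma2`` (chains, draws, R) holds
    the mixing variances of the R random coefficients (order of
    ``random_set``); ``deviance`` (chains, draws) is -2 log-likelihood at each
    draw's own coefficients.  Observation-level coefficients are not stored
    draw-by-draw; ``beta_mean`` (n, R) keeps their pooled posterior mean for
    the conditional DIC.
    """

    columns: list[str]
    random_set: list[str]
    mu: np.ndarray
    sigma2: np.ndarray
    deviance: np.ndarray
    beta_mean: np.ndarray
    n_obs: int
    accept_rates: dict[str, float] = field(default_factory=dict)
    seeds: list[int] = field(default_factory=list)
    fingerprint: str = ""

    @property
    def n_chains(self) -> int:
        return self.mu.shape[0]

    @property
    def n_draws(self) -> int:
        return self.mu.shape[1]

    def mu_pooled(self) -> np.ndarray:
        return self.mu.reshape(-1, self.mu.shape[2])

    def sigma2_pooled(self) -> np.ndarray:
        return self.sigma2.reshape(self.n_chains * self.n_draws, self.sigma2.shape[2])

    def sd_pooled(self) -> np.ndarray:
        """Draws of the mixing-distribution SD, sqrt(Sigma_k)."""
        return np.sqrt(self.sigma2_pooled())

    def column_index(self, label: str) -> int:
        return self.columns.index(label)


def _log1pexp(eta: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, eta)


def log_likelihood(beta: np.ndarray, dm: DesignMatrix, y: np.ndarray) -> float:
    """Bernoulli-logit log likelihood; ``beta`` is (k+1,) or (n, k+1)."""
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("outcome vector must be binary 0/1")
    beta = np.asarray(beta, dtype=float)
    if beta.ndim == 1:
        eta = dm.X @ beta
    else:
        if beta.shape != dm.X.shape:
            raise ValueError(f"beta shape {beta.shape} != design shape {dm.X.shape}")
        eta = np.einsum("ij,ij->i", beta, dm.X)
    return float(np.sum(y * eta - _log1pexp(eta)))


def _log_ig(v: np.ndarray | float, shape: float, rate: float):
    return shape * np.log(rate) - gammaln(shape) - (shape + 1) * np.log(v) - rate / v


def log_posterior(
    mu: np.ndarray,
    sigma2: np.ndarray,
    beta: np.ndarray | None,
    dm: DesignMatrix,
    y: np.ndarray,
    prior: PriorSpec,
    groups: np.ndarray | None = None,
) -> float:
    """Log joint posterior (up to the normalising constant).

    ``mu`` is (k+1,); ``sigma2`` (R,) and ``beta`` (n, R) cover the random
    coefficients in ``prior.random_set`` order (both empty/None for the
    fixed-parameter model).  With group-level random parameters ``beta`` has
    one row per group and ``groups`` maps observations to rows.  Non-positive
    mixing variances yield -inf (a rejected state), not an exception.
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    if sigma2.size and (sigma2 <= 0).any():
        return -np.inf
    r_idx = [dm.column_index(c) for c in prior.random_set]
    full = np.tile(np.asarray(mu, dtype=float), (dm.n, 1))
    if r_idx:
        if beta is None:
            raise ValueError("beta draws required for random coefficients")
        full[:, r_idx] = beta if groups is None else beta[groups]
    lp = log_likelihood(full, dm, y)
    if r_idx:
        resid = beta - np.asarray(mu)[r_idx]
        lp += float(
            np.sum(-0.5 * np.log(2 * np.pi * sigma2) - 0.5 * resid**2 / sigma2)
        )
        lp += float(np.sum(_log_ig(sigma2, prior.var_shape, prior.var_rate)))
    lp += float(
        np.sum(
            -0.5 * np.log(2 * np.pi * prior.mean_var)
            - 0.5 * (np.asarray(mu) - prior.mean_loc) ** 2 / prior.mean_var
        )
    )
    return lp


# ---------------------------------------------------------------------------
# conditional updates


def mu_conditional(beta_col: np.ndarray, sigma2_k: float, prior: PriorSpec) -> tuple[float, float]:
    """Conjugate normal full conditional (mean, variance) of mu_k given
    the observation-level coefficients of a random column."""
    n = len(beta_col)
    v = 1.0 / (n / sigma2_k + 1.0 / prior.mean_var)
    m = v * (beta_col.sum() / sigma2_k + prior.mean_loc / prior.mean_var)
    return m, v


def gibbs_update_mu(
    beta_col: np.ndarray, sigma2_k: float, prior: PriorSpec, rng: np.random.Generator
) -> float:
    m, v = mu_conditional(beta_col, sigma2_k, prior)
    return m + np.sqrt(v) * rng.standard_normal()


def sigma_conditional(
    beta_col: np.ndarray, mu_k: float, prior: PriorSpec
) -> tuple[float, float]:
    """Conjugate inverse-gamma full conditional (shape, rate) of Sigma_k."""
    n = len(beta_col)
    shape = prior.var_shape + n / 2.0
    rate = prior.var_rate + 0.5 * float(np.sum((beta_col - mu_k) ** 2))
    return shape, rate


def gibbs_update_sigma(
    beta_col: np.ndarray, mu_k: float, prior: PriorSpec, rng: np.random.Generator
) -> float:
    shape, rate = sigma_conditional(beta_col, mu_k, prior)
    return rate / rng.gamma(shape)


def metropolis_update_beta(
    beta_col: np.ndarray,
    eta: np.ndarray,
    x_col: np.ndarray,
    y: np.ndarray,
    mu_k: float,
    sigma2_k: float,
    scale: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Vectorised per-observation random-walk Metropolis for one random column.

    The full conditional of beta_{i,k} factorises over i (each observation's
    likelihood involves only its own coefficients), so all n proposals are
    accepted or rejected independently in one pass.  Returns the updated
    column, the updated linear predictor, and the acceptance rate.
    """
    n = len(beta_col)
    beta_new, eta_new, _, rate = _beta_sweep(
        beta_col, eta, _log1pexp(eta), x_col, y, mu_k, sigma2_k, scale, rng, np.arange(n)
    )
    return beta_new, eta_new, rate


def _beta_sweep(beta_col, eta, lse, x_col, y, mu_k, sigma2_k, scale, rng, g):
    """Grouped variant of :func:`metropolis_update_beta` carrying the cached
    log1pexp(eta); ``beta_col`` has one entry per group, ``g`` maps each
    observation to its group (identity for observation-level effects)."""
    G = len(beta_col)
    prop = beta_col + scale * rng.standard_normal(G)
    d_eta = (prop - beta_col)[g] * x_col
    eta_prop = eta + d_eta
    lse_prop = _log1pexp(eta_prop)
    d_ll = np.bincount(g, weights=y * d_eta - (lse_prop - lse), minlength=G)
    d_prior = -0.5 * ((prop - mu_k) ** 2 - (beta_col - mu_k) ** 2) / sigma2_k
    accept = np.log(rng.random(G)) < d_ll + d_prior
    acc_obs = accept[g]
    beta_new = np.where(accept, prop, beta_col)
    eta_new = np.where(acc_obs, eta_prop, eta)
    lse_new = np.where(acc_obs, lse_prop, lse)
    return beta_new, eta_new, lse_new, float(accept.mean())


class _Adaptive:
    """Robbins-Monro-free scale adaptation: nudge the proposal scale whenever
    the windowed acceptance rate leaves [low, high]; frozen after burn-in."""

    def __init__(self, scale: float, window: tuple[float, float]):
        self.scale = scale
        self.low, self.high = window
        self.acc = 0.0
        self.count = 0

    def record(self, rate: float) -> None:
        self.acc += rate
        self.count += 1

    def maybe_adapt(self) -> None:
        if self.count == 0:
            return
        rate = self.acc / self.count
        if rate < self.low:
            self.scale *= 0.7
        elif rate > self.high:
            self.scale *= 1.4
        self.acc = 0.0
        self.count = 0


def _fingerprint(dm: DesignMatrix, y: np.ndarray) -> str:
    import hashlib

    h = hashlib.blake2b(digest_size=8)
    h.update(np.ascontiguousarray(dm.X).tobytes())
    h.update(np.ascontiguousarray(np.asarray(y, dtype=np.int8)).tobytes())
    return h.hexdigest()


def maximum_likelihood_logit(dm: DesignMatrix, y: np.ndarray) -> np.ndarray:
    """Maximum-likelihood fixed-logit coefficients (statsmodels backend);
    falls back to zeros if the fit fails (e.g. complete separation)."""
    import statsmodels.api as sm

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(np.asarray(y, dtype=float), dm.X).fit(disp=0, maxiter=200)
        params = np.asarray(res.params, dtype=float)
        if np.all(np.isfinite(params)):
            return params
    except Exception:
        pass
    return np.zeros(dm.X.shape[1])


def _run_single_chain(
    dm: DesignMatrix,
    y: np.ndarray,
    prior: PriorSpec,
    config: MCMCConfig,
    chain: int,
    init: dict | None,
    ml_params: np.ndarray,
    g: np.ndarray,
):
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, chain]))
    X = dm.X
    n, K = X.shape
    G = int(g.max()) + 1 if len(g) else 0
    labels = dm.columns
    r_idx = np.array([dm.column_index(c) for c in prior.random_set], dtype=int)
    f_idx = np.array([j for j in range(K) if j not in set(r_idx)], dtype=int)
    R = len(r_idx)
    y = np.asarray(y, dtype=float)

    # initial state: chain 0 at zeros, chain 1 at jittered ML estimates
    if init is not None:
        mu = np.asarray(init.get("mu", np.zeros(K)), dtype=float).copy()
        sigma2 = np.asarray(init.get("sigma2", np.full(R, 0.1)), dtype=float).copy()
    elif chain == 0:
        mu = np.zeros(K)
        sigma2 = np.full(R, 0.1)
    else:
        # clip guards against runaway ML estimates under quasi-separation
        mu = np.clip(ml_params, -10, 10) + 0.5 * rng.standard_normal(K)
        sigma2 = np.full(R, 0.1)
    B = np.tile(mu[r_idx], (G, 1)) if R else np.zeros((G, 0))
    Xr = X[:, r_idx] if R else np.zeros((n, 0))

    eta = X[:, f_idx] @ mu[f_idx] + (np.einsum("ij,ij->i", B[g], Xr) if R else 0.0)
    lp0 = log_posterior(mu, sigma2, B if R else None, dm, y, prior, groups=g)
    if not np.isfinite(lp0):
        raise RuntimeError(
            "log posterior is not finite at the initial state; supply different initial values"
        )

    scales = {
        **{f"beta:{labels[j]}": _Adaptive(1.0, config.accept_window) for j in r_idx},
        "mu_block": _Adaptive(1.0, config.accept_window),
        **{f"shift:{labels[j]}": _Adaptive(0.1, config.accept_window) for j in r_idx},
        **{f"scale:{labels[j]}": _Adaptive(0.5, config.accept_window) for j in r_idx},
    }

    # Preconditioned block proposal for the fixed-coefficient means: a
    # Cholesky factor of the Laplace-approximation covariance (inverse of
    # observed information at the ML fit plus the prior precision — the
    # prior term keeps the proposal sane under quasi-separation), scaled by
    # 2.38/sqrt(dim) and adapted further.
    F = len(f_idx)
    if F:
        Xf = X[:, f_idx]
        p_ml = 1.0 / (1.0 + np.exp(-(X @ ml_params)))
        info = (Xf * (p_ml * (1 - p_ml))[:, None]).T @ Xf
        info += (1.0 / prior.mean_var + 1e-8) * np.eye(F)
        try:
            chol = np.linalg.cholesky(np.linalg.inv(info))
        except np.linalg.LinAlgError:
            chol = np.eye(F)
        scales["mu_block"].scale = 2.38 / np.sqrt(F)

    kept = (config.iterations - config.burnin) // config.thin
    mu_out = np.empty((kept, K))
    sig_out = np.empty((kept, R))
    dev_out = np.empty(kept)
    beta_sum = np.zeros((n, R))
    beta_count = 0
    out_i = 0

    c_, d_ = prior.var_shape, prior.var_rate
    lse = _log1pexp(eta)
    for it in range(config.iterations):
        # per-effect Metropolis sweep over random columns
        for r in range(R):
            j = r_idx[r]
            ad = scales[f"beta:{labels[j]}"]
            B[:, r], eta, lse, rate = _beta_sweep(
                B[:, r], eta, lse, Xr[:, r], y, mu[j], sigma2[r], ad.scale, rng, g
            )
            ad.record(rate)

        # conjugate draws for the hierarchy
        for r in range(R):
            j = r_idx[r]
            mu[j] = gibbs_update_mu(B[:, r], sigma2[r], prior, rng)
            draw = gibbs_update_sigma(B[:, r], mu[j], prior, rng)
            if draw >= SIGMA_FLOOR:
                sigma2[r] = draw

        # block random-walk Metropolis for fixed-coefficient means
        if F:
            ad = scales["mu_block"]
            delta = ad.scale * (chol @ rng.standard_normal(F))
            eta_prop = eta + Xf @ delta
            lse_prop = _log1pexp(eta_prop)
            d_ll = float(np.sum(y * (eta_prop - eta) - (lse_prop - lse)))
            mu_prop = mu[f_idx] + delta
            d_pr = float(
                -0.5
                * np.sum((mu_prop - prior.mean_loc) ** 2 - (mu[f_idx] - prior.mean_loc) ** 2)
                / prior.mean_var
            )
            if np.log(rng.random()) < d_ll + d_pr:
                mu[f_idx] = mu_prop
                eta, lse = eta_prop, lse_prop
                ad.record(1.0)
            else:
                ad.record(0.0)

        # group moves: translation and rescaling per random column
        for r in range(R):
            j = r_idx[r]
            ad = scales[f"shift:{labels[j]}"]
            delta = ad.scale * rng.standard_normal()
            eta_prop = eta + delta * Xr[:, r]
            lse_prop = _log1pexp(eta_prop)
            d_ll = float(np.sum(y * delta * Xr[:, r] - (lse_prop - lse)))
            mu_prop = mu[j] + delta
            d_pr = -0.5 * ((mu_prop - prior.mean_loc) ** 2 - (mu[j] - prior.mean_loc) ** 2) / prior.mean_var
            if np.log(rng.random()) < d_ll + d_pr:
                mu[j] = mu_prop
                B[:, r] += delta
                eta, lse = eta_prop, lse_prop
                ad.record(1.0)
            else:
                ad.record(0.0)

            ad = scales[f"scale:{labels[j]}"]
            eps = ad.scale * rng.standard_normal()
            t = np.exp(eps)
            if sigma2[r] * t >= SIGMA_FLOOR:
                root = np.sqrt(t)
                resid = B[:, r] - mu[j]
                d_eta = (root - 1.0) * resid[g] * Xr[:, r]
                eta_prop = eta + d_eta
                lse_prop = _log1pexp(eta_prop)
                d_ll = float(np.sum(y * d_eta - (lse_prop - lse)))
                # prior on Sigma plus the Jacobian of the joint rescaling map
                d_pr = -(c_ + 1.0) * eps - d_ * (1.0 / (sigma2[r] * t) - 1.0 / sigma2[r]) + eps
                if np.log(rng.random()) < d_ll + d_pr:
                    sigma2[r] *= t
                    B[:, r] = mu[j] + resid * root
                    eta, lse = eta_prop, lse_prop
                    ad.record(1.0)
                else:
                    ad.record(0.0)

        if it < config.burnin:
            if (it + 1) % config.adapt_interval == 0:
                for ad in scales.values():
                    ad.maybe_adapt()
        elif (it - config.burnin) % config.thin == 0:
            mu_out[out_i] = mu
            sig_out[out_i] = sigma2
            dev_out[out_i] = -2.0 * float(np.sum(y * eta - lse))
            out_i += 1
            beta_sum += B[g]
            beta_count += 1

    rates = {name: ad.acc / ad.count if ad.count else np.nan for name, ad in scales.items()}
    return mu_out[:out_i], sig_out[:out_i], dev_out[:out_i], beta_sum, beta_count, rates


def run_chain(
    dm: DesignMatrix,
    y: np.ndarray,
    prior: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    groups: np.ndarray | None = None,
) -> PosteriorDraws:
    """Run all configured MCMC chains and collect post-burn-in draws.

    Chain 1 starts at zeros; subsequent chains at maximum-likelihood
    fixed-logit estimates jittered by N(0, 0.5^2) — overdispersed starting
    points for the between-chain convergence diagnostic.

    By default random coefficients vary per observation.  ``groups`` (a
    label per observation, e.g. site or site-period) switches to group-level
    random parameters: riders in the same group share one realisation of
    each random coefficient, which makes the mixing SD far better identified
    than one Bernoulli trial per effect can.
    """
    prior = prior or PriorSpec()
    config = config or MCMCConfig()
    unknown = set(prior.random_set) - set(dm.columns)
    if unknown:
        raise KeyError(f"random_set labels not in design matrix: {sorted(unknown)}")
    y = np.asarray(y)
    if groups is None:
        g = np.arange(dm.n)
    else:
        if len(groups) != dm.n:
            raise ValueError("groups must have one label per observation")
        g = np.unique(np.asarray(groups), return_inverse=True)[1]
    ml_params = maximum_likelihood_logit(dm, y) if config.chains > 1 else np.zeros(dm.X.shape[1])

    mus, sigs, devs = [], [], []
    beta_sum = np.zeros((dm.n, len(prior.random_set)))
    beta_count = 0
    rate_acc: dict[str, list[float]] = {}
    for chain in range(config.chains):
        init = None
        if config.initial_values is not None:
            init = config.initial_values[chain]
        m, s, d, bs, bc, rates = _run_single_chain(
            dm, y, prior, config, chain, init, ml_params, g
        )
        mus.append(m)
        sigs.append(s)
        devs.append(d)
        beta_sum += bs
        beta_count += bc
        for k, v in rates.items():
            rate_acc.setdefault(k, []).append(v)

    draws = PosteriorDraws(
        columns=list(dm.columns),
        random_set=list(prior.random_set),
        mu=np.stack(mus),
        sigma2=np.stack(sigs),
        deviance=np.stack(devs),
        beta_mean=beta_sum / max(beta_count, 1),
        n_obs=dm.n,
        accept_rates={
            k: float(np.nanmean(v))
            for k, v in rate_acc.items()
            if not np.all(np.isnan(v))
        },
        seeds=[config.seed] * config.chains,
        fingerprint=_fingerprint(dm, y),
    )
    post_mean = draws.mu_pooled().mean(axis=0)
    if np.abs(post_mean).max() > 10:
        warnings.warn(
            "some posterior coefficient means exceed 10 in absolute value; the data may be "
            "(quasi-)separable, in which case the flat-ish prior lets the posterior drift",
            UserWarning,
            stacklevel=2,
        )
    return draws


def fit_fixed_logit(
    dm: DesignMatrix,
    y: np.ndarray,
    prior: PriorSpec | None = None,
    config: MCMCConfig | None = None,
) -> PosteriorDraws:
    """Fixed-parameter Bayesian logit: identical machinery, empty random set."""
    base = prior or PriorSpec()
    fixed_prior = PriorSpec(
        mean_loc=base.mean_loc,
        mean_var=base.mean_var,
        var_shape=base.var_shape,
        var_rate=base.var_rate,
        random_set=(),
    )
    return run_chain(dm, y, fixed_prior, config)


def gelman_rubin(draws: PosteriorDraws) -> dict[str, float]:
    """Potential scale reduction factor per mu_k and Sigma_k.

    Classic between/within-chain variance ratio; chains that are exactly
    constant (degenerate but converged) report 1.0.
    """
    if draws.n_chains < 2:
        raise ValueError("convergence diagnostic requires at least 2 chains")
    if draws.n_draws < 10:
        raise ValueError("need at least 10 post-burn-in draws per chain")

    def _psrf(x: np.ndarray) -> float:  # x: (chains, draws)
        m, nd = x.shape
        means = x.mean(axis=1)
        W = float(x.var(axis=1, ddof=1).mean())
        Bn = float(means.var(ddof=1))  # = B/n in the usual notation
        tiny = 1e-24 * max(float(np.abs(x).max()), 1.0) ** 2
        if W <= tiny:  # constant chains: degenerate but converged
            return 1.0 if Bn <= tiny else np.inf
        var_hat = (nd - 1) / nd * W + Bn
        return float(np.sqrt(var_hat / W))

    out: dict[str, float] = {}
    for j, label in enumerate(draws.columns):
        out[f"mu[{label}]"] = _psrf(draws.mu[:, :, j])
    for r, label in enumerate(draws.random_set):
        out[f"sigma2[{label}]"] = _psrf(draws.sigma2[:, :, r])
    return out


def dic(draws: PosteriorDraws, dm: DesignMatrix, y: np.ndarray) -> DICResult:
    """Conditional DIC from stored per-draw deviances and plug-in means."""
    if draws.n_draws == 0:
        raise ValueError("no post-burn-in draws")
    if draws.fingerprint and draws.fingerprint != _fingerprint(dm, y):
        raise ValueError("draws were produced from different data than supplied")
    dbar = float(draws.deviance.mean())
    mu_mean = draws.mu_pooled().mean(axis=0)
    full = np.tile(mu_mean, (dm.n, 1))
    if draws.random_set:
        r_idx = [draws.column_index(c) for c in draws.random_set]
        full[:, r_idx] = draws.beta_mean
    dhat = -2.0 * log_likelihood(full, dm, y)
    return DICResult(dbar=dbar, dhat=float(dhat), fingerprint=draws.fingerprint)
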