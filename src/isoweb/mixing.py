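"""Bayesian stable-isotope mixing model.

Infers the dietary proportions ``p = (p_1 .. p_K)`` of K basal sources for a
group of consumers from their (trophic-level corrected) delta13C / delta15N
values.  The observation model for consumer ``j`` and isotope ``X`` is

    delta_jX ~ Normal( sum_k p_k (mu_kX + lambda_X),
                       sum_k p_k^2 (sigma_kX^2 + tau_X^2) + eps_X^2 )

where ``mu_kX, sigma_kX`` are the source summaries, ``lambda_X`` and
``tau_X`` the mean and SD of the residual trophic fractionation (defaults
0 +/- 1.3 permil for carbon, 0 +/- 1.0 permil for nitrogen because the
consumers are pre-corrected), and ``eps_X`` a free residual SD with a
half-Normal(0, 5 permil) prior.  The prior on ``p`` is the flat
Dirichlet(1, .., 1).

Sampling is adaptive random-walk Metropolis on unconstrained additive
log-ratio coordinates (plus log residual SDs), run as several independent
chains whose convergence is checked with split-chain Gelman-Rubin R-hat and
Geweke z-scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError

__all__ = [
    "McmcSettings", "MixingResult", "DietMixingModel", "fit_mixing_model",
    "gelman_rubin", "geweke", "summarize_posterior",
]

log = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))

#: SD (permil) of the half-Normal prior on the residual error SDs.
RESIDUAL_PRIOR_SD = 5.0


@dataclass(frozen=True)
class McmcSettings:
    """Markov-chain settings for the mixing model.

    The long profile matches the published analysis (300k iterations, 200k
    burn-in, thinning 100); :meth:`desk` returns a desk-scale profile
    adequate for K <= 5 sources with well-separated signatures.
    """

    chains: int = 3
    iterations: int = 300_000
    burn_in: int = 200_000
    thin: int = 100
    step_scale: float = 0.25
    seed: int | None = None

    def __post_init__(self):
        if self.chains < 2:
            raise ConfigError("mcmc: chains must be >= 2")
        if not (0 <= self.burn_in < self.iterations):
            raise ConfigError("mcmc: burn_in must satisfy "
                              "0 <= burn_in < iterations")
        if self.thin < 1:
            raise ConfigError("mcmc: thin must be >= 1")
        if (self.iterations - self.burn_in) // self.thin < 500:
            raise ConfigError("mcmc: need >= 500 retained draws per chain")
        if self.step_scale <= 0:
            raise ConfigError("mcmc: step_scale must be positive")

    @classmethod
    def desk(cls, seed: int | None = None) -> "McmcSettings":
        """Desk-scale profile: 30k iterations, 10k burn-in, thin 20."""
        return cls(chains=3, iterations=30_000, burn_in=10_000, thin=20,
                   seed=seed)


@dataclass
class MixingResult:
    """Posterior summary of dietary proportions for one consumer group."""

    group: tuple                  # (area, season, taxon_group)
    sources: list
    draws: np.ndarray             # pooled (n_draws, K) simplex points
    medians: np.ndarray
    ci95: np.ndarray              # (K, 2) central credible bounds
    rhat: np.ndarray
    geweke_z: np.ndarray
    n_consumers: int
    converged: bool = True
    acceptance: float = float("nan")
    chain_draws: np.ndarray | None = field(default=None, repr=False)

    def summary(self) -> pd.DataFrame:
        """Tidy per-source table (medians and 95% CI, raw and percent)."""
        return pd.DataFrame({
            "source": self.sources,
            "median": self.medians,
            "ci95_lo": self.ci95[:, 0],
            "ci95_hi": self.ci95[:, 1],
            "median_pct": np.round(100 * self.medians).astype(int),
            "ci95_lo_pct": np.round(100 * self.ci95[:, 0]).astype(int),
            "ci95_hi_pct": np.round(100 * self.ci95[:, 1]).astype(int),
            "rhat": self.rhat,
            "geweke_z": self.geweke_z,
        })


def _softmax_alr(theta: np.ndarray) -> np.ndarray:
    """Map (C, K-1) additive log-ratio coordinates to (C, K) simplex."""
    full = np.concatenate([theta, np.zeros((theta.shape[0], 1))], axis=1)
    full -= full.max(axis=1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=1, keepdims=True)


class DietMixingModel:
    """Scikit-learn style estimator for the Bayesian diet mixing model.

    Parameters
    ----------
    settings : McmcSettings
        Chain configuration; defaults to the desk-scale profile.
    tdf_sd : (float, float)
        SD (permil) of the residual trophic fractionation per isotope,
        default ``(1.3, 1.0)``; its mean is zero (consumers must already be
        corrected to basal trophic level).

    After :meth:`fit`: ``draws_`` (pooled posterior simplex draws),
    ``medians_``, ``ci95_``, ``rhat_``, ``geweke_z_``, ``sources_``,
    ``converged_``, ``acceptance_``.
    """

    def __init__(self, settings: McmcSettings | None = None,
                 tdf_sd=(1.3, 1.0)):
        self.settings = settings
        self.tdf_sd = tdf_sd

    def get_params(self, deep: bool = True) -> dict:
        return {"settings": self.settings, "tdf_sd": self.tdf_sd}

    def set_params(self, **params) -> "DietMixingModel":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, source_mu, source_sd, sources=None) -> "DietMixingModel":
        """Fit the model to one consumer group.

        Parameters
        ----------
        X : (n, 2) array
            Corrected consumer (d13c, d15n) values; n >= 2.
        source_mu, source_sd : (K, 2) arrays
            Source means and SDs per isotope, row order = ``sources``.
        sources : list of str, optional
            Source names (defaults to ``source_1`` ..).
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        mu = np.atleast_2d(np.asarray(source_mu, dtype=float))
        sd = np.atleast_2d(np.asarray(source_sd, dtype=float))
        if X.shape[1] != 2 or mu.shape[1] != 2 or sd.shape[1] != 2:
            raise InputError("expected two isotope columns (d13c, d15n)")
        if mu.shape != sd.shape:
            raise InputError("source_mu and source_sd shapes differ")
        if np.any(sd < 0) or np.any(~np.isfinite(sd)):
            raise InputError("source SDs must be finite and >= 0")
        k = mu.shape[0]
        n = X.shape[0]
        self.sources_ = list(sources) if sources is not None \
            else [f"source_{i + 1}" for i in range(k)]
        if len(self.sources_) != k:
            raise InputError("len(sources) must match source_mu rows")
        settings = self.settings or McmcSettings.desk()
        if k == 1:
            # single source: the diet is degenerate, no sampling needed
            self.draws_ = np.ones((1000, 1))
            self.chain_draws_ = np.ones((settings.chains, 1000 //
                                         settings.chains or 1, 1))
            self.medians_ = np.ones(1)
            self.ci95_ = np.array([[1.0, 1.0]])
            self.rhat_ = np.array([np.nan])
            self.geweke_z_ = np.array([0.0])
            self.converged_ = True
            self.acceptance_ = float("nan")
            self.n_consumers_ = n
            return self
        if n < 2:
            raise InputError("need >= 2 consumers to fit the mixing model")
        chain_p, acc = _run_chains(X, mu, sd, np.asarray(self.tdf_sd, float),
                                   settings)
        self.chain_draws_ = chain_p             # (chains, n_keep, K)
        self.draws_ = chain_p.reshape(-1, k)
        self.medians_, self.ci95_ = summarize_posterior(self.draws_)
        self.rhat_ = np.array([gelman_rubin(chain_p[:, :, j])
                               for j in range(k)])
        # Geweke per parameter: most extreme z across chains (conservative)
        gz = np.empty(k)
        for j in range(k):
            zs = [geweke(chain_p[c, :, j]) for c in range(settings.chains)]
            gz[j] = zs[int(np.argmax(np.abs(zs)))]
        self.geweke_z_ = gz
        self.acceptance_ = acc
        self.converged_ = bool(np.all(np.nan_to_num(self.rhat_, nan=1.0)
                                      < 1.1))
        if not self.converged_:
            log.warning("mixing model flagged non-converged: max R-hat "
                        "%.3f", float(np.nanmax(self.rhat_)))
        self.n_consumers_ = n
        return self

    def result(self, group=("", "", "")) -> MixingResult:
        """Package the fitted posterior as a :class:`MixingResult`."""
        return MixingResult(group=tuple(group), sources=self.sources_,
                            draws=self.draws_, medians=self.medians_,
                            ci95=self.ci95_, rhat=self.rhat_,
                            geweke_z=self.geweke_z_,
                            n_consumers=self.n_consumers_,
                            converged=self.converged_,
                            acceptance=self.acceptance_,
                            chain_draws=self.chain_draws_)


def _run_chains(x, mu, sd, tau, settings: McmcSettings):
    """Vectorized adaptive random-walk Metropolis over all chains at once.

    State per chain: K-1 additive log-ratio coordinates of p plus the two
    log residual SDs.  During burn-in the per-chain step scale adapts toward
    a 30% acceptance rate and the proposal covariance adapts to the pooled
    empirical covariance of the visited states (the posterior is typically a
    narrow ridge in diet space, which an isotropic walk explores poorly);
    both are frozen at the end of burn-in.
    """
    c = settings.chains
    k = mu.shape[0]
    d = (k - 1) + 2
    n = x.shape[0]
    rng = np.random.default_rng(settings.seed)
    # sufficient statistics of the Normal likelihood per isotope
    sx = x.sum(axis=0)            # (2,)
    sxx = (x * x).sum(axis=0)     # (2,)
    var_k = sd * sd + tau * tau   # (K, 2) per-source total variance

    def log_post(theta, log_eps):
        p = _softmax_alr(theta)                       # (C, K)
        mean = p @ mu                                 # (C, 2)
        eps2 = np.exp(2.0 * log_eps)                  # (C, 2)
        var = (p * p) @ var_k + eps2                  # (C, 2)
        ss = sxx - 2.0 * mean * sx + n * mean * mean  # (C, 2)
        loglik = -0.5 * (n * (_LOG_2PI + np.log(var)) + ss / var)
        # Dirichlet(1) prior via the ALR Jacobian, half-Normal prior on eps
        lp_p = np.log(p).sum(axis=1)
        lp_eps = (-eps2 / (2.0 * RESIDUAL_PRIOR_SD ** 2)
                  + log_eps).sum(axis=1)
        return loglik.sum(axis=1) + lp_p + lp_eps, p

    theta = 0.1 * rng.standard_normal((c, k - 1))
    log_eps = np.log(1.0 + rng.uniform(0.0, 1.0, (c, 2)))
    lp, p = log_post(theta, log_eps)
    step = np.full(c, settings.step_scale)
    n_keep = (settings.iterations - settings.burn_in) // settings.thin
    kept = np.empty((c, n_keep, k))
    accepted = np.zeros(c)
    post_burn_proposals = 0
    store = 0
    target = 0.30
    chol = np.eye(d)
    state_sum = np.zeros(d)
    state_outer = np.zeros((d, d))
    n_acc = 0
    adapt_start = max(200, settings.burn_in // 10)
    for t in range(settings.iterations):
        z = rng.standard_normal((c, d)) @ chol.T
        theta_prop = theta + step[:, None] * z[:, :k - 1]
        log_eps_prop = log_eps + step[:, None] * z[:, k - 1:]
        lp_prop, p_prop = log_post(theta_prop, log_eps_prop)
        accept = np.log(rng.uniform(size=c)) < lp_prop - lp
        theta[accept] = theta_prop[accept]
        log_eps[accept] = log_eps_prop[accept]
        lp[accept] = lp_prop[accept]
        p[accept] = p_prop[accept]
        if t < settings.burn_in:
            # Robbins-Monro adaptation of the per-chain step scale
            gamma = min(0.05, 2.0 / np.sqrt(t + 10.0))
            step *= np.exp(gamma * (accept.astype(float) - target))
            states = np.concatenate([theta, log_eps], axis=1)
            state_sum += states.sum(axis=0)
            state_outer += states.T @ states
            n_acc += c
            if t >= adapt_start and t % 200 == 0:
                mean = state_sum / n_acc
                cov = state_outer / n_acc - np.outer(mean, mean)
                cov += 1e-6 * np.eye(d)
                try:
                    new_chol = np.linalg.cholesky(cov)
                    # normalize so step_scale keeps its magnitude meaning
                    scale = np.sqrt(np.trace(cov) / d)
                    chol = new_chol / scale
                except np.linalg.LinAlgError:
                    pass
        else:
            accepted += accept
            post_burn_proposals += 1
            if (t - settings.burn_in) % settings.thin == settings.thin - 1:
                kept[:, store, :] = p
                store += 1
    kept = kept[:, :store, :]
    acc_rate = float(accepted.mean() / max(post_burn_proposals, 1))
    return kept, acc_rate


def fit_mixing_model(consumers, sources, model_tdf_sd=(1.3, 1.0),
                     settings: McmcSettings | None = None,
                     group=("", "", "")) -> MixingResult:
    """Functional wrapper over :class:`DietMixingModel`.

    ``consumers`` is a DataFrame with ``d13c_corr``/``d15n_corr`` columns
    (or a plain (n, 2) array); ``sources`` a summary DataFrame with
    ``source, mu13, sd13, mu15, sd15`` columns (or ``(names, mu, sd)``).
    """
    if isinstance(consumers, pd.DataFrame):
        x = consumers[["d13c_corr", "d15n_corr"]].to_numpy(dtype=float)
    else:
        x = np.asarray(consumers, dtype=float)
    if isinstance(sources, pd.DataFrame):
        names = sources["source"].tolist()
        mu = sources[["mu13", "mu15"]].to_numpy(dtype=float)
        sd = sources[["sd13", "sd15"]].to_numpy(dtype=float)
    else:
        names, mu, sd = sources
    model = DietMixingModel(settings=settings, tdf_sd=model_tdf_sd)
    model.fit(x, mu, sd, sources=names)
    return model.result(group=group)


def gelman_rubin(chains) -> float:
    """Split-chain potential scale reduction factor (R-hat).

    ``chains`` is an (m, n) array of m parallel chains.  Each chain is split
    in half, and R-hat = sqrt(((n-1)/n * W + B/n) / W) computed over the 2m
    half-chains.  Returns NaN (with a warning) when every chain has zero
    variance.
    """
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    m, n = chains.shape
    if m < 2 or n < 10:
        raise InputError("gelman_rubin: need >= 2 chains of length >= 10")
    half = n // 2
    split = np.concatenate([chains[:, :half], chains[:, half:2 * half]],
                           axis=0)
    w = split.var(axis=1, ddof=1).mean()
    if w == 0:
        warnings.warn("gelman_rubin: zero within-chain variance, R-hat "
                      "undefined", stacklevel=2)
        return float("nan")
    b_over_n = split.mean(axis=1).var(ddof=1)
    var_plus = (half - 1) / half * w + b_over_n
    return float(np.sqrt(var_plus / w))


def geweke(chain, first_frac: float = 0.1, last_frac: float = 0.5) -> float:
    """Geweke convergence z-score of a single chain.

    Compares the mean of the first ``first_frac`` of the chain with the mean
    of the last ``last_frac`` using batch-means standard errors:
    ``z = (m_first - m_last) / sqrt(se_first^2 + se_last^2)``.  A constant
    chain returns 0 (degenerate, with a warning).
    """
    chain = np.asarray(chain, dtype=float).ravel()
    n = len(chain)
    if n < 100:
        raise InputError("geweke: chain length must be >= 100")
    if np.ptp(chain) == 0:
        warnings.warn("geweke: constant chain, z reported as 0",
                      stacklevel=2)
        return 0.0
    first = chain[:int(first_frac * n)]
    last = chain[n - int(last_frac * n):]

    def batch_se(seg):
        nb = max(4, int(np.sqrt(len(seg))))
        usable = (len(seg) // nb) * nb
        batches = seg[:usable].reshape(nb, -1).mean(axis=1)
        return np.sqrt(batches.var(ddof=1) / nb)

    se1, se2 = batch_se(first), batch_se(last)
    denom = np.sqrt(se1 ** 2 + se2 ** 2)
    if denom == 0:
        return 0.0
    return float((first.mean() - last.mean()) / denom)


def summarize_posterior(draws, credibility: float = 0.95):
    """Per-source posterior medians and central credible intervals.

    ``draws`` is an (M, K) matrix of simplex points, M >= 500.  Returns
    ``(medians, intervals)`` with ``intervals`` of shape (K, 2).
    """
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    if draws.shape[0] < 500:
        raise InputError("summarize_posterior: need >= 500 draws")
    if not (0.0 < credibility < 1.0):
        raise ConfigError("credibility must lie in (0, 1)")
    medians = np.median(draws, axis=0)
    lo = (1.0 - credibility) / 2.0
    intervals = np.quantile(draws, [lo, 1.0 - lo], axis=0).T
    return medians, intervals
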