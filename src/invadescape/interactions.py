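"""Stage-2 regression: how landscape-metric effects shift with invader traits.

For one landscape metric and one invasion response, the stage-1 posterior
mean coefficients (one per trait combination) become the response of a
Bayesian linear model on the four invasiveness traits:

    beta_hat_i ~ Normal(lambda + Z_i Phi, sigma^2)
    Phi_j, lambda ~ Normal(0, precision 0.001)
    sigma ~ Uniform(0.001, 30)

A trait interacts with the metric when the 95% equal-tailed credible
interval of its Phi excludes 0. Trait columns are centered and scaled before
fitting so Phi magnitudes are comparable across traits measured on
different raw scales (multipliers vs. frequencies).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DimensionError
from .lasso import MCMCConfig, MCMC_PRESETS, _draw_sigma2, gelman_rubin

__all__ = [
    "TRAIT_NAMES",
    "InteractionDesign",
    "InteractionPosterior",
    "fit_interaction_model",
    "relative_importance",
    "interaction_table",
]

TRAIT_NAMES = ("dispersal_mult", "growth_mult", "establishment_freq",
               "corridor_usage")


@dataclass
class InteractionDesign:
    """Stage-1 coefficients for one (metric, response) over the trait grid."""

    beta_hats: np.ndarray  # (m,) posterior means, one per trait combination
    Z: np.ndarray          # (m, 4) raw trait values, column order TRAIT_NAMES

    def __post_init__(self) -> None:
        self.beta_hats = np.asarray(self.beta_hats, dtype=float)
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.ndim != 2 or self.Z.shape[1] != len(TRAIT_NAMES):
            raise DimensionError("Z must be (m, 4) in trait order")
        if len(self.beta_hats) != len(self.Z):
            raise DimensionError("beta_hats and Z row counts differ")

    def standardized_Z(self) -> np.ndarray:
        """Centered/scaled trait columns; constant columns are centered only
        (their coefficient is then indistinguishable from the intercept and
        stays prior-shrunk near 0)."""
        mean = self.Z.mean(axis=0)
        sd = self.Z.std(axis=0)
        scale = np.maximum(np.abs(self.Z).max(axis=0), 1.0)
        constant = (np.ptp(self.Z, axis=0) == 0) | (sd < 1e-12 * scale)
        out = (self.Z - mean) / np.where(constant, 1.0, sd)
        out[:, constant] = 0.0
        return out


@dataclass
class InteractionPosterior:
    """Posterior of the intercept lambda and the four trait effects Phi."""

    lam: np.ndarray    # (chains, n)
    phi: np.ndarray    # (chains, n, 4)
    sigma: np.ndarray  # (chains, n)
    rhat: np.ndarray   # (6,): lambda, phi_1..4, sigma
    converged: bool

    @property
    def lam_mean(self) -> float:
        return float(self.lam.mean())

    @property
    def phi_mean(self) -> np.ndarray:
        return self.phi.reshape(-1, self.phi.shape[-1]).mean(axis=0)

    def phi_interval(self, level: float = 0.95) -> np.ndarray:
        a = 100 * (1 - level) / 2
        flat = self.phi.reshape(-1, self.phi.shape[-1])
        return np.percentile(flat, [a, 100 - a], axis=0).T

    @property
    def significant(self) -> np.ndarray:
        """Per-trait flag: 95% credible interval excludes 0."""
        ci = self.phi_interval()
        return (ci[:, 0] > 0) | (ci[:, 1] < 0)


def _run_normal_chain(X: np.ndarray, y: np.ndarray, prior_prec: np.ndarray,
                      iters: int, burnin: int, rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Gibbs for a Gaussian linear model with fixed Normal priors on the
    coefficient vector and a Uniform(0.001, 30) prior on sigma."""
    n, k = X.shape
    XtX = X.T @ X
    Xty = X.T @ y
    sigma2 = max(float(np.var(y)), 1e-6)
    coef_out = np.empty((iters, k))
    sig_out = np.empty(iters)
    for it in range(burnin + iters):
        A = XtX / sigma2
        A[np.diag_indices_from(A)] += prior_prec
        L = np.linalg.cholesky(A)
        mean = np.linalg.solve(A, Xty / sigma2)
        coef = mean + np.linalg.solve(L.T, rng.standard_normal(k))
        resid = y - X @ coef
        sigma2 = _draw_sigma2(n, float(resid @ resid), rng)
        if it >= burnin:
            coef_out[it - burnin] = coef
            sig_out[it - burnin] = np.sqrt(sigma2)
    return coef_out, sig_out


def fit_interaction_model(design: InteractionDesign,
                          mcmc: MCMCConfig = MCMC_PRESETS["reduced"],
                          seed: int = 0) -> InteractionPosterior:
    """Sample the posterior of (lambda, Phi, sigma) for one design."""
    m = len(design.beta_hats)
    if m < 8:
        raise ConfigurationError(
            f"interaction model needs >= 8 trait combinations, got {m}")
    if m < 30:
        import warnings
        warnings.warn(f"only {m} trait combinations; Phi will be imprecise",
                      stacklevel=2)
    Z = design.standardized_Z()
    X = np.column_stack([np.ones(m), Z])
    prior_prec = np.full(X.shape[1], 0.001)  # vague: variance 1000

    ss = np.random.SeedSequence([int(seed) % (2**63), 2])
    chains = [
        _run_normal_chain(X, design.beta_hats, prior_prec, mcmc.iters,
                          mcmc.burnin, np.random.default_rng(child))
        for child in ss.spawn(mcmc.chains)
    ]
    coef = np.stack([c[0] for c in chains])   # (chains, n, 5)
    sigma = np.stack([c[1] for c in chains])

    if mcmc.chains > 1:
        rhat = np.array(
            [gelman_rubin(coef[:, :, j]) for j in range(coef.shape[2])]
            + [gelman_rubin(sigma)]
        )
        converged = bool(np.all(rhat <= 1.1))
    else:
        rhat = np.full(coef.shape[2] + 1, np.nan)
        converged = True
    return InteractionPosterior(coef[:, :, 0], coef[:, :, 1:], sigma, rhat,
                                converged)


def relative_importance(beta_means: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Scale coefficient magnitudes relative to the strongest predictor.

    Returns (relative in [0, 1] with the argmax at exactly 1, signs in
    {-1, 0, +1}, all_zero flag). An all-zero vector maps to zeros and raises
    the flag instead of dividing by zero.
    """
    beta = np.asarray(beta_means, dtype=float)
    signs = np.sign(beta).astype(int)
    top = np.abs(beta).max()
    if top == 0:
        return np.zeros_like(beta), signs, True
    return np.abs(beta) / top, signs, False


def interaction_table(fits: dict[tuple[str, str], InteractionPosterior],
                      responses: tuple[str, ...],
                      metric_names: tuple[str, ...]
                      ) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Assemble the long results table: one row per
    (response, trait, metric) with Phi mean, CI bounds and significance.

    Missing (response, metric) fits are returned in a separate list rather
    than silently dropped; present rows keep the metric registry order.
    """
    rows = []
    missing = []
    for resp in responses:
        for metric in metric_names:
            post = fits.get((resp, metric))
            if post is None:
                missing.append((resp, metric))
                continue
            ci = post.phi_interval()
            sig = post.significant
            phi = post.phi_mean
            for t, trait in enumerate(TRAIT_NAMES):
                rows.append({
                    "response": resp,
                    "trait": trait,
                    "metric": metric,
                    "phi_mean": phi[t],
                    "ci_lower": ci[t, 0],
                    "ci_upper": ci[t, 1],
                    "significant": bool(sig[t]),
                })
    return pd.DataFrame(rows), missing
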