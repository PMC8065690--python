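"""Conjugate Gaussian location pair: the closed-form oracle model.

y_t ~ iid N(mu, 1) with mu ~ N(0, 1) under the unrestricted model G_U and
mu = 0 under the restricted model G_R. There are no latent variables and the
marginal likelihoods are available in closed form,

    ln BF_U,R = -(1/2) ln(T+1) + (sum y_t)^2 / (2 (T+1)),

so every estimator variant and the corrected arithmetic-mean marginal
likelihood can be validated against exact truth. Posterior draws of mu are
iid N(sum y / (T+1), 1/(T+1)) — no MCMC needed.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .draws import DrawMatrix
from .models import ModelDensities

__all__ = [
    "gaussian_models",
    "closed_form_log10_bf_ur",
    "posterior_mu_draws",
    "prior_mu_draws",
    "simulate_data",
]

LN10 = math.log(10.0)


def gaussian_models() -> tuple[ModelDensities, ModelDensities]:
    """(G_U, G_R) density interfaces; mu is the single (specific) parameter."""

    def sampling(y, params, latents):
        mu = np.asarray(params.get("mu", 0.0), dtype=float)
        resid2 = (y - (mu[..., None] if mu.ndim else mu)) ** 2
        return -0.5 * resid2.sum(axis=-1) - 0.5 * y.size * np.log(2.0 * np.pi)

    def param_prior(params):
        if "mu" not in params:
            return np.zeros(())
        mu = np.asarray(params["mu"], dtype=float)
        return -0.5 * mu**2 - 0.5 * np.log(2.0 * np.pi)

    g_u = ModelDensities(
        model_id="G_U",
        log_sampling_density=sampling,
        log_param_prior=param_prior,
        specific_params=("mu",),
    )
    g_r = ModelDensities(model_id="G_R", log_sampling_density=sampling)
    return g_u, g_r


def closed_form_log10_bf_ur(y: np.ndarray) -> float:
    """Exact decimal-log Bayes factor of mu-free against mu=0."""
    y = np.asarray(y, dtype=float)
    T = y.size
    ln_bf = -0.5 * math.log(T + 1.0) + y.sum() ** 2 / (2.0 * (T + 1.0))
    return ln_bf / LN10


def simulate_data(T: int, mu_true: float, rng: np.random.Generator) -> np.ndarray:
    return mu_true + rng.standard_normal(T)


def posterior_mu_draws(y: np.ndarray, k: int, rng: np.random.Generator) -> DrawMatrix:
    """iid draws from the exact posterior N(sum y/(T+1), 1/(T+1)) of G_U."""
    y = np.asarray(y, dtype=float)
    T = y.size
    mean = y.sum() / (T + 1.0)
    sd = 1.0 / math.sqrt(T + 1.0)
    return DrawMatrix(
        pd.DataFrame({"mu": rng.normal(mean, sd, size=k)}), source="posterior", model_id="G_U"
    )


def prior_mu_draws(k: int, rng: np.random.Generator) -> DrawMatrix:
    return DrawMatrix(
        pd.DataFrame({"mu": rng.standard_normal(k)}), source="prior", model_id="G_U"
    )
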