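"""Corrected arithmetic-mean estimator (CAME) of a marginal likelihood.

For a model whose latent variables have been integrated out analytically, the
marginal data density p(y) = E_prior[p(y|theta)] satisfies, for any region A
with positive posterior probability,

    p(y) * Pr(A|y) = E_prior[ p(y|theta) * I_A(theta) ],

so the prior-sample mean of the likelihood restricted to A, divided by the
posterior-sample fraction inside A, estimates p(y). Restricting the prior
average to a region where the likelihood is non-negligible removes the naive
prior-mean estimator's reliance on rare high-likelihood prior draws. With
A = the whole space the estimator reduces to the naive prior-mean estimator
bit-for-bit.

The region defaults to the hyper-cuboid spanned by the posterior sample
range ("auto"); quantile boxes are available via ``quantile``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
from scipy.special import logsumexp

from .core import LN10, _safe_nse
from .draws import DrawMatrix
from .errors import EmptyOverlapError
from .trim import TrimRegion

__all__ = ["MarginalLikelihoodEstimate", "came_log_marginal", "random_walk_metropolis"]

LogLik = Callable[[Mapping[str, np.ndarray]], np.ndarray]


@dataclass
class MarginalLikelihoodEstimate:
    """A decimal-log marginal-likelihood estimate with diagnostics."""

    log10_ml: float
    prob_region: float
    k_prior: int
    k_posterior: int
    nse_log10: float
    k_prior_inside: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.prob_region <= 1.0):
            raise ValueError("prob_region must lie in (0, 1]")
        if not np.isfinite(self.log10_ml):
            raise ValueError("log10_ml must be finite")

    def to_dict(self) -> dict:
        return {
            "log10_ml": self.log10_ml,
            "prob_region": self.prob_region,
            "k_prior": self.k_prior,
            "k_posterior": self.k_posterior,
            "k_prior_inside": self.k_prior_inside,
            "nse_log10": self.nse_log10,
            "convention": "decimal (base-10) logarithm",
        }


def _auto_region(posterior_draws: DrawMatrix, quantile: float | None) -> TrimRegion:
    box = {}
    for name in posterior_draws.columns:
        x = posterior_draws.column(name)
        if quantile is None:
            box[name] = (float(x.min()), float(x.max()))
        else:
            box[name] = (
                float(np.quantile(x, quantile)),
                float(np.quantile(x, 1.0 - quantile)),
            )
    return TrimRegion(box=box, provenance=(posterior_draws.model_id, posterior_draws.model_id))


def came_log_marginal(
    prior_draws: DrawMatrix,
    log_lik: LogLik,
    posterior_draws: DrawMatrix,
    region: TrimRegion | str = "auto",
    quantile: float | None = None,
    n_batches: int = 20,
) -> MarginalLikelihoodEstimate:
    """Corrected arithmetic-mean estimate of log10 p(y).

    Parameters
    ----------
    prior_draws
        Draws from the parameter prior p(theta).
    log_lik
        Batched evaluator of the latent-integrated log likelihood
        ln p(y|theta): mapping ``name -> (k,) array`` to a ``(k,)`` array.
    posterior_draws
        Draws from p(theta|y), used for the region box and for Pr(A|y).
    region
        A :class:`TrimRegion` (box only), or ``"auto"`` for the posterior
        sample-range hyper-cuboid (optionally shrunk to the ``quantile`` /
        ``1-quantile`` coordinatewise quantiles).
    """
    if isinstance(region, str):
        if region != "auto":
            raise ValueError(f"region must be a TrimRegion or 'auto', got {region!r}")
        region = _auto_region(posterior_draws, quantile)

    ll = np.asarray(log_lik(prior_draws.params_dict(prior_draws.columns)), dtype=float)
    if ll.shape != (prior_draws.k,):
        raise ValueError("log_lik must return one value per prior draw")
    inside = region.contains(prior_draws)
    n_inside = int(inside.sum())
    if n_inside == 0:
        raise EmptyOverlapError(
            "no prior draw falls inside the region A; the corrected "
            "arithmetic mean is undefined (enlarge the prior sample or A)"
        )
    k_prior = prior_draws.k
    log10_num = float((logsumexp(ll[inside]) - np.log(k_prior)) / LN10)

    p_post = float(region.contains(posterior_draws).mean())
    if p_post == 0.0:
        raise EmptyOverlapError("no posterior draw inside A: Pr(A|y) estimate is zero")

    nse_num = _safe_nse(ll, inside, n_batches)
    k_post = posterior_draws.k
    se_p = np.sqrt(p_post * (1.0 - p_post) / k_post)
    nse = float(np.sqrt(nse_num**2 + (se_p / (p_post * LN10)) ** 2))

    return MarginalLikelihoodEstimate(
        log10_ml=log10_num - float(np.log10(p_post)),
        prob_region=p_post,
        k_prior=k_prior,
        k_posterior=k_post,
        nse_log10=nse,
        k_prior_inside=n_inside,
    )


def random_walk_metropolis(
    log_post: Callable[[np.ndarray], float],
    x0: np.ndarray,
    n_iter: int,
    burn_in: int,
    rng: np.random.Generator,
    target_accept: float = 0.3,
    init_scale: float = 0.1,
) -> np.ndarray:
    """Gaussian random-walk Metropolis with scale adaptation during burn-in.

    The global proposal scale is adapted every 50 burn-in iterations toward
    ``target_accept`` and per-coordinate widths are refreshed from the
    running chain spread; both are frozen after burn-in so the retained chain
    is a valid Markov chain. Returns the ``(n_iter - burn_in, d)`` retained
    draws.
    """
    x = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    d = x.size
    scale = float(init_scale)
    widths = np.ones(d)
    lp = float(log_post(x))
    if not np.isfinite(lp):
        raise ValueError("log_post must be finite at the initial point")
    kept = np.empty((n_iter - burn_in, d))
    acc_window = 0
    history: list[np.ndarray] = []
    for it in range(n_iter):
        prop = x + scale * widths * rng.standard_normal(d)
        lp_prop = float(log_post(prop))
        if np.log(rng.uniform()) < lp_prop - lp:
            x, lp = prop, lp_prop
            acc_window += 1
        if it < burn_in:
            history.append(x.copy())
            if (it + 1) % 50 == 0:
                rate = acc_window / 50.0
                scale *= float(np.exp(1.2 * (rate - target_accept)))
                acc_window = 0
                if len(history) >= 200:
                    sd = np.std(np.asarray(history[-200:]), axis=0, ddof=1)
                    widths = np.where(sd > 0, sd, widths)
        else:
            kept[it - burn_in] = x
    return kept
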