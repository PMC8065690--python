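"""Model density interfaces.

A Bayesian model with latent variables is described to the estimators through
three log-density evaluators,

* ``log_sampling_density(y, params, latents)`` for ``p(y | theta, h, M)``,
* ``log_latent_prior(latents, params)``       for ``p(h | theta, M)``,
* ``log_param_prior(params)``                 for ``p(theta | M)``,

plus the partition of the parameter vector into coordinates *common* to a pair
of nested models (theta_R) and coordinates *specific* to the larger model
(theta_A), and the names of the latent coordinates h.

Evaluator contract
------------------
Evaluators are batched: ``params`` is a mapping ``name -> (k,) array``,
``latents`` a ``(k, T)`` array (or ``None`` for models without latents), and
the return value a ``(k,)`` array of natural-log densities. A zero density is
encoded as ``-inf``; ``+inf`` and NaN are contract violations. For
parameter-prior ratios, ``log_param_prior`` must accept a mapping containing
only the common coordinates and return the corresponding prior marginal
(exact under the assumed prior independence of theta_A and theta_R).

The estimators trust — and do not verify — the structural assumptions under
which each ratio variant is valid (shared latent space, prior independence,
matching priors on the shared block); these are the caller's responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional

import numpy as np

ParamMap = Mapping[str, np.ndarray]
SamplingDensity = Callable[[np.ndarray, ParamMap, Optional[np.ndarray]], np.ndarray]
LatentPrior = Callable[[np.ndarray, ParamMap], np.ndarray]
ParamPrior = Callable[[ParamMap], np.ndarray]

__all__ = ["ModelDensities"]


@dataclass
class ModelDensities:
    """The density evaluators and coordinate layout defining one model."""

    model_id: str
    log_sampling_density: SamplingDensity
    log_latent_prior: LatentPrior | None = None
    log_param_prior: ParamPrior | None = None
    common_params: tuple[str, ...] = ()
    specific_params: tuple[str, ...] = ()
    latent_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.common_params = tuple(self.common_params)
        self.specific_params = tuple(self.specific_params)
        self.latent_names = tuple(self.latent_names)
        groups = [self.common_params, self.specific_params, self.latent_names]
        seen: set[str] = set()
        for g in groups:
            for name in g:
                if name in seen:
                    raise ValueError(
                        f"coordinate {name!r} appears in more than one of "
                        "common_params/specific_params/latent_names"
                    )
                seen.add(name)

    @property
    def param_names(self) -> tuple[str, ...]:
        """All parameter coordinates, common first."""
        return self.common_params + self.specific_params

    @property
    def all_names(self) -> tuple[str, ...]:
        return self.param_names + self.latent_names

    # -- guarded evaluation ------------------------------------------------
    def _check(self, out: np.ndarray, k: int, what: str) -> np.ndarray:
        out = np.asarray(out, dtype=float)
        if out.shape in ((), (1,)):
            # constant density (e.g. a parameter-free model): broadcast to the batch
            out = np.broadcast_to(out.reshape(()), (k,)).copy()
        if out.shape != (k,):
            raise ValueError(
                f"{what} evaluator of model {self.model_id!r} returned shape "
                f"{out.shape}, expected ({k},)"
            )
        if np.isnan(out).any() or np.isposinf(out).any():
            raise ValueError(
                f"{what} evaluator of model {self.model_id!r} returned NaN or +inf; "
                "evaluators must return finite reals or -inf"
            )
        return out

    def sampling_logpdf(
        self, y: np.ndarray, params: ParamMap, latents: np.ndarray | None, k: int
    ) -> np.ndarray:
        return self._check(self.log_sampling_density(y, params, latents), k, "sampling-density")

    def latent_logpdf(self, latents: np.ndarray, params: ParamMap, k: int) -> np.ndarray:
        if self.log_latent_prior is None:
            raise ValueError(f"model {self.model_id!r} has no latent-prior evaluator")
        return self._check(self.log_latent_prior(latents, params), k, "latent-prior")

    def param_logpdf(self, params: ParamMap, k: int) -> np.ndarray:
        if self.log_param_prior is None:
            raise ValueError(f"model {self.model_id!r} has no parameter-prior evaluator")
        return self._check(self.log_param_prior(params), k, "parameter-prior")
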