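"""Latent-prior density ratio for the inverted-gamma MSF volatility factor.

In the hybrid IG-MSF-SBEKK volatility model the scalar latent factor follows

    ln h_t = phi * ln h_{t-1} + ln gamma_t,     gamma_t ~ iid IG(v/2, v/2),

so for phi = 0 the factors are iid inverted-gamma and the model reduces to the
t-SBEKK specification (Student-t conditional distribution). Comparing the two
latent priors over a path h_0, h_1, ..., h_T gives the closed-form ratio

    p(h | theta_U, M_U) / p(h | theta_R, M_R)
        = prod_{t=1..T} h_{t-1}^{v phi / 2} exp[ (v / (2 h_t)) (1 - h_{t-1}^phi) ],

which plugs into the generic trimmed estimators as a latent-prior ratio. The
initial factor h_0 is drawn from the phi = 0 stationary law IG(v/2, v/2) by
default and is exposed so users can condition on a fixed value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = ["MSFLatentPath", "igmsf_latent_log_ratio", "simulate_msf_path", "RATIO_PLUGINS"]


@dataclass
class MSFLatentPath:
    """A latent volatility-factor path h_0..h_T with its (v, phi) parameters."""

    h: np.ndarray  # length T+1, h[0] is the initial condition h_0
    v: float
    phi: float

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        if self.h.ndim != 1 or self.h.size < 2:
            raise ValueError("path must contain h_0 and at least one h_t")
        if (self.h <= 0).any():
            raise DomainError("all latent factors h_t must be > 0")
        if self.v <= 0:
            raise DomainError("v must be > 0")
        if not abs(self.phi) < 1:
            raise DomainError("|phi| must be < 1")

    @property
    def T(self) -> int:
        return self.h.size - 1


def igmsf_latent_log_ratio(path: MSFLatentPath) -> float:
    """Natural log of the IG-MSF over t-SBEKK latent-prior density ratio.

    ``sum_{t=1..T} [ (v phi / 2) ln h_{t-1} + (v / (2 h_t)) (1 - h_{t-1}^phi) ]``.
    Identically 0 for phi = 0 (the models coincide) and for unit paths.
    """
    h_prev = path.h[:-1]
    h_cur = path.h[1:]
    v, phi = path.v, path.phi
    terms = 0.5 * v * phi * np.log(h_prev) + 0.5 * v / h_cur * (1.0 - h_prev**phi)
    return float(terms.sum())


def simulate_msf_path(
    T: int,
    v: float,
    phi: float,
    seed: int | np.random.Generator | None = None,
) -> MSFLatentPath:
    """Simulate h_t = h_{t-1}^phi * gamma_t with gamma_t ~ IG(v/2, v/2).

    Requires v > 2 so the stationary inverted-gamma mean v/(v-2) exists
    (matching the prior truncation used with this model class).
    """
    if v <= 2:
        raise DomainError("v must be > 2 for the IG stationary mean to exist")
    if not abs(phi) < 1:
        raise DomainError("|phi| must be < 1")
    if T < 1:
        raise DomainError("T must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # X ~ Gamma(v/2, rate v/2)  =>  1/X ~ IG(v/2, v/2)
    gammas = 1.0 / rng.gamma(0.5 * v, 2.0 / v, size=T + 1)
    h = np.empty(T + 1)
    h[0] = gammas[0]
    for t in range(1, T + 1):
        h[t] = h[t - 1] ** phi * gammas[t]
    return MSFLatentPath(h, v, phi)


def _igmsf_plugin(h: np.ndarray, v: float, phi: float) -> float:
    return igmsf_latent_log_ratio(MSFLatentPath(np.asarray(h, float), v, phi))


#: Named ratio plug-ins usable from the CLI with a path file.
RATIO_PLUGINS = {"igmsf_vs_tsbekk": _igmsf_plugin}
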