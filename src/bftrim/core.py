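"""Bayes-factor estimation from draw tables and density evaluators.

The Bayes factor BF_ij = p(y|M_i)/p(y|M_j) equals the posterior expectation,
under model M_j, of the density ratio

    r_ij(theta, h) = p(y|theta,h,M_i) p(h|theta,M_i) p(theta|M_i)
                     ------------------------------------------------
                     p(y|theta,h,M_j) p(h|theta,M_j) p(theta|M_j),

so an arithmetic mean of r_ij over posterior draws estimates BF_ij. In high
dimensions that raw mean is pseudo-biased — a few extreme ratio values
dominate, much as with the harmonic-mean estimator. The remedy implemented
here trims the draws to a subset D of the parameter/latent space and divides
the trimmed mean by Monte-Carlo estimates of the posterior (and, where
relevant, prior) probability of D:

    BF_ij,D = (1 / Pr(D|y,M_i)) * (1/k) * sum_q I_D(theta_q, h_q) r_ij(q).

For nested pairs (an unrestricted model M_U with specific parameters theta_A
on top of the shared block theta_R of the restricted model M_R), the full
ratio collapses — depending on which structural assumption differs between
the models — to a latent-prior ratio, a parameter-prior ratio, or a
sampling-density ratio; all are available through ``ratio_kind``.

All arithmetic is carried out in natural-log space with log-sum-exp; only
reported quantities are converted to decimal logarithms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .draws import DrawMatrix, join_columns
from .errors import (
    DegenerateSupportError,
    EmptySubsetError,
    EstimateZeroError,
    InsufficientDrawsError,
    InvalidCorrectionError,
    SchemaError,
    TailPointError,
    UsageError,
    ZeroProbabilityError,
)
from .models import ModelDensities

LN10 = np.log(10.0)

RATIO_KINDS = ("full", "latent_prior", "param_prior", "sampling_density")

__all__ = [
    "LogRatioSeries",
    "CorrectionTerm",
    "BFEstimate",
    "ReciprocalCheck",
    "log_ratio_terms",
    "bf_uncorrected",
    "bf_corrected",
    "prob_subset",
    "estimate_bf_nested",
    "nse_log10",
    "reciprocal_consistency",
    "posterior_model_probs",
    "savage_dickey_log_bf",
]


# ---------------------------------------------------------------------------
# value types
# ---------------------------------------------------------------------------
@dataclass
class LogRatioSeries:
    """Natural-log density-ratio values ln r_ij evaluated at k draws."""

    values: np.ndarray
    ratio_kind: str
    direction: tuple[str, str]  # (numerator model id, denominator model id)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("LogRatioSeries requires a non-empty 1-D value array")
        if np.isnan(self.values).any() or np.isposinf(self.values).any():
            raise ValueError("log-ratio values must be real or -inf")
        if self.ratio_kind not in RATIO_KINDS:
            raise ValueError(f"unknown ratio_kind {self.ratio_kind!r}")

    def __len__(self) -> int:
        return self.values.size

    def flipped(self) -> "LogRatioSeries":
        """The reciprocal ratio series (numerator and denominator swapped).

        Only valid when no value is -inf (a zero numerator cannot become a
        denominator).
        """
        if np.isneginf(self.values).any():
            idx = int(np.flatnonzero(np.isneginf(self.values))[0])
            raise DegenerateSupportError(idx)
        return LogRatioSeries(-self.values, self.ratio_kind, self.direction[::-1])


@dataclass
class CorrectionTerm:
    """One subset-probability correction applied to a trimmed mean."""

    label: str
    probability: float
    direction: str  # "multiply" or "divide"
    mc_se: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.probability <= 1.0):
            raise InvalidCorrectionError(
                f"correction {self.label!r} has probability {self.probability}; "
                "must lie in (0, 1]"
            )
        if self.direction not in ("multiply", "divide"):
            raise ValueError(f"invalid correction direction {self.direction!r}")

    @property
    def log10_contribution(self) -> float:
        sign = 1.0 if self.direction == "multiply" else -1.0
        return sign * float(np.log10(self.probability))


@dataclass
class BFEstimate:
    """A directional decimal-log Bayes-factor estimate with diagnostics."""

    log10_bf: float
    nse_log10: float
    k_total: int
    k_retained: int
    direction: tuple[str, str]
    corrections: list[CorrectionTerm] = field(default_factory=list)
    ratio_kind: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.k_retained <= self.k_total):
            raise ValueError("k_retained must lie in [0, k_total]")
        if self.nse_log10 < 0:
            raise ValueError("nse_log10 must be >= 0")

    @property
    def log10_corrections(self) -> list[tuple[str, float]]:
        """(label, probability) pairs of the applied corrections."""
        return [(c.label, c.probability) for c in self.corrections]

    def to_dict(self) -> dict:
        return {
            "log10_bf": self.log10_bf,
            "nse_log10": self.nse_log10,
            "k_total": self.k_total,
            "k_retained": self.k_retained,
            "direction": list(self.direction),
            "ratio_kind": self.ratio_kind,
            "corrections": [
                {
                    "label": c.label,
                    "probability": c.probability,
                    "direction": c.direction,
                    "mc_se": c.mc_se,
                }
                for c in self.corrections
            ],
            "convention": "decimal (base-10) logarithm",
        }


@dataclass
class ReciprocalCheck:
    """Consistency diagnostic for a pair of opposite-direction estimates."""

    discrepancy_log10: float
    combined_nse: float
    tol_in_nse: float
    passed: bool


# ---------------------------------------------------------------------------
# ratio evaluation
# ---------------------------------------------------------------------------
def _latents_of(draws: DrawMatrix, model: ModelDensities) -> np.ndarray | None:
    if not model.latent_names:
        return None
    return draws.array(model.latent_names)


def log_ratio_terms(
    draws: DrawMatrix,
    num: ModelDensities,
    den: ModelDensities,
    ratio_kind: str,
    y: np.ndarray | None = None,
) -> LogRatioSeries:
    """Evaluate ln r = ln(numerator density / denominator density) per draw.

    ``ratio_kind`` selects which density component(s) enter the ratio:

    * ``"full"``             — all three components of each model;
    * ``"latent_prior"``     — p(h|theta, num) / p(h|theta, den);
    * ``"param_prior"``      — prior marginal ratio on the shared block;
    * ``"sampling_density"`` — p(y|theta, h, num) / p(y|theta, h, den).

    A zero numerator density yields ``-inf``; a zero denominator density is
    an error (the ratio is undefined there), raised with the draw index.
    """
    if ratio_kind not in RATIO_KINDS:
        raise ValueError(f"unknown ratio_kind {ratio_kind!r}; one of {RATIO_KINDS}")
    k = draws.k

    def params_for(model: ModelDensities, names) -> dict[str, np.ndarray]:
        try:
            return draws.params_dict(names)
        except SchemaError as exc:
            raise SchemaError(
                f"{exc.args[0]} (required by model {model.model_id!r} for "
                f"ratio_kind={ratio_kind!r})"
            ) from None

    if ratio_kind == "sampling_density":
        if y is None:
            raise ValueError("sampling-density ratios require the observation vector y")
        ln_num = num.sampling_logpdf(
            np.asarray(y, float), params_for(num, num.param_names), _latents_of(draws, num), k
        )
        ln_den = den.sampling_logpdf(
            np.asarray(y, float), params_for(den, den.param_names), _latents_of(draws, den), k
        )
    elif ratio_kind == "latent_prior":
        h_num = _latents_of(draws, num)
        h_den = _latents_of(draws, den)
        if h_num is None or h_den is None:
            raise ValueError("latent-prior ratios require models with latent coordinates")
        ln_num = num.latent_logpdf(h_num, params_for(num, num.param_names), k)
        ln_den = den.latent_logpdf(h_den, params_for(den, den.param_names), k)
    elif ratio_kind == "param_prior":
        shared = tuple(n for n in num.common_params if n in den.common_params)
        if not shared:
            raise ValueError("param-prior ratios require a shared common-parameter block")
        ln_num = num.param_logpdf(params_for(num, shared), k)
        ln_den = den.param_logpdf(params_for(den, shared), k)
    else:  # full
        if y is None:
            raise ValueError("full ratios require the observation vector y")
        y = np.asarray(y, float)

        def full_logpdf(model: ModelDensities) -> np.ndarray:
            p = params_for(model, model.param_names)
            h = _latents_of(draws, model)
            out = model.sampling_logpdf(y, p, h, k)
            if model.latent_names:
                out = out + model.latent_logpdf(h, p, k)
            if model.log_param_prior is not None and model.param_names:
                out = out + model.param_logpdf(p, k)
            return out

        ln_num = full_logpdf(num)
        ln_den = full_logpdf(den)

    if np.isneginf(ln_den).any():
        idx = int(np.flatnonzero(np.isneginf(ln_den))[0])
        raise DegenerateSupportError(idx)
    with np.errstate(invalid="ignore"):
        values = ln_num - ln_den
    return LogRatioSeries(values, ratio_kind, (num.model_id, den.model_id))


# ---------------------------------------------------------------------------
# numerical standard error (batch means)
# ---------------------------------------------------------------------------
def _batch_log10_means(
    values: np.ndarray, indicators: np.ndarray | None, n_batches: int
) -> np.ndarray:
    """Per-batch log10 of the (indicator-masked, /k_batch) arithmetic mean."""
    chunks = np.array_split(np.arange(values.size), n_batches)
    out = []
    for idx in chunks:
        v = values[idx]
        if indicators is not None:
            v = v[indicators[idx]]
        if v.size == 0 or np.all(np.isneginf(v)):
            continue  # an empty/zero batch carries no log-scale information
        out.append((logsumexp(v) - np.log(idx.size)) / LN10)
    return np.asarray(out)


def nse_log10(
    ratios: LogRatioSeries | np.ndarray,
    indicators: np.ndarray | None = None,
    n_batches: int = 20,
) -> float:
    """Batch-means numerical standard error of the decimal-log estimate.

    The (retained) ratio series is split into ``n_batches`` contiguous
    batches, the decimal-log arithmetic-mean estimate is computed per batch,
    and sd/sqrt(n_batches) over the batch estimates is returned. Contiguous
    batching respects Markov-chain autocorrelation in the usual batch-means
    fashion.
    """
    values = ratios.values if isinstance(ratios, LogRatioSeries) else np.asarray(ratios, float)
    if values.size < 2 * n_batches:
        raise InsufficientDrawsError(
            f"batch-means NSE needs k >= 2*n_batches ({2 * n_batches}); got k={values.size}"
        )
    batch_vals = _batch_log10_means(values, indicators, n_batches)
    if batch_vals.size < 2:
        raise InsufficientDrawsError(
            "fewer than 2 batches contained retained draws; cannot form an NSE"
        )
    return float(np.std(batch_vals, ddof=1) / np.sqrt(batch_vals.size))


def _safe_nse(values: np.ndarray, indicators: np.ndarray | None, n_batches: int) -> float:
    """NSE with batch count adapted to short series (0.0 when k < 4)."""
    k = values.size
    nb = min(n_batches, k // 2)
    if nb < 2:
        return 0.0
    try:
        return nse_log10(values, indicators, nb)
    except InsufficientDrawsError:
        return 0.0


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------
def bf_uncorrected(ratios: LogRatioSeries, n_batches: int = 20) -> BFEstimate:
    """Plain arithmetic-mean estimator: log10( (1/k) sum_q r(q) )."""
    values = ratios.values
    k = values.size
    if np.all(np.isneginf(values)):
        raise EstimateZeroError(
            "all ratio terms are zero: the arithmetic-mean estimate is 0 "
            "(log BF = -inf); refusing to report it silently"
        )
    log10_bf = float((logsumexp(values) - np.log(k)) / LN10)
    return BFEstimate(
        log10_bf=log10_bf,
        nse_log10=_safe_nse(values, None, n_batches),
        k_total=k,
        k_retained=k,
        direction=ratios.direction,
        ratio_kind=ratios.ratio_kind,
    )


def bf_corrected(
    ratios: LogRatioSeries,
    indicators: np.ndarray,
    corrections: list[CorrectionTerm],
    n_batches: int = 20,
) -> BFEstimate:
    """Trimmed, probability-corrected arithmetic-mean estimator.

    Computes ``log10[(1/k) sum_q I(q) r(q)]`` plus the signed decimal logs of
    the supplied correction probabilities. The mean divides by the *total*
    draw count k, not the retained count: when the draws have instead been
    pre-truncated to D (rejection from the full run), the caller passes
    all-true indicators and supplies the corresponding Pr(D|y, M_j)-type
    correction explicitly — the two forms are algebraically equivalent.
    """
    values = ratios.values
    indicators = np.asarray(indicators, dtype=bool)
    if indicators.shape != values.shape:
        raise ValueError("indicators must align one-to-one with the ratio series")
    k = values.size
    k_ret = int(indicators.sum())
    if k_ret == 0:
        raise EmptySubsetError("no draws retained inside the trimming subset D")
    masked = values[indicators]
    if np.all(np.isneginf(masked)):
        raise EstimateZeroError("all retained ratio terms are zero")
    log10_mean = float((logsumexp(masked) - np.log(k)) / LN10)
    log10_bf = log10_mean + sum(c.log10_contribution for c in corrections)
    nse = _safe_nse(values, indicators, n_batches)
    # fold the corrections' Monte-Carlo error in by the delta method
    extra = sum((c.mc_se / (c.probability * LN10)) ** 2 for c in corrections)
    nse = float(np.sqrt(nse**2 + extra))
    return BFEstimate(
        log10_bf=log10_bf,
        nse_log10=nse,
        k_total=k,
        k_retained=k_ret,
        direction=ratios.direction,
        corrections=list(corrections),
        ratio_kind=ratios.ratio_kind,
    )


def prob_subset(
    draws: DrawMatrix,
    region,
    ratios: LogRatioSeries | None = None,
) -> tuple[float, float]:
    """Monte-Carlo probability of the trimming subset D under a draw set.

    Returns ``(retained/k, sqrt(p(1-p)/k))`` — a binomial standard error that
    ignores draw autocorrelation (flagged design choice; it is reported as a
    diagnostic, not used for inference).
    """
    if region.log_band is not None and ratios is None:
        raise ValueError("region has a log-ratio band: the ratio series is required")
    inside = region.contains(draws, ratios)
    k = draws.k
    p = float(inside.sum()) / k
    if p == 0.0:
        raise ZeroProbabilityError(
            "no draws inside the subset D: the probability correction is undefined"
        )
    return p, float(np.sqrt(p * (1.0 - p) / k))


# ---------------------------------------------------------------------------
# nested-pair orchestration
# ---------------------------------------------------------------------------
def _box_fraction(draws: DrawMatrix, region, names) -> float:
    """Fraction of draws inside the box restricted to the given coordinates."""
    inside = np.ones(draws.k, dtype=bool)
    for name in names:
        if name not in region.box:
            continue
        lo, hi = region.box[name]
        x = draws.column(name)
        inside &= (x >= lo) & (x <= hi)
    return float(inside.mean())


def estimate_bf_nested(
    direction: str,
    ratio_kind: str,
    *,
    models: tuple[ModelDensities, ModelDensities],
    y: np.ndarray | None,
    draws_u: DrawMatrix | None = None,
    draws_r: DrawMatrix | None = None,
    prior_specific: DrawMatrix | None = None,
    region=None,
    corrected: bool = True,
    include_latents: bool = True,
    use_band: bool = True,
    n_batches: int = 20,
    series_u: LogRatioSeries | None = None,
    series_r: LogRatioSeries | None = None,
) -> BFEstimate:
    """Estimate the Bayes factor between a nested model pair.

    Parameters
    ----------
    direction
        ``"R_vs_U"`` (restricted over unrestricted; averages the ratio over
        the M_U posterior) or ``"U_vs_R"`` (averages over M_R posterior draws
        paired row-by-row with independent prior draws of the specific
        parameters theta_A).
    models
        ``(M_U, M_R)`` density interfaces; M_U's ``specific_params`` are the
        theta_A block.
    draws_u, draws_r, prior_specific
        Posterior draws of M_U, posterior draws of M_R (may be ``None`` when
        M_R has no free coordinates), and prior draws of theta_A. The
        corrected variants need all streams that enter either the trimmed
        mean or the correction probabilities for the chosen direction.
    region
        A prebuilt :class:`~bftrim.trim.TrimRegion`; built automatically from
        the two sampler outputs when omitted and ``corrected=True``.
    corrected
        ``False`` computes the plain arithmetic-mean estimator instead.
    series_u, series_r
        Optional precomputed U-over-R log-ratio series for ``draws_u`` and
        for the joined R-side table (avoids re-evaluating the densities when
        several estimators share one pair of sampler outputs).

    Notes
    -----
    The correction wiring follows the identities for the chosen direction:
    ``U_vs_R`` divides the trimmed mean by Pr(D|y,M_U); ``R_vs_U`` divides by
    Pr(D_R|y,M_R) * Pr(D_A|M_U), estimated jointly under the product measure
    of the prior theta_A draws and the M_R posterior draws (the band couples
    theta_A with the shared block, so only the product is identified; the
    reported split is exact for the theta_A box factor).
    """
    from .trim import build_trim_region  # deferred: trim imports core types

    if direction not in ("R_vs_U", "U_vs_R"):
        raise ValueError(f"direction must be 'R_vs_U' or 'U_vs_R', got {direction!r}")
    model_u, model_r = models
    joined_r = None
    if draws_r is not None or prior_specific is not None:
        joined_r = join_columns(prior_specific, draws_r)

    if not corrected:
        if direction == "R_vs_U":
            if draws_u is None:
                raise ValueError("R_vs_U needs posterior draws of the unrestricted model")
            if series_u is None:
                series_u = log_ratio_terms(draws_u, model_u, model_r, ratio_kind, y)
            series = series_u.flipped()
        else:
            if joined_r is None:
                raise ValueError(
                    "U_vs_R needs restricted-model posterior draws and/or prior "
                    "draws of the specific parameters"
                )
            if series_r is None:
                series_r = log_ratio_terms(joined_r, model_u, model_r, ratio_kind, y)
            series = series_r
        return bf_uncorrected(series, n_batches)

    if draws_u is None or joined_r is None:
        raise ValueError(
            "corrected estimators need both samplers' outputs: draws_u and "
            "(draws_r and/or prior_specific)"
        )
    if series_u is None:
        series_u = log_ratio_terms(draws_u, model_u, model_r, ratio_kind, y)
    if series_r is None:
        series_r = log_ratio_terms(joined_r, model_u, model_r, ratio_kind, y)
    if region is None:
        region = build_trim_region(
            draws_u,
            joined_r,
            models=(model_u, model_r),
            ratio_kind=ratio_kind,
            y=y,
            include_latents=include_latents,
            with_band=use_band,
            series_m1=series_u,
            series_m2=series_r,
        )

    if direction == "U_vs_R":
        # trimmed mean over (prior theta_A, M_R posterior); divide by Pr(D|y,M_U)
        indicators = region.contains(joined_r, series_r)
        p_u, se_u = prob_subset(draws_u, region, series_u)
        corrections = [CorrectionTerm("Pr(D|y,M_U)", p_u, "divide", se_u)]
        return bf_corrected(series_r, indicators, corrections, n_batches)

    # R_vs_U: trimmed mean over M_U posterior; divide by the product-measure
    # probability of D under prior theta_A (x) M_R posterior.
    indicators = region.contains(draws_u, series_u)
    p_joint, se_joint = prob_subset(joined_r, region, series_r)
    specific = model_u.specific_params
    p_a = _box_fraction(joined_r, region, specific) if specific else 1.0
    if p_a <= 0.0:
        raise ZeroProbabilityError("no prior draws of theta_A inside the box")
    p_r = min(p_joint / p_a, 1.0)
    corrections = [
        CorrectionTerm("Pr(D_R|y,M_R)", p_r, "divide", se_joint),
        CorrectionTerm("Pr(D_A|M_U)", p_a, "divide", 0.0),
    ]
    try:
        flipped = series_u.flipped()
    except DegenerateSupportError:
        raise
    return bf_corrected(flipped, indicators, corrections, n_batches)


def reciprocal_consistency(
    bf_ij: BFEstimate, bf_ji: BFEstimate, tol_in_nse: float = 4.0
) -> ReciprocalCheck:
    """Check |log10 BF_ij + log10 BF_ji| against the combined NSE.

    BF_ij = 1/BF_ji exactly, so opposite-direction estimates should agree up
    to Monte-Carlo error; a large discrepancy indicates a numerically
    inadequate choice of the trimming subset D or too small a sample.
    """
    if bf_ij.direction == bf_ji.direction or bf_ij.direction != bf_ji.direction[::-1]:
        raise UsageError(
            f"reciprocal check needs opposite directions; got {bf_ij.direction} "
            f"and {bf_ji.direction}"
        )
    disc = abs(bf_ij.log10_bf + bf_ji.log10_bf)
    combined = float(np.hypot(bf_ij.nse_log10, bf_ji.nse_log10))
    passed = disc <= tol_in_nse * combined if combined > 0 else disc == 0.0
    return ReciprocalCheck(disc, combined, tol_in_nse, passed)


# ---------------------------------------------------------------------------
# model probabilities and Savage–Dickey
# ---------------------------------------------------------------------------
def posterior_model_probs(prior_probs, bf_vs_reference) -> np.ndarray:
    """Posterior model probabilities from Bayes factors against a reference.

    ``p(M_i|y) = p(M_i) B_ik / sum_j p(M_j) B_jk`` — invariant to the choice
    of reference model k.
    """
    prior = np.asarray(prior_probs, dtype=float)
    bf = np.asarray(bf_vs_reference, dtype=float)
    if prior.shape != bf.shape or prior.ndim != 1:
        raise ValueError("prior_probs and bf_vs_reference must be 1-D of equal length")
    if (prior <= 0).any() or (bf <= 0).any():
        raise ValueError("prior probabilities and Bayes factors must be positive")
    if abs(prior.sum() - 1.0) > 1e-9:
        raise ValueError("prior probabilities must sum to 1")
    w = prior * bf
    return w / w.sum()


def savage_dickey_log_bf(
    posterior_scalar_draws,
    prior_log_density_at_point: float,
    point: float = 0.0,
    bins: str | int = "fd",
) -> float:
    """Savage–Dickey decimal-log Bayes factor for a point restriction.

    Estimates the marginal posterior density of the restriction parameter at
    ``point`` from a histogram of the sampled values (Freedman–Diaconis bin
    width by default) and returns ``log10(posterior density / prior
    density)`` — the Bayes factor of the restricted against the unrestricted
    model. ``prior_log_density_at_point`` is the natural-log prior density.

    Not reliable when ``point`` lies in the tail of the posterior; a point
    outside the draw range, or in an empty bin, raises ``TailPointError``.
    """
    draws = np.asarray(posterior_scalar_draws, dtype=float).ravel()
    if draws.size < 2:
        raise ValueError("need at least 2 posterior draws")
    if draws.size < 1000:
        warnings.warn(
            "fewer than 1000 posterior draws: the histogram density estimate "
            "at the restriction point may be unreliable",
            stacklevel=2,
        )
    if not (draws.min() <= point <= draws.max()):
        raise TailPointError(
            f"restriction point {point} lies outside the sampled range "
            f"[{draws.min()}, {draws.max()}]"
        )
    edges = np.histogram_bin_edges(draws, bins=bins)
    dens, edges = np.histogram(draws, bins=edges, density=True)
    idx = min(int(np.searchsorted(edges, point, side="right")) - 1, dens.size - 1)
    idx = max(idx, 0)
    if dens[idx] == 0.0:
        raise TailPointError(
            f"the histogram bin containing {point} is empty; the Savage–Dickey "
            "density estimate is undefined there"
        )
    return float(np.log10(dens[idx]) - prior_log_density_at_point / LN10)
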