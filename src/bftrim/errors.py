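"""Exception hierarchy.

Every failure mode that the estimators can hit (empty trimming subset, zero
correction probability, undefined density ratio, ...) raises a distinct class so
callers can react to — rather than silently propagate — infinities.
"""


class BFTrimError(Exception):
    """Base class for all package errors."""


class SchemaError(BFTrimError, KeyError):
    """A draw table is missing a column that an evaluator or region requires."""


class ParseError(BFTrimError, ValueError):
    """A draw-table file is malformed (ragged row, non-numeric cell, bad header)."""


class DomainError(BFTrimError, ValueError):
    """An argument is outside the mathematical domain (e.g. v <= 0, h <= 0)."""


class DegenerateSupportError(BFTrimError):
    """The denominator density is zero at a draw, so the ratio is undefined there."""

    def __init__(self, draw_index: int, message: str | None = None):
        self.draw_index = draw_index
        super().__init__(
            message
            or f"denominator density is zero at draw index {draw_index}; "
            "the density ratio is undefined on the sampled support"
        )


class EstimateZeroError(BFTrimError):
    """Every ratio term is zero: the arithmetic-mean estimate is 0 (log BF = -inf)."""


class EmptySubsetError(BFTrimError):
    """No retained draws inside the trimming subset D."""


class ZeroProbabilityError(BFTrimError):
    """A subset probability estimate is zero, so the correction is undefined."""


class InvalidCorrectionError(BFTrimError, ValueError):
    """A correction probability is outside (0, 1]."""


class InsufficientDrawsError(BFTrimError):
    """Too few draws for the requested batch-means computation."""


class EmptyIntersectionError(BFTrimError):
    """The coordinatewise range intersection of the two samplers is empty."""

    def __init__(self, coordinate: str, lower: float, upper: float):
        self.coordinate = coordinate
        super().__init__(
            f"empty range intersection on coordinate {coordinate!r}: "
            f"lower {lower} > upper {upper}"
        )


class EmptyBandError(BFTrimError):
    """The intersection of the two samplers' log-ratio ranges is empty."""


class DegenerateRegionError(BFTrimError):
    """A trimming region retains no draws from one of the samplers."""


class EmptyOverlapError(BFTrimError):
    """No prior draw falls inside the region A (corrected-arithmetic-mean step)."""


class TailPointError(BFTrimError):
    """The evaluation point lies in an empty histogram bin / outside the draws."""


class SamplingError(BFTrimError):
    """A conditional sampler could not bracket an integrable density."""


class UsageError(BFTrimError, ValueError):
    """An API contract violation (e.g. same-direction reciprocal check)."""


class ConfigError(BFTrimError, ValueError):
    """An invalid run configuration (CLI / run_from_config)."""
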