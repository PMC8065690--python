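"""Construction of the trimming subset D = (A x B) ∩ C.

A is a hyper-cuboid over parameter coordinates and B one over latent
coordinates, both limited by the range of the two samplers' outputs: per
coordinate, the lower bound is the larger of the two per-model sample minima
and the upper bound the smaller of the two per-model maxima. C is a band on
the density ratio between the two models, again the intersection of the two
samplers' observed ratio ranges,

    L = max_m min_q ratio(q, m),     Q = min_m max_q ratio(q, m).

Membership is closed (boundary points belong to D).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core import LogRatioSeries, log_ratio_terms
from .draws import DrawMatrix
from .errors import (
    DegenerateRegionError,
    EmptyBandError,
    EmptyIntersectionError,
    SchemaError,
)
from .models import ModelDensities

__all__ = ["TrimRegion", "coordinate_box", "ratio_band", "build_trim_region"]


@dataclass
class TrimRegion:
    """The subset D: a per-coordinate box plus an optional log-ratio band."""

    box: dict[str, tuple[float, float]]
    log_band: tuple[float, float] | None = None
    ratio_kind: str | None = None
    band_direction: tuple[str, str] | None = None
    provenance: tuple[str, str] | None = None
    retention: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.box.items():
            if lo > hi:
                raise EmptyIntersectionError(name, lo, hi)
        if self.log_band is not None:
            lo, hi = self.log_band
            if lo > hi:
                raise EmptyBandError(f"empty log-ratio band: L={lo} > Q={hi}")

    # -- membership -------------------------------------------------------
    def contains(
        self, draws: DrawMatrix, ratios: LogRatioSeries | np.ndarray | None = None
    ) -> np.ndarray:
        """Boolean membership of each draw (closed region)."""
        inside = np.ones(draws.k, dtype=bool)
        missing = [n for n in self.box if n not in draws.columns]
        if missing:
            raise SchemaError(
                f"draw table lacks region coordinates {missing}; membership undefined"
            )
        for name, (lo, hi) in self.box.items():
            x = draws.column(name)
            inside &= (x >= lo) & (x <= hi)
        if self.log_band is not None:
            if ratios is None:
                raise ValueError("region has a ratio band: log-ratio values required")
            values = ratios.values if isinstance(ratios, LogRatioSeries) else np.asarray(ratios)
            if isinstance(ratios, LogRatioSeries) and self.band_direction is not None:
                if ratios.direction == self.band_direction[::-1]:
                    values = -values
                elif ratios.direction != self.band_direction:
                    raise ValueError(
                        f"ratio series direction {ratios.direction} does not match "
                        f"the band direction {self.band_direction}"
                    )
            if values.shape[0] != draws.k:
                raise ValueError("ratio series must align with the draw table")
            lo, hi = self.log_band
            inside &= (values >= lo) & (values <= hi)
        return inside

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "box": {k: [float(v[0]), float(v[1])] for k, v in self.box.items()},
            "log_band": None if self.log_band is None else [float(x) for x in self.log_band],
            "ratio_kind": self.ratio_kind,
            "band_direction": None if self.band_direction is None else list(self.band_direction),
            "provenance": None if self.provenance is None else list(self.provenance),
            "retention": self.retention,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "TrimRegion":
        return cls(
            box={k: (float(v[0]), float(v[1])) for k, v in d["box"].items()},
            log_band=None if d.get("log_band") is None else tuple(d["log_band"]),
            ratio_kind=d.get("ratio_kind"),
            band_direction=None
            if d.get("band_direction") is None
            else tuple(d["band_direction"]),
            provenance=None if d.get("provenance") is None else tuple(d["provenance"]),
            retention=d.get("retention", {}),
        )

    @classmethod
    def from_json(cls, path) -> "TrimRegion":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def coordinate_box(
    draws_m1: DrawMatrix, draws_m2: DrawMatrix, coords
) -> dict[str, tuple[float, float]]:
    """Range-intersection box over the given coordinates.

    A coordinate present in both draw tables gets the intersection of the two
    sample ranges [max of minima, min of maxima]; a model-specific coordinate
    present in only one table takes that single sample's range (the other
    model has no such coordinate to intersect with).
    """
    box: dict[str, tuple[float, float]] = {}
    for name in coords:
        ranges = []
        for dm in (draws_m1, draws_m2):
            if dm.has(name):
                x = dm.column(name)
                ranges.append((float(x.min()), float(x.max())))
        if not ranges:
            raise SchemaError(f"coordinate {name!r} found in neither draw table")
        lo = max(r[0] for r in ranges)
        hi = min(r[1] for r in ranges)
        if lo > hi:
            raise EmptyIntersectionError(name, lo, hi)
        box[name] = (lo, hi)
    return box


def ratio_band(
    log_ratios_m1: LogRatioSeries, log_ratios_m2: LogRatioSeries
) -> tuple[float, float]:
    """Intersection of the two samplers' observed log-ratio ranges (log L, log Q)."""
    if log_ratios_m1.ratio_kind != log_ratios_m2.ratio_kind:
        raise ValueError("ratio series must share the same ratio_kind")
    if log_ratios_m1.direction != log_ratios_m2.direction:
        raise ValueError("ratio series must share the same direction")
    log_l = max(float(log_ratios_m1.values.min()), float(log_ratios_m2.values.min()))
    log_q = min(float(log_ratios_m1.values.max()), float(log_ratios_m2.values.max()))
    if log_l > log_q:
        raise EmptyBandError(f"empty log-ratio band: L={log_l} > Q={log_q}")
    return log_l, log_q


def build_trim_region(
    draws_m1: DrawMatrix,
    draws_m2: DrawMatrix,
    models: tuple[ModelDensities, ModelDensities],
    ratio_kind: str,
    y: np.ndarray | None = None,
    include_latents: bool = True,
    with_band: bool = True,
    series_m1: LogRatioSeries | None = None,
    series_m2: LogRatioSeries | None = None,
) -> TrimRegion:
    """Assemble D from two samplers' outputs and score both sets against it.

    The box spans all parameter coordinates of both models (and all latent
    coordinates when ``include_latents``); with T latent coordinates the box
    can become restrictive, so retention diagnostics for both draw sets are
    recorded on the returned region. ``with_band=False`` drops the ratio
    band C (box-only trimming). Precomputed log-ratio series for the two
    draw sets may be supplied to avoid re-evaluating the densities.
    """
    m1, m2 = models
    coords = list(dict.fromkeys(m1.param_names + m2.param_names))
    if include_latents:
        coords += list(dict.fromkeys(m1.latent_names + m2.latent_names))
    box = coordinate_box(draws_m1, draws_m2, coords)

    band = None
    series1, series2 = series_m1, series_m2
    if with_band:
        if series1 is None:
            series1 = log_ratio_terms(draws_m1, m1, m2, ratio_kind, y)
        if series2 is None:
            series2 = log_ratio_terms(draws_m2, m1, m2, ratio_kind, y)
        band = ratio_band(series1, series2)

    region = TrimRegion(
        box=box,
        log_band=band,
        ratio_kind=ratio_kind if with_band else None,
        band_direction=(m1.model_id, m2.model_id) if with_band else None,
        provenance=(draws_m1.model_id, draws_m2.model_id),
    )
    r1 = float(region.contains(draws_m1, series1).mean())
    r2 = float(region.contains(draws_m2, series2).mean())
    region.retention = {"m1": r1, "m2": r2}
    if r1 == 0.0 or r2 == 0.0:
        raise DegenerateRegionError(
            f"trimming region retains no draws from one sampler (retention {region.retention})"
        )
    return region
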