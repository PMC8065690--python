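"""Labelled tables of Monte-Carlo draws.

A :class:`DrawMatrix` is a k x d table of posterior or prior draws — one draw
per row, one parameter or latent coordinate per column — together with its
provenance (which model, posterior or prior, seed, sampler length). It is the
common currency between the samplers, the trimming-region construction and the
Bayes-factor estimators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = ["DrawMatrix", "join_columns"]


@dataclass
class DrawMatrix:
    """A table of Monte-Carlo draws with provenance.

    Parameters
    ----------
    draws
        ``(k, d)`` table of reals; column names identify parameter/latent
        coordinates and must match a model layout.
    source
        ``"posterior"``, ``"prior"`` or ``"unknown"``.
    model_id
        Identifier of the model the draws belong to.
    seed
        Seed of the generating sampler, if known.
    n_iterations
        Sampler length before thinning/burn-in, if known.
    burn_in
        Burn-in discarded by the generating sampler, if known.
    """

    draws: pd.DataFrame
    source: str = "unknown"
    model_id: str = ""
    seed: int | None = None
    n_iterations: int | None = None
    burn_in: int | None = None
    _colindex: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.draws, pd.DataFrame):
            self.draws = pd.DataFrame(self.draws)
        if self.draws.shape[0] < 1 or self.draws.shape[1] < 1:
            raise ValueError("DrawMatrix requires k >= 1 draws and d >= 1 columns")
        cols = list(self.draws.columns)
        if len(set(cols)) != len(cols):
            raise ValueError("DrawMatrix columns must be unique")
        if self.source not in ("posterior", "prior", "unknown"):
            raise ValueError(f"invalid source {self.source!r}")
        values = self.draws.to_numpy()
        if not np.isfinite(values).all():
            raise ValueError("DrawMatrix must not contain missing/non-finite entries")
        self._colindex = {c: i for i, c in enumerate(cols)}

    # -- basic geometry ---------------------------------------------------
    @property
    def k(self) -> int:
        """Number of draws."""
        return self.draws.shape[0]

    @property
    def columns(self) -> list[str]:
        return list(self.draws.columns)

    def has(self, *names: str) -> bool:
        return all(n in self._colindex for n in names)

    def require(self, names) -> None:
        missing = [n for n in names if n not in self._colindex]
        if missing:
            raise SchemaError(f"draw table is missing columns {missing}")

    # -- array access -----------------------------------------------------
    def array(self, names) -> np.ndarray:
        """Return the ``(k, len(names))`` array for the given columns."""
        self.require(names)
        idx = [self._colindex[n] for n in names]
        return self.draws.to_numpy()[:, idx]

    def column(self, name: str) -> np.ndarray:
        self.require([name])
        return self.draws[name].to_numpy()

    def params_dict(self, names) -> dict[str, np.ndarray]:
        """Mapping name -> column array, for density evaluators."""
        self.require(names)
        return {n: self.draws[n].to_numpy() for n in names}

    def head(self, k: int) -> "DrawMatrix":
        return DrawMatrix(
            self.draws.iloc[:k].reset_index(drop=True),
            source=self.source,
            model_id=self.model_id,
            seed=self.seed,
            n_iterations=self.n_iterations,
            burn_in=self.burn_in,
        )

    def metadata(self) -> dict:
        return {
            "model_id": self.model_id,
            "source": self.source,
            "seed": self.seed,
            "n_iterations": self.n_iterations,
            "burn_in": self.burn_in,
        }


def join_columns(a: DrawMatrix | None, b: DrawMatrix | None) -> DrawMatrix:
    """Pair two draw streams row-by-row into a single table.

    Used to join independent prior draws of model-specific parameters with
    posterior draws of the restricted model (row q of one stream is paired with
    row q of the other). On mismatched counts, k = min of the two with a
    warning.
    """
    if a is None and b is None:
        raise ValueError("nothing to join")
    if a is None:
        return b  # type: ignore[return-value]
    if b is None:
        return a
    overlap = set(a.columns) & set(b.columns)
    if overlap:
        raise SchemaError(f"cannot join draw tables sharing columns {sorted(overlap)}")
    k = min(a.k, b.k)
    if a.k != b.k:
        warnings.warn(
            f"joining draw tables of unequal length ({a.k} vs {b.k}); "
            f"using the first {k} rows of each",
            stacklevel=2,
        )
    df = pd.concat(
        [a.draws.iloc[:k].reset_index(drop=True), b.draws.iloc[:k].reset_index(drop=True)],
        axis=1,
    )
    return DrawMatrix(
        df,
        source=a.source if a.source == b.source else "unknown",
        model_id=a.model_id or b.model_id,
        seed=a.seed,
        n_iterations=a.n_iterations,
    )
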