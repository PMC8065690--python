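"""Savage–Dickey density ratio for a point restriction in a nested pair.

For mu ~ N(0,1) a priori and a Gaussian posterior, the Bayes factor of the
restriction mu = 0 equals the posterior-over-prior density ratio at 0. The
posterior density is estimated from a histogram of sampled values
(Freedman–Diaconis bin width), so the method needs the restriction point to
be covered by posterior draws — it degrades in the tail, which is why the
trimmed ratio estimators are preferable when the restriction is far from
the posterior mass.
"""

import numpy as np

import bftrim as bt
from bftrim.errors import TailPointError

rng = np.random.default_rng(5)
prior_ln_at_0 = -0.5 * np.log(2 * np.pi)  # ln N(0 | 0, 1)

# posterior concentrated at 0 with sd 0.25: density ratio at 0 is exactly 4
draws = rng.normal(0.0, 0.25, size=100_000)
val = bt.savage_dickey_log_bf(draws, prior_ln_at_0, point=0.0)
print(f"log10 SD ratio (posterior N(0, 0.25^2)): {val:+.4f}  [exact: {np.log10(4):+.4f}]")

# posterior centred away from 0: evidence against the restriction
draws = rng.normal(0.5, 0.25, size=100_000)
val = bt.savage_dickey_log_bf(draws, prior_ln_at_0, point=0.0)
print(f"log10 SD ratio (posterior N(0.5, 0.25^2)): {val:+.4f}  (restriction disfavoured)")

# restriction point outside the sampled range: refused, not extrapolated
try:
    bt.savage_dickey_log_bf(rng.normal(5.0, 0.1, size=10_000), prior_ln_at_0, point=0.0)
except TailPointError as exc:
    print(f"tail point rejected as expected: {exc}")
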