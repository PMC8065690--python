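"""The inverted-gamma MSF latent-prior ratio as a plug-in density ratio.

In the hybrid IG-MSF-SBEKK volatility model the latent factor follows
ln h_t = phi ln h_{t-1} + ln gamma_t with gamma_t ~ IG(v/2, v/2); phi = 0
collapses it to iid inverted-gamma factors (the t-SBEKK case). The
closed-form log ratio of the two latent priors is evaluated on simulated
paths and fed to the generic arithmetic-mean machinery; as phi -> 0 the
implied Bayes factor between the phi-model and the phi=0 model goes to 0 on
the log scale (the models coincide).
"""

import numpy as np

from bftrim.core import LogRatioSeries, bf_uncorrected
from bftrim.msf import MSFLatentPath, igmsf_latent_log_ratio, simulate_msf_path

v = 8.0
path = simulate_msf_path(T=200, v=v, phi=0.4, seed=3)
print(f"simulated path: T={path.T}, mean h_t = {path.h[1:].mean():.3f} "
      f"(iid IG mean would be v/(v-2) = {v / (v - 2):.3f})")
print(f"log latent-prior ratio on this path: {igmsf_latent_log_ratio(path):+.3f}")

for phi_star in (0.4, 0.1, 0.01):
    rng = np.random.default_rng(4)
    values = []
    for _ in range(400):
        p = simulate_msf_path(T=50, v=v, phi=0.0, seed=rng)  # draws from phi=0 law
        values.append(igmsf_latent_log_ratio(MSFLatentPath(p.h, v, phi_star)))
    est = bf_uncorrected(LogRatioSeries(np.array(values), "latent_prior", ("MSF", "t")))
    print(
        f"phi* = {phi_star:<5}: log10 BF(phi*, 0) ~ {est.log10_bf:+.4f} "
        f"(NSE {est.nse_log10:.4f})"
    )
# The estimated log10 Bayes factor of the phi* latent prior against the
# phi=0 prior shrinks toward 0 as phi* -> 0: nearby models are
# indistinguishable, and the ratio machinery reports that honestly.
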