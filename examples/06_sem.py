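"""Fit the latent LA = LG + RD structural equation model.

Local aerosol (LA: log bacterial abundance + local PM10) is regressed on
local generation (LG: humidity, pressure, cloud) and regional dispersal
(RD: three dust-immigration indices).  Data are simulated from a known
standardized structure and the ML fit is standardized back for comparison.
"""

from dataclasses import replace

import numpy as np

from aerodyn import default_spec, fit_indices, fit_sem, simulate, standardize
from aerodyn.sem import build_true_theta

spec = default_spec()
loadings = dict(zip(spec.observed,
                    [-0.99, 0.59, -0.55, 0.92, 0.93, 0.95, 0.45, 0.43]))
paths = {("LA", "LG"): 0.51, ("LA", "RD"): 0.35}
covs = {("LG", "RD"): 0.64}
theta = build_true_theta(spec, loadings, paths, covs)
psi = 1 - (0.51 ** 2 + 0.35 ** 2 + 2 * 0.51 * 0.35 * 0.64)

data = simulate(theta, replace(spec, psi_fixed=psi), n=2000,
                rng=np.random.default_rng(7))
fit = fit_sem(data, spec, seed=0)
std = standardize(fit)

print(f"chi2 = {fit.chi2:.1f} on df = {fit.df} (n = {fit.n})")
print("standardized paths:     "
      + ", ".join(f"{k} = {v:+.2f}" for k, v in std.paths.items()))
print(f"latent covariance:      LG~~RD = "
      f"{std.latent_covariances['LG~~RD']:+.2f}")
print("loadings (explained variance):")
for name in spec.observed:
    print(f"  {name:14s} {std.loadings[name]:+.2f} "
          f"({std.explained_variance[name]:.2f})")
idx = fit_indices(fit)
print(f"fit indices: TLI {idx['tli']:.3f}, RMSEA {idx['rmsea']:.3f}, "
      f"SRMR {idx['srmr']:.3f}")
# Recovered paths near +0.51/+0.35 with covariance near +0.64 mean local
# generation dominates, but desert dispersal adds a substantial share.
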