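"""Fitting LD decay with the Hill-Weir drift expectation.

Generates (distance, r^2) pairs with binomial sampling noise around a known
decay curve, fits rho by nonlinear least squares, and reports the distance at
which the fitted expectation falls to the background LD level (r^2 = 0.26) —
the LD decay distance that governs GWAS marker density and resolution.
"""

import numpy as np

from radnet import pop_ld, simdata
from radnet.ld_map import DEFAULT_BACKGROUND_R2

TRUE_RHO = 2e-6
N_LINES = 189

d, r2 = simdata.simulate_decay_r2_pairs(TRUE_RHO, N_LINES, n_pairs=2000,
                                        max_bp=3_000_000, seed=42, noise=True)
ok = np.isfinite(r2)
fit = pop_ld.fit_ld_decay(d[ok], r2[ok], n_lines=N_LINES,
                          background=DEFAULT_BACKGROUND_R2)

print(f"true rho: {TRUE_RHO:.3g} /bp, fitted rho: {fit.rho:.3g} /bp "
      f"({fit.n_pairs} pairs, SSE {fit.residual_sse:.1f})")
print(f"fitted E(r^2) at 0 bp: {fit.expected_r2(1):.3f} "
      f"(the curve's ceiling for n = {N_LINES} lines)")
print(f"LD decay distance to r^2 = {fit.background}: "
      f"{fit.decay_distance_bp / 1000:.0f} kb")
print("interpretation: marker pairs closer than this are expected to show "
      "LD above the panel's unlinked background")
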