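"""Decompose realized population growth into vital-rate components.

Runs the stochastic projection, extracts realized per-capita rates, shows
that the additive decomposition reproduces each year's growth rate exactly,
and prints the analytic sensitivities of growth to each component.
"""

import numpy as np

from nestipm import core, ltre

T = 15
rates = core.VitalRateSeries(
    pB=np.full((2, T), 0.8), CS=np.full((2, T), 6.3),
    pNS=np.full(T, 0.85), sN=np.full((2, T), 0.88),
    sJ=np.full(T, 0.11), sA=np.full(T, 0.47))
ens = core.stochastic_project(rates, np.full((2, T), 25.0), (60, 120),
                              seed=4, reps=1)

theta = core.realized_theta(ens)[0]          # (T-1, 12) realized components
lam_direct = core.realized_growth(ens.ntot[0].astype(float))
lam_decomp = core.lambda_decomposed(theta)

print("year  lambda(real)  lambda(decomposed)  |difference|")
for t in range(T - 1):
    print(f"{t:4d}  {lam_direct[t]:12.6f}  {lam_decomp[t]:18.6f}"
          f"  {abs(lam_direct[t] - lam_decomp[t]):.1e}")

sens = ltre.sensitivities(theta.mean(axis=0))
print("\nsensitivities of lambda at the temporal mean:")
for name, value in zip(core.THETA_NAMES, sens.values):
    print(f"  d lambda / d {name:8s} = {value: .4f}")
# Survival and the immigration rates enter growth additively, so their
# sensitivities are exactly 1; reproductive components act through the
# 0.5 * sJ * F chain and therefore carry much smaller leverage.
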