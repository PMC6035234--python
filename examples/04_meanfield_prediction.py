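"""Mean-field kinetics: fixed barrier versus autocatalytic barrier.

Integrates dp/dt = k_overall (1-p)^2 with the barrier-effect rate
constants.  With a fixed barrier the rate decays monotonically; with an
autocatalytically decreasing barrier (xi > 0) the rate passes through an
interior maximum -- the sigmoidal fingerprint of autocatalysis.
"""
import numpy as np

from patchykin import MeanFieldRateParams, integrate_kinetics

par = MeanFieldRateParams(k_c=4.56e-3, k_d=1.015, n0=2.01, n_inf=1.830,
                          b=0.31, D0=0.05, dU0=4.0, xi=50.0)
t = np.linspace(0.0, 4.0e4, 500)
fixed = integrate_kinetics(par, t, mode="fixed")
auto = integrate_kinetics(par, t, mode="auto")
r_auto = np.gradient(auto.p, t)
k_peak = int(np.argmax(r_auto))
print(f"fixed barrier : p({t[-1]:.0f}) = {fixed.p[-1]:.3f}")
print(f"autocatalytic : p({t[-1]:.0f}) = {auto.p[-1]:.3f}")
print(f"autocatalytic rate peaks at t = {t[k_peak]:.0f} "
      f"(p = {auto.p[k_peak]:.3f}) -- interior maximum = sigmoidal p(t)")
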