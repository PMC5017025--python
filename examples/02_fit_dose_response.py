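"""Fit a five-parameter log-logistic curve to noisy bioassay counts.

Simulates one toxicant-only arm (binomial survival of 500 organisms per
concentration), runs the standard pipeline — Williams monotonisation,
log-scale interpolation to 10 smoothing points, multi-start least-squares
LL.5 fit with the lower limit fixed at 0 and the upper limit at the
control response — and reports the lethal concentrations LC10 and LC50.
"""

import numpy as np

from samtox import DoseResponseDataset, LL5Params, fit_dose_response, lc, ll5_survival

rng = np.random.default_rng(7)

true = LL5Params(b=1.8, c=0.0, d=0.95, e=12.0, f=0.6)
conc = np.logspace(-0.5, 2.5, 8)
n = 500
survived = rng.binomial(n, np.asarray(ll5_survival(true, conc)))
data = DoseResponseDataset.from_counts(conc, survived, np.full(8, n),
                                       control_survival=rng.binomial(n, true.d) / n)

fit = fit_dose_response(data, williams=True, interpolate=10)

print(f"true curve:   b={true.b:.3f}  d={true.d:.3f}  e={true.e:.3f}  f={true.f:.3f}")
print(f"fitted curve: b={fit.b:.3f}  d={fit.d:.3f}  e={fit.e:.3f}  f={fit.f:.3f}")
print(f"LC10 = {lc(fit, 10):.2f}   (true {lc(true, 10):.2f})")
print(f"LC50 = {lc(fit, 50):.2f}   (true {lc(true, 50):.2f})")
print()
print("Lethal concentrations are read off the fitted curve on the")
print("control-normalised (Abbott-corrected) mortality scale.")
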