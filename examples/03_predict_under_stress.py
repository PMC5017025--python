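"""Predict a toxicant's concentration-response curve under extra stress.

Given a fitted toxicant-alone curve and the mortality the environmental
stressor causes by itself, SAM predicts the whole combined-stress curve
and the sensitivity shifts LCx/LCx*. The CA and EA baselines are shown
for comparison: EA never shifts the curve's midpoint on its own scale,
CA shifts it moderately, SAM the most.
"""

import numpy as np

from samtox import (
    LL5Params,
    StressCapacityDistribution,
    ca_lcx_shift,
    lc,
    predict_combined_curve,
    sam_lcx_shift,
)

curve = LL5Params(b=2.5, c=0.0, d=1.0, e=10.0, f=0.3)  # right-skewed toxicant curve
dist = StressCapacityDistribution(3.2, 3.2)
m_env = 0.2  # environmental stressor alone kills 20%

grid = np.logspace(-1, 2, 7)
pred = predict_combined_curve(dist, curve, m_env, grid)
print("concentration   survival(tox alone)   survival(tox + env, SAM)")
from samtox import ll5_survival

for c, p in zip(grid, pred):
    print(f"{c:12.2f}   {float(ll5_survival(curve, c)):19.3f}   {p:24.3f}")

print()
for x in (10, 50):
    sam = sam_lcx_shift(dist, curve, m_env, x)
    ca = ca_lcx_shift(curve, m_env, x)
    print(f"LC{x} shift:  SAM {sam:5.2f}x   CA {ca:5.2f}x   EA 1.00x "
          f"(LC{x} alone = {lc(curve, x):.2f})")
print()
print("A shift of k means the stressed population reaches the same")
print("mortality at a k-fold lower toxicant concentration.")
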