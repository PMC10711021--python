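"""Fit a Rosenthal-Henderson B-factor from a resolution-vs-count series.

The B-factor is the exponential decay constant of high-resolution signal:
on a plot of ln(particle count) against 1/d^2 the points fall on a line of
slope B/2. Here a synthetic series generated with B = 90 A^2 (plus noise
emulating refinement variability over repeated half-splits) is fitted
back.
"""

import math

import numpy as np

from particlesieve import fit_rh_bfactor

B_TRUE, INTERCEPT = 90.0, 2.8
rng = np.random.default_rng(0)
points = []
for d in (6.0, 5.0, 4.2, 3.6, 3.2):
    for _ in range(3):  # repeated half-splitting style replicates
        ln_n = INTERCEPT + (B_TRUE / 2.0) / d**2 + rng.normal(0.0, 0.05)
        points.append((math.exp(ln_n), d))

fit = fit_rh_bfactor(points)
print(f"true B = {B_TRUE:.1f} A^2")
print(f"fitted B = {fit.b_factor_A2:.1f} A^2 "
      f"(intercept {fit.intercept:.2f}, {len(fit.points)} points)")
print("\nA lower fitted B means high-resolution amplitude decays more "
      "slowly with frequency,\ni.e. fewer particles are needed for each "
      "extra shell of resolution.")
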