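"""Fit the worm-like chain to a noisy force-extension segment.

Builds a synthetic elastic branch with a 24.1 nm contour length and 0.4 nm
persistence length, adds 5 pN of Gaussian force noise, and recovers the
contour length by least squares with the persistence length held fixed --
the standard way of sizing an unfolded protein segment from AFM data.
"""

import numpy as np

import mechpath as mp

true = mp.WLCParams(Lc=24.1, rho=0.4)
rng = np.random.default_rng(3)
x = np.linspace(0.1 * true.Lc, 0.9 * true.Lc, 200)
force = mp.wlc_force(x, true) + rng.normal(0, 5.0, x.size)

fit, diag = mp.fit_wlc(x, force, rho=0.4)
print(f"true contour length : {true.Lc:.2f} nm")
print(f"fitted contour length: {fit.Lc:.2f} +/- {diag['Lc_se']:.2f} nm "
      f"(rmse {diag['rmse']:.2f} pN, n={diag['n']})")
print("\nThe fitted Lc estimates the full stretched length of the unfolded "
      "chain; errors of a few tenths of a nm are typical at this noise level.")
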