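"""Default latent correlation matrix of the synthetic-data generator.

Calibrated (offline, penalized least squares on a fixed Monte-Carlo sample
of 200k draws) so that on the design scale each column's multiple R-squared
on the other sixteen matches the target covariate-structure profile, the
linear predictor variance gives a global R-squared of 0.47 at a noise SD of
0.93, and latent correlations stay within [-0.3, 0.8].  Latents 6, 13 and
15 (columns X6, X15, X17) are exactly independent of everything.
"""

import numpy as np

DEFAULT_LATENT_CORR = np.array([
    [1.0000, -0.2780, -0.0780, -0.2101, 0.1989, 0.0000, -0.2812, -0.0134, 0.3910, 0.0938, -0.2491, -0.2442, 0.0000, 0.1219, 0.0000],
    [-0.2780, 1.0000, 0.1888, -0.0355, -0.2791, 0.0000, 0.8000, -0.2968, 0.1754, 0.1443, -0.3000, 0.2364, 0.0000, 0.1422, 0.0000],
    [-0.0780, 0.1888, 1.0000, -0.3000, -0.2562, 0.0000, -0.3000, -0.3000, 0.8000, -0.0624, -0.2271, -0.3000, 0.0000, -0.2720, 0.0000],
    [-0.2101, -0.0355, -0.3000, 1.0000, 0.0142, 0.0000, -0.1681, -0.0566, -0.2296, -0.2328, 0.2662, -0.1750, 0.0000, -0.1432, 0.0000],
    [0.1989, -0.2791, -0.2562, 0.0142, 1.0000, 0.0000, -0.1676, -0.0689, -0.2533, 0.0771, 0.0418, -0.0125, 0.0000, -0.1135, 0.0000],
    [0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 1.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000],
    [-0.2812, 0.8000, -0.3000, -0.1681, -0.1676, 0.0000, 1.0000, -0.1169, -0.3000, 0.1808, -0.2515, 0.4100, 0.0000, 0.3869, 0.0000],
    [-0.0134, -0.2968, -0.3000, -0.0566, -0.0689, 0.0000, -0.1169, 1.0000, -0.2910, 0.1730, 0.6353, -0.1154, 0.0000, -0.0005, 0.0000],
    [0.3910, 0.1754, 0.8000, -0.2296, -0.2533, 0.0000, -0.3000, -0.2910, 1.0000, -0.0911, -0.3000, -0.2963, 0.0000, -0.2101, 0.0000],
    [0.0938, 0.1443, -0.0624, -0.2328, 0.0771, 0.0000, 0.1808, 0.1730, -0.0911, 1.0000, -0.0818, 0.0266, 0.0000, 0.0862, 0.0000],
    [-0.2491, -0.3000, -0.2271, 0.2662, 0.0418, 0.0000, -0.2515, 0.6353, -0.3000, -0.0818, 1.0000, 0.0278, 0.0000, -0.3000, 0.0000],
    [-0.2442, 0.2364, -0.3000, -0.1750, -0.0125, 0.0000, 0.4100, -0.1154, -0.2963, 0.0266, 0.0278, 1.0000, 0.0000, -0.0785, 0.0000],
    [0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 1.0000, 0.0000, 0.0000],
    [0.1219, 0.1422, -0.2720, -0.1432, -0.1135, 0.0000, 0.3869, -0.0005, -0.2101, 0.0862, -0.3000, -0.0785, 0.0000, 1.0000, 0.0000],
    [0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 1.0000],
])
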