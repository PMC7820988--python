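"""Backward elimination on a small dataset, step by step.

Builds a 5-covariate linear dataset (two real predictors, three pure noise
columns), then eliminates terms whose Wald p-value exceeds 0.157 — the
level at which dropping a 1-df term is AIC-neutral — and prints the
elimination trace.

Reading the output: the trace lists each removed term with the p-value it
had when removed (always >= 0.157); every term left in the final model has
p < 0.157.  The padded coefficient vector shows eliminated terms as exact
zeros, the representation all stability measures build on.
"""

import numpy as np

from selstab import Dataset, backward_eliminate

rng = np.random.default_rng(3)
N = 200
X = rng.standard_normal((N, 5))
y = 1.0 * X[:, 0] + 0.4 * X[:, 1] + rng.standard_normal(N)
cols = ["age", "bp", "noise1", "noise2", "noise3"]
data = Dataset(X, y, {c: [j] for j, c in enumerate(cols)}, "linear",
               columns=cols)

result = backward_eliminate(data, alpha=0.157)
print("selected model:", " + ".join(result.selected_terms))
print("elimination trace:")
for term, p in result.trace:
    print(f"  removed {term:<8s} at p = {p:.3f}")
print("padded coefficients (0 = eliminated):")
for c in cols:
    print(f"  {c:<8s} {result.coef(c):+.3f}")
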