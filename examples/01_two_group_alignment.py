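"""Recover group factor means and variances from configural estimates.

Builds a fully invariant 10-item bank, pushes it to the configural
scale under group ability distributions N(0, 1) and N(-1, 2) — exactly
what a configural fit would estimate, since that model forces every
group to N(0, 1) and absorbs the true differences into the item
parameters — then aligns and recovers the generating distributions.
"""

import numpy as np

from irtalign import AlignmentOptions, ConfiguralFit, align, inverse_align_transform

rng = np.random.default_rng(5)
P = 10
loadings = rng.uniform(0.8, 2.0, P)
thresholds = rng.uniform(-1.5, 1.5, P) * loadings

alphas = np.array([0.0, -1.0])  # generating factor means
psis = np.array([1.0, 2.0])  # generating factor variances

lam0, tau0 = inverse_align_transform(
    np.tile(loadings[:, None], (1, 2)),
    np.tile(thresholds[:, None], (1, 2)),
    alphas,
    psis,
)
fit = ConfiguralFit.from_params(
    groups=["g1", "g2"],
    items=[f"Y{i + 1}" for i in range(P)],
    loadings=lam0,
    thresholds=tau0,
    group_sizes=[1000, 1000],
)

result = align(fit, AlignmentOptions(seed=3))

print("estimated group factor distributions (group 1 is the fixed reference):")
for g, a, p in zip(result.groups, result.alphas, result.psis):
    print(f"  {g}: mean {a:+.4f}, variance {p:.4f}")
print(f"total loss {result.loss:.4f} (floor for perfectly invariant items: "
      f"{2 * P * result.weights[0, 1] * (1e-4 ** 0.25):.4f})")
print()
print("The estimates reproduce the generating values (0, 1) and (-1, 2):")
print("the loss sits exactly on its floor because, once the right group")
print("distributions are restored, every aligned item parameter is equal")
print("across the two groups.")
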