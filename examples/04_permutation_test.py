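"""One-sample sign-flip permutation tests, exact and Monte-Carlo.

For n <= 12 observations all 2^n sign patterns are enumerated exactly; for
larger samples a seeded Monte-Carlo null is drawn with the add-one p-value
convention.
"""

import numpy as np

import morphcat as mc

accuracies = [0.9, 0.8, 1.0]
result = mc.one_sample_permutation_test(accuracies, null_value=0.5,
                                        alternative="greater")
print(f"three block accuracies {accuracies} vs chance 0.5:")
print(f"  statistic (mean - 0.5) = {result.statistic:.2f}")
print(f"  exact enumeration of {result.n_permutations} sign patterns, "
      f"p = {result.p_value:.4g}")
print("  (only the all-positive pattern attains the observed mean: p = 1/8)")

rng = np.random.default_rng(0)
values = 0.5 + rng.normal(0.05, 0.1, size=30)
result = mc.one_sample_permutation_test(values, 0.5, "greater",
                                        n_permutations=10000, rng=rng)
print(f"\n30 noisy accuracies with a true +0.05 shift:")
print(f"  statistic = {result.statistic:.3f}, Monte-Carlo p = "
      f"{result.p_value:.4g} ({result.n_permutations} permutations)")

null_values = 0.5 + rng.normal(0.0, 0.1, size=30)
result = mc.one_sample_permutation_test(null_values, 0.5, "greater",
                                        n_permutations=10000, rng=rng)
print(f"  same test on null data: p = {result.p_value:.3g} "
      "(no evidence, as it should be)")
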