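"""Show how the learned instance weights separate noisy genes from clean ones.

The robust factorization assigns each gene a nonnegative weight on a fixed
budget; genes whose mutation profile cannot be explained by the latent
subgroup structure (dense unstructured columns) should end near zero while
structured genes keep weight ~1.
"""

import numpy as np

from ragnmf import CohortSpec, RagnmfConfig, fit, simulate_cohort

X, truth = simulate_cohort(CohortSpec(seed=3))
state = fit(X, RagnmfConfig(k=4, seed=3))

noisy = set(truth.noisy_genes)
w_noisy = np.mean([w for g, w in zip(X.genes, state.W) if g in noisy])
w_clean = np.mean([w for g, w in zip(X.genes, state.W) if g not in noisy])
zeroed = sum(1 for g, w in zip(X.genes, state.W) if g in noisy and w < 1e-8)

print(f"planted noisy genes: {len(noisy)} (mutation rate 0.3 across the whole cohort)")
print(f"mean weight of noisy genes: {w_noisy:.3f}")
print(f"mean weight of clean genes: {w_clean:.3f}")
print(f"noisy genes driven exactly to zero weight: {zeroed}/{len(noisy)}")
print("a clean/noisy weight gap means the solver fits the subgroup structure")
print("instead of chasing unstructured dense columns.")
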