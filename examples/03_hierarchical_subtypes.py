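"""Two-stage estimation of monocyte subtype fractions.

Stage 1 estimates total monocytes with a full panel; stage 2 splits them
into classical vs non-classical with a dedicated subtype panel; the final
absolute fractions are the product of the two estimates.
"""

import numpy as np

import epimix as em
from epimix.simulate import make_hierarchical_cohort

# one sample: 10% total monocytes, split 70/30 between the two subtypes
parent_ref, subtype_ref, beta = make_hierarchical_cohort(
    parent_fractions=[[0.50, 0.40, 0.10]],
    subtype_split=[[0.70, 0.30]],
)
result = em.hierarchical_subtypes(beta, parent_ref, subtype_ref, "Mono")

print("absolute subtype fractions:")
print(result.data.round(4).to_string())
parent = em.rpc_deconvolve(beta, parent_ref).data["Mono"]
print(f"\nstage-1 total monocyte fraction: {parent.iloc[0]:.4f}")
print(f"subtype sum equals parent: {np.allclose(result.values.sum(1), parent)}")
# Noiseless nested panels give exactly 0.07 / 0.03 = 0.10 x (0.7, 0.3).
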