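"""Associate genomic features with metastatic-potential classes.

Builds a mutation matrix over 21 cell lines (7 high-potential, 14 low)
where one gene is mutated in 4 of the 7 high-potential lines and none of
the low ones, plus background features, and tests each for enrichment.
"""

import numpy as np

from metpool.association import FeatureMatrix, rank_top_correlates, two_class_compare

rng = np.random.default_rng(3)
lines = [f"high{i}" for i in range(7)] + [f"low{i}" for i in range(14)]
labels = {l: ("high" if l.startswith("high") else "low") for l in lines}

values = (rng.random((20, 21)) < 0.15).astype(float)  # background mutations
values[0] = [1] * 4 + [0] * 3 + [0] * 14            # the enriched gene
features = FeatureMatrix(
    values=values,
    feature_ids=["GENE_X"] + [f"bg{i}" for i in range(1, 20)],
    line_ids=lines,
    feature_type="mutation",
)

result = two_class_compare(features, labels, alternative="greater")
top = rank_top_correlates(result, k=3)
print(top.to_string(index=False, float_format=lambda x: f"{x:.4g}"))

p = result.set_index("feature").loc["GENE_X", "p"]
print(f"\nGENE_X one-sided Fisher p = {p:.6f} (= 35/5985 = {35/5985:.6f}):")
print("with 4 mutations among 21 lines, the chance that all 4 land in the "
      "7 high-potential lines is C(7,4)/C(21,4).")
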