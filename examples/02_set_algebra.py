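"""Common genes, opposite-direction genes and condition-specific lists.

Two comparisons sharing a reference condition are intersected; concordant
common genes (shared biology) are subtracted, while genes moving in
opposite directions — the most condition-discriminating — stay in both
specific lists.
"""

from deapr import (
    FixtureSpec, generate, intersect_comparisons, select_de_genes,
    sets_by_label, specific_genes,
)

bundle = generate(FixtureSpec(seed=42))
sets = sets_by_label(bundle.sample_sets)

comp1 = select_de_genes(bundle.matrix, bundle.annotation, sets["B11_0"], sets["THP1_0"])
comp2 = select_de_genes(bundle.matrix, bundle.annotation, sets["B11_0"], sets["B11_1"])

common = intersect_comparisons(comp1, comp2)
discordant = [c for c in common if not c.concordant]
spec1 = specific_genes(comp1, common)
spec2 = specific_genes(comp2, intersect_comparisons(comp2, comp1))

print(f"comparison 1: {len(comp1)} DE genes; comparison 2: {len(comp2)}")
print(f"common to both: {len(common)}, of which {len(discordant)} opposite-direction")
print(f"specific lists: {len(spec1)} and {len(spec2)}")
print(f"identity |specific| = |A| - |common| + |discordant|: "
      f"{len(spec1)} = {len(comp1)} - {len(common)} + {len(discordant)}\n")

print("opposite-direction genes (up with one condition, down with the other):")
for c in discordant[:5]:
    print(f"  {c.symbol:<10} fc_A={c.fc_in_a:+6.2f}  fc_B={c.fc_in_b:+6.2f}")
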