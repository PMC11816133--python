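"""Classify dose-response shapes over a three-level dose series.

Genes DE between the middle and highest dose are classified by their
per-set means into upward, downward, A-shift (peak at the middle dose) or
V-shift (trough at the middle dose) trends; the lowest dose contributes
shape only.
"""

from collections import Counter

from deapr import (
    FixtureSpec, classify_dose_patterns, direction_summary, generate,
    select_de_genes, sets_by_label,
)

bundle = generate(FixtureSpec(seed=42))
sets = sets_by_label(bundle.sample_sets)

# dose escalation: mid dose (reference) vs high dose (test)
comp = select_de_genes(bundle.matrix, bundle.annotation, sets["B11_1"], sets["B11_10"])
patterns = classify_dose_patterns(
    bundle.matrix, comp, low=sets["B11_0"], mid=sets["B11_1"], high=sets["B11_10"])

print(f"{len(comp)} DE genes in the dose-escalation comparison")
print("pattern census:", dict(Counter(p.pattern for p in patterns)))
print("direction split:", direction_summary(comp))
print()
for p in patterns[:5]:
    print(f"  {p.symbol:<10} {p.pattern:<10} "
          f"means {p.mean_low:7.1f} -> {p.mean_mid:7.1f} -> {p.mean_high:7.1f}")

# A large down-regulated share at the top dose, dominated by A-shift genes,
# is the signature of feedback suppression kicking in above the middle dose.
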