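"""Family assignment by the 70% LTR rule and insertion dating.

Builds three same-species elements (two related, one distant), clusters
them into families, and dates a constructed LTR pair with the K2P clock.
"""

import random

from centroscan import FamilyInput, assign_families, estimate_age, ltr_identity

rng = random.Random(3)
ltr_a = "".join(rng.choice("ACGT") for _ in range(600))
ltr_b = list(ltr_a)  # ~95% identity relative of ltr_a
for i in rng.sample(range(600), 30):
    ltr_b[i] = next(c for c in "CAGT" if c != ltr_a[i])
ltr_c = "".join(rng.choice("ACGT") for _ in range(600))  # unrelated

elements = [
    FamilyInput("elem1", "Pisum sativum", ltr_a, 7000),
    FamilyInput("elem2", "Pisum sativum", "".join(ltr_b), 6800),
    FamilyInput("elem3", "Pisum sativum", ltr_c, 7200),
]
for x, y in [("elem1", "elem2"), ("elem1", "elem3")]:
    a = next(e.ltr5_seq for e in elements if e.element_id == x)
    b = next(e.ltr5_seq for e in elements if e.element_id == y)
    ident, cov = ltr_identity(a, b)
    print(f"{x} vs {y}: {ident:.1f}% LTR identity (coverage {cov:.2f})")

families, _ = assign_families(elements)
for fam in families:
    print(f"{fam.family_id}: members {fam.members}")

# Date an element whose LTR pair has accumulated 20 transitions over 1 kb
aged = list("".join(rng.choice("ACGT") for _ in range(1000)))
young = "".join(aged)
ti = {"A": "G", "G": "A", "C": "T", "T": "C"}
for i in rng.sample(range(1000), 20):
    aged[i] = ti[aged[i]]
est = estimate_age(young, "".join(aged))
print(f"K2P distance K = {est.k:.6f}, age = {est.age_years / 1e6:.3f} My "
      f"(rate {est.rate:.1e}/site/yr)")

# Elements sharing >= 70% LTR identity in one species form one family; the
# age is K / (2r): the LTR pair was identical at insertion, so its corrected
# divergence measures twice the time elapsed.
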