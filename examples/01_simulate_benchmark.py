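"""Generate a synthetic benchmark genome with ground truth.

Builds a small genome carrying group A/B/C CRM-like insertions plus one
non-CRM decoy, and prints what the manifest knows about each element.
"""

from centroscan import SimConfig, generate_benchmark

cfg = SimConfig(n_elements=4, age_years=(0.0, 1.5e6))
bench = generate_benchmark(cfg, seed=42)

print(f"genome: {bench.genome.id}, {len(bench.genome):,} bp, "
      f"{len(bench.manifest.elements)} implanted elements")
for t in bench.manifest.elements:
    print(f"  {t.element_id}: group {t.group} ({t.clade}), family {t.family_id}, "
          f"{t.start}-{t.end} ({t.end - t.start} bp), "
          f"LTR {t.ltr5[1] - t.ltr5[0]} bp, TSD {t.tsd_seq}, "
          f"age {t.age_years / 1e6:.2f} My")
print(f"small-RNA library: {len(bench.reads)} reads (mode 24 nt)")

# Each line is one ground-truth insertion: its PTD group (A = CR motif,
# B = none, C = type II chromodomain), clade, coordinates, LTR length, the
# 5-bp target site duplication and the age used to diverge its LTR pair.
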