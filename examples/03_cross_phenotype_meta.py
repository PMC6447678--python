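"""Cross-phenotype funnel: nominal-in-both filter, Fisher meta, intersection.

Also reproduces the published candidate-gene meta columns from the bundled
reference table: recomputing −2(ln P₁ + ln P₂) ~ χ²₄ from each row's two
per-disease gene p-values must match the published χ² and meta p.
"""
from pleiogene import bonferroni_threshold, fisher_meta, intersect_methods
from pleiogene.refdata import load_reference_candidates

df = load_reference_candidates()
print("recomputing published meta columns from per-disease gene p-values:")
print(f"{'gene':14s} {'p dis1':>9s} {'p dis2':>9s} {'chi2':>7s} {'meta p':>9s}  published")
for row in df.itertuples(index=False):
    chi2, meta_p = fisher_meta(row.p_is, row.p_pd)
    print(f"{row.gene:14s} {row.p_is:9.2e} {row.p_pd:9.2e} {chi2:7.2f} {meta_p:9.2e}"
          f"  ({row.chi2:.2f}, {row.meta_p:.2e})")

print("\nBonferroni thresholds: 0.05 / candidates / phenotypes")
print(f"  75 candidates, 2 phenotypes -> {bonferroni_threshold(75, 2):.2e}")
print(f"  33 candidates, 2 phenotypes -> {bonferroni_threshold(33, 2):.2e}")

shared = intersect_methods(
    df[df.method == "vegas"].gene.tolist(),
    df[df.method == "setscreen"].gene.tolist(),
)
print(f"\ngenes significant under BOTH methods: {shared}")
print("requiring agreement of two different gene tests is the final filter "
      "against method-specific artifacts")
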