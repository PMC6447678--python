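"""The whole analysis in one call: simulate → test → meta → intersect → DE.

Runs the bundled demo configuration (60 genes, 6 pleiotropic, 6 + 6
phenotype-specific, two expression cohorts) and prints the funnel the
pipeline logs: testable genes → doubly-nominal candidates → Bonferroni
survivors per method → two-method intersection.
"""
import pandas as pd

from pleiogene import demo_config, run_pipeline

manifest = run_pipeline(demo_config(seed=17, outdir="runs/demo"))

print("funnel counts per method:")
for method in ("vegas", "setscreen"):
    c = manifest.counts[method]
    print(f"  {method:10s} testable {c['testable_pheno1']}/{c['testable_pheno2']}"
          f" -> candidates {c['candidates']} -> significant {c['significant']}")
print(f"  intersection of the two significant sets: {manifest.counts['intersected']}")
print(f"\nshared genes: {manifest.shared_genes}")

truth = pd.read_csv("runs/demo/truth.tsv", sep="\t", keep_default_na=False)
planted = sorted(truth[truth.label == "shared"].gene_id)
print(f"planted pleiotropic genes: {planted}")
print("\nevery output table plus a manifest with file digests is in runs/demo/;"
      "\nrerunning with the same seed reproduces all files bit-identically")
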