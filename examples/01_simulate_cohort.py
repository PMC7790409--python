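"""Generate a synthetic tumor-exome cohort and inspect its ground truth.

The default presets emulate a 15-tumor study: 7 "WT-like" tumors with a
moderate AID-like mutational process and 8 "KI-like" tumors with more
mutations, stronger WRC/GYW hotspot focusing and a heavier subclonal
compartment, plus one healthy-tissue control sharing 50 germline variants.
"""

from aidscope import default_config, simulate_cohort, write_cohort

config = default_config(seed=7)
cohort = simulate_cohort(config)
manifest = write_cohort(cohort, "scratch/example_cohort")

truth = cohort.truth
somatic = truth[truth.origin.str.startswith(("clonal", "subclonal"))]
print(f"samples: {len(cohort.samples)} tumors + healthy control")
print(f"somatic variants: {len(somatic)}, "
      f"germline calls: {(truth.origin == 'germline').sum()}")
print(f"hotspot fraction of somatic SNVs: {somatic.hotspot.mean():.3f}")
print("origin mix:")
print(somatic.origin.value_counts().to_string())
# 'clonal' variants sit at VAF ~ purity*CCF/2 = 0.38; each 'subclonal:k'
# clone sits lower, which is what the VAF clustering stage must recover.
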