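"""Build the panel of normals and remove germline/artifact calls.

The panel combines three rules: caller-concordant healthy-tissue variants
(set1), variants called in every tumor plus healthy with at most two
NO_PASS labels (set2), and variants called in >=13 tumors plus healthy
that are PASS everywhere called (set3).  Filtering then drops any tumor
call present in the panel, in the healthy tissue, or in a known-sites
list.
"""

from collections import Counter

from aidscope import default_config, simulate_cohort
from aidscope.pon import FilterConfig, build_pon, filter_somatic

cohort = simulate_cohort(default_config(seed=7))
cfg = FilterConfig(n_all=15, n_most=13, max_no_pass_set2=2)
pon = build_pon(cohort.healthy_germline, cohort.healthy_somatic,
                cohort.tumor_records, cfg)

prov = Counter(tag for tags in pon.provenance.values() for tag in tags)
print(f"panel of normals: {len(pon)} entries "
      f"(set1={prov['set1']}, set2={prov['set2']}, set3={prov['set3']})")

res = filter_somatic(cohort.tumor_records, pon,
                     list(cohort.healthy_germline) + list(cohort.healthy_somatic),
                     {"known": cohort.known_sites})
print(res.report().to_string(index=False))
# Every tumor loses its ~50 shared germline calls and ~30 recurrent
# artifacts; the private somatic variants all survive.
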