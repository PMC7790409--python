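"""Panel-of-normals set logic, checked against a brute-force oracle."""

import numpy as np
import pytest

from aidscope.core_io import NO_PASS, PASS, VariantRecord
from aidscope.pon import (FilterConfig, PanelOfNormals, build_pon,
                          filter_somatic, record_key)


def rec(pos, sample, flt=PASS, ref="A", alt="G", chrom="chr1"):
    return VariantRecord(chrom, pos, ref, alt, sample, 100, 40, flt)


# ---------------------------------------------------------------------------
# independent brute-force oracle: evaluates the three panel rules and the
# removal rules by exhaustive set membership, with no shared code paths

def oracle_pon(healthy_germline, healthy_somatic, tumor_calls, n_most,
               max_no_pass):
    def keyset(recs):
        return {record_key(r) for r in recs}

    germ, som = keyset(healthy_germline), keyset(healthy_somatic)
    healthy = germ | som
    all_keys = set().union(*(keyset(v) for v in tumor_calls.values()), healthy)
    panel = {}
    for k in all_keys:
        prov = set()
        if k in germ and k in som:
            prov.add("set1")
        tumors_with = [s for s, v in tumor_calls.items() if k in keyset(v)]
        labels = {}
        for s in tumors_with:
            labs = {r.caller_filter for r in tumor_calls[s]
                    if record_key(r) == k}
            labels[s] = PASS if PASS in labs else NO_PASS
        n_np = sum(1 for v in labels.values() if v == NO_PASS)
        if k in healthy and len(tumors_with) == len(tumor_calls) \
                and n_np <= max_no_pass:
            prov.add("set2")
        if k in healthy and len(tumors_with) >= n_most and n_np == 0:
            prov.add("set3")
        if prov:
            panel[k] = frozenset(prov)
    return panel


def oracle_filter(tumor_calls, panel, healthy_keys, known):
    kept, reasons = {}, {}
    for s, recs in tumor_calls.items():
        kept[s] = []
        for r in recs:
            k = record_key(r)
            if k in panel:
                reasons[(s, k)] = "pon"
            elif k in healthy_keys:
                reasons[(s, k)] = "healthy"
            elif k in known:
                reasons[(s, k)] = "known_sites"
            else:
                kept[s].append(r)
    return kept, reasons


def random_toy_cohort(rng, n_samples=None, n_variants=None):
    n_samples = n_samples or int(rng.integers(2, 7))
    n_variants = n_variants or int(rng.integers(20, 500))
    positions = rng.choice(5000, size=n_variants, replace=False) + 1
    samples = [f"T{i}" for i in range(n_samples)]
    tumor_calls = {s: [] for s in samples}
    healthy_germ, healthy_som, known = [], [], set()
    for pos in positions:
        pos = int(pos)
        in_germ, in_som = rng.random() < 0.3, rng.random() < 0.3
        if in_germ:
            healthy_germ.append(rec(pos, "healthy"))
        if in_som:
            healthy_som.append(rec(pos, "healthy"))
        if rng.random() < 0.1:
            known.add(("chr1", pos, "A", "G"))
        for s in samples:
            if rng.random() < 0.6:
                flt = NO_PASS if rng.random() < 0.25 else PASS
                tumor_calls[s].append(rec(pos, s, flt))
    return healthy_germ, healthy_som, tumor_calls, known


class TestBuildPon:
    def test_set1_is_healthy_intersection(self):
        germ = [rec(10, "healthy"), rec(20, "healthy")]
        som = [rec(10, "healthy"), rec(30, "healthy")]
        pon = build_pon(germ, som, {"T0": [rec(99, "T0")]},
                        FilterConfig(n_all=1, n_most=1, max_no_pass_set2=0))
        assert pon.provenance[("chr1", 10, "A", "G")] == frozenset({"set1"})
        assert ("chr1", 20, "A", "G") not in pon

    @pytest.mark.parametrize("n_no_pass,in_set2", [(0, True), (1, True),
                                                   (2, False)])
    def test_set2_no_pass_tolerance(self, n_no_pass, in_set2):
        # toy cohort n_all=3, max_no_pass_set2=1
        cfg = FilterConfig(n_all=3, n_most=3, max_no_pass_set2=1)
        tumors = {}
        for i in range(3):
            flt = NO_PASS if i < n_no_pass else PASS
            tumors[f"T{i}"] = [rec(10, f"T{i}", flt)]
        pon = build_pon([rec(10, "healthy")], [], tumors, cfg)
        assert (("chr1", 10, "A", "G") in pon
                and "set2" in pon.provenance[("chr1", 10, "A", "G")]) == in_set2

    def test_set3_requires_pass_everywhere_called(self):
        cfg = FilterConfig(n_all=3, n_most=3, max_no_pass_set2=1)
        all_pass = {f"T{i}": [rec(10, f"T{i}", PASS)] for i in range(3)}
        pon = build_pon([rec(10, "healthy")], [], all_pass, cfg)
        assert "set3" in pon.provenance[("chr1", 10, "A", "G")]
        one_np = {f"T{i}": [rec(10, f"T{i}", NO_PASS if i == 0 else PASS)]
                  for i in range(3)}
        pon = build_pon([rec(10, "healthy")], [], one_np, cfg)
        prov = pon.provenance.get(("chr1", 10, "A", "G"), frozenset())
        assert "set3" not in prov and "set2" in prov  # may still be set2

    def test_sample_count_mismatch_is_error(self):
        cfg = FilterConfig(n_all=15)
        with pytest.raises(ValueError, match="n_all"):
            build_pon([], [], {"T0": [rec(1, "T0")]}, cfg)
        build_pon([], [], {"T0": [rec(1, "T0")]}, cfg, allow_n_mismatch=True)

    def test_provenance_partition_counts(self, small_cohort):
        cfg = FilterConfig(n_all=len(small_cohort.samples),
                           n_most=len(small_cohort.samples) - 2)
        pon = build_pon(small_cohort.healthy_germline,
                        small_cohort.healthy_somatic,
                        small_cohort.tumor_records, cfg)
        assert len(pon) > 0
        assert all(v for v in pon.provenance.values())
        assert len(pon.entries) == len(pon.provenance)


class TestFilterSomatic:
    def test_known_site_removed_with_reason(self):
        pon = PanelOfNormals({})
        res = filter_somatic({"T0": [rec(10, "T0")]}, pon, set(),
                             {"dbsnp": {("chr1", 10, "A", "G")}})
        assert res.kept["T0"] == []
        assert res.removed["T0"]["known_sites"] == 1

    def test_private_variant_retained(self):
        res = filter_somatic({"T0": [rec(10, "T0")]}, PanelOfNormals({}),
                             set(), {})
        assert len(res.kept["T0"]) == 1

    def test_reason_precedence_pon_first(self):
        key = ("chr1", 10, "A", "G")
        pon = PanelOfNormals({key: frozenset({"set1"})})
        res = filter_somatic({"T0": [rec(10, "T0")]}, pon, {key},
                             {"dbsnp": {key}})
        assert res.removal_reasons[("T0", key)] == "pon"

    def test_known_sites_monotonicity(self):
        rng = np.random.default_rng(0)
        germ, som, tumors, known = random_toy_cohort(rng, n_samples=4)
        cfg = FilterConfig(n_all=4, n_most=3, max_no_pass_set2=1)
        pon = build_pon(germ, som, tumors, cfg)
        healthy = germ + som
        base = filter_somatic(tumors, pon, healthy, {"k": known})
        bigger = known | {("chr1", 4999, "A", "G"), ("chr1", 4998, "A", "G")}
        more = filter_somatic(tumors, pon, healthy, {"k": bigger})
        for s in tumors:
            assert set(r.key for r in more.kept[s]) <= \
                set(r.key for r in base.kept[s])

    def test_position_only_matching_mode(self):
        res = filter_somatic({"T0": [rec(10, "T0", alt="C")]},
                             PanelOfNormals({}), set(),
                             {"dbsnp": {("chr1", 10, "A", "G")}},
                             known_site_match="position")
        assert res.kept["T0"] == []  # same position, different allele


def test_filter_matches_oracle_on_random_cohorts():
    """Panel construction + filtering equal brute-force set logic."""
    rng = np.random.default_rng(1234)
    for _ in range(30):
        germ, som, tumors, known = random_toy_cohort(rng)
        n = len(tumors)
        n_most = max(1, n - 1)
        cfg = FilterConfig(n_all=n, n_most=n_most, max_no_pass_set2=1)
        pon = build_pon(germ, som, tumors, cfg)
        expected_panel = oracle_pon(germ, som, tumors, n_most, 1)
        assert pon.provenance == expected_panel

        healthy_keys = {record_key(r) for r in germ + som}
        res = filter_somatic(tumors, pon, germ + som, {"k": known})
        exp_kept, exp_reasons = oracle_filter(tumors, expected_panel,
                                              healthy_keys, known)
        assert res.kept == exp_kept
        assert res.removal_reasons == exp_reasons
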