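"""Substitution classification, hotspot motif logic and spectrum tests."""

import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from aidscope.core_io import TargetSpace, VariantRecord, records_to_frame
from aidscope.spectrum import (WRC, WRCY, HotspotIndex, classify_substitution,
                               compare_spectra, hotspot_mask, is_hotspot,
                               spectrum_summary, target_composition,
                               association_test)

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def regex_oracle_mask(seq, four_mer=False):
    """Both-strand regex scan for WRC/GYW (or WRCY/RGYW) hotspot C/G."""
    mask = np.zeros(len(seq), dtype=bool)
    fwd = r"(?=[AT][AG]C[CT])" if four_mer else r"(?=[AT][AG]C)"
    rev = r"(?=[AG]G[CT][AT])" if four_mer else r"(?=G[CT][AT])"
    off_c = 2
    for m in re.finditer(fwd, seq):
        mask[m.start() + off_c] = True
    off_g = 1 if four_mer else 0
    for m in re.finditer(rev, seq):
        mask[m.start() + off_g] = True
    return mask


class TestClassify:
    @pytest.mark.parametrize("ref,alt,expected", [
        ("C", "T", ("Ts", "CG")), ("G", "A", ("Ts", "CG")),
        ("C", "A", ("Tv", "CG")), ("C", "G", ("Tv", "CG")),
        ("G", "T", ("Tv", "CG")), ("G", "C", ("Tv", "CG")),
        ("A", "G", ("Ts", "AT")), ("T", "C", ("Ts", "AT")),
        ("A", "C", ("Tv", "AT")), ("A", "T", ("Tv", "AT")),
        ("T", "A", ("Tv", "AT")), ("T", "G", ("Tv", "AT")),
    ])
    def test_all_substitutions(self, ref, alt, expected):
        assert classify_substitution(ref, alt) == expected

    @pytest.mark.parametrize("ref,alt", [("A", "A"), ("N", "G"), ("C", "N")])
    def test_invalid_inputs(self, ref, alt):
        with pytest.raises(ValueError):
            classify_substitution(ref, alt)


class TestHotspot:
    def test_wrc_c(self, make_targets):
        ts = make_targets({"chr1": "TACGA"})
        assert is_hotspot(ts, "chr1", 3, "C") is True  # TAC: W=T, R=A

    def test_gyw_requires_pyrimidine(self, make_targets):
        ts = make_targets({"chr1": "TACGA"})
        # G at pos 4 needs G,Y,W downstream: G,A,... -> Y=A fails
        assert is_hotspot(ts, "chr1", 4, "G") is False

    def test_edge_position_flagged(self, make_targets):
        ts = make_targets({"chr1": "AGTAG"})
        hot, edge = is_hotspot(ts, "chr1", 5, "G", with_edge=True)
        assert hot is False and edge is True

    def test_gyw_positive(self, make_targets):
        ts = make_targets({"chr1": "AGTAG"})  # G at pos 2: G,T,A = G,Y,W
        assert is_hotspot(ts, "chr1", 2, "G") is True

    def test_reference_mismatch_is_error(self, make_targets):
        ts = make_targets({"chr1": "TACGA"})
        with pytest.raises(ValueError, match="mismatch"):
            is_hotspot(ts, "chr1", 3, "G")

    def test_hotspot_independent_of_alt(self, make_targets):
        # status is a property of the reference site only
        ts = make_targets({"chr1": "TACGA"})
        assert is_hotspot(ts, "chr1", 3, "C") is True

    def test_four_mer_motif_variant(self):
        # WRCY: TACT -> C hotspot only if downstream Y present
        assert hotspot_mask("TACT", WRCY)[2]
        assert not hotspot_mask("TACA", WRCY)[2]
        assert hotspot_mask("TAC", WRC)[2]

    def test_mask_matches_regex_oracle_on_random_sequences(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            seq = "".join(rng.choice(list("ACGT"), size=1000))
            np.testing.assert_array_equal(hotspot_mask(seq),
                                          regex_oracle_mask(seq))
            np.testing.assert_array_equal(
                hotspot_mask(seq, WRCY), regex_oracle_mask(seq, four_mer=True))

    @settings(max_examples=50, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=3, max_size=200))
    def test_strand_symmetry(self, seq):
        """Reverse-complementing the reference preserves hotspot status."""
        rc = seq.translate(COMPLEMENT)[::-1]
        np.testing.assert_array_equal(hotspot_mask(seq),
                                      hotspot_mask(rc)[::-1])


class TestComposition:
    def test_tacgt_counts(self, make_targets):
        comp = target_composition(make_targets({"chr1": "TACGT"}))
        assert (comp.n_cg, comp.n_at) == (2, 3)
        # C in TAC is hotspot; G at pos 4 has GYW context truncated -> edge
        assert comp.n_cg_hotspot == 1

    def test_composition_matches_oracle(self, make_targets):
        rng = np.random.default_rng(11)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=1000))
            comp = target_composition(make_targets({"chr1": seq}))
            arr = np.array(list(seq))
            assert comp.n_cg == int(np.isin(arr, ["C", "G"]).sum())
            assert comp.n_at == len(seq) - comp.n_cg
            assert comp.n_cg_hotspot == int(regex_oracle_mask(seq).sum())

    def test_edge_bases_count_in_total_only(self, make_targets):
        # two abutting-but-separate intervals truncate motif context
        seq = "TACGATACGA"
        whole = target_composition(make_targets({"chr1": seq}))
        split = target_composition(make_targets(
            {"chr1": seq}, intervals=[("chr1", 0, 3), ("chr1", 4, 10)]))
        assert split.n_cg <= whole.n_cg
        assert split.n_cg_hotspot <= whole.n_cg_hotspot


class TestSummary:
    def _targets(self, make_targets):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        return make_targets({"chr1": seq}), seq

    def test_simple_frequency(self, make_targets):
        ts, seq = self._targets(make_targets)
        comp = target_composition(ts)
        c_pos = seq.index("C") + 1
        recs = [VariantRecord("chr1", c_pos, "C", "T", "s1", 100, 40)]
        summary = spectrum_summary(records_to_frame(recs), ts, {"s1": "g"})
        row = summary.per_sample.iloc[0]
        assert row.ts_cg == 1
        assert row.freq_ts_cg == pytest.approx(1 / comp.n_cg)

    def test_zero_variants_all_zero(self, make_targets):
        ts, _ = self._targets(make_targets)
        summary = spectrum_summary(records_to_frame([]), ts, {"s1": "g"})
        assert (summary.per_sample[["ts_cg", "tv_cg", "ts_at", "tv_at"]]
                .to_numpy() == 0).all()

    def test_duplicated_cohort_leaves_frequencies_unchanged(self, make_targets):
        """Doubling all counts and denominators preserves frequencies."""
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        single = make_targets({"chr1": seq})
        double = make_targets({"chr1": seq, "chr2": seq})
        recs = []
        for i, p in enumerate(np.flatnonzero(np.array(list(seq)) == "C")[:20]):
            recs.append(VariantRecord("chr1", int(p) + 1, "C", "T", "s1",
                                      100, 40))
        mirrored = recs + [VariantRecord("chr2", r.pos, r.ref, r.alt, "s1",
                                         r.depth, r.alt_count) for r in recs]
        f1 = spectrum_summary(records_to_frame(recs), single, {"s1": "g"})
        f2 = spectrum_summary(records_to_frame(mirrored), double, {"s1": "g"})
        for col in ["freq_ts_cg", "freq_ts_cg_hotspot"]:
            assert f2.per_sample[col].iloc[0] == pytest.approx(
                f1.per_sample[col].iloc[0])

    def test_variant_outside_targets_counted(self, make_targets):
        ts = make_targets({"chr1": "TACGATACGA"},
                          intervals=[("chr1", 0, 5)])
        recs = [VariantRecord("chr1", 8, "C", "T", "s1", 100, 40)]
        summary = spectrum_summary(records_to_frame(recs), ts, {"s1": "g"})
        assert summary.n_outside_targets == 1
        assert summary.per_sample.iloc[0].ts_cg == 0


class TestTwoByTwo:
    def test_identical_margins_fisher_p1(self):
        _, p = association_test(np.array([[10, 90], [10, 90]]), "fisher")
        assert p == pytest.approx(1.0)

    def test_fisher_matches_exhaustive_enumeration(self):
        """Two-sided rule: sum of tables at most as probable as observed."""
        table = np.array([[1, 9], [11, 3]])
        _, p = association_test(table, "fisher")
        assert p == pytest.approx(_fisher_enum(table), rel=1e-9)
        assert p == pytest.approx(2.7594561852e-3, rel=1e-6)

    def test_chi2_equals_closed_form_pearson(self):
        table = np.array([[20, 980], [40, 960]])
        stat, _ = association_test(table, "chi2")
        expected = table.sum() * (20 * 960 - 980 * 40) ** 2 / \
            (60 * 1940 * 1000 * 1000)
        assert stat == pytest.approx(expected)

    def test_zero_margin_is_error(self):
        with pytest.raises(ValueError, match="margin"):
            association_test(np.array([[0, 0], [5, 5]]), "chi2")


def _fisher_enum(table):
    a, b = table[0]
    c, d = table[1]
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    pmf = {x: stats.hypergeom.pmf(x, n, c1, r1) for x in range(lo, hi + 1)}
    return sum(p for p in pmf.values() if p <= pmf[a] * (1 + 1e-9))


class TestCompareSpectra:
    def test_contrasts_reported(self, make_targets, small_cohort):
        from aidscope.pipeline import analyze_cohort
        res = analyze_cohort(small_cohort)
        tests = res["spectrum_tests"]
        assert len(tests) == 4
        assert (tests.p_value.between(0, 1)).all()
        # simulated KI-like group is hotspot-enriched vs WT-like
        hot = tests[tests.contrast.str.startswith("hotspot_cg")].iloc[0]
        assert hot.p_value < 1e-6

    def test_enrichment_ratio_orders_with_w(self, small_cohort):
        from aidscope.pipeline import analyze_cohort
        res = analyze_cohort(small_cohort)
        pg = res["spectrum"].per_group.set_index("group")
        assert pg.loc["KI-like", "hotspot_enrichment"] > \
            pg.loc["WT-like", "hotspot_enrichment"]
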