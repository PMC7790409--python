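"""Mutation-spectrum statistics over AID hotspot context.

AID deaminates cytosines preferentially inside the WRC motif (W = A/T,
R = A/G), with GYW (Y = C/T) the reverse-complement context marking the
paired G on the forward strand.  In UNG-deficient cells the resulting U:G
mismatches replicate into C:G transitions, so the analysis classifies each
substitution by transition/transversion and C/G vs A/T reference base,
flags hotspot context, and normalizes counts by the base composition of the
captured target space (mutations per eligible base).

Hotspot status depends only on the reference sequence, never on the alt
allele.  A position whose motif context runs past its target-interval or
chromosome boundary is never a hotspot ("edge" positions); edge C/G bases
still count in the total C/G denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import TargetSpace

__all__ = [
    "HotspotMotif", "WRC", "WRCY", "TargetComposition", "SpectrumSummary",
    "HotspotIndex", "classify_substitution", "is_hotspot", "hotspot_mask",
    "target_composition", "spectrum_summary", "compare_spectra",
    "association_test", "get_motif",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

W = frozenset("AT")
R = frozenset("AG")
Y = frozenset("CT")


@dataclass(frozen=True)
class HotspotMotif:
    """Hotspot context around a mutable C, plus its strand mirror for G.

    ``upstream`` are the base sets immediately 5' of the C (ordered outermost
    first) and ``downstream`` the sets 3' of it.  The G-strand pattern is
    derived by reverse complement, so WRC yields GYW and WRCY yields RGYW
    automatically.
    """

    name: str
    upstream: tuple[frozenset, ...] = (W, R)
    downstream: tuple[frozenset, ...] = ()

    @property
    def span_before(self) -> int:
        return len(self.upstream)

    @property
    def span_after(self) -> int:
        return len(self.downstream)

    def _complement_set(self, bases: frozenset) -> frozenset:
        return frozenset(_COMPLEMENT[b] for b in bases)

    def c_matches(self, seq: str, i: int) -> bool:
        """Is the C at 0-based ``i`` of ``seq`` in hotspot context?"""
        if seq[i] != "C":
            return False
        if i - self.span_before < 0 or i + self.span_after >= len(seq):
            return False
        up = all(seq[i - self.span_before + j] in s
                 for j, s in enumerate(self.upstream))
        down = all(seq[i + 1 + j] in s for j, s in enumerate(self.downstream))
        return up and down

    def g_matches(self, seq: str, i: int) -> bool:
        if seq[i] != "G":
            return False
        if i + self.span_before >= len(seq) or i - self.span_after < 0:
            return False
        up = all(seq[i + self.span_before - j] in self._complement_set(s)
                 for j, s in enumerate(self.upstream))
        down = all(seq[i - 1 - j] in self._complement_set(s)
                    for j, s in enumerate(self.downstream))
        return up and down


#: 3-mer motif (headline analysis): WRC / GYW.
WRC = HotspotMotif("wrc", upstream=(W, R))
#: 4-mer motif variant: WRCY / RGYW.
WRCY = HotspotMotif("wrcy", upstream=(W, R), downstream=(Y,))
#: Literal printed-alphabet variant with R = C/G (nonstandard; see docs).
WRC_PRINTED = HotspotMotif("wrc-printed", upstream=(W, frozenset("CG")))

_MOTIFS = {"wrc": WRC, "wrcy": WRCY, "wrc-printed": WRC_PRINTED}


def get_motif(motif: str | HotspotMotif) -> HotspotMotif:
    if isinstance(motif, HotspotMotif):
        return motif
    try:
        return _MOTIFS[motif.lower()]
    except KeyError:
        raise ValueError(f"unknown motif {motif!r}; use one of {sorted(_MOTIFS)}")


def classify_substitution(ref: str, alt: str) -> tuple[str, str]:
    """Classify a substitution as (``Ts``|``Tv``, ``CG``|``AT``).

    Transitions are purine<->purine or pyrimidine<->pyrimidine
    ({A,G} or {C,T} pairs); the base class follows the reference base.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in "ACGT" or alt not in "ACGT" or len(ref) != 1 or len(alt) != 1:
        raise ValueError(f"non-ACGT substitution {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError(f"ref equals alt ({ref})")
    ts = {ref, alt} in ({"A", "G"}, {"C", "T"})
    return ("Ts" if ts else "Tv", "CG" if ref in "CG" else "AT")


def hotspot_mask(seq: str, motif: str | HotspotMotif = WRC) -> np.ndarray:
    """Boolean hotspot flag per position of ``seq`` (edges always False).

    Vectorized scan: a C is flagged when its upstream window matches the
    motif, a G when its downstream window matches the reverse complement.
    Non-C/G positions are always False.
    """
    m = get_motif(motif)
    arr = np.frombuffer(seq.upper().encode(), dtype="S1")
    n = arr.size
    mask = np.zeros(n, dtype=bool)
    if n == 0:
        return mask

    def base_in(offset: int, bases: frozenset) -> np.ndarray:
        """Window test at each position + offset; out-of-range is False."""
        ok = np.zeros(n, dtype=bool)
        lo, hi = max(0, -offset), min(n, n - offset)
        if lo >= hi:
            return ok
        window = arr[lo + offset:hi + offset]
        hit = np.zeros(hi - lo, dtype=bool)
        for b in bases:
            hit |= window == b.encode()
        ok[lo:hi] = hit
        return ok

    c_ok = arr == b"C"
    for j, s in enumerate(m.upstream):
        c_ok &= base_in(-m.span_before + j, s)
    for j, s in enumerate(m.downstream):
        c_ok &= base_in(1 + j, s)

    comp = {b: frozenset(_COMPLEMENT[x] for x in b) for b in set(m.upstream) | set(m.downstream)}
    g_ok = arr == b"G"
    for j, s in enumerate(m.upstream):
        g_ok &= base_in(m.span_before - j, comp[s])
    for j, s in enumerate(m.downstream):
        g_ok &= base_in(-1 - j, comp[s])

    mask = c_ok | g_ok
    return mask


def is_hotspot(targets: TargetSpace, chrom: str, pos: int, ref: str,
               motif: str | HotspotMotif = WRC,
               with_edge: bool = False) -> bool | tuple[bool, bool]:
    """Hotspot status of the reference base at a 1-based target position.

    Raises if ``ref`` disagrees with the reference genome.  With
    ``with_edge=True`` also returns whether the motif context ran past the
    containing target interval (edge positions are never hotspots).
    """
    m = get_motif(motif)
    actual = targets.base_at(chrom, pos)
    if actual != ref.upper():
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: expected {actual}, got {ref}")
    interval = next(((c, s, e) for c, s, e in targets.intervals
                     if c == chrom and s <= pos - 1 < e), None)
    if interval is None:
        raise ValueError(f"{chrom}:{pos} outside target space")
    _, start, end = interval
    seq = targets.interval_sequence(chrom, start, end)
    i = pos - 1 - start
    if ref.upper() == "C":
        edge = i - m.span_before < 0 or i + m.span_after >= len(seq)
        hot = (not edge) and m.c_matches(seq, i)
    elif ref.upper() == "G":
        edge = i + m.span_before >= len(seq) or i - m.span_after < 0
        hot = (not edge) and m.g_matches(seq, i)
    else:
        edge, hot = False, False
    return (hot, edge) if with_edge else hot


class HotspotIndex:
    """Precomputed per-interval hotspot masks for fast repeated lookups.

    Computes each target interval's hotspot mask once; queries are then
    O(log #intervals).  Semantics match :func:`is_hotspot` (edge positions
    are never hotspots).
    """

    def __init__(self, targets: TargetSpace, motif: str | HotspotMotif = WRC):
        self.targets = targets
        self.motif = get_motif(motif)
        self._by_chrom: dict[str, list[tuple[int, int, np.ndarray]]] = {}
        for chrom, start, end, seq in targets.iter_sequences():
            self._by_chrom.setdefault(chrom, []).append(
                (start, end, hotspot_mask(seq, self.motif)))

    def query(self, chrom: str, pos: int) -> bool:
        """Hotspot status at a 1-based position (False outside targets)."""
        for start, end, mask in self._by_chrom.get(chrom, ()):
            if start <= pos - 1 < end:
                return bool(mask[pos - 1 - start])
        return False


@dataclass(frozen=True)
class TargetComposition:
    """Base-composition denominators of the captured space."""

    n_cg: int
    n_cg_hotspot: int
    n_at: int

    def __post_init__(self):
        if self.n_cg_hotspot > self.n_cg:
            raise ValueError("n_cg_hotspot exceeds n_cg")

    @property
    def n_cg_nonhotspot(self) -> int:
        return self.n_cg - self.n_cg_hotspot

    @property
    def total(self) -> int:
        return self.n_cg + self.n_at


def target_composition(targets: TargetSpace,
                       motif: str | HotspotMotif = WRC) -> TargetComposition:
    """Exact linear-scan base counts of the target space.

    Edge C/G bases (motif context truncated by an interval boundary) count
    in ``n_cg`` but never in ``n_cg_hotspot``.
    """
    n_cg = n_cg_hot = n_at = 0
    for _, _, _, seq in targets.iter_sequences():
        arr = np.frombuffer(seq.upper().encode(), dtype="S1")
        cg = (arr == b"C") | (arr == b"G")
        n_cg += int(cg.sum())
        n_at += int(((arr == b"A") | (arr == b"T")).sum())
        n_cg_hot += int(hotspot_mask(seq, motif).sum())
    return TargetComposition(n_cg=n_cg, n_cg_hotspot=n_cg_hot, n_at=n_at)


_COUNT_COLS = ["ts_cg", "tv_cg", "ts_at", "tv_at", "ts_cg_hotspot", "tv_cg_hotspot"]


@dataclass
class SpectrumSummary:
    """Per-sample and per-group hotspot spectrum counts and frequencies.

    ``per_group`` reports both the pooled-count frequency
    (sum of counts / denominator) and the mean of per-sample frequencies;
    pooled is the headline figure.
    """

    per_sample: pd.DataFrame
    per_group: pd.DataFrame
    composition: TargetComposition
    n_outside_targets: int = 0


def _add_frequencies(df: pd.DataFrame, comp: TargetComposition) -> pd.DataFrame:
    df = df.copy()
    df["freq_ts_cg"] = df["ts_cg"] / comp.n_cg
    df["freq_tv_cg"] = df["tv_cg"] / comp.n_cg
    df["freq_ts_at"] = df["ts_at"] / comp.n_at
    df["freq_ts_cg_hotspot"] = df["ts_cg_hotspot"] / comp.n_cg_hotspot
    nonhot = comp.n_cg_nonhotspot
    df["freq_ts_cg_nonhotspot"] = (df["ts_cg"] - df["ts_cg_hotspot"]) / nonhot
    with np.errstate(divide="ignore", invalid="ignore"):
        df["hotspot_enrichment"] = np.where(
            df["freq_ts_cg_nonhotspot"] > 0,
            df["freq_ts_cg_hotspot"] / df["freq_ts_cg_nonhotspot"], np.nan)
    return df


def spectrum_summary(variants: pd.DataFrame, targets: TargetSpace,
                     grouping: Mapping[str, str],
                     composition: TargetComposition | None = None,
                     motif: str | HotspotMotif = WRC) -> SpectrumSummary:
    """Count substitutions by class and hotspot context per sample and group.

    ``variants`` is the normalized variant table; only SNVs inside the
    target space are counted (others are tallied in ``n_outside_targets``
    or ignored if INDELs).  ``grouping`` maps sample -> group label.
    """
    comp = composition or target_composition(targets, motif)
    snv = variants[variants["variant_class"] == "SNV"] if len(variants) else variants
    index = HotspotIndex(targets, motif)

    counts: dict[str, dict[str, int]] = {
        s: dict.fromkeys(_COUNT_COLS, 0) for s in grouping}
    n_outside = 0
    for row in snv.itertuples(index=False):
        if row.sample not in counts:
            continue
        if not targets.contains(row.chrom, int(row.pos)):
            n_outside += 1
            continue
        mut_type, base_class = classify_substitution(str(row.ref), str(row.alt))
        col = f"{mut_type.lower()}_{base_class.lower()}"
        counts[row.sample][col] += 1
        if base_class == "CG" and index.query(str(row.chrom), int(row.pos)):
            counts[row.sample][col + "_hotspot"] += 1

    per_sample = pd.DataFrame(
        [{"sample": s, "group": grouping[s], **c} for s, c in sorted(counts.items())])
    per_sample = _add_frequencies(per_sample, comp)

    pooled = per_sample.groupby("group", sort=True)[_COUNT_COLS].sum().reset_index()
    pooled = _add_frequencies(pooled, comp)
    means = (per_sample.groupby("group", sort=True)
             [[c for c in per_sample.columns if c.startswith("freq_")]]
             .mean().add_prefix("mean_").reset_index())
    per_group = pooled.merge(means, on="group")
    return SpectrumSummary(per_sample=per_sample, per_group=per_group,
                           composition=comp, n_outside_targets=n_outside)


def _two_by_two(mutated_a: int, total_a: int, mutated_b: int, total_b: int) -> np.ndarray:
    return np.array([[mutated_a, total_a - mutated_a],
                     [mutated_b, total_b - mutated_b]], dtype=np.int64)


def association_test(table: np.ndarray, mode: str = "chi2") -> tuple[float, float]:
    """Two-tailed test on a 2x2 mutated/unmutated table.

    chi2 is Pearson's statistic without continuity correction; fisher is
    the exact two-sided hypergeometric rule (sum of tables at least as
    extreme in probability as observed).  Returns (statistic, p); the
    Fisher statistic is the odds ratio.
    """
    table = np.asarray(table)
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("degenerate 2x2 table with a zero margin")
    if mode == "chi2":
        res = stats.chi2_contingency(table, correction=False)
        return float(res.statistic), float(res.pvalue)
    if mode == "fisher":
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return float(odds), float(p)
    raise ValueError(f"unknown test mode {mode!r}")


def compare_spectra(summary: SpectrumSummary, group_a: str, group_b: str,
                    mode: str = "chi2") -> pd.DataFrame:
    """Group contrasts on pooled transition-at-C/G counts.

    Three contrast families, each a 2x2 of mutated vs unmutated eligible
    bases: total C/G between groups, hotspot C/G between groups, and
    hotspot-vs-total within each group.
    """
    comp = summary.composition
    g = summary.per_group.set_index("group")
    for grp in (group_a, group_b):
        if grp not in g.index:
            raise ValueError(f"group {grp!r} not in summary")
    rows = []
    contrasts = [
        (f"total_cg:{group_a}_vs_{group_b}",
         _two_by_two(int(g.loc[group_a, "ts_cg"]), comp.n_cg,
                     int(g.loc[group_b, "ts_cg"]), comp.n_cg)),
        (f"hotspot_cg:{group_a}_vs_{group_b}",
         _two_by_two(int(g.loc[group_a, "ts_cg_hotspot"]), comp.n_cg_hotspot,
                     int(g.loc[group_b, "ts_cg_hotspot"]), comp.n_cg_hotspot)),
    ]
    for grp in (group_a, group_b):
        contrasts.append((
            f"hotspot_vs_total:{grp}",
            _two_by_two(int(g.loc[grp, "ts_cg_hotspot"]), comp.n_cg_hotspot,
                        int(g.loc[grp, "ts_cg"]), comp.n_cg)))
    for name, table in contrasts:
        statistic, p = association_test(table, mode)
        rows.append({"contrast": name, "mode": mode,
                     "a_mutated": int(table[0, 0]), "a_unmutated": int(table[0, 1]),
                     "b_mutated": int(table[1, 0]), "b_unmutated": int(table[1, 1]),
                     "statistic": statistic, "p_value": p})
    return pd.DataFrame(rows)
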