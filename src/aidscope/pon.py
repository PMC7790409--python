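"""Custom panel-of-normals construction and somatic false-positive removal.

The panel is assembled from three rules over the cohort's raw call sets:

* set1 — alleles called by both the germline and the somatic caller in the
  healthy-tissue control (caller-concordant germline).
* set2 — alleles called in every tumor sample *and* in healthy tissue,
  tolerating a NO_PASS caller label in at most ``max_no_pass_set2`` of the
  tumors (recurrent artifacts that occasionally trip caller filters).
* set3 — alleles called in at least ``n_most`` tumors and in healthy
  tissue, PASS in every tumor where called (near-universal germline or
  systematic artifacts).

"Called in" a sample means the allele key is present in that sample's call
file regardless of PASS label, except where a rule names the label
explicitly.  A tumor variant survives filtering iff its key is outside the
panel, absent from the healthy calls, and absent from every known-site
list (dbSNP-like / strain-variant-like).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_io import NO_PASS, PASS, VariantRecord, normalize_indel

__all__ = ["FilterConfig", "PanelOfNormals", "build_pon", "filter_somatic",
           "FilterResult"]

Key = tuple[str, int, str, str]

#: Removal reasons in fixed precedence order (first match wins).
REMOVAL_ORDER = ("pon", "healthy", "known_sites")


def record_key(rec: VariantRecord) -> Key:
    """Normalized allele key: INDELs are left-aligned and parsimony-trimmed
    before any cross-sample set comparison."""
    pos, ref, alt = normalize_indel(rec.pos, rec.ref, rec.alt)
    return (rec.chrom, pos, ref, alt)


@dataclass(frozen=True)
class FilterConfig:
    """Cohort-level thresholds for panel construction.

    Defaults follow the 15-tumor design: a set2/set3 panel entry must be
    seen in all 15 (``n_all``) or at least 13 (``n_most``) tumors, with at
    most 2 NO_PASS labels tolerated by set2.
    """

    n_all: int = 15
    n_most: int = 13
    max_no_pass_set2: int = 2
    healthy_mode: str = "either"  # either | somatic | germline
    known_site_match: str = "allele"  # allele | position

    def __post_init__(self):
        if self.n_most > self.n_all:
            raise ValueError("n_most must be <= n_all")
        if self.max_no_pass_set2 >= self.n_all:
            raise ValueError("max_no_pass_set2 must be < n_all")
        if self.healthy_mode not in ("either", "somatic", "germline"):
            raise ValueError(f"bad healthy_mode {self.healthy_mode!r}")
        if self.known_site_match not in ("allele", "position"):
            raise ValueError(f"bad known_site_match {self.known_site_match!r}")


@dataclass
class PanelOfNormals:
    """Allele keys with the provenance rule(s) that admitted each."""

    provenance: dict[Key, frozenset[str]] = field(default_factory=dict)

    @property
    def entries(self) -> set[Key]:
        return set(self.provenance)

    def __contains__(self, key: Key) -> bool:
        return key in self.provenance

    def __len__(self) -> int:
        return len(self.provenance)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3],
                 "provenance": ",".join(sorted(v))}
                for k, v in sorted(self.provenance.items())]
        return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                           "provenance"])


def _keys(records: Iterable[VariantRecord]) -> set[Key]:
    return {record_key(r) for r in records}


def build_pon(healthy_germline: Iterable[VariantRecord],
              healthy_somatic: Iterable[VariantRecord],
              tumor_calls: Mapping[str, Iterable[VariantRecord]],
              cfg: FilterConfig,
              allow_n_mismatch: bool = False) -> PanelOfNormals:
    """Assemble the panel of normals from the three provenance rules.

    ``tumor_calls`` must cover exactly ``cfg.n_all`` samples unless
    ``allow_n_mismatch`` is set (the all-tumors rule is meaningless
    otherwise).
    """
    tumor_calls = {s: list(v) for s, v in tumor_calls.items()}
    if not tumor_calls:
        raise ValueError("tumor_calls is empty")
    if len(tumor_calls) != cfg.n_all and not allow_n_mismatch:
        raise ValueError(
            f"cfg.n_all={cfg.n_all} but {len(tumor_calls)} tumor samples "
            f"provided (pass allow_n_mismatch=True to override)")

    germ_keys = _keys(healthy_germline)
    som_keys = _keys(healthy_somatic)
    if cfg.healthy_mode == "either":
        healthy_keys = germ_keys | som_keys
    elif cfg.healthy_mode == "somatic":
        healthy_keys = som_keys
    else:
        healthy_keys = germ_keys

    # per-key: in how many tumors called, and caller label per tumor
    called_in: dict[Key, int] = {}
    no_pass_in: dict[Key, int] = {}
    for sample, recs in tumor_calls.items():
        per_sample: dict[Key, str] = {}
        for r in recs:
            k = record_key(r)
            # a key PASS for any of its records in a sample counts as PASS
            prev = per_sample.get(k)
            per_sample[k] = PASS if PASS in (prev, r.caller_filter) else NO_PASS
        for k, label in per_sample.items():
            called_in[k] = called_in.get(k, 0) + 1
            if label == NO_PASS:
                no_pass_in[k] = no_pass_in.get(k, 0) + 1

    n_tumors = len(tumor_calls)
    prov: dict[Key, set[str]] = {}

    for k in germ_keys & som_keys:
        prov.setdefault(k, set()).add("set1")
    for k, n in called_in.items():
        if k not in healthy_keys:
            continue
        npass = no_pass_in.get(k, 0)
        if n == n_tumors and npass <= cfg.max_no_pass_set2:
            prov.setdefault(k, set()).add("set2")
        if n >= cfg.n_most and npass == 0:
            prov.setdefault(k, set()).add("set3")

    return PanelOfNormals({k: frozenset(v) for k, v in prov.items()})


@dataclass
class FilterResult:
    """Filtered per-tumor calls plus removal accounting."""

    kept: dict[str, list[VariantRecord]]
    removed: dict[str, dict[str, int]]  # sample -> reason -> count
    removal_reasons: dict[tuple[str, Key], str]

    def report(self) -> pd.DataFrame:
        rows = []
        for sample in sorted(self.removed):
            counts = self.removed[sample]
            rows.append({"sample": sample,
                         "kept": len(self.kept.get(sample, [])),
                         **{f"removed_{r}": counts.get(r, 0)
                            for r in REMOVAL_ORDER}})
        return pd.DataFrame(rows)


def filter_somatic(variants: Mapping[str, Iterable[VariantRecord]],
                   pon: PanelOfNormals,
                   healthy_calls: Iterable[VariantRecord] | set[Key],
                   known_sites: Mapping[str, Iterable[Key] | set[Key]] | None = None,
                   known_site_match: str = "allele") -> FilterResult:
    """Remove panel, healthy-tissue and known-site variants per tumor.

    Removal reasons are assigned by fixed precedence (panel, then healthy,
    then known sites) so per-reason counts are deterministic when rules
    overlap.  Known-site matching is by full allele key by default; the
    ``position`` mode matches on (chrom, pos) only.
    """
    if isinstance(healthy_calls, set):
        healthy_keys = healthy_calls
    else:
        healthy_keys = _keys(healthy_calls)
    known: set = set()
    for name, sites in (known_sites or {}).items():
        for k in sites:
            known.add(k if known_site_match == "allele" else (k[0], k[1]))

    kept: dict[str, list[VariantRecord]] = {}
    removed: dict[str, dict[str, int]] = {}
    reasons: dict[tuple[str, Key], str] = {}
    for sample in sorted(variants):
        kept[sample] = []
        removed[sample] = dict.fromkeys(REMOVAL_ORDER, 0)
        for r in variants[sample]:
            k = record_key(r)
            probe = k if known_site_match == "allele" else (k[0], k[1])
            if k in pon:
                reason = "pon"
            elif k in healthy_keys:
                reason = "healthy"
            elif probe in known:
                reason = "known_sites"
            else:
                kept[sample].append(r)
                continue
            removed[sample][reason] += 1
            reasons[(sample, k)] = reason
    return FilterResult(kept=kept, removed=removed, removal_reasons=reasons)
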