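"""Readers/writers for the standard formats the pipeline touches.

All stages exchange a normalized variant table (:class:`VariantRecord`
collections, or their :class:`pandas.DataFrame` form).  Position conventions:
VCF is 1-based, BED is 0-based half-open; every internal position is 1-based
and the conversions live in this module only.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "VariantRecord",
    "TargetSpace",
    "load_variants",
    "load_targets",
    "write_table",
    "read_table",
    "records_to_frame",
    "frame_to_records",
    "variant_key",
    "normalize_indel",
]

PASS = "PASS"
NO_PASS = "NO_PASS"

#: Column order of the exchanged TSV tables.
TABLE_COLUMNS = [
    "chrom", "pos", "ref", "alt", "sample", "depth", "alt_count", "vaf",
    "caller_filter", "gene", "consequence", "variant_class",
]


@dataclass(frozen=True)
class VariantRecord:
    """One called substitution or INDEL in one sample.

    ``vaf`` is ``alt_count / depth``; it is ``nan`` (flagged undefined) when
    ``depth == 0``.  ``caller_filter`` collapses the caller's FILTER column to
    ``PASS`` versus ``NO_PASS`` — anything other than the exact string
    ``PASS`` (including ``.``) is ``NO_PASS``.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    sample: str
    depth: int
    alt_count: int
    caller_filter: str = PASS
    gene: str = ""
    consequence: str = ""

    def __post_init__(self):
        if self.depth < 0 or self.alt_count < 0:
            raise ValueError(
                f"negative depth/alt_count at {self.chrom}:{self.pos}")
        if self.alt_count > self.depth:
            raise ValueError(
                f"alt_count {self.alt_count} > depth {self.depth} "
                f"at {self.chrom}:{self.pos}")
        if self.caller_filter not in (PASS, NO_PASS):
            raise ValueError(f"caller_filter must be PASS/NO_PASS, "
                             f"got {self.caller_filter!r}")

    @property
    def vaf(self) -> float:
        if self.depth == 0:
            return float("nan")
        return self.alt_count / self.depth

    @property
    def variant_class(self) -> str:
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "INDEL"

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Allele key (chrom, pos, ref, alt) used by every set operation."""
        return (self.chrom, self.pos, self.ref, self.alt)


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> tuple[str, int, str, str]:
    return (chrom, int(pos), ref, alt)


def normalize_indel(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-align and parsimony-trim an allele pair.

    Callers represent the same INDEL with different anchor bases; set
    comparisons across call files key on the normalized form.  SNVs pass
    through unchanged.
    """
    ref, alt = ref.upper(), alt.upper()
    # trim identical trailing bases
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim identical leading bases (keep one anchor)
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


class TargetSpace:
    """Captured target intervals plus the reference they index into.

    ``intervals`` are 0-based half-open, merged and sorted.  ``sequences``
    maps chromosome name to its full sequence string (upper case).
    """

    def __init__(self, intervals: Sequence[tuple[str, int, int]],
                 sequences: Mapping[str, str]):
        self.sequences = {c: str(s).upper() for c, s in sequences.items()}
        self.intervals = merge_intervals(intervals)
        for chrom, start, end in self.intervals:
            if chrom not in self.sequences:
                raise ValueError(f"chromosome {chrom!r} absent from reference")
            if end > len(self.sequences[chrom]):
                raise ValueError(
                    f"interval {chrom}:{start}-{end} beyond chromosome "
                    f"end ({len(self.sequences[chrom])})")
            if end <= start:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")

    def interval_sequence(self, chrom: str, start: int, end: int) -> str:
        return self.sequences[chrom][start:end]

    def iter_sequences(self) -> Iterator[tuple[str, int, int, str]]:
        """Yield (chrom, start, end, sequence) per merged interval."""
        for chrom, start, end in self.intervals:
            yield chrom, start, end, self.interval_sequence(chrom, start, end)

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position in the target space."""
        p0 = pos - 1
        return any(c == chrom and s <= p0 < e for c, s, e in self.intervals)

    def base_at(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        return self.sequences[chrom][pos - 1]

    @property
    def total_bases(self) -> int:
        return sum(e - s for _, s, e in self.intervals)


def merge_intervals(
        intervals: Iterable[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Sort and union possibly-overlapping half-open intervals."""
    out: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted((str(c), int(s), int(e)) for c, s, e in intervals):
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            prev = out[-1]
            out[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            out.append((chrom, start, end))
    return out


def _alt_depth_counts(variant, alt_index: int) -> tuple[int, int]:
    """Pull (depth, alt_count) for one ALT allele of a cyvcf2 record.

    Per-sample AD/DP are tried first, then the INFO column; absence is an
    error (a silent zero would corrupt every downstream VAF cutoff).
    """
    ad = variant.format("AD")
    if ad is not None and ad.size >= alt_index + 2:
        counts = np.asarray(ad).reshape(-1)
        alt_count = int(counts[alt_index + 1])
        dp = variant.format("DP")
        if dp is not None:
            depth = int(np.asarray(dp).reshape(-1)[0])
        else:  # fall back to summing AD over alleles
            depth = int(counts[counts >= 0].sum())
        return depth, alt_count
    info = dict(variant.INFO)
    if "DP" in info and "AD" in info:
        ad_info = info["AD"]
        if isinstance(ad_info, (tuple, list)):
            alt_count = int(ad_info[alt_index + 1])
        else:
            alt_count = int(ad_info)
        return int(info["DP"]), alt_count
    raise ValueError(
        f"no AD/DP depth fields at {variant.CHROM}:{variant.POS} "
        f"{variant.REF}>{variant.ALT}")


def load_variants(vcf_path: str | os.PathLike, sample: str) -> list[VariantRecord]:
    """Load one sample's calls from a VCF into :class:`VariantRecord`\\ s.

    Multi-allelic records are split into one record per ALT allele; FILTER
    ``PASS`` maps to ``PASS`` and any other value (or ``.``) to ``NO_PASS``.
    """
    records: list[VariantRecord] = []
    vcf = VCF(str(vcf_path))
    try:
        for v in vcf:
            # cyvcf2: FILTER is None for PASS and for '.', so check raw field
            raw_filter = str(v).split("\t")[6]
            caller_filter = PASS if raw_filter == "PASS" else NO_PASS
            for i, alt in enumerate(v.ALT):
                depth, alt_count = _alt_depth_counts(v, i)
                records.append(VariantRecord(
                    chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=alt,
                    sample=sample, depth=depth, alt_count=alt_count,
                    caller_filter=caller_filter))
    finally:
        vcf.close()
    seen = set()
    for r in records:
        k = r.key + (r.sample,)
        if k in seen:
            raise ValueError(f"duplicate variant {k} in {vcf_path}")
        seen.add(k)
    return records


def load_targets(bed_path: str | os.PathLike,
                 fasta_path: str | os.PathLike) -> TargetSpace:
    """Load capture intervals (BED 3+) over an (indexable) FASTA."""
    from pyfaidx import Fasta

    fasta = Fasta(str(fasta_path))
    sequences = {name: str(fasta[name][:]) for name in fasta.keys()}
    intervals = []
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                fields = line.split()
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if chrom not in sequences:
                raise ValueError(f"chromosome {chrom!r} in BED absent from FASTA")
            if end > len(sequences[chrom]):
                raise ValueError(
                    f"BED interval {chrom}:{start}-{end} beyond chromosome end")
            intervals.append((chrom, start, end))
    return TargetSpace(intervals, sequences)


def records_to_frame(records: Iterable[VariantRecord]) -> pd.DataFrame:
    """Normalized variant table: one row per record, fixed column order."""
    rows = []
    for r in records:
        d = asdict(r)
        d["vaf"] = r.vaf
        d["variant_class"] = r.variant_class
        rows.append(d)
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    if df.empty:
        df = pd.DataFrame(columns=TABLE_COLUMNS)
    return df.sort_values(["chrom", "pos", "sample", "ref", "alt"],
                          kind="mergesort").reset_index(drop=True)


def frame_to_records(df: pd.DataFrame) -> list[VariantRecord]:
    return [
        VariantRecord(
            chrom=str(row.chrom), pos=int(row.pos), ref=str(row.ref),
            alt=str(row.alt), sample=str(row.sample), depth=int(row.depth),
            alt_count=int(row.alt_count), caller_filter=str(row.caller_filter),
            gene="" if pd.isna(row.gene) else str(row.gene),
            consequence="" if pd.isna(row.consequence) else str(row.consequence),
        )
        for row in df.itertuples(index=False)
    ]


def write_table(records: pd.DataFrame | Iterable[VariantRecord],
                path: str | os.PathLike) -> None:
    """Write the variant table as TSV, rows sorted by (chrom, pos, sample)."""
    if not isinstance(records, pd.DataFrame):
        records = records_to_frame(records)
    else:
        if set(TABLE_COLUMNS) <= set(records.columns):
            records = records[TABLE_COLUMNS]
        records = records.sort_values(
            ["chrom", "pos", "sample", "ref", "alt"],
            kind="mergesort").reset_index(drop=True)
    records.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t",
                     dtype={"chrom": str, "sample": str, "ref": str, "alt": str},
                     keep_default_na=False, na_values=["nan"])
    for col in ("gene", "consequence"):
        if col in df.columns:
            df[col] = df[col].astype(str)
    return df
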