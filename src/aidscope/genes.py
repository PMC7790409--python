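"""Cancer gene-set annotation, consequence reduction, exclusivity analysis.

Filtered somatic variants are intersected with user-supplied cancer gene
sets (driver genes and lymphoma-associated genes), reduced to one
most-severe consequence per gene per tumor, organised into a
presence/absence gene x tumor matrix, and partitioned into genes mutated
exclusively in one genotype group versus shared.  The mutation spectrum of
exclusive-gene variants (C/G vs A/T, hotspot vs not) is tested against the
target-space base composition.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import TargetSpace, VariantRecord
from .spectrum import (HotspotIndex, TargetComposition,
                       classify_substitution, association_test)

__all__ = ["GeneSets", "GeneMatrix", "load_gene_sets", "annotate_cancer_genes",
           "exclusive_genes", "exclusive_spectrum", "DEFAULT_SEVERITY_ORDER"]

#: Consequence severity, least to most severe. The caller's annotations must
#: all appear here (or in a user-supplied override).
DEFAULT_SEVERITY_ORDER = [
    "synonymous_variant",
    "intron_variant",
    "non_coding_transcript_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "missense_variant",
    "inframe_insertion",
    "inframe_deletion",
    "splice_region_variant",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "stop_gained",
    "frameshift_variant",
]


def _normalize(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass(frozen=True)
class GeneSets:
    drivers: frozenset[str]
    lymphoma: frozenset[str]

    @property
    def union(self) -> frozenset[str]:
        return self.drivers | self.lymphoma


def _read_symbols(path: str | os.PathLike) -> frozenset[str]:
    symbols = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                symbols.add(_normalize(line))
    if not symbols:
        raise ValueError(f"gene-set file {path} contains no symbols")
    return frozenset(symbols)


def load_gene_sets(driver_path: str | os.PathLike,
                   lymphoma_path: str | os.PathLike) -> GeneSets:
    """Load one-symbol-per-line gene lists (comments allowed, case-folded)."""
    return GeneSets(drivers=_read_symbols(driver_path),
                    lymphoma=_read_symbols(lymphoma_path))


@dataclass
class GeneMatrix:
    """Presence/absence of cancer-gene variants per gene x tumor.

    ``presence.loc[g, s]`` is True when tumor ``s`` carries >= 1 retained
    variant in gene ``g``; ``consequence.loc[g, s]`` is that gene's most
    severe consequence in that tumor (empty where absent).
    """

    presence: pd.DataFrame
    consequence: pd.DataFrame
    per_tumor_counts: pd.DataFrame  # tumor x consequence variant counts

    @property
    def genes(self) -> list[str]:
        return list(self.presence.index)

    @property
    def samples(self) -> list[str]:
        return list(self.presence.columns)

    def restrict(self, samples: Sequence[str]) -> "GeneMatrix":
        return GeneMatrix(self.presence[list(samples)],
                          self.consequence[list(samples)],
                          self.per_tumor_counts.loc[
                              self.per_tumor_counts.index.isin(samples)])


def annotate_cancer_genes(
        variants: Mapping[str, Iterable[VariantRecord]],
        sets: GeneSets,
        severity_order: Sequence[str] | None = None) -> GeneMatrix:
    """Build the cancer-gene presence matrix with per-gene consequence
    reduction (maximum under the severity order)."""
    order = list(severity_order or DEFAULT_SEVERITY_ORDER)
    rank = {c: i for i, c in enumerate(order)}

    rows = []
    for sample, recs in variants.items():
        for r in recs:
            gene = _normalize(r.gene)
            if not gene or gene not in sets.union:
                continue
            if r.consequence not in rank:
                raise ValueError(
                    f"consequence {r.consequence!r} absent from severity "
                    f"order (extend severity_order)")
            rows.append({"sample": sample, "gene": gene,
                         "consequence": r.consequence,
                         "rank": rank[r.consequence]})
    samples = sorted(variants)
    if not rows:
        empty = pd.DataFrame(index=pd.Index([], name="gene"), columns=samples)
        return GeneMatrix(empty.astype(bool), empty.astype(str),
                          pd.DataFrame(index=samples))
    df = pd.DataFrame(rows)
    genes = sorted(df["gene"].unique())

    presence = pd.DataFrame(False, index=genes, columns=samples)
    consequence = pd.DataFrame("", index=genes, columns=samples)
    worst = df.loc[df.groupby(["sample", "gene"])["rank"].idxmax()]
    for row in worst.itertuples(index=False):
        presence.loc[row.gene, row.sample] = True
        consequence.loc[row.gene, row.sample] = row.consequence
    counts = (df.groupby(["sample", "consequence"]).size()
              .unstack(fill_value=0).reindex(samples, fill_value=0))
    presence.index.name = consequence.index.name = "gene"
    return GeneMatrix(presence=presence, consequence=consequence,
                      per_tumor_counts=counts)


def exclusive_genes(matrix_a: GeneMatrix, matrix_b: GeneMatrix,
                    min_recurrence: int = 1
                    ) -> tuple[set[str], set[str], set[str]]:
    """Partition mutated genes into exclusive-to-A, exclusive-to-B, shared.

    A gene counts as mutated in a group when present in at least
    ``min_recurrence`` of that group's tumors (the per-group recurrence
    screen applied before exclusivity is assessed).
    """
    def mutated(matrix: GeneMatrix) -> set[str]:
        hits = matrix.presence.sum(axis=1)
        return set(hits.index[hits >= min_recurrence])

    a, b = mutated(matrix_a), mutated(matrix_b)
    return a - b, b - a, a & b


def exclusive_spectrum(variants: Iterable[VariantRecord],
                       genes: set[str],
                       targets: TargetSpace,
                       composition: TargetComposition,
                       motif: str = "wrc") -> dict:
    """Spectrum of SNVs in a set of (exclusively mutated) genes.

    Reports the C/G vs A/T and hotspot vs non-hotspot proportions of the
    mutations, each with a Fisher two-tailed test against the target-space
    base composition (are C/G — or hotspot — bases mutated more often than
    their share of eligible bases predicts?).
    """
    index = HotspotIndex(targets, motif)
    n_cg = n_at = n_hot = 0
    for r in variants:
        if r.variant_class != "SNV" or _normalize(r.gene) not in genes:
            continue
        _, base_class = classify_substitution(r.ref, r.alt)
        if base_class == "CG":
            n_cg += 1
            if index.query(r.chrom, r.pos):
                n_hot += 1
        else:
            n_at += 1
    total = n_cg + n_at
    out = {
        "n_snv": total, "n_cg": n_cg, "n_at": n_at, "n_cg_hotspot": n_hot,
        "cg_proportion": n_cg / total if total else np.nan,
        "hotspot_proportion": n_hot / n_cg if n_cg else np.nan,
        "cg_vs_at_p": np.nan, "hotspot_p": np.nan,
    }
    if total == 0:
        return out
    comp = composition
    # observed C/G vs A/T split against the eligible-base split
    table = np.array([[n_cg, n_at],
                      [comp.n_cg, comp.n_at]])
    _, out["cg_vs_at_p"] = association_test(table, mode="fisher")
    if n_cg:
        table = np.array([[n_hot, n_cg - n_hot],
                          [comp.n_cg_hotspot, comp.n_cg_nonhotspot]])
        _, out["hotspot_p"] = association_test(table, mode="fisher")
    return out
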