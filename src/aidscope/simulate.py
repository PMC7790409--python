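"""Synthetic tumor-exome cohort generator with full ground truth.

Emulates the study design the downstream analysis assumes: a cohort of
tumors of two genotype groups plus one healthy-tissue control, sequenced by
exome capture.  Each tumor carries clonal and subclonal somatic mutations
drawn from an AID-like mutational process (C:G transitions concentrated in
WRC/GYW hotspot context), shared germline variants, recurrent artifact
loci to exercise panel-of-normals construction, and binomial read-support
sampling at Poisson depth.  Every emitted variant is recorded in a truth
table so downstream stages can be scored exactly.

The default configuration is the study condition itself: 7 "WT-like" plus
8 "KI-like" tumors (the KI-like group has more mutations, stronger hotspot
focusing and a heavier subclonal compartment), one healthy control, 50
shared germline variants, tumor purity 0.8 and mean depth 150.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (NO_PASS, PASS, TargetSpace, VariantRecord,
                      records_to_frame)
from .spectrum import WRC, HotspotMotif, get_motif, hotspot_mask

__all__ = [
    "GroupParams", "SimulationConfig", "SimulatedCohort",
    "simulate_reference", "simulate_cohort", "emit_gene_annotations",
    "write_cohort", "default_config",
]

BASES = np.array(["A", "C", "G", "T"])

#: Consequence vocabulary (VEP-like) with draw probabilities for SNVs.
SNV_CONSEQUENCES = [
    ("missense_variant", 0.40), ("synonymous_variant", 0.25),
    ("intron_variant", 0.12), ("5_prime_UTR_variant", 0.05),
    ("3_prime_UTR_variant", 0.05), ("splice_region_variant", 0.04),
    ("stop_gained", 0.09),
]
INDEL_CONSEQUENCES = [
    ("frameshift_variant", 0.60), ("inframe_deletion", 0.12),
    ("inframe_insertion", 0.08), ("intron_variant", 0.15),
    ("splice_region_variant", 0.05),
]


@dataclass(frozen=True)
class GroupParams:
    """Mutational-process parameters of one genotype group.

    ``hotspot_enrichment`` (w >= 1) multiplies the sampling weight of
    hotspot C/G sites relative to non-hotspot C/G sites.
    ``subclonal_fraction`` of somatic mutations is split evenly across the
    subclones; the rest are clonal at ``clonal_ccf``.
    """

    n_tumors: int
    mutations_per_tumor: int
    p_cg_transition: float
    hotspot_enrichment: float
    clonal_ccf: float = 0.95
    subclone_ccf: tuple[float, ...] = ()
    subclonal_fraction: float = 0.0

    def __post_init__(self):
        if self.hotspot_enrichment < 1:
            raise ValueError("hotspot_enrichment must be >= 1")
        if not 0 <= self.p_cg_transition <= 1:
            raise ValueError("p_cg_transition must be in [0,1]")
        if not 0 < self.clonal_ccf <= 1:
            raise ValueError("clonal_ccf must be in (0,1]")
        if any(c >= self.clonal_ccf or c <= 0 for c in self.subclone_ccf):
            raise ValueError("subclone CCFs must lie strictly below clonal_ccf")
        if self.subclone_ccf and not 0 < self.subclonal_fraction < 1:
            raise ValueError("subclonal_fraction must be in (0,1) with subclones")

    @property
    def n_subclones(self) -> int:
        return len(self.subclone_ccf)


@dataclass(frozen=True)
class SimulationConfig:
    genome_length: int = 2_000_000
    gc_content: float = 0.42
    groups: Mapping[str, GroupParams] = field(default_factory=dict)
    n_germline: int = 50
    germline_hom_fraction: float = 0.2
    germline_known_fraction: float = 0.7
    n_shared_artifacts: int = 30
    healthy_somatic_overlap: float = 0.9
    mean_depth: float = 150.0
    purity: float = 0.8
    indel_fraction: float = 0.24
    artifact_nopass_fraction: float = 0.05
    n_genes: int = 2000
    n_driver_genes: int = 120
    n_lymphoma_genes: int = 60
    n_cnv_per_tumor: int = 2
    cnv_length: int = 30_000
    motif: str = "wrc"
    seed: int = 0

    def __post_init__(self):
        for name, frac in [("gc_content", self.gc_content),
                           ("purity", self.purity),
                           ("indel_fraction", self.indel_fraction),
                           ("germline_known_fraction", self.germline_known_fraction),
                           ("artifact_nopass_fraction", self.artifact_nopass_fraction)]:
            if not 0 <= frac <= 1:
                raise ValueError(f"{name} must be in [0,1]")
        if self.genome_length < 1000:
            raise ValueError("genome_length must be >= 1000")

    @property
    def n_tumors(self) -> int:
        return sum(g.n_tumors for g in self.groups.values())


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The built-in two-genotype cohort presets (7 WT-like + 8 KI-like)."""
    groups = {
        "WT-like": GroupParams(
            n_tumors=7, mutations_per_tumor=600, p_cg_transition=0.70,
            hotspot_enrichment=2.0, clonal_ccf=0.95,
            subclone_ccf=(0.30,), subclonal_fraction=0.25),
        "KI-like": GroupParams(
            n_tumors=8, mutations_per_tumor=800, p_cg_transition=0.80,
            hotspot_enrichment=5.0, clonal_ccf=0.95,
            subclone_ccf=(0.45, 0.28, 0.15), subclonal_fraction=0.50),
    }
    return SimulationConfig(groups=groups, seed=seed, **overrides)


def simulate_reference(config: SimulationConfig,
                       rng: np.random.Generator | None = None) -> TargetSpace:
    """Random single-chromosome genome at the requested GC content.

    The capture space defaults to the whole genome as one interval.
    """
    rng = rng or np.random.default_rng(config.seed)
    p = np.array([(1 - config.gc_content) / 2, config.gc_content / 2,
                  config.gc_content / 2, (1 - config.gc_content) / 2])
    seq = "".join(BASES[rng.choice(4, size=config.genome_length, p=p)])
    return TargetSpace([("chr1", 0, config.genome_length)], {"chr1": seq})


@dataclass
class SimulatedCohort:
    """In-memory cohort: call sets, ground truth and provenance."""

    config: SimulationConfig
    targets: TargetSpace
    tumor_records: dict[str, list[VariantRecord]]
    healthy_germline: list[VariantRecord]
    healthy_somatic: list[VariantRecord]
    known_sites: set[tuple[str, int, str, str]]
    cnv_regions: dict[str, list[tuple[str, int, int]]]
    truth: pd.DataFrame
    group_of: dict[str, str]
    gene_spans: list[tuple[str, str, int, int]]  # (gene, chrom, start0, end0)
    gene_sets: dict[str, set[str]]

    @property
    def samples(self) -> list[str]:
        return sorted(self.tumor_records)


def _weighted_distinct(rng: np.random.Generator, pool: np.ndarray,
                       weights: np.ndarray, n: int) -> np.ndarray:
    """Draw n distinct entries from pool with probability ∝ weights.

    Gumbel top-k: deterministic given the generator state and order-stable
    because the pool is position-sorted.
    """
    if n > pool.size:
        raise ValueError(f"requested {n} sites from a pool of {pool.size}")
    if n == 0:
        return pool[:0]
    keys = np.log(weights) + rng.gumbel(size=pool.size)
    return pool[np.argpartition(-keys, n - 1)[:n]]


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _draw_reads(rng: np.random.Generator, n: int, mean_depth: float,
                evaf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Poisson depth and zero-truncated binomial alt support.

    A caller only reports variants with at least one supporting read, so
    zero draws are redrawn (depth floored at 1 for the same reason).
    """
    depth = rng.poisson(mean_depth, size=n)
    depth = np.maximum(depth, 1)
    alt = rng.binomial(depth, evaf)
    for _ in range(200):
        zero = alt == 0
        if not zero.any():
            break
        alt[zero] = rng.binomial(depth[zero], evaf[zero])
    alt = np.maximum(alt, 1)  # degenerate evaf≈0 guard
    return depth, alt


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate the full cohort with ground truth.

    Site draws are without replacement within each sample; germline and
    artifact loci are reserved first so somatic draws never collide with
    them (the healthy-tissue filter must remove only true germline).
    """
    if not config.groups:
        raise ValueError("config.groups is empty")
    rng = np.random.default_rng(config.seed)
    targets = simulate_reference(config, rng)
    seq = targets.sequences["chr1"]
    motif = get_motif(config.motif)
    hot = hotspot_mask(seq, motif)
    arr = np.frombuffer(seq.encode(), dtype="S1")

    positions = {b: np.flatnonzero(arr == b.encode()) + 1 for b in "ACGT"}  # 1-based
    L = config.genome_length

    truth_rows: list[dict] = []
    known_sites: set[tuple[str, int, str, str]] = set()

    # ---- germline variants (shared by every sample incl. healthy) ----
    n_germ = config.n_germline
    germ_pos = np.sort(rng.choice(L, size=n_germ + config.n_shared_artifacts,
                                  replace=False) + 1)
    rng.shuffle(germ_pos)
    art_pos = germ_pos[n_germ:]
    germ_pos = np.sort(germ_pos[:n_germ])
    art_pos = np.sort(art_pos)
    reserved = set(germ_pos) | set(art_pos)

    germline = []
    for pos in germ_pos:
        ref = seq[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        hom = rng.random() < config.germline_hom_fraction
        known = rng.random() < config.germline_known_fraction
        germline.append((int(pos), ref, alt, 1.0 if hom else 0.5, known))
        if known:
            known_sites.add(("chr1", int(pos), ref, alt))

    artifacts = []
    for pos in art_pos:
        ref = seq[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        artifacts.append((int(pos), ref, alt))

    # sample naming: WT-like -> WT01.., KI-like -> KI01..
    group_of: dict[str, str] = {}
    for gname, params in config.groups.items():
        prefix = "".join(ch for ch in gname if ch.isalnum())[:2].upper() or "T"
        for i in range(params.n_tumors):
            group_of[f"{prefix}{i + 1:02d}"] = gname
    samples = sorted(group_of)

    # which tumors carry each artifact NO_PASS (exercises PON sets 2/3)
    n_t = len(samples)
    art_nopass: list[set[str]] = []
    for _ in artifacts:
        k = int(rng.choice([0, 1, 2, 3, 4], p=[0.4, 0.2, 0.2, 0.1, 0.1]))
        chosen = rng.choice(n_t, size=min(k, n_t), replace=False)
        art_nopass.append({samples[j] for j in chosen})

    tumor_records: dict[str, list[VariantRecord]] = {}
    cnv_regions: dict[str, list[tuple[str, int, int]]] = {}

    other_classes = [(r, a) for r in "ACGT" for a in "ACGT"
                     if r != a and not (r in "CG" and a == _TRANSITION[r])]

    for sample in samples:
        params = config.groups[group_of[sample]]
        recs: list[VariantRecord] = []
        used = set(reserved)

        # germline + artifact calls in this tumor
        for pos, ref, alt, evaf, known in germline:
            depth, ac = _draw_reads(rng, 1, config.mean_depth, np.array([evaf]))
            flt = NO_PASS if rng.random() < config.artifact_nopass_fraction else PASS
            recs.append(VariantRecord("chr1", pos, ref, alt, sample,
                                      int(depth[0]), int(ac[0]), flt))
            truth_rows.append(dict(chrom="chr1", pos=pos, ref=ref, alt=alt,
                                   sample=sample, origin="germline",
                                   true_ccf=np.nan, true_vaf=evaf,
                                   hotspot=False, in_known_sites=known))
        for (pos, ref, alt), nopass_in in zip(artifacts, art_nopass):
            depth, ac = _draw_reads(rng, 1, config.mean_depth, np.array([0.35]))
            flt = NO_PASS if sample in nopass_in else PASS
            recs.append(VariantRecord("chr1", pos, ref, alt, sample,
                                      int(depth[0]), int(ac[0]), flt))
            truth_rows.append(dict(chrom="chr1", pos=pos, ref=ref, alt=alt,
                                   sample=sample, origin="artifact",
                                   true_ccf=np.nan, true_vaf=0.35,
                                   hotspot=False, in_known_sites=False))

        # ---- somatic mutations ----
        n_mut = params.mutations_per_tumor
        n_indel = int(round(config.indel_fraction * n_mut))
        n_snv = n_mut - n_indel

        n_cg_ts = int(rng.binomial(n_snv, params.p_cg_transition))
        n_other = n_snv - n_cg_ts
        other_counts = rng.multinomial(n_other,
                                       np.full(len(other_classes),
                                               1 / len(other_classes)))

        somatic: list[tuple[int, str, str, bool, str]] = []  # pos,ref,alt,hot,cls

        # C:G transitions over the weighted C+G pool
        cg_pool = np.concatenate([positions["C"], positions["G"]])
        keep = ~np.isin(cg_pool, list(reserved))
        cg_pool = cg_pool[keep]
        w = np.where(hot[cg_pool - 1], params.hotspot_enrichment, 1.0)
        sites = _weighted_distinct(rng, cg_pool, w, n_cg_ts)
        for pos in sites:
            ref = seq[pos - 1]
            somatic.append((int(pos), ref, _TRANSITION[ref],
                            bool(hot[pos - 1]), "SNV"))
            used.add(int(pos))

        # remaining substitution classes, uniform over classes
        per_base_needed: dict[str, list[str]] = {b: [] for b in "ACGT"}
        for (ref, alt), cnt in zip(other_classes, other_counts):
            per_base_needed[ref].extend([alt] * int(cnt))
        for base, alts in per_base_needed.items():
            if not alts:
                continue
            pool = positions[base]
            pool = pool[~np.isin(pool, list(used))]
            wts = (np.where(hot[pool - 1], params.hotspot_enrichment, 1.0)
                   if base in "CG" else np.ones(pool.size))
            sites = _weighted_distinct(rng, pool, wts, len(alts))
            rng.shuffle(sites)
            for pos, alt in zip(sites, alts):
                somatic.append((int(pos), base, alt, bool(hot[pos - 1]), "SNV"))
                used.add(int(pos))

        # short INDELs (1-5 bp), positions uniform
        all_pos = np.arange(1, L + 1)
        avail = all_pos[~np.isin(all_pos, list(used))]
        indel_sites = rng.choice(avail, size=n_indel, replace=False)
        for pos in indel_sites:
            pos = int(pos)
            length = int(rng.integers(1, 6))
            if rng.random() < 0.5 and pos + length <= L:  # deletion
                ref = seq[pos - 1:pos - 1 + length + 1]
                alt = ref[0]
            else:  # insertion
                ref = seq[pos - 1]
                alt = ref + "".join(rng.choice(list("ACGT"), size=length))
            somatic.append((pos, ref, alt, False, "INDEL"))
            used.add(pos)

        # clone assignment and read support
        ccfs = [params.clonal_ccf, *params.subclone_ccf]
        labels = ["clonal"] + [f"subclonal:{k + 1}"
                               for k in range(params.n_subclones)]
        if params.n_subclones:
            probs = [1 - params.subclonal_fraction] + \
                [params.subclonal_fraction / params.n_subclones] * params.n_subclones
        else:
            probs = [1.0]
        clone_idx = rng.choice(len(ccfs), size=len(somatic), p=probs)
        evaf = np.array([config.purity * ccfs[c] / 2 for c in clone_idx])
        depth, alt_count = _draw_reads(rng, len(somatic), config.mean_depth, evaf)

        for (pos, ref, alt, is_hot, cls), c, d, a in zip(
                somatic, clone_idx, depth, alt_count):
            flt = NO_PASS if rng.random() < config.artifact_nopass_fraction else PASS
            recs.append(VariantRecord("chr1", pos, ref, alt, sample,
                                      int(d), int(a), flt))
            truth_rows.append(dict(chrom="chr1", pos=pos, ref=ref, alt=alt,
                                   sample=sample, origin=labels[c],
                                   true_ccf=ccfs[c],
                                   true_vaf=config.purity * ccfs[c] / 2,
                                   hotspot=is_hot, in_known_sites=False))

        recs.sort(key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
        tumor_records[sample] = recs

        # CNV regions (copy-neutral VAFs; emitted only to exercise exclusion)
        cnvs = []
        for _ in range(config.n_cnv_per_tumor):
            start = int(rng.integers(0, max(1, L - config.cnv_length)))
            cnvs.append(("chr1", start, start + config.cnv_length))
        cnv_regions[sample] = sorted(cnvs)

    # ---- healthy control call sets ----
    healthy_germline = []
    for pos, ref, alt, evaf, _ in sorted(germline):
        depth, ac = _draw_reads(rng, 1, config.mean_depth, np.array([evaf]))
        healthy_germline.append(VariantRecord(
            "chr1", pos, ref, alt, "healthy", int(depth[0]), int(ac[0]), PASS))
        truth_rows.append(dict(chrom="chr1", pos=pos, ref=ref, alt=alt,
                               sample="healthy", origin="germline",
                               true_ccf=np.nan, true_vaf=evaf,
                               hotspot=False, in_known_sites=False))
    healthy_somatic = []
    in_overlap = rng.random(len(germline)) < config.healthy_somatic_overlap
    for (pos, ref, alt, evaf, _), keep in zip(sorted(germline), in_overlap):
        if not keep:
            continue
        depth, ac = _draw_reads(rng, 1, config.mean_depth, np.array([evaf]))
        healthy_somatic.append(VariantRecord(
            "chr1", pos, ref, alt, "healthy", int(depth[0]), int(ac[0]), PASS))
    for pos, ref, alt in sorted(artifacts):
        depth, ac = _draw_reads(rng, 1, config.mean_depth, np.array([0.35]))
        healthy_somatic.append(VariantRecord(
            "chr1", pos, ref, alt, "healthy", int(depth[0]), int(ac[0]), PASS))
    healthy_somatic.sort(key=lambda r: (r.pos, r.ref, r.alt))

    truth = pd.DataFrame(truth_rows).sort_values(
        ["sample", "chrom", "pos", "ref", "alt"],
        kind="mergesort").reset_index(drop=True)

    cohort = SimulatedCohort(
        config=config, targets=targets, tumor_records=tumor_records,
        healthy_germline=healthy_germline, healthy_somatic=healthy_somatic,
        known_sites=known_sites, cnv_regions=cnv_regions, truth=truth,
        group_of=group_of, gene_spans=[], gene_sets={})
    emit_gene_annotations(cohort, rng)
    return cohort


def emit_gene_annotations(cohort: SimulatedCohort,
                          rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Partition the genome into synthetic genes and annotate every variant.

    Each variant gets the gene whose span contains it and a consequence
    drawn from a fixed VEP-like vocabulary; random subsets of genes become
    the synthetic "driver" and "lymphoma" gene sets.  Records are annotated
    in place (replaced with annotated copies); returns the annotation table.
    """
    config = cohort.config
    rng = rng or np.random.default_rng(config.seed + 1)
    L = config.genome_length
    bounds = np.linspace(0, L, config.n_genes + 1).astype(int)
    genes = [f"Gene{i + 1:03d}" for i in range(config.n_genes)]
    cohort.gene_spans = [("chr1", genes[i], int(bounds[i]), int(bounds[i + 1]))
                         for i in range(config.n_genes)]

    n_driver = min(config.n_driver_genes, config.n_genes)
    n_lymph = min(config.n_lymphoma_genes, config.n_genes)
    shuffled = list(genes)
    rng.shuffle(shuffled)
    drivers = set(shuffled[:n_driver])
    # lymphoma set overlaps drivers partially
    lymph = set(shuffled[n_driver - n_lymph // 3:
                         n_driver - n_lymph // 3 + n_lymph])
    cohort.gene_sets = {"drivers": drivers, "lymphoma": lymph}

    def gene_at(pos: int) -> str:
        i = min(np.searchsorted(bounds, pos - 1, side="right") - 1,
                config.n_genes - 1)
        return genes[i]

    snv_names, snv_p = zip(*SNV_CONSEQUENCES)
    ind_names, ind_p = zip(*INDEL_CONSEQUENCES)

    ann: dict[tuple, tuple[str, str]] = {}

    def annotate(rec: VariantRecord) -> VariantRecord:
        key = rec.key
        if key not in ann:
            gene = gene_at(rec.pos)
            if rec.variant_class == "SNV":
                csq = str(rng.choice(snv_names, p=snv_p))
            else:
                csq = str(rng.choice(ind_names, p=ind_p))
            ann[key] = (gene, csq)
        gene, csq = ann[key]
        return replace(rec, gene=gene, consequence=csq)

    for sample in cohort.samples:
        cohort.tumor_records[sample] = [annotate(r)
                                        for r in cohort.tumor_records[sample]]
    cohort.healthy_germline = [annotate(r) for r in cohort.healthy_germline]
    cohort.healthy_somatic = [annotate(r) for r in cohort.healthy_somatic]

    table = pd.DataFrame(
        [{"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3],
          "gene": g, "consequence": c} for k, (g, c) in sorted(ann.items())])
    return table


# ---------------------------------------------------------------------------
# on-disk emission

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=aidscope-simulator
##contig=<ID={chrom},length={length}>
##FILTER=<ID=artifact,Description="Flagged by the simulated caller">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_vcf(records: Sequence[VariantRecord], path: str | os.PathLike,
              sample: str, contig_lengths: Mapping[str, int]) -> None:
    """Emit calls as a minimal single-sample VCF 4.2 (plain text)."""
    chroms = sorted(contig_lengths)
    lines = []
    for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)):
        flt = "PASS" if r.caller_filter == PASS else "artifact"
        gt = "1/1" if r.depth and r.alt_count / r.depth > 0.9 else "0/1"
        lines.append(
            f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t{flt}\tDP={r.depth}"
            f"\tGT:AD:DP\t{gt}:{r.depth - r.alt_count},{r.alt_count}:{r.depth}")
    header = _VCF_HEADER.format(chrom=chroms[0],
                                length=contig_lengths[chroms[0]],
                                sample=sample)
    if len(chroms) > 1:
        extra = "".join(f"##contig=<ID={c},length={contig_lengths[c]}>\n"
                        for c in chroms[1:])
        header = header.replace("##FILTER", extra + "##FILTER", 1)
    Path(path).write_text(header + "\n".join(lines) + ("\n" if lines else ""))


def write_cohort(cohort: SimulatedCohort, out_dir: str | os.PathLike) -> dict:
    """Write the full cohort to disk (FASTA, BEDs, VCFs, truth, gene files).

    Returns a manifest of emitted paths.  Output is byte-deterministic for a
    fixed config and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    targets = cohort.targets
    contig_lengths = {c: len(s) for c, s in targets.sequences.items()}

    fasta = out / "reference.fa"
    with open(fasta, "w") as fh:
        for chrom in sorted(targets.sequences):
            fh.write(f">{chrom}\n")
            s = targets.sequences[chrom]
            for i in range(0, len(s), 70):
                fh.write(s[i:i + 70] + "\n")
    bed = out / "targets.bed"
    with open(bed, "w") as fh:
        for chrom, start, end in targets.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")

    manifest = {"reference": str(fasta), "targets": str(bed),
                "tumors": {}, "cnv": {}}
    vcf_dir = out / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    for sample in cohort.samples:
        p = vcf_dir / f"{sample}.vcf"
        write_vcf(cohort.tumor_records[sample], p, sample, contig_lengths)
        manifest["tumors"][sample] = str(p)
    for name, recs in [("healthy_germline", cohort.healthy_germline),
                       ("healthy_somatic", cohort.healthy_somatic)]:
        p = vcf_dir / f"{name}.vcf"
        write_vcf(recs, p, "healthy", contig_lengths)
        manifest[name] = str(p)

    known = [VariantRecord(c, p_, r_, a_, "known", 0, 0, PASS)
             for c, p_, r_, a_ in sorted(cohort.known_sites)]
    p = out / "known_sites.vcf"
    write_vcf(known, p, "known", contig_lengths)
    manifest["known_sites"] = str(p)

    cnv_dir = out / "cnv"
    cnv_dir.mkdir(exist_ok=True)
    for sample, regions in cohort.cnv_regions.items():
        p = cnv_dir / f"{sample}.cnv.bed"
        with open(p, "w") as fh:
            for chrom, start, end in regions:
                fh.write(f"{chrom}\t{start}\t{end}\n")
        manifest["cnv"][sample] = str(p)

    ann_rows = {}
    for recs in [*cohort.tumor_records.values(), cohort.healthy_germline,
                 cohort.healthy_somatic]:
        for r in recs:
            ann_rows[r.key] = {"chrom": r.chrom, "pos": r.pos, "ref": r.ref,
                               "alt": r.alt, "gene": r.gene,
                               "consequence": r.consequence}
    ann = pd.DataFrame([ann_rows[k] for k in sorted(ann_rows)])
    p = out / "annotations.tsv"
    ann.to_csv(p, sep="\t", index=False)
    manifest["annotations"] = str(p)

    for set_name, members in cohort.gene_sets.items():
        p = out / f"geneset_{set_name}.txt"
        p.write_text("".join(f"{g}\n" for g in sorted(members)))
        manifest[f"geneset_{set_name}"] = str(p)

    p = out / "truth.tsv"
    cohort.truth.to_csv(p, sep="\t", index=False, float_format="%.10g")
    manifest["truth"] = str(p)

    groups = pd.DataFrame(sorted(cohort.group_of.items()),
                          columns=["sample", "group"])
    p = out / "sample_groups.tsv"
    groups.to_csv(p, sep="\t", index=False)
    manifest["sample_groups"] = str(p)
    return manifest
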