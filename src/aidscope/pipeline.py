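"""End-to-end orchestration: simulate -> PON -> filter -> spectrum ->
clonality -> cancer genes.

Every stage is importable on its own; this module wires them together over
a :class:`~aidscope.simulate.SimulatedCohort` (in memory) or an output
directory tree (the CLI path).  All randomness flows from the simulation
config seed, so a fixed config yields a byte-identical output tree.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import clonality as clonality_mod
from . import genes as genes_mod
from .core_io import records_to_frame, write_table
from .pon import FilterConfig, build_pon, filter_somatic
from .simulate import SimulatedCohort, SimulationConfig, default_config, \
    simulate_cohort, write_cohort
from .spectrum import compare_spectra, spectrum_summary, target_composition

__all__ = ["analyze_cohort", "run_all"]


def _clonality_seed(base_seed: int, index: int) -> int:
    return (base_seed + 1_000_003 * (index + 1)) % (2 ** 31)


def analyze_cohort(cohort: SimulatedCohort, out_dir: str | Path | None = None,
                   filter_cfg: FilterConfig | None = None,
                   min_depth: int = 100, max_vaf: float = 0.8,
                   k_max: int = 6, min_recurrence: int = 2) -> dict:
    """Run the full downstream analysis on a simulated cohort.

    Returns a results dict with the per-stage tables and headline numbers;
    when ``out_dir`` is given, also writes the deterministic TSV tree.
    """
    config = cohort.config
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # ---- panel of normals + false-positive filtering ----
    cfg = filter_cfg or FilterConfig(n_all=config.n_tumors,
                                     n_most=max(1, config.n_tumors - 2),
                                     max_no_pass_set2=2)
    pon = build_pon(cohort.healthy_germline, cohort.healthy_somatic,
                    cohort.tumor_records, cfg)
    known = {"known_sites": cohort.known_sites}
    filt = filter_somatic(cohort.tumor_records, pon,
                          list(cohort.healthy_germline) + list(cohort.healthy_somatic),
                          known, known_site_match=cfg.known_site_match)

    if out is not None:
        pon.to_frame().to_csv(out / "pon.tsv", sep="\t", index=False)
        filt.report().to_csv(out / "filter_report.tsv", sep="\t", index=False)
        fdir = out / "filtered"
        fdir.mkdir(exist_ok=True)
        for sample in sorted(filt.kept):
            write_table(filt.kept[sample], fdir / f"{sample}.tsv")

    # ---- hotspot mutation spectrum ----
    comp = target_composition(cohort.targets, config.motif)
    all_kept = [r for s in sorted(filt.kept) for r in filt.kept[s]]
    summary = spectrum_summary(records_to_frame(all_kept), cohort.targets,
                               cohort.group_of, composition=comp,
                               motif=config.motif)
    groups = sorted(set(cohort.group_of.values()))
    tests = None
    if len(groups) == 2:
        tests = compare_spectra(summary, groups[0], groups[1], mode="chi2")
    if out is not None:
        summary.per_sample.to_csv(out / "spectrum_per_sample.tsv", sep="\t",
                                  index=False, float_format="%.10g")
        summary.per_group.to_csv(out / "spectrum_group.tsv", sep="\t",
                                 index=False, float_format="%.10g")
        if tests is not None:
            tests.to_csv(out / "spectrum_tests.tsv", sep="\t", index=False,
                         float_format="%.10g")

    # ---- clonal architecture / ITH ----
    archs: dict[str, clonality_mod.ClonalArchitecture] = {}
    unclustered: list[str] = []
    for i, sample in enumerate(sorted(filt.kept)):
        try:
            archs[sample] = clonality_mod.cluster_tumor(
                filt.kept[sample], cohort.cnv_regions.get(sample, ()),
                min_depth=min_depth, max_vaf=max_vaf, k_max=k_max,
                seed=_clonality_seed(config.seed, i), sample=sample)
        except ValueError:
            unclustered.append(sample)
    ith = None
    if len(groups) == 2:
        by_group = {g: [a for s, a in sorted(archs.items())
                        if cohort.group_of[s] == g] for g in groups}
        if all(by_group.values()):
            ith = clonality_mod.compare_ith(by_group[groups[0]],
                                            by_group[groups[1]],
                                            names=(groups[0], groups[1]))
    if out is not None:
        cdir = out / "clusters"
        cdir.mkdir(exist_ok=True)
        rows = []
        for sample in sorted(archs):
            a = archs[sample]
            a.to_frame().to_csv(cdir / f"clusters_{sample}.tsv", sep="\t",
                                index=False, float_format="%.10g")
            rows.append({"sample": sample, "group": cohort.group_of[sample],
                         "k": a.k, "n_clustered": a.n_variants,
                         "subclonal_proportion": a.subclonal_proportion,
                         **{f"excluded_{k}": v for k, v in a.n_excluded.items()}})
        pd.DataFrame(rows).to_csv(out / "clonality_summary.tsv", sep="\t",
                                  index=False, float_format="%.10g")
        if ith is not None:
            t = ith["table"]
            pd.DataFrame([{
                "group_a": groups[0], "group_b": groups[1],
                "clonal_a": int(t[0, 0]), "subclonal_a": int(t[0, 1]),
                "clonal_b": int(t[1, 0]), "subclonal_b": int(t[1, 1]),
                "odds_ratio": ith["odds_ratio"], "p_value": ith["p_value"],
            }]).to_csv(out / "ith_test.tsv", sep="\t", index=False,
                       float_format="%.10g")

    # ---- cancer gene sets ----
    sets = genes_mod.GeneSets(
        drivers=frozenset(g.upper() for g in cohort.gene_sets.get("drivers", ())),
        lymphoma=frozenset(g.upper() for g in cohort.gene_sets.get("lymphoma", ())))
    matrix = genes_mod.annotate_cancer_genes(filt.kept, sets)
    gene_results: dict = {"matrix": matrix}
    if len(groups) == 2:
        samples_by_group = {g: sorted(s for s, gg in cohort.group_of.items()
                                      if gg == g) for g in groups}
        ma = matrix.restrict(samples_by_group[groups[0]])
        mb = matrix.restrict(samples_by_group[groups[1]])
        ex_a, ex_b, shared = genes_mod.exclusive_genes(ma, mb, min_recurrence)
        gene_results.update(exclusive_a=ex_a, exclusive_b=ex_b, shared=shared)
        ex_spectra = {}
        for grp, ex in ((groups[0], ex_a), (groups[1], ex_b)):
            ex_spectra[grp] = genes_mod.exclusive_spectrum(
                [r for s in samples_by_group[grp] for r in filt.kept[s]],
                ex, cohort.targets, comp, motif=config.motif)
        gene_results["exclusive_spectrum"] = ex_spectra
        if out is not None:
            rows = ([{"gene": g, "status": f"exclusive_{groups[0]}"}
                     for g in sorted(ex_a)] +
                    [{"gene": g, "status": f"exclusive_{groups[1]}"}
                     for g in sorted(ex_b)] +
                    [{"gene": g, "status": "shared"} for g in sorted(shared)])
            pd.DataFrame(rows, columns=["gene", "status"]).to_csv(
                out / "exclusive_genes.tsv", sep="\t", index=False)
            pd.DataFrame([{"group": grp, **sp}
                          for grp, sp in ex_spectra.items()]).to_csv(
                out / "exclusive_spectrum.tsv", sep="\t", index=False,
                float_format="%.10g")
    if out is not None:
        matrix.presence.astype(int).to_csv(out / "gene_matrix.tsv", sep="\t")

    return {
        "config": config,
        "pon": pon,
        "filter": filt,
        "composition": comp,
        "spectrum": summary,
        "spectrum_tests": tests,
        "architectures": archs,
        "unclustered": unclustered,
        "ith": ith,
        "genes": gene_results,
        "groups": groups,
    }


def run_all(config: SimulationConfig | None = None,
            out_dir: str | Path = "aidscope_out",
            seed: int | None = None, **analysis_kwargs) -> dict:
    """Simulate the cohort, write its inputs, and run every analysis stage.

    The output tree under ``out_dir`` is byte-identical across repeat runs
    with the same config and seed.
    """
    if config is None:
        config = default_config(seed=0 if seed is None else seed)
    elif seed is not None and seed != config.seed:
        from dataclasses import replace
        config = replace(config, seed=seed)
    out = Path(out_dir)
    cohort = simulate_cohort(config)
    write_cohort(cohort, out / "sim")
    results = analyze_cohort(cohort, out_dir=out, **analysis_kwargs)
    results["cohort"] = cohort

    headline = {
        "n_tumors": config.n_tumors,
        "n_variants_called": int(sum(len(v) for v in cohort.tumor_records.values())),
        "n_variants_retained": int(sum(len(v) for v in results["filter"].kept.values())),
        "pon_size": len(results["pon"]),
    }
    if results["ith"] is not None:
        for g, p in results["ith"]["subclonal_proportion"].items():
            headline[f"subclonal_proportion_{g}"] = float(p)
        headline["ith_fisher_p"] = float(results["ith"]["p_value"])
    (out / "summary.json").write_text(json.dumps(headline, indent=2,
                                                 sort_keys=True) + "\n")
    return results
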