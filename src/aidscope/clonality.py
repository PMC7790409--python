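"""VAF-based clonal architecture and intratumor-heterogeneity estimation.

Variant allele frequencies of copy-neutral somatic variants cluster around
``purity * CCF / 2``; the cluster with the highest mean VAF holds the
early, clonal mutations and every lower cluster holds a subclone.  The
subclonal proportion — subclonal variants over all clustered variants —
serves as the intratumor-heterogeneity (ITH) proxy compared between
genotype groups.

Clustering is a k-component binomial mixture over (alt_count, depth) fit
by expectation-maximization, with the component count chosen by BIC over
k = 1..k_max and near-identical components merged afterwards.  Before
clustering, variants are screened: read support >= ``min_depth`` (default
100) for statistical robustness, VAF <= ``max_vaf`` (default 0.8) to drop
residual germline, and no overlap with a copy-number-variant region (the
copy-neutral VAF model does not hold there).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .core_io import VariantRecord
from .spectrum import association_test

__all__ = ["ClonalArchitecture", "filter_for_clustering", "fit_vaf_clusters",
           "label_clonality", "compare_ith", "cluster_tumor"]

EXCLUSION_ORDER = ("low_depth", "high_vaf", "in_cnv")
MIN_VARIANTS = 10


@dataclass
class ClonalArchitecture:
    """Per-tumor VAF clusters with clonal/subclonal labels.

    ``assignment[i]`` is the cluster index of the i-th clustered variant;
    ``labels`` maps cluster index to ``clonal``/``subclonal`` once
    :func:`label_clonality` has run.
    """

    mean_vaf: np.ndarray              # per cluster
    weight: np.ndarray                # mixing proportions
    assignment: np.ndarray            # per variant, cluster index
    log_likelihood: float
    bic: float
    labels: dict[int, str] = field(default_factory=dict)
    n_excluded: dict[str, int] = field(default_factory=dict)
    sample: str = ""

    @property
    def k(self) -> int:
        return len(self.mean_vaf)

    @property
    def n_variants(self) -> int:
        return len(self.assignment)

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.k)

    @property
    def clonal_cluster(self) -> int:
        if not self.labels:
            raise ValueError("architecture is unlabeled; run label_clonality")
        return next(i for i, lab in self.labels.items() if lab == "clonal")

    @property
    def subclonal_proportion(self) -> float:
        if not self.labels:
            raise ValueError("architecture is unlabeled; run label_clonality")
        sizes = self.cluster_sizes()
        sub = sum(sizes[i] for i, lab in self.labels.items()
                  if lab == "subclonal")
        return sub / sizes.sum()

    def to_frame(self) -> pd.DataFrame:
        sizes = self.cluster_sizes()
        return pd.DataFrame({
            "cluster": np.arange(self.k),
            "mean_vaf": self.mean_vaf,
            "weight": self.weight,
            "n_variants": sizes,
            "label": [self.labels.get(i, "") for i in range(self.k)],
        })


def _in_regions(chrom: str, pos: int,
                regions: Sequence[tuple[str, int, int]]) -> bool:
    p0 = pos - 1
    return any(c == chrom and s <= p0 < e for c, s, e in regions)


def filter_for_clustering(
        variants: Iterable[VariantRecord],
        cnv_regions: Sequence[tuple[str, int, int]] = (),
        min_depth: int = 100,
        max_vaf: float = 0.8) -> tuple[list[VariantRecord], dict[str, int]]:
    """Screen variants for VAF clustering; tally exclusions by first
    matching reason in fixed order (low_depth, high_vaf, in_cnv)."""
    kept: list[VariantRecord] = []
    excluded = dict.fromkeys(EXCLUSION_ORDER, 0)
    for r in variants:
        if r.depth < min_depth:
            excluded["low_depth"] += 1
        elif r.vaf > max_vaf:
            excluded["high_vaf"] += 1
        elif _in_regions(r.chrom, r.pos, cnv_regions):
            excluded["in_cnv"] += 1
        else:
            kept.append(r)
    return kept, excluded


def _binom_log_pmf_matrix(alt: np.ndarray, depth: np.ndarray,
                          p: np.ndarray) -> np.ndarray:
    """log Binomial(alt | depth, p_j) for every variant x component."""
    p = np.clip(p, 1e-9, 1 - 1e-9)
    coef = (gammaln(depth + 1) - gammaln(alt + 1)
            - gammaln(depth - alt + 1))[:, None]
    return coef + alt[:, None] * np.log(p)[None, :] \
        + (depth - alt)[:, None] * np.log1p(-p)[None, :]


def _em_fit(alt: np.ndarray, depth: np.ndarray, init_p: np.ndarray,
            max_iter: int = 150, tol: float = 1e-6):
    """Batched EM over restarts of a k-component binomial mixture.

    ``init_p`` has shape (restarts, k); all restarts are updated in one
    vectorized loop and the best-likelihood restart is returned as
    (p, weights, LL).  The binomial coefficient is constant in the
    parameters, so it is folded in once; each restart's log-likelihood is
    monotonically non-decreasing across iterations (asserted; a violation
    indicates a numerical defect).
    """
    init_p = np.atleast_2d(init_p)
    r, k = init_p.shape
    coef_sum = float((gammaln(depth + 1) - gammaln(alt + 1)
                      - gammaln(depth - alt + 1)).sum())
    a_col = alt[:, None, None]
    d_col = (depth - alt)[:, None, None]
    p = init_p.copy()                       # (r, k)
    w = np.full((r, k), 1.0 / k)
    prev_ll = np.full(r, -np.inf)
    for _ in range(max_iter):
        pc = np.clip(p, 1e-9, 1 - 1e-9)
        log_comp = (a_col * np.log(pc)[None]
                    + d_col * np.log1p(-pc)[None]
                    + np.log(np.maximum(w, 1e-300))[None])  # (n, r, k)
        m = log_comp.max(axis=2, keepdims=True)
        e = np.exp(log_comp - m)
        s = e.sum(axis=2)                   # (n, r)
        ll = np.log(s).sum(axis=0) + m.sum(axis=(0, 2)) + coef_sum
        assert np.all(ll >= prev_ll - 1e-6), "EM log-likelihood decreased"
        resp = e / s[:, :, None]
        w = resp.mean(axis=0)
        denom = np.einsum("nrk,n->rk", resp, depth)
        p = np.where(denom > 0,
                     np.einsum("nrk,n->rk", resp, alt) / np.maximum(denom, 1e-300),
                     p)
        done = ll - prev_ll < tol * np.maximum(1.0, np.abs(ll))
        prev_ll = ll
        if done.all():
            break
    best = int(np.argmax(prev_ll))
    return p[best], w[best], float(prev_ll[best])


def _kmeanspp_init(vaf_sorted: np.ndarray, k: int,
                   rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seeding on the sorted VAF values (order-invariant)."""
    centers = [vaf_sorted[rng.integers(len(vaf_sorted))]]
    while len(centers) < k:
        d2 = np.min([(vaf_sorted - c) ** 2 for c in centers], axis=0)
        total = d2.sum()
        if total <= 0:
            centers.append(centers[0])
            continue
        centers.append(vaf_sorted[rng.choice(len(vaf_sorted), p=d2 / total)])
    return np.sort(np.array(centers))


def fit_vaf_clusters(alt_counts: Sequence[int], depths: Sequence[int],
                     k_max: int = 6, seed: int = 0, n_restarts: int = 10,
                     merge_tol: float = 0.02,
                     min_variants: int = MIN_VARIANTS) -> ClonalArchitecture:
    """Fit binomial-mixture VAF clusters with BIC model selection.

    For each k in 1..k_max the mixture is fit from ``n_restarts`` seeded
    k-means++-style initializations, keeping the best likelihood; the BIC
    minimizer is selected and components whose means differ by less than
    ``merge_tol`` are merged.  Deterministic given ``seed`` and invariant
    to input order.
    """
    alt = np.asarray(alt_counts, dtype=float)
    depth = np.asarray(depths, dtype=float)
    if alt.shape != depth.shape or alt.ndim != 1:
        raise ValueError("alt_counts and depths must be 1-D and equal length")
    n = len(alt)
    if n < min_variants:
        raise ValueError(
            f"only {n} variants after filtering (< {min_variants}); "
            f"report this tumor unclustered")
    if np.any(alt > depth) or np.any(depth <= 0):
        raise ValueError("require 0 <= alt_count <= depth and depth > 0")

    # canonical internal order => order-invariant initialization
    order = np.lexsort((alt, depth, alt / depth))
    alt_s, depth_s = alt[order], depth[order]
    vaf_s = alt_s / depth_s

    best = None
    for k in range(1, k_max + 1):
        rng = np.random.default_rng([seed, k])
        init = np.stack([_kmeanspp_init(vaf_s, k, rng)
                         for _ in range(n_restarts)])
        p, w, ll = _em_fit(alt_s, depth_s, init)
        bic = -2 * ll + (2 * k - 1) * np.log(n)
        if best is None or bic < best[3]:
            best = (p, w, ll, bic)

    p, w, ll, bic = best
    p, w = _merge_components(p, w, merge_tol)
    # final E-step on the merged model, in original input order
    log_comp = _binom_log_pmf_matrix(alt, depth, p) + np.log(w)[None, :]
    resp = np.exp(log_comp - logsumexp(log_comp, axis=1, keepdims=True))
    assignment = np.argmax(resp, axis=1)
    ll_final = float(logsumexp(log_comp, axis=1).sum())
    k_final = len(p)
    bic_final = -2 * ll_final + (2 * k_final - 1) * np.log(n)
    # order clusters by descending mean VAF
    order_c = np.argsort(-p)
    remap = np.empty_like(order_c)
    remap[order_c] = np.arange(k_final)
    return ClonalArchitecture(
        mean_vaf=p[order_c], weight=w[order_c],
        assignment=remap[assignment],
        log_likelihood=ll_final, bic=bic_final)


def _merge_components(p: np.ndarray, w: np.ndarray,
                      merge_tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively merge components whose means differ by < merge_tol."""
    p, w = p.copy(), w.copy()
    while len(p) > 1:
        order = np.argsort(p)
        p, w = p[order], w[order]
        gaps = np.diff(p)
        i = int(np.argmin(gaps))
        if gaps[i] >= merge_tol:
            break
        wt = w[i] + w[i + 1]
        merged_p = (p[i] * w[i] + p[i + 1] * w[i + 1]) / wt
        p = np.concatenate([p[:i], [merged_p], p[i + 2:]])
        w = np.concatenate([w[:i], [wt], w[i + 2:]])
    return p, w


def label_clonality(arch: ClonalArchitecture,
                    merge_tol: float = 0.02) -> ClonalArchitecture:
    """Label the highest-mean-VAF cluster clonal, all others subclonal.

    A tie within ``merge_tol`` of the maximum would be a merge defect;
    such clusters are merged before labeling.
    """
    if arch.k == 0:
        raise ValueError("no clusters to label")
    top = float(arch.mean_vaf[0])  # clusters sorted descending by mean
    near = np.flatnonzero(top - arch.mean_vaf < merge_tol)
    if len(near) > 1:
        keep = int(near[0])
        sizes = arch.cluster_sizes()
        wts = arch.weight[near] * 0 + sizes[near]
        merged_mean = float(np.average(arch.mean_vaf[near], weights=np.maximum(wts, 1)))
        mapping = {int(i): keep for i in near}
        new_assign = np.array([mapping.get(int(a), int(a))
                               for a in arch.assignment])
        keep_idx = [i for i in range(arch.k) if i not in near[1:]]
        remap = {old: new for new, old in enumerate(keep_idx)}
        arch.mean_vaf = np.array(
            [merged_mean if i == keep else arch.mean_vaf[i] for i in keep_idx])
        arch.weight = np.array(
            [arch.weight[near].sum() if i == keep else arch.weight[i]
             for i in keep_idx])
        arch.assignment = np.array([remap[a] for a in new_assign])
    arch.labels = {0: "clonal",
                   **{i: "subclonal" for i in range(1, arch.k)}}
    return arch


def cluster_tumor(variants: Iterable[VariantRecord],
                  cnv_regions: Sequence[tuple[str, int, int]] = (),
                  min_depth: int = 100, max_vaf: float = 0.8,
                  k_max: int = 6, seed: int = 0, sample: str = "",
                  merge_tol: float = 0.02) -> ClonalArchitecture:
    """Filter, fit and label one tumor's clonal architecture."""
    recs = sorted(variants, key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    kept, excluded = filter_for_clustering(recs, cnv_regions, min_depth, max_vaf)
    arch = fit_vaf_clusters([r.alt_count for r in kept],
                            [r.depth for r in kept],
                            k_max=k_max, seed=seed, merge_tol=merge_tol)
    arch = label_clonality(arch, merge_tol)
    arch.n_excluded = excluded
    arch.sample = sample
    return arch


def compare_ith(group_a: Sequence[ClonalArchitecture],
                group_b: Sequence[ClonalArchitecture],
                names: tuple[str, str] = ("a", "b")) -> dict:
    """Pool clonal/subclonal counts per group and Fisher-test the 2x2.

    Per-tumor subclonal proportions are reported descriptively; the pooled
    table carries the headline test.
    """
    def pooled(archs):
        clonal = subclonal = 0
        for a in archs:
            sizes = a.cluster_sizes()
            for i, lab in a.labels.items():
                if lab == "clonal":
                    clonal += int(sizes[i])
                else:
                    subclonal += int(sizes[i])
        return clonal, subclonal

    ca, sa = pooled(group_a)
    cb, sb = pooled(group_b)
    if ca + sa == 0 or cb + sb == 0:
        raise ValueError("a group has zero clustered variants")
    table = np.array([[ca, sa], [cb, sb]])
    odds, p = association_test(table, mode="fisher")
    per_tumor = pd.DataFrame(
        [{"group": names[0], "sample": a.sample,
          "subclonal_proportion": a.subclonal_proportion} for a in group_a] +
        [{"group": names[1], "sample": b.sample,
          "subclonal_proportion": b.subclonal_proportion} for b in group_b])
    return {
        "table": table,
        "odds_ratio": odds,
        "p_value": p,
        "subclonal_proportion": {
            names[0]: sa / (ca + sa), names[1]: sb / (cb + sb)},
        "per_tumor": per_tumor,
    }
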