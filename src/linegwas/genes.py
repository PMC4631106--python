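"""Gene-level association: SNP assignment and the Fisher combination test.

Per gene, the single-SNP p-values are combined as T = -2 * sum(ln p_i).
Significance is empirical: the null T for a gene with N SNPs is the
Fisher statistic of N p-values resampled with replacement from the
genome-wide pool of all tested SNP p-values, and the empirical p-value
is the plain proportion of null statistics >= the observed one (an
optional (r+1)/(B+1) correction is available but off by default).  The
pooled i.i.d. resampling ignores intra-gene LD; an experimental mode
resamples contiguous SNP windows instead, preserving local correlation.

Genes need at least two assigned SNPs to be tested; intervals may be
extended by a fixed flank (e.g. 5 kb) to catch regulatory variants, and
SNPs in overlapping genes count for every gene they fall in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import GeneAnnotation, GenotypePanel


@dataclass
class GeneSnpMap:
    """gene_id -> variant ids (>= 2 SNPs), plus the skipped small genes."""

    assigned: dict[str, list[str]]
    extension: int = 0
    skipped: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.assigned)


def assign_snps_to_genes(
    panel: GenotypePanel,
    annotation: GeneAnnotation,
    extension: int = 0,
) -> GeneSnpMap:
    """Containment test of SNP positions in (extended) gene intervals.

    Intervals are 1-based inclusive and extended by ``extension`` bp on
    both sides (floored at 1).  Genes receiving fewer than two SNPs are
    excluded from testing but listed in ``skipped``.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in panel.variants.groupby("chrom", sort=False):
        by_chrom[chrom] = (grp["pos"].to_numpy(), grp["variant_id"].to_numpy())
    assigned: dict[str, list[str]] = {}
    skipped: list[str] = []
    for row in annotation.genes.itertuples(index=False):
        entry = by_chrom.get(row.chrom)
        if entry is None:
            skipped.append(row.gene_id)
            continue
        pos, vids = entry
        lo = np.searchsorted(pos, max(row.start - extension, 1), side="left")
        hi = np.searchsorted(pos, row.end + extension, side="right")
        if hi - lo >= 2:
            assigned[row.gene_id] = list(vids[lo:hi])
        else:
            skipped.append(row.gene_id)
    if not assigned:
        raise ValueError("no gene received >= 2 SNPs; check annotation/panel coordinates")
    return GeneSnpMap(assigned=assigned, extension=extension, skipped=skipped)


def fisher_T(p_values) -> float:
    """Fisher's combination statistic T = -2 * sum(ln p_i).

    Zero p-values are clamped to the smallest positive float with a
    warning (the statistic would otherwise be infinite).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if np.any(p == 0):
        warnings.warn("p-value of 0 clamped to the smallest positive float")
        p = np.maximum(p, np.finfo(float).tiny)
    return float(-2.0 * np.log(p).sum())


def _empirical_counts(
    neg2logp: np.ndarray,
    sizes: np.ndarray,
    t_obs: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    chunk: int = 200_000,
) -> np.ndarray:
    """count of null T >= T_obs per gene, pooled i.i.d. resampling."""
    M = neg2logp.shape[0]
    counts = np.zeros(len(sizes), dtype=np.int64)
    for g, (N, t0) in enumerate(zip(sizes, t_obs)):
        done = 0
        while done < n_perm:
            b = min(chunk // max(N, 1) + 1, n_perm - done)
            idx = rng.integers(0, M, size=(b, N))
            counts[g] += int((neg2logp[idx].sum(axis=1) >= t0).sum())
            done += b
    return counts


def permutation_gene_test(
    gene_map: GeneSnpMap,
    snp_results: pd.DataFrame,
    n_perm: int = 10_000,
    n_perm_top: int = 1_000_000,
    top_n: int = 40,
    seed: int = 0,
    counting: str = "plain",
    mode: str = "pooled",
) -> pd.DataFrame:
    """Empirical gene-wide significance by genome-wide resampling.

    Parameters
    ----------
    gene_map
        SNP assignment from :func:`assign_snps_to_genes`.
    snp_results
        Single-SNP association table with ``variant_id`` and ``p``
        columns; all tested SNPs form the resampling pool.
    n_perm, n_perm_top, top_n
        First-pass permutation count; the ``top_n`` genes by first-pass
        empirical p are re-evaluated with ``n_perm_top`` permutations.
    counting
        ``"plain"`` uses the proportion of null >= observed (can be 0);
        ``"add_one"`` uses (r+1)/(B+1).
    mode
        ``"pooled"`` resamples p-values i.i.d. from the genome-wide pool;
        ``"window"`` (experimental) resamples contiguous windows of SNPs,
        preserving local LD in the null.

    Returns
    -------
    DataFrame with gene_id, n_snps, T_obs, empirical_p, n_permutations_used,
    sorted ascending by empirical p (ties: larger T first, then gene id).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pool = snp_results.dropna(subset=["p"])
    pvals = pool.set_index("variant_id")["p"]
    neg2logp = -2.0 * np.log(np.maximum(pvals.to_numpy(), np.finfo(float).tiny))

    gene_ids = sorted(gene_map.assigned)
    sizes, t_obs = [], []
    for gid in gene_ids:
        vids = [v for v in gene_map.assigned[gid] if v in pvals.index]
        if len(vids) < 2:
            raise ValueError(f"gene {gid!r} has < 2 SNPs with p-values")
        sizes.append(len(vids))
        t_obs.append(fisher_T(pvals.loc[vids].to_numpy()))
    sizes = np.asarray(sizes)
    t_obs = np.asarray(t_obs)

    rng = np.random.default_rng(seed)
    if mode == "pooled":
        counts = _empirical_counts(neg2logp, sizes, t_obs, n_perm, rng)
    elif mode == "window":
        counts = _window_counts(neg2logp, sizes, t_obs, n_perm, rng)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    denom = n_perm
    if counting == "add_one":
        emp = (counts + 1) / (n_perm + 1)
    else:
        emp = counts / denom
    n_used = np.full(len(gene_ids), n_perm)

    out = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "n_snps": sizes,
            "T_obs": t_obs,
            "empirical_p": emp,
            "n_permutations_used": n_used,
        }
    )
    out = out.sort_values(
        ["empirical_p", "T_obs", "gene_id"], ascending=[True, False, True]
    ).reset_index(drop=True)

    if n_perm_top > n_perm and top_n > 0 and len(out):
        top = out.head(top_n)
        idx = [gene_ids.index(g) for g in top["gene_id"]]
        counts_top = (
            _empirical_counts(neg2logp, sizes[idx], t_obs[idx], n_perm_top, rng)
            if mode == "pooled"
            else _window_counts(neg2logp, sizes[idx], t_obs[idx], n_perm_top, rng)
        )
        if counting == "add_one":
            emp_top = (counts_top + 1) / (n_perm_top + 1)
        else:
            emp_top = counts_top / n_perm_top
        out = out.set_index("gene_id")
        out.loc[top["gene_id"], "empirical_p"] = emp_top
        out.loc[top["gene_id"], "n_permutations_used"] = n_perm_top
        out = out.reset_index()
        out = out.sort_values(
            ["empirical_p", "T_obs", "gene_id"], ascending=[True, False, True]
        ).reset_index(drop=True)
    return out


def _window_counts(neg2logp, sizes, t_obs, n_perm, rng, chunk=200_000):
    """Experimental null: contiguous windows of the SNP-ordered pool."""
    M = neg2logp.shape[0]
    cumsum = np.concatenate([[0.0], np.cumsum(neg2logp)])
    counts = np.zeros(len(sizes), dtype=np.int64)
    for g, (N, t0) in enumerate(zip(sizes, t_obs)):
        if N > M:
            raise ValueError("gene larger than the pool")
        done = 0
        while done < n_perm:
            b = min(chunk // max(N, 1) + 1, n_perm - done)
            start = rng.integers(0, M - N + 1, size=b)
            t_null = cumsum[start + N] - cumsum[start]
            counts[g] += int((t_null >= t0).sum())
            done += b
    return counts


class GeneBasedTest(BaseEstimator):
    """Estimator wrapper: ``fit(snp_results, gene_map)`` -> ``results_``."""

    def __init__(self, n_perm: int = 10_000, n_perm_top: int = 1_000_000,
                 top_n: int = 40, seed: int = 0, counting: str = "plain",
                 mode: str = "pooled"):
        self.n_perm = n_perm
        self.n_perm_top = n_perm_top
        self.top_n = top_n
        self.seed = seed
        self.counting = counting
        self.mode = mode

    def fit(self, snp_results: pd.DataFrame, gene_map: GeneSnpMap):
        self.results_ = permutation_gene_test(
            gene_map,
            snp_results,
            n_perm=self.n_perm,
            n_perm_top=self.n_perm_top,
            top_n=self.top_n,
            seed=self.seed,
            counting=self.counting,
            mode=self.mode,
        )
        return self


def ranked_gene_list(gene_results: pd.DataFrame) -> list[str]:
    """Deterministic ranking for enrichment: ascending empirical p,
    ties broken by descending T then gene id."""
    ordered = gene_results.sort_values(
        ["empirical_p", "T_obs", "gene_id"], ascending=[True, False, True]
    )
    return list(ordered["gene_id"])
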