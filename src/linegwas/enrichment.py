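"""Gene-set enrichment over a ranked gene list.

Two complementary tests, both taking the gene-based ranking (rank 1 =
most associated) as input:

* an exact upper-tail hypergeometric test for over-representation of a
  set among the top-k ranked genes, and
* a Wilcoxon rank-sum test comparing the ranks of set members against
  non-members across the whole list (the rank-based category test used
  by Catmap-style ontology analyses), one-sided toward better (smaller)
  ranks by default.

The universe is whatever gene list the caller ranks — typically the
genes actually tested in the gene-based stage, not all annotated genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneSetCollection


@dataclass
class EnrichmentResult:
    set_id: str
    test: str
    statistic: float
    p_value: float
    n_category_in_universe: int
    universe_size: int
    top_k: int | None = None
    observed_overlap: int | None = None
    flag: str = ""


def hypergeom_top_k(
    ranked_genes: list[str],
    gene_set,
    top_k: int,
    set_id: str = "set",
) -> EnrichmentResult:
    """P(X >= k) for the overlap between a gene set and the top-k genes.

    Population N = length of the ranked list, successes K = members of
    the set present in the list, draws n = top_k, observed k = members
    among the top n.  Exact tail via scipy's log-gamma hypergeometric.
    """
    if top_k > len(ranked_genes):
        raise ValueError("top_k exceeds the universe size")
    universe = list(ranked_genes)
    members = set(gene_set) & set(universe)
    if not members:
        raise ValueError(f"gene set {set_id!r} has no overlap with the universe")
    N = len(universe)
    K = len(members)
    k_obs = sum(1 for g in universe[:top_k] if g in members)
    p = float(stats.hypergeom.sf(k_obs - 1, N, K, top_k))
    return EnrichmentResult(
        set_id=set_id,
        test="hypergeometric",
        statistic=float(k_obs),
        p_value=min(max(p, np.finfo(float).tiny), 1.0),
        n_category_in_universe=K,
        universe_size=N,
        top_k=top_k,
        observed_overlap=k_obs,
    )


def _rank_sum_p(member_ranks: np.ndarray, other_ranks: np.ndarray,
                alternative: str) -> tuple[float, float]:
    """Wilcoxon rank-sum on rank values; exact for small universes
    (distinct ranks have no ties), asymptotic with continuity correction
    otherwise.  Returns (rank sum of members, p)."""
    n_total = len(member_ranks) + len(other_ranks)
    method = "exact" if n_total <= 50 else "asymptotic"
    res = stats.mannwhitneyu(
        member_ranks, other_ranks, alternative=alternative, method=method
    )
    w = float(member_ranks.sum())
    return w, float(res.pvalue)


def wilcoxon_rank_enrichment(
    ranked_genes: list[str],
    sets: GeneSetCollection,
    n_tests_for_bonferroni: int | None = None,
    alpha: float = 0.05,
    alternative: str = "less",
) -> pd.DataFrame:
    """Rank-sum enrichment of every set over the full ranked list.

    ``alternative="less"`` tests whether members rank better (smaller
    rank numbers) than non-members; ``"two-sided"`` is available.  Sets
    with fewer than 2 members in the universe, or equal to the whole
    universe, are flagged and get NaN p-values.  The Bonferroni flag
    compares p against alpha / n_tests (default: number of sets tested).
    """
    universe = list(ranked_genes)
    rank_of = {g: i + 1 for i, g in enumerate(universe)}
    n = len(universe)
    restricted, _unknown = sets.restrict_to(universe)
    n_tests = n_tests_for_bonferroni or max(
        sum(1 for m in restricted.sets.values() if 2 <= len(m) < n), 1
    )
    threshold = alpha / n_tests
    rows = []
    all_ranks = np.arange(1, n + 1)
    for sid, members in restricted.sets.items():
        K = len(members)
        if K < 2:
            rows.append((sid, K, np.nan, np.nan, False, "fewer than 2 members in universe"))
            continue
        if K == n:
            rows.append((sid, K, np.nan, np.nan, False, "set equals universe"))
            continue
        member_ranks = np.array(sorted(rank_of[g] for g in members), dtype=float)
        mask = np.zeros(n, dtype=bool)
        mask[(member_ranks - 1).astype(int)] = True
        other_ranks = all_ranks[~mask].astype(float)
        w, p = _rank_sum_p(member_ranks, other_ranks, alternative)
        rows.append((sid, K, w, p, p < threshold, ""))
    out = pd.DataFrame(
        rows,
        columns=["set_id", "n_in_universe", "rank_sum", "p_value",
                 "bonferroni_significant", "flag"],
    )
    out.attrs["bonferroni_threshold"] = threshold
    out.attrs["universe_size"] = n
    out.attrs["n_tests"] = n_tests
    return out
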