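"""SNP-to-gene assignment and the permutation Fisher combination test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from linegwas import (
    GeneBasedTest,
    assign_snps_to_genes,
    fisher_T,
    permutation_gene_test,
    ranked_gene_list,
)
from linegwas.datatypes import GeneAnnotation

from conftest import make_panel


def _annotation(rows):
    return GeneAnnotation(pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"]))


def _panel_with_positions(positions, chrom="2L"):
    m = len(positions)
    dos = 2.0 * (np.random.default_rng(0).random((6, m)) < 0.5)
    return make_panel(dos, chrom=[chrom] * m, pos=positions)


def test_assignment_boundaries_and_extension():
    panel = _panel_with_positions([95, 100, 200, 201, 5300])
    ann = _annotation([("gA", "2L", 100, 200)])
    # inclusive boundaries at extension 0
    m0 = assign_snps_to_genes(panel, ann, extension=0)
    assert m0.assigned["gA"] == ["v1", "v2"]
    # +-5 kb flank pulls in the nearby SNPs (5300 > 200 + 5000 stays out)
    m5 = assign_snps_to_genes(panel, ann, extension=5000)
    assert m5.assigned["gA"] == ["v0", "v1", "v2", "v3"]


def test_overlapping_genes_share_snps():
    panel = _panel_with_positions([100, 150, 180, 300])
    ann = _annotation([("gA", "2L", 90, 200), ("gB", "2L", 140, 350)])
    gm = assign_snps_to_genes(panel, ann)
    shared = set(gm.assigned["gA"]) & set(gm.assigned["gB"])
    assert shared == {"v1", "v2"}


def test_small_genes_skipped_and_empty_errors():
    panel = _panel_with_positions([100, 110, 5000])
    ann = _annotation([("gA", "2L", 90, 120), ("gTiny", "2L", 4990, 5010)])
    gm = assign_snps_to_genes(panel, ann)
    assert "gTiny" in gm.skipped and "gA" in gm.assigned
    ann_none = _annotation([("gX", "2L", 40000, 40100)])
    with pytest.raises(ValueError, match="no gene"):
        assign_snps_to_genes(panel, ann_none)


# ------------------------------------------------------------------ fisher_T

def test_fisher_examples():
    assert fisher_T([1.0, 1.0, 1.0]) == 0.0
    assert fisher_T([0.05, 0.01]) == pytest.approx(15.2018, abs=5e-5)
    with pytest.warns(UserWarning, match="clamped"):
        t = fisher_T([0.0, 0.5])
    assert np.isfinite(t)
    with pytest.raises(ValueError):
        fisher_T([1.2])
    with pytest.raises(ValueError):
        fisher_T([])


def test_fisher_is_chi2_under_uniform_null():
    rng = np.random.default_rng(7)
    N = 4
    T = np.array([fisher_T(rng.uniform(size=N)) for _ in range(3000)])
    ks = stats.kstest(T, stats.chi2(df=2 * N).cdf)
    assert ks.pvalue > 0.01


# ------------------------------------------------------- permutation test

def _snp_table(pvals):
    return pd.DataFrame(
        {"variant_id": [f"v{i}" for i in range(len(pvals))], "p": pvals}
    )


def _map_for(genes, extension=0):
    from linegwas.genes import GeneSnpMap
    return GeneSnpMap(assigned=genes, extension=extension)


def test_gene_of_maximal_pvalues_is_null():
    snp = _snp_table([1.0, 1.0, 1.0, 0.2, 0.3, 0.7])
    gm = _map_for({"gA": ["v0", "v1", "v2"]})
    res = permutation_gene_test(gm, snp, n_perm=500, n_perm_top=500, seed=1)
    assert res.empirical_p[0] > 0.95


def test_empirical_p_matches_chi2_tail_for_uniform_pool():
    rng = np.random.default_rng(8)
    pool = rng.uniform(size=20_000)
    pool[:5] = [0.2, 0.1, 0.3, 0.05, 0.5]
    snp = _snp_table(pool)
    gm = _map_for({"gA": ["v0", "v1", "v2", "v3", "v4"]})
    res = permutation_gene_test(gm, snp, n_perm=40_000, n_perm_top=40_000, seed=2)
    t_obs = fisher_T(pool[:5])
    expected = stats.chi2(df=10).sf(t_obs)
    assert res.empirical_p[0] == pytest.approx(expected, abs=0.01)


def test_determinism_and_snp_order_invariance():
    rng = np.random.default_rng(9)
    snp = _snp_table(rng.uniform(size=300))
    gm1 = _map_for({"gA": ["v1", "v5", "v9"], "gB": ["v2", "v3"]})
    gm2 = _map_for({"gA": ["v9", "v1", "v5"], "gB": ["v3", "v2"]})
    r1 = permutation_gene_test(gm1, snp, n_perm=1000, n_perm_top=1000, seed=3)
    r2 = permutation_gene_test(gm2, snp, n_perm=1000, n_perm_top=1000, seed=3)
    pd.testing.assert_frame_equal(r1, r2)


def test_top_tier_escalation_uses_more_permutations():
    rng = np.random.default_rng(10)
    snp = _snp_table(rng.uniform(size=500))
    genes = {f"g{i}": [f"v{2*i}", f"v{2*i+1}"] for i in range(20)}
    res = permutation_gene_test(_map_for(genes), snp, n_perm=200,
                                n_perm_top=2000, top_n=5, seed=4)
    assert (res["n_permutations_used"] == 2000).sum() == 5
    assert res["n_permutations_used"].iloc[0] == 2000  # best gene escalated


def test_add_one_counting_never_zero():
    # a gene holding the only two tiny p-values of a large pool: the
    # plain proportion is 0, the corrected estimate 1/(B+1)
    rng = np.random.default_rng(13)
    pool = rng.uniform(0.5, 1.0, size=2000)
    pool[:2] = 1e-10
    snp = _snp_table(pool)
    gm = _map_for({"gA": ["v0", "v1"]})
    plain = permutation_gene_test(gm, snp, n_perm=200, n_perm_top=200, seed=5)
    corrected = permutation_gene_test(gm, snp, n_perm=200, n_perm_top=200,
                                      seed=5, counting="add_one")
    assert plain.empirical_p[0] == 0.0
    assert corrected.empirical_p[0] == pytest.approx(1 / 201)


def test_window_mode_runs_and_is_deterministic():
    rng = np.random.default_rng(11)
    snp = _snp_table(rng.uniform(size=400))
    gm = _map_for({"gA": ["v0", "v1", "v2"], "gB": ["v10", "v11"]})
    r1 = permutation_gene_test(gm, snp, n_perm=500, n_perm_top=500, seed=6, mode="window")
    r2 = permutation_gene_test(gm, snp, n_perm=500, n_perm_top=500, seed=6, mode="window")
    pd.testing.assert_frame_equal(r1, r2)


def test_estimator_and_ranking():
    rng = np.random.default_rng(12)
    snp = _snp_table(rng.uniform(size=100))
    genes = {f"g{i}": [f"v{3*i}", f"v{3*i+1}", f"v{3*i+2}"] for i in range(10)}
    est = GeneBasedTest(n_perm=500, n_perm_top=500, seed=7).fit(snp, _map_for(genes))
    ranked = ranked_gene_list(est.results_)
    assert len(ranked) == 10
    # ranking is ascending empirical p with deterministic tie-breaks
    ps = est.results_.set_index("gene_id").loc[ranked, "empirical_p"].to_numpy()
    assert (np.diff(ps) >= 0).all()
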