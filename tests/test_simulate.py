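"""Generator behaviour: determinism, dosage coding, MAF spectrum,
heritability scaling, annotation and gene-set construction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from linegwas import (
    SimulationConfig,
    estimate_h2,
    simulate_annotation,
    simulate_gene_sets,
    simulate_panel,
)
from linegwas.qc import compute_variant_stats
from linegwas.simulate import SimulationError


def test_same_seed_is_byte_identical():
    cfg = SimulationConfig(n_snps=600, n_causal=20, seed=42)
    p1, f1, t1 = simulate_panel(cfg)
    p2, f2, t2 = simulate_panel(cfg)
    np.testing.assert_array_equal(p1.dosages, p2.dosages)
    pd.testing.assert_frame_equal(p1.variants, p2.variants)
    pd.testing.assert_frame_equal(f1.flies, f2.flies)
    assert t1.causal_snp_ids == t2.causal_snp_ids
    assert t1.realized_H2 == t2.realized_H2


def test_different_seed_differs():
    p1, _, _ = simulate_panel(SimulationConfig(n_snps=600, seed=1))
    p2, _, _ = simulate_panel(SimulationConfig(n_snps=600, seed=2))
    assert not np.array_equal(p1.dosages, p2.dosages, equal_nan=True)


def test_dosages_are_homozygous_codes():
    panel, _, _ = simulate_panel(SimulationConfig(n_snps=500, seed=3))
    vals = panel.dosages[~np.isnan(panel.dosages)]
    assert set(np.unique(vals)) <= {0.0, 2.0}
    assert 0.0 < np.isnan(panel.dosages).mean() < 0.1


def test_null_trait_has_near_zero_heritability():
    # no causal SNPs and target_H2 = 0: flies are i.i.d. within and across lines
    ests = []
    for seed in range(8):
        cfg = SimulationConfig(n_snps=300, n_causal=0, target_H2=0.0, seed=seed)
        _, phenos, truth = simulate_panel(cfg)
        assert truth.realized_H2 == 0.0
        ests.append(estimate_h2(phenos).H2)
    assert np.mean(ests) < 0.05


def test_maf_spectrum_matches_request():
    # folded MAF of the default uniform(0.02, 0.5) spectrum; KS distance
    # tolerance covers 197-line binomial noise plus founder-grid rounding
    panel, _, _ = simulate_panel(SimulationConfig(n_snps=10_000, seed=5))
    maf = compute_variant_stats(panel)["maf"].to_numpy()
    D = stats.kstest(maf, lambda x: np.clip((x - 0.02) / 0.48, 0.0, 1.0)).statistic
    assert D < 0.06


def test_ld_blocks_are_correlated_and_chromosomes_independent():
    cfg = SimulationConfig(n_snps=2000, missing_rate=0.0, seed=6)
    panel, _, _ = simulate_panel(cfg)
    D = panel.dosages
    var = D.var(axis=0)
    common = np.flatnonzero(var > 0.5)
    # adjacent common SNPs (same block, ~200 bp apart) should be in strong LD
    r2_adj = []
    for j in common[:-1]:
        k = j + 1
        if k in set(common) and panel.variants.chrom[j] == panel.variants.chrom[k] \
                and abs(panel.variants.pos[j] - panel.variants.pos[k]) < 2000:
            r = np.corrcoef(D[:, j], D[:, k])[0, 1]
            r2_adj.append(r * r)
    assert np.median(r2_adj) > 0.3
    # SNPs on different chromosomes: r2 near zero on average
    chroms = panel.variants.chrom.to_numpy()
    j = common[chroms[common] == "2L"][0]
    ks = common[chroms[common] == "3L"][:200]
    r2_cross = [np.corrcoef(D[:, j], D[:, k])[0, 1] ** 2 for k in ks]
    assert np.mean(r2_cross) < 0.05


def test_heritability_scaling_error():
    cfg = SimulationConfig(n_snps=500, n_causal=100, effect_sd=5.0,
                           target_H2=0.05, seed=7)
    with pytest.raises(SimulationError, match="impossible H2"):
        simulate_panel(cfg)


def test_effect_fill_makes_trait_fully_genetic():
    cfg = SimulationConfig(n_snps=800, n_causal=50, effect_scaling="fill",
                           target_H2=0.4, seed=8)
    _, _, truth = simulate_panel(cfg)
    assert truth.sigma2_line_env == pytest.approx(0.0, abs=1e-9)
    expected = 10.6**2 * 0.4 / 0.6
    assert truth.line_genetic_values.var(ddof=1) == pytest.approx(expected, rel=1e-6)


def test_config_validation():
    with pytest.raises(SimulationError):
        SimulationConfig(n_causal=100, n_snps=50)
    with pytest.raises(SimulationError):
        SimulationConfig(target_H2=1.0)
    with pytest.raises(SimulationError):
        SimulationConfig(wolbachia_prevalence=1.5)
    with pytest.raises(SimulationError):
        SimulationConfig(n_lines=0)


def test_wolbachia_prevalence():
    _, phenos, _ = simulate_panel(SimulationConfig(n_snps=300, seed=9))
    prev = phenos.wolbachia().mean()
    assert 0.35 < prev < 0.65


# ---------------------------------------------------------------- annotation

def test_annotation_no_overlap():
    ann = simulate_annotation(50, genome_length=100_000, overlap_fraction=0.0, seed=1)
    df = ann.genes.sort_values("start")
    assert (df["start"].to_numpy()[1:] > df["end"].to_numpy()[:-1]).all()


def test_annotation_single_gene():
    ann = simulate_annotation(1, genome_length=1000, seed=2)
    assert len(ann) == 1


def test_annotation_too_short():
    with pytest.raises(SimulationError, match="too short"):
        simulate_annotation(100, genome_length=150)


def _overlap_fraction(ann):
    df = ann.genes.sort_values(["chrom", "start"]).reset_index(drop=True)
    hit = np.zeros(len(df), dtype=bool)
    for c, grp in df.groupby("chrom"):
        idx = grp.index.to_numpy()
        s, e = grp["start"].to_numpy(), grp["end"].to_numpy()
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                if s[b] > e[a]:
                    break
                hit[idx[a]] = hit[idx[b]] = True
    return hit.mean()


def test_annotation_overlap_rate():
    # direct interval-intersection count as the oracle for the planted rate
    ann = simulate_annotation(2000, genome_length=4_000_000,
                              overlap_fraction=0.2, seed=3)
    assert _overlap_fraction(ann) == pytest.approx(0.2, abs=0.05)


# ---------------------------------------------------------------- gene sets

def test_gene_set_of_all_genes():
    ann = simulate_annotation(30, genome_length=10_000, seed=4)
    sets = simulate_gene_sets(ann, set_sizes=[30], seed=0)
    assert sorted(sets["set0001"]) == sorted(ann.gene_ids)


def test_gene_sets_deterministic_and_planted():
    ann = simulate_annotation(100, genome_length=50_000, seed=5)
    causal = list(ann.gene_ids[:10])
    s1 = simulate_gene_sets(ann, [20, 30], enriched_genes=causal, enriched_size=15, seed=6)
    s2 = simulate_gene_sets(ann, [20, 30], enriched_genes=causal, enriched_size=15, seed=6)
    assert s1.sets == s2.sets
    assert set(causal) <= set(s1["planted"])
    assert len(s1["planted"]) == 15


def test_gene_set_size_validation():
    ann = simulate_annotation(10, genome_length=10_000, seed=7)
    with pytest.raises(SimulationError):
        simulate_gene_sets(ann, set_sizes=[11])
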