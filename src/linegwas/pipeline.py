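"""End-to-end orchestration: simulate -> QC -> PCA -> GWAS -> gene test
-> polygenic scores -> enrichment -> heritability.

Mostly a convenience layer so the whole analysis can be run (and its
determinism verified) with one call; every stage is the public API of
its own module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .covariates import build_covariates, genotype_pca
from .datatypes import GeneAnnotation, GenotypePanel, PhenotypeTable
from .enrichment import hypergeom_top_k, wilcoxon_rank_enrichment
from .genes import assign_snps_to_genes, permutation_gene_test, ranked_gene_list
from .gwas import bonferroni_threshold, run_gwas
from .heritability import estimate_h2, phenotype_summary
from .polygenic import ClumpParams, cross_validated_r2, permuted_null_profile, summarize_profiles
from .qc import QcReport, apply_filters
from .simulate import SimulationConfig, simulate_annotation, simulate_gene_sets, simulate_panel


@dataclass
class PipelineResult:
    panel: GenotypePanel
    phenotypes: PhenotypeTable
    qc_report: QcReport
    covariates: pd.DataFrame
    gwas: pd.DataFrame
    gene_results: pd.DataFrame
    prs_summary: pd.DataFrame
    enrichment: pd.DataFrame
    h2: dict
    summary: dict
    extras: dict = field(default_factory=dict)


def run_pipeline(
    config: SimulationConfig,
    annotation: GeneAnnotation | None = None,
    n_components: int = 4,
    gene_extension: int = 0,
    n_perm: int = 2000,
    n_genes: int = 400,
    prs_repeats: int = 20,
    prs_thresholds=(1.0, 0.5, 0.1, 0.01, 0.001),
    seed: int = 0,
) -> PipelineResult:
    """Run every stage on a synthetic panel; fully determined by
    ``config.seed`` and ``seed``."""
    panel, phenos, truth = simulate_panel(config)
    panel, report = apply_filters(panel)

    pcs = genotype_pca(panel, n_components=n_components)
    covars = build_covariates(pcs, phenos)
    assoc = run_gwas(panel, phenos, covars)

    if annotation is None:
        per_chrom = panel.variants.groupby("chrom", sort=False)["pos"].max()
        annotation = simulate_annotation(
            n_genes,
            genome_length=int(per_chrom.sum()),
            overlap_fraction=0.05,
            seed=seed,
            chromosomes={c: int(v) for c, v in per_chrom.items()},
        )
    gene_map = assign_snps_to_genes(panel, annotation, extension=gene_extension)
    gene_results = permutation_gene_test(
        gene_map, assoc, n_perm=n_perm, n_perm_top=n_perm, seed=seed
    )
    ranked = ranked_gene_list(gene_results)

    causal_genes = sorted(
        {g for g, vids in gene_map.assigned.items()
         if set(vids) & set(truth.causal_snp_ids)}
    )
    gene_sets = simulate_gene_sets(
        annotation,
        set_sizes=[20, 50, 100],
        enriched_genes=causal_genes or None,
        enriched_size=min(30, max(len(causal_genes), 5)) if causal_genes else None,
        seed=seed,
    )
    restricted, _ = gene_sets.restrict_to(ranked)
    enr = wilcoxon_rank_enrichment(ranked, restricted)
    hyper = {
        sid: hypergeom_top_k(ranked, members, top_k=min(100, len(ranked)), set_id=sid)
        for sid, members in restricted.sets.items()
        if len(members) >= 2
    }

    observed = cross_validated_r2(
        panel, phenos, covars, ClumpParams(), prs_thresholds, prs_repeats, seed
    )
    null = permuted_null_profile(
        panel, phenos, covars, ClumpParams(), prs_thresholds, prs_repeats, seed + 1
    )
    prs_summary = summarize_profiles(observed, null)

    h2 = estimate_h2(phenos)
    return PipelineResult(
        panel=panel,
        phenotypes=phenos,
        qc_report=report,
        covariates=covars,
        gwas=assoc,
        gene_results=gene_results,
        prs_summary=prs_summary,
        enrichment=enr,
        h2=h2.to_dict(),
        summary=phenotype_summary(phenos),
        extras={
            "truth": truth,
            "bonferroni_snp": bonferroni_threshold(0.05, len(assoc)),
            "bonferroni_gene": bonferroni_threshold(0.05, len(gene_results)),
            "hypergeom": hyper,
            "ranked_genes": ranked,
            "annotation": annotation,
        },
    )
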