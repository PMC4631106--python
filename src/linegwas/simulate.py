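"""Synthetic inbred-panel generator with known ground truth.

Emulates the statistical structure of a reference panel of fully inbred
fly lines: homozygous genotypes with a specified minor-allele-frequency
spectrum and blockwise linkage disequilibrium, latent population
structure mimicking segregating inversion karyotypes, ~50% Wolbachia
infection prevalence, additive causal effects on lifespan plus line- and
fly-level environmental noise calibrated to a target broad-sense
heritability, and a 5 vials x 5 flies replicate design per line.

LD model
--------
Genotypes are a haplotype mosaic.  Each chromosome is cut into blocks of
``ld_block_length`` bp; each block has a circular pool of ``n_founders``
founder haplotypes, and every line copies one founder per block.  At a
SNP with allele frequency q the alt allele occupies an arc of
``round(n_founders * q)`` consecutive founders whose offset drifts with
base-pair position, so nearby SNPs share most of their arc (high |r|)
and correlation decays along the block; blocks are independent.  Because
each line picks a founder uniformly at random, the marginal alt count at
a SNP is exactly Binomial(n_lines, round(Kq)/K), which keeps the
realized MAF spectrum tight around the requested distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GeneAnnotation, GeneSetCollection, GenotypePanel, PhenotypeTable

#: Chromosome arm labels used for simulated panels (fly-style for the
#: first six, then generic).
CHROM_LABELS = ("2L", "2R", "3L", "3R", "X", "4")


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Knobs of the synthetic panel; defaults are the reference study design.

    197 lines, 5 vials x 5 flies per line, ~50% Wolbachia prevalence,
    mean lifespan 55.28 days with within-line SD 10.6 days and a target
    broad-sense heritability of 0.413.
    """

    n_lines: int = 197
    n_snps: int = 10_000
    n_chromosomes: int = 5
    maf_distribution: tuple = ("uniform", 0.02, 0.5)
    ld_block_length: int = 10_000          # bp
    mean_snp_spacing: int = 200            # bp
    n_founders: int = 64                   # haplotype pool size per block
    n_causal: int = 200
    effect_sd: float = 0.5                 # days per alt-allele copy
    effect_scaling: str = "fixed"          # "fixed" | "fill" (see simulate_panel)
    target_H2: float = 0.413
    mean_lifespan: float = 55.28           # days
    within_line_sd: float = 10.6           # days, fly-level SD
    wolbachia_prevalence: float = 0.5
    wolbachia_effect: float = 0.0          # days, added to infected lines
    n_structure_groups: int = 2
    structure_shift: float = 0.2           # allele-frequency delta between extreme groups
    structure_fraction: float = 0.15       # fraction of LD blocks carrying the shift
    vials_per_line: int = 5
    flies_per_vial: int = 5
    vial_sd: float = 0.0                   # optional vial effect, days
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_lines": self.n_lines,
            "n_snps": self.n_snps,
            "n_chromosomes": self.n_chromosomes,
            "ld_block_length": self.ld_block_length,
            "n_founders": self.n_founders,
            "n_structure_groups": self.n_structure_groups,
            "vials_per_line": self.vials_per_line,
            "flies_per_vial": self.flies_per_vial,
        }
        for name, value in counts.items():
            if value < 1:
                raise SimulationError(f"{name} must be >= 1 (got {value})")
        if self.n_causal < 0:
            raise SimulationError("n_causal must be >= 0")
        if self.n_causal > self.n_snps:
            raise SimulationError(
                f"n_causal ({self.n_causal}) exceeds n_snps ({self.n_snps})"
            )
        for name in ("wolbachia_prevalence", "structure_fraction", "missing_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise SimulationError(f"{name} must lie in [0, 1] (got {value})")
        if not 0.0 <= self.target_H2 < 1.0:
            raise SimulationError("target_H2 must lie in [0, 1)")
        if self.effect_scaling not in ("fixed", "fill"):
            raise SimulationError("effect_scaling must be 'fixed' or 'fill'")


@dataclass
class GroundTruth:
    """What the generator actually planted, for downstream validation."""

    causal_snp_ids: list[str]
    causal_effects: np.ndarray            # days per alt-allele copy
    realized_H2: float
    structure_assignment: pd.Series       # line_id -> group label
    line_genetic_values: pd.Series = field(repr=False, default=None)
    sigma2_line_env: float = 0.0
    sigma2_within: float = 0.0


# ----------------------------------------------------------------------
# genotype machinery
# ----------------------------------------------------------------------

def _draw_allele_freqs(rng: np.random.Generator, n: int, dist: tuple) -> np.ndarray:
    """Draw minor allele frequencies from the configured spectrum."""
    kind = dist[0]
    if kind == "uniform":
        lo, hi = dist[1], dist[2]
        if not 0 < lo <= hi <= 0.5:
            raise SimulationError("uniform MAF bounds must satisfy 0 < lo <= hi <= 0.5")
        return rng.uniform(lo, hi, n)
    if kind == "beta":
        a, b, lo, hi = dist[1], dist[2], dist[3], dist[4]
        return lo + (hi - lo) * rng.beta(a, b, n)
    raise SimulationError(f"unknown maf_distribution kind {kind!r}")


def _simulate_genotypes(cfg: SimulationConfig, rng: np.random.Generator):
    """Return (variants df, true dosage matrix, group assignment per line)."""
    m = cfg.n_snps
    per_chrom = np.full(cfg.n_chromosomes, m // cfg.n_chromosomes)
    per_chrom[: m % cfg.n_chromosomes] += 1
    labels = [
        CHROM_LABELS[i] if i < len(CHROM_LABELS) else f"chr{i + 1}"
        for i in range(cfg.n_chromosomes)
    ]

    chroms, positions = [], []
    for label, n_c in zip(labels, per_chrom):
        gaps = rng.integers(1, 2 * cfg.mean_snp_spacing, n_c)
        pos = np.cumsum(gaps)
        chroms.extend([label] * n_c)
        positions.append(pos)
    pos_all = np.concatenate(positions)
    chrom_all = np.asarray(chroms)

    maf = _draw_allele_freqs(rng, m, cfg.maf_distribution)
    # random minor-allele side: alt frequency q is maf or 1 - maf
    flip = rng.random(m) < 0.5
    q = np.where(flip, maf, 1.0 - maf)

    # block bookkeeping: blocks are per chromosome, indexed globally
    block_local = pos_all // cfg.ld_block_length
    chrom_code = pd.factorize(chrom_all)[0].astype(np.int64)
    combined = chrom_code * (block_local.max() + 1) + block_local
    _, block_key = np.unique(combined, return_inverse=True)
    n_blocks = block_key.max() + 1
    block_start = block_local * cfg.ld_block_length

    # group-differentiated frequencies on a subset of blocks (inversion mimic)
    G = cfg.n_structure_groups
    group_of_line = rng.permutation(np.arange(cfg.n_lines) % G)
    structured_block = rng.random(n_blocks) < cfg.structure_fraction
    snp_structured = structured_block[block_key]
    if G > 1:
        centered = np.linspace(-0.5, 0.5, G)
    else:
        centered = np.zeros(1)
    sign = np.where(rng.random(m) < 0.5, 1.0, -1.0)
    K = cfg.n_founders
    eps = 1.0 / (2 * K)
    q_group = np.empty((G, m))
    for g in range(G):
        delta = np.where(snp_structured, cfg.structure_shift * centered[g] * sign, 0.0)
        q_group[g] = np.clip(q + delta, eps, 1.0 - eps)
    arc_len = np.rint(K * q_group).astype(np.int32)          # (G, m)

    # arc offset drifts with bp position inside the block
    rel = (pos_all - block_start) / cfg.ld_block_length
    block_offset = rng.integers(0, K, n_blocks)
    offset = (block_offset[block_key] + np.floor(K * rel).astype(np.int64)) % K

    # each line copies one founder per block
    founder = rng.integers(0, K, size=(cfg.n_lines, n_blocks), dtype=np.int32)
    rotated = (founder[:, block_key] - offset[None, :]) % K   # (n_lines, m)
    dosage = 2.0 * (rotated < arc_len[group_of_line])

    variants = pd.DataFrame(
        {
            "variant_id": [f"snp{i:07d}" for i in range(m)],
            "chrom": chrom_all,
            "pos": pos_all,
            "ref": rng.choice(list("ACGT"), m),
            "alt": "N",
        }
    )
    # pick alt != ref
    bases = np.array(list("ACGT"))
    alt_idx = (np.searchsorted(bases, variants["ref"]) + rng.integers(1, 4, m)) % 4
    variants["alt"] = bases[alt_idx]
    return variants, dosage.astype(float), group_of_line


# ----------------------------------------------------------------------
# public operations
# ----------------------------------------------------------------------

def simulate_panel(config: SimulationConfig):
    """Simulate a full inbred panel.

    Returns
    -------
    (GenotypePanel, PhenotypeTable, GroundTruth)
        Genotypes carry missing calls at ``missing_rate``; phenotypes are
        fly-level lifespans with the configured replicate structure; the
        ground truth records causal SNPs, effects, realized heritability
        and the latent structure assignment.

    Raises
    ------
    SimulationError
        If the configuration is inconsistent, or the realized genetic
        variance already exceeds the among-line variance implied by
        ``target_H2`` (impossible heritability scaling).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    variants, true_dosage, group_of_line = _simulate_genotypes(cfg, rng)
    line_ids = [f"line_{i + 1:03d}" for i in range(cfg.n_lines)]

    # --- phenotypes ----------------------------------------------------
    sigma2_w = cfg.within_line_sd**2
    sigma2_between_target = sigma2_w * cfg.target_H2 / (1.0 - cfg.target_H2)

    if cfg.n_causal > 0:
        causal_idx = np.sort(rng.choice(cfg.n_snps, cfg.n_causal, replace=False))
        effects = rng.normal(0.0, cfg.effect_sd, cfg.n_causal)
        g = true_dosage[:, causal_idx] @ effects
        g = g - g.mean()
        if cfg.effect_scaling == "fill" and cfg.target_H2 > 0:
            # rescale effects so the causal SNPs carry the whole among-line
            # variance implied by target_H2 (purely additive-genetic trait)
            var_g0 = float(np.var(g, ddof=1))
            if var_g0 <= 0:
                raise SimulationError("cannot scale effects: zero genetic variance")
            scale = math.sqrt(sigma2_between_target / var_g0)
            effects = effects * scale
            g = g * scale
    else:
        causal_idx = np.array([], dtype=int)
        effects = np.array([])
        g = np.zeros(cfg.n_lines)

    var_g = float(np.var(g, ddof=1)) if cfg.n_lines > 1 else 0.0
    sigma2_line_env = sigma2_between_target - var_g
    if sigma2_line_env < -1e-9:
        raise SimulationError(
            f"impossible H2 scaling: realized genetic variance {var_g:.2f} days^2 "
            f"exceeds the among-line variance {sigma2_between_target:.2f} days^2 "
            f"implied by target_H2={cfg.target_H2}; reduce n_causal or effect_sd"
        )
    sigma2_line_env = max(sigma2_line_env, 0.0)

    wolbachia = (rng.random(cfg.n_lines) < cfg.wolbachia_prevalence).astype(int)
    line_env = rng.normal(0.0, math.sqrt(sigma2_line_env), cfg.n_lines)
    line_value = (
        cfg.mean_lifespan + g + line_env + cfg.wolbachia_effect * wolbachia
    )

    n_rep = cfg.vials_per_line * cfg.flies_per_vial
    vial_effects = rng.normal(0.0, cfg.vial_sd, (cfg.n_lines, cfg.vials_per_line))
    fly_noise = rng.normal(0.0, cfg.within_line_sd, (cfg.n_lines, n_rep))
    rows = []
    for i, lid in enumerate(line_ids):
        for v in range(cfg.vials_per_line):
            for f in range(cfg.flies_per_vial):
                k = v * cfg.flies_per_vial + f
                rows.append(
                    (
                        lid,
                        v + 1,
                        f + 1,
                        line_value[i] + vial_effects[i, v] + fly_noise[i, k],
                        wolbachia[i],
                    )
                )
    flies = pd.DataFrame(rows, columns=["line_id", "vial", "fly", "lifespan_days", "wolbachia"])
    # lifespans must be positive; at the default scale (55 +/- ~14 days) the
    # clamp is essentially never active
    flies["lifespan_days"] = flies["lifespan_days"].clip(lower=0.1)

    # --- missingness last: phenotype truth uses complete genotypes -----
    dosage = true_dosage.copy()
    if cfg.missing_rate > 0:
        dosage[rng.random(dosage.shape) < cfg.missing_rate] = np.nan

    panel = GenotypePanel(line_ids=line_ids, variants=variants, dosages=dosage)
    phenos = PhenotypeTable(flies=flies)

    var_between = float(np.var(g + line_env, ddof=1)) if cfg.n_lines > 1 else 0.0
    realized_H2 = var_between / (var_between + sigma2_w) if var_between + sigma2_w > 0 else 0.0
    truth = GroundTruth(
        causal_snp_ids=[variants["variant_id"].iloc[i] for i in causal_idx],
        causal_effects=effects,
        realized_H2=realized_H2,
        structure_assignment=pd.Series(group_of_line, index=line_ids, name="group"),
        line_genetic_values=pd.Series(g, index=line_ids, name="genetic_value"),
        sigma2_line_env=sigma2_line_env,
        sigma2_within=sigma2_w,
    )
    return panel, phenos, truth


def simulate_annotation(
    n_genes: int,
    genome_length: int,
    overlap_fraction: float = 0.0,
    seed: int = 0,
    chromosomes: dict[str, int] | None = None,
) -> GeneAnnotation:
    """Tile gene intervals over the genome with a controlled overlap rate.

    ``overlap_fraction`` is the expected fraction of genes that intersect
    at least one other gene; a gene is pulled back over its predecessor
    with probability 1 - sqrt(1 - overlap_fraction) so that, counting
    both partners of each overlap event, the expected intersecting
    fraction matches.

    ``chromosomes`` maps chromosome label to length; by default a single
    chromosome "2L" of ``genome_length`` bp is used, otherwise genes are
    apportioned proportionally to chromosome length.
    """
    if n_genes < 1:
        raise SimulationError("n_genes must be >= 1")
    if not 0.0 <= overlap_fraction < 1.0:
        raise SimulationError("overlap_fraction must lie in [0, 1)")
    if chromosomes is None:
        chromosomes = {"2L": int(genome_length)}
    total = sum(chromosomes.values())
    if total < 4 * n_genes:
        raise SimulationError(
            f"genome too short ({total} bp) to place {n_genes} genes"
        )
    rng = np.random.default_rng(seed)
    pull_prob = 1.0 - math.sqrt(1.0 - overlap_fraction)

    alloc = {}
    remaining = n_genes
    items = list(chromosomes.items())
    for i, (label, length) in enumerate(items):
        if i == len(items) - 1:
            alloc[label] = remaining
        else:
            k = int(round(n_genes * length / total))
            k = min(k, remaining)
            alloc[label] = k
            remaining -= k

    rows = []
    gene_no = 0
    for label, length in items:
        k = alloc[label]
        if k == 0:
            continue
        slot = length // k
        prev_end = 0
        for j in range(k):
            gene_len = int(rng.integers(max(2, slot // 2), max(3, int(slot * 0.8))))
            start = j * slot + int(rng.integers(1, max(2, slot - gene_len))) + 1
            if j > 0 and rng.random() < pull_prob and prev_end >= 2:
                # pull back so this gene overlaps the previous one
                start = max(1, prev_end - int(rng.integers(1, max(2, gene_len // 2))))
            start = max(start, 1)
            end = start + gene_len - 1
            gene_no += 1
            rows.append((f"gene{gene_no:05d}", label, start, end))
            prev_end = end
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    return GeneAnnotation(genes=genes)


def simulate_gene_sets(
    annotation: GeneAnnotation,
    set_sizes: list[int],
    enriched_genes: list[str] | None = None,
    enriched_size: int | None = None,
    seed: int = 0,
) -> GeneSetCollection:
    """Random gene-set memberships, optionally with one planted set.

    The planted set (id ``"planted"``) preferentially contains
    ``enriched_genes`` (e.g. the genes harbouring causal SNPs), padded
    with random genes up to ``enriched_size``.
    """
    gene_ids = list(annotation.gene_ids)
    n = len(gene_ids)
    for size in set_sizes:
        if size > n:
            raise SimulationError(f"set size {size} exceeds number of genes {n}")
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    for i, size in enumerate(set_sizes):
        members = rng.choice(n, size=size, replace=False)
        sets[f"set{i + 1:04d}"] = [gene_ids[j] for j in sorted(members)]
    if enriched_genes is not None:
        size = enriched_size if enriched_size is not None else len(enriched_genes)
        core = [g for g in dict.fromkeys(enriched_genes) if g in set(gene_ids)][:size]
        pool = [g for g in gene_ids if g not in set(core)]
        pad = size - len(core)
        if pad > 0:
            extra = rng.choice(len(pool), size=pad, replace=False)
            core = core + [pool[j] for j in sorted(extra)]
        sets["planted"] = core
    return GeneSetCollection(sets=sets)
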