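# Methods

This note documents the statistical models behind `linegwas`, the
parameter choices that matter, what the synthetic panel generator does
and does not emulate, and the package's known limitations.

## Study design and the unit of analysis

The package targets panels of fully inbred lines (DGRP-style): each
line is near-homozygous, genotyped once, and phenotyped on replicate
individuals — here lifespan in days measured on N = 25 virgin females
per line (five flies in each of five vials).  Association analyses use
the **line mean** as the response; the fly-level replicates are used
only for variance-component estimation.  Genotypes are coded as alt
allele dosage ∈ {0, 2} (diploid-homozygote convention), so regression
coefficients are on the same days-per-allele-copy scale as an outbred
diploid GWAS and the difference between homozygous genotype classes is
2β.  Missing calls are an explicit NaN sentinel, never imputed at I/O
or QC time.

## Quality control

Filters are applied in the order call rate → MAF → per-line
missingness, with inclusive thresholds (a call rate of exactly 0.90
passes at a 0.90 cut-off).  The MAF denominator is the non-missing
lines only, each contributing two allele copies; MAF is folded to
≤ 0.5.  A variant failing more than one rule is counted against the
first rule applied, so the QC report reconciles exactly with the panel
dimension change.  Variant statistics are not recomputed after line
removal; with the default thresholds (0.9 / 0.02 / 0.2) this matters
only marginally and keeps the bookkeeping unambiguous.

## Covariates

Population structure (e.g. segregating inversion karyotypes) and
*Wolbachia* infection are handled as regression covariates: the binary
infection status plus the first four principal components of the
normalised genotype matrix.  Normalisation is the population-genetics
standard: centre each variant by its mean dosage and scale by
√(p̂(1−p̂)) with the shrunk frequency p̂ = (1 + Σg)/(2 + 2n) (g the
per-line dosage, n the non-missing count), which keeps rare variants
from blowing up the scale.  Missing entries are mean-imputed (zero
after centring) before the SVD.  PC signs are fixed by making the
largest-magnitude score element positive, and scores are standardised
to unit variance, so the decomposition is fully deterministic.
Constant covariate columns (e.g. an all-uninfected panel) are dropped
with a warning rather than erroring.

## Single-SNP association

For each variant: OLS of line-mean lifespan on
[intercept, dosage, covariates] over the lines with a non-missing call
at that variant; two-sided t-test on the dosage coefficient with
n_used − (k + 2) residual degrees of freedom.  Lines with a missing
dosage are dropped per variant, never imputed.  The computation is
batched across variants by treating missingness as 0/1 weights in the
normal equations and solving per variant via the Frisch–Waugh
decomposition — this is exact OLS (the test suite asserts agreement
with a reference OLS implementation to 1e-10), not an approximation.
Degenerate variants (constant dosage among used lines, collinearity
with a covariate, n_used ≤ k + 2) yield NaN results, flagged by
absence.

## Power

For the additive dosage test the noncentrality is
λ = (Δ/2)² · 4·maf·(1−maf) · n / σ², where Δ is the mean difference
between homozygote classes (days), 4·maf·(1−maf) the dosage variance
in a homozygous panel, and σ the residual SD of line means.
`power_additive` evaluates, by default, the exact noncentral-F tail of
the regression t-test actually performed (so power(Δ=0) = α exactly,
and the Monte-Carlo rejection rate of the simulated test is matched to
better than 0.02 even at α ≈ 2×10⁻⁸, where the normal approximation is
off by ~0.05).  The familiar large-sample form
Φ(√λ − z_{1−α/2}) + Φ(−√λ − z_{1−α/2}) used by conventional GWAS power
calculators is available via `method="normal"`; the acceptance script
reports that form, with σ taken as the phenotypic SD of simulated line
means, because it is the convention of the power calculators of the
study's era.  The residual-SD assumption is exposed as a parameter
since no single value is canonical.

## Gene-based test

SNPs are assigned to genes by position containment in 1-based
inclusive intervals, optionally extended ±5 kb to capture regulatory
flanks; SNPs in overlapping genes count for every gene, and genes with
fewer than two assigned SNPs are excluded (but reported).  Per gene,
T = −2 Σ ln pᵢ over its SNP p-values.  The null distribution is
empirical: for a gene with N SNPs, null statistics are Fisher
combinations of N p-values resampled i.i.d., with replacement, from
the genome-wide pool of all tested SNP p-values; the empirical p is
the plain proportion of null T ≥ T_obs (it may be exactly 0; an
(r+1)/(B+1) correction is available but off by default to keep the
plain-proportion semantics).  Top-ranked genes are re-evaluated with a
larger permutation count (default: top 40 at 10⁶ draws, configurable)
for resolution in the tail.

**Calibration caveat.**  Pooled i.i.d. resampling ignores LD among the
SNPs inside a gene.  Under strong intra-gene LD the effective number
of independent p-values is smaller than N and the pooled null is
anti-conservative for LD-heavy genes.  This is an intrinsic property
of the pooled-resampling definition, not an implementation artifact;
the calibration checks in the test suite therefore use a
near-independent-SNP configuration of the generator (one SNP per LD
block), where empirical gene p-values are verifiably uniform and the
N = 5 empirical tail matches the χ²₁₀ closed form to 0.01.  An
experimental `mode="window"` resamples contiguous SNP windows instead,
preserving local correlation in the null.

Gene ranking for downstream enrichment is ascending empirical p with
deterministic tie-breaks (descending T, then gene id).

## Polygenic scores

Each of 100 repeats splits the lines at random into discovery/target
halves (⌈n/2⌉ vs ⌊n/2⌋; 99 vs 98 at 197 lines).  The discovery half
gets the covariate-adjusted GWAS; its results are LD-clumped greedily
(keep the most associated remaining SNP, drop neighbours within
±250 kb with r² > 0.25 to it, pairwise-complete r² over shared
non-missing lines).  For each threshold in
{1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.2, 0.1, 0.05, 0.01, 0.005, 0.001,
0.0005, 0.0001} the clumped SNPs with p ≤ t are scored on the target
half — per line, the mean of dosage × β over non-missing scored SNPs
(score-average convention) — and R² is the squared Pearson correlation
between score and target line means (identical to the R² of the
single-regressor OLS; covariates enter the discovery GWAS only).
Within a repeat the SNP set at a tighter threshold is a subset of the
looser one, so n_snps is monotone along the ladder.  The permuted-
phenotype null repeats the identical procedure after shuffling line
means once per repeat, which quantifies the overfitting floor
(E[R²] ≈ 1/(n_target − 1) plus structure effects — strictly positive).
Observed and null R² distributions are compared per threshold with a
one-sided Welch t-test; note the repeats share one phenotype
realisation, so these p-values measure separation of the two arms on
this panel, not a frequentist error rate over panels.

## Heritability

Broad-sense H² = σ²_line/(σ²_line + σ²_within) at the individual-fly
level, by one-way random-effects ANOVA method of moments:
σ²_within = MS_within; σ²_line = (MS_between − MS_within)/n₀ with
n₀ = (N − Σn_i²/N)/(a − 1) for unbalanced designs.  Negative moment
estimates are truncated to zero and flagged.  Vial nesting is
collapsed into the within-line variance (a vial variance component can
be simulated, in which case it folds into σ²_within for estimation).
Method of moments is used for transparency; with 197 lines × 25 flies
the estimator recovers a 0.413 target to within ±0.01 on average over
150–200 replicates.

## Enrichment

The top-k test is the exact hypergeometric upper tail
P(X ≥ k) with population N = ranked-list length, successes
K = set members in the list, draws n = top_k (log-gamma evaluation,
matched to brute-force enumeration exactly for N ≤ 30 in the tests).
The whole-list test is the Wilcoxon rank-sum of member ranks vs
non-member ranks, one-sided toward smaller (better) ranks by default;
the exact permutation distribution is used for small universes and the
tie/continuity-corrected normal approximation otherwise.  The universe
is the ranked list the caller provides — canonically the genes that
actually received a gene-based test (≥ 2 SNPs), not all annotated
genes.  Multiple testing across categories uses Bonferroni.

The self-contained consistency check on the top-100 pathway
enrichment deserves a note: the three tail probabilities reported for
the pathway (k ≥ 5 of N = 15,145; k ≥ 4 after excluding the best gene,
i.e. category size K−1; k ≥ 3 of N = 14,146) are mutually compatible
under a single pathway size, and a least-squares search over integer K
recovers K = 38, at which the three recomputed tails agree with the
quoted values to ~1% / ~9% / ~0.2% (the middle value is quoted to two
significant figures).

## The synthetic panel generator

What it emulates, and how:

* **Homozygous genotypes with LD** — a founder-arc haplotype mosaic.
  Each chromosome is cut into blocks (default 10 kb); each block has a
  circular pool of K = 64 founder haplotypes; each line copies one
  founder per block.  At a SNP with alt frequency q the alt allele
  occupies an arc of round(K·q) consecutive founders whose offset
  drifts with bp position, so nearby SNPs are strongly correlated
  (median adjacent-SNP r² > 0.3 at defaults) and blocks are
  independent.  Because lines draw founders uniformly, the marginal
  alt count is Binomial(n_lines, round(Kq)/K) — the realised MAF
  spectrum tracks the requested distribution (uniform on [0.02, 0.5]
  by default) with KS distance < 0.06 at 10⁴ SNPs.
* **Inversion-karyotype-like structure** — a configurable fraction
  (default 15%) of blocks carry group-differentiated allele
  frequencies (default two groups, ±0.1 shifts).  At default settings
  PC1 of the normalised genotype matrix separates the groups with
  point-biserial |r| > 0.9.
* **Phenotypes** — line value = grand mean (55.28 d) + additive
  genetic value Σβ·dosage + Gaussian line-environment effect +
  optional *Wolbachia* effect; flies add i.i.d. Gaussian noise
  (SD 10.6 d) and an optional vial effect (off by default, since line
  means are the analysis unit).  The line-environment variance is set
  so the among-line variance fraction equals the target H² (0.413 by
  default) exactly in expectation; if the realised genetic variance
  already exceeds the implied among-line variance the generator
  refuses (impossible-H² error).  With `effect_scaling="fill"` the
  drawn effects are rescaled so the causal SNPs carry the *entire*
  among-line variance — the right construct for planted-signal
  polygenic-score experiments, where "planted H²" should mean
  heritable variance attributable to the planted SNPs.  The default
  (`"fixed"`) keeps the drawn effect sizes and tops up with
  line-environment variance, modelling a trait whose broad-sense
  heritability exceeds its additive SNP component.
* **Replicate structure** — 5 vials × 5 flies per line; *Wolbachia*
  drawn Bernoulli(0.5); ~2% missing genotype calls.

All randomness flows from a single integer seed through one
`numpy` generator (spawned per repeat where stages are repeated), so
identical configurations are byte-identical across runs.

What it does **not** emulate: realistic demography or recombination
maps, allele-frequency/effect-size coupling, indels and multi-allelic
sites, X-chromosome dosage, genotype-calling error, block-structured
missingness, epistasis, or GxE.  Passing tests on this generator
demonstrate the statistical machinery is correct and calibrated under
its assumptions — not that real-panel results are unbiased under, say,
strong intra-gene LD (see the gene-based caveat above).

## Problem sizes

Simulations in the test suite and acceptance script are sized for a
single CPU: panels of 1,500–20,000 SNPs × 197 lines, 100
cross-validation repeats per polygenic arm, 2×10³–2×10⁵ permutations
per gene, 150–200 replicate simulations for heritability recovery.
These sizes give Monte-Carlo standard errors comfortably below each
assertion's tolerance; all conclusions are insensitive to scaling the
panel up.

## Numerical choices and edge cases

* p-values are clamped to the smallest positive float before logs;
  Fisher's T of an exact zero warns.
* Pairwise r² with a constant vector is defined as 0 (flagged path).
* A polygenic threshold retaining zero SNPs records NaN R² for that
  cell; a line missing every scored SNP gets a NaN score and is
  dropped from the R² regression.
* Clumping ties on p are broken by variant order (stable sort), making
  selection deterministic.
* Heterozygous VCF calls in an inbred panel default to missing with a
  warning; a strict mode errors instead.
* BED intervals are converted to the internal 1-based inclusive
  convention at the boundary; the conversion is an exact bijection.

## Known limitations

* No mixed-model/kinship correction: PCs absorb the panel's major
  structure, as appropriate for inversion-driven stratification, but
  fine-scale relatedness is not modelled.
* The pooled permutation null for gene tests is LD-naive (discussed
  above); the window-resampling mode is provided but experimental.
* The Welch comparison between observed and permuted R² profiles
  inherits the dependence among repeats of a single panel.
* Narrow-sense heritability via kinship and eQTL-style analyses are
  out of scope.
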