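"""Polygenic-score cross-validation with LD clumping and a permuted null.

Each repeat splits the lines into discovery/target halves (ceil/floor,
e.g. 99 vs 98 at 197 lines), runs the covariate-adjusted GWAS on the
discovery half, greedily clumps the discovery results (keep the most
associated SNP, drop neighbours within the bp window correlated above
r2_max), then for each p-value threshold scores the target lines with
the discovery betas and records R^2 — the squared Pearson correlation
from regressing target line means on the score.  The permuted-phenotype
arm shuffles line means once per repeat before splitting, estimating
the overfitting floor when genotype and phenotype are unrelated.

Scores follow the PLINK score-average convention: per line, the mean of
dosage x beta over the non-missing scored SNPs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .datatypes import GenotypePanel, PhenotypeTable
from .gwas import _batched_ols

#: The canonical ladder of selection thresholds.
DEFAULT_THRESHOLDS = (
    1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.2, 0.1, 0.05,
    0.01, 0.005, 0.001, 0.0005, 0.0001,
)


@dataclass
class ClumpParams:
    r2_max: float = 0.25
    window: int = 250_000  # bp

    def __post_init__(self) -> None:
        if not 0.0 < self.r2_max <= 1.0:
            raise ValueError("r2_max must lie in (0, 1]")
        if self.window <= 0:
            raise ValueError("window must be positive")


def ld_r2(panel: GenotypePanel, v1: str, v2: str) -> float:
    """Squared Pearson correlation of two dosage columns over lines
    non-missing at both; 0 (flagged via NaN-free return) if either is
    constant on the shared lines."""
    ids = panel.variant_ids
    j1, j2 = ids.get_loc(v1), ids.get_loc(v2)
    x, y = panel.dosages[:, j1], panel.dosages[:, j2]
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _pairwise_r2_one_vs_many(
    D0: np.ndarray, W: np.ndarray, j: int, cols: np.ndarray
) -> np.ndarray:
    """Pairwise-complete r^2 of column j against each of ``cols``.

    ``D0`` is the dosage matrix with missing entries zeroed and ``W``
    the 0/1 presence mask; all masked cross-sums reduce to one small
    matrix product.
    """
    A = np.stack([W[:, j], D0[:, j], D0[:, j] ** 2])          # (3, n)
    S = A @ np.concatenate([W[:, cols], D0[:, cols], D0[:, cols] ** 2], axis=1)
    c = cols.size
    n = S[0, :c]
    sy = S[0, c:2 * c]
    syy = S[0, 2 * c:]
    sx = S[1, :c]
    sxy = S[1, c:2 * c]
    sxx = S[2, :c]
    with np.errstate(invalid="ignore", divide="ignore"):
        num = n * sxy - sx * sy
        den = (n * sxx - sx * sx) * (n * syy - sy * sy)
        r2 = np.where(den > 0, num * num / np.where(den > 0, den, 1.0), 0.0)
    return r2


def _greedy_clump_indices(
    D: np.ndarray,
    chrom_codes: np.ndarray,
    pos: np.ndarray,
    p: np.ndarray,
    r2_max: float,
    window: int,
) -> np.ndarray:
    """Greedy clumping on raw arrays; returns retained column indices in
    ascending-p selection order.  NaN p-values are ignored."""
    W = (~np.isnan(D)).astype(float)
    D0 = np.where(W > 0, np.nan_to_num(D), 0.0)
    valid = np.flatnonzero(~np.isnan(p))
    order = valid[np.argsort(p[valid], kind="mergesort")]
    alive = np.zeros(D.shape[1], dtype=bool)
    alive[valid] = True
    kept: list[int] = []
    for j in order:
        if not alive[j]:
            continue
        kept.append(j)
        alive[j] = False
        same = np.flatnonzero(
            alive
            & (chrom_codes == chrom_codes[j])
            & (np.abs(pos - pos[j]) <= window)
        )
        if same.size:
            r2 = _pairwise_r2_one_vs_many(D0, W, j, same)
            alive[same[r2 > r2_max]] = False
    return np.asarray(kept, dtype=int)


def clump(
    results: pd.DataFrame,
    panel: GenotypePanel,
    params: ClumpParams = ClumpParams(),
) -> list[str]:
    """Greedy LD clumping on an association table.

    Repeatedly takes the remaining SNP with the smallest p-value as an
    index SNP and removes all SNPs on the same chromosome within
    ``params.window`` bp whose r^2 with the index exceeds
    ``params.r2_max``.  Returns the retained variant ids in selection
    order.  SNPs with missing p-values are ignored.
    """
    ids = panel.variant_ids
    p = pd.Series(np.nan, index=ids)
    p.loc[results["variant_id"]] = results["p"].to_numpy()
    chrom_codes = pd.factorize(panel.variants["chrom"])[0]
    pos = panel.variants["pos"].to_numpy()
    kept = _greedy_clump_indices(
        panel.dosages, chrom_codes, pos, p.to_numpy(), params.r2_max, params.window
    )
    return [ids[j] for j in kept]


def polygenic_score(
    panel: GenotypePanel, weights: pd.Series
) -> pd.Series:
    """Score-average per line: mean over non-missing selected variants of
    dosage x beta.  Lines missing every selected variant get NaN."""
    ids = panel.variant_ids
    cols = np.array([ids.get_loc(v) for v in weights.index])
    D = panel.dosages[:, cols]
    W = ~np.isnan(D)
    contrib = np.where(W, D, 0.0) * weights.to_numpy()
    n = W.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(n > 0, contrib.sum(axis=1) / np.maximum(n, 1), np.nan)
    return pd.Series(score, index=pd.Index(panel.line_ids, name="line_id"), name="score")


def _r2_score_vs_phenotype(score: np.ndarray, y: np.ndarray) -> float:
    """Variance explained by the score: squared Pearson correlation,
    identical to the R^2 of the single-regressor OLS of y on score."""
    keep = ~np.isnan(score)
    s, yy = score[keep], y[keep]
    if len(s) < 3 or s.std() == 0 or yy.std() == 0:
        return np.nan
    r = np.corrcoef(s, yy)[0, 1]
    return float(r * r)


def _cv_engine(
    panel: GenotypePanel,
    y: np.ndarray,
    C: np.ndarray | None,
    params: ClumpParams,
    thresholds,
    n_repeats: int,
    seed: int,
    permute: bool,
) -> pd.DataFrame:
    n = panel.n_lines
    if n < 20:
        raise ValueError("need at least 20 lines for cross-validation")
    n_disc = math.ceil(n / 2)
    chrom_codes = pd.factorize(panel.variants["chrom"])[0]
    pos = panel.variants["pos"].to_numpy()
    D = panel.dosages

    rows = []
    root = np.random.SeedSequence(seed)
    for rep, ss in enumerate(root.spawn(n_repeats)):
        rng = np.random.default_rng(ss)
        y_rep = rng.permutation(y) if permute else y
        perm = rng.permutation(n)
        disc, targ = perm[:n_disc], perm[n_disc:]

        Dd = D[disc]
        Cd = None if C is None else C[disc]
        res = _batched_ols(Dd, y_rep[disc], Cd)
        p = res["p"].to_numpy()
        beta = res["beta"].to_numpy()
        kept = _greedy_clump_indices(
            Dd, chrom_codes, pos, p, params.r2_max, params.window
        )
        kept_p = p[kept]

        Dt = D[targ][:, kept]
        Wt = ~np.isnan(Dt)
        contrib_all = np.where(Wt, Dt, 0.0) * beta[kept]
        for t in thresholds:
            sel = kept_p <= t
            n_sel = int(sel.sum())
            if n_sel == 0:
                rows.append((rep, t, 0, np.nan))
                continue
            m = Wt[:, sel].sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                score = np.where(
                    m > 0, contrib_all[:, sel].sum(axis=1) / np.maximum(m, 1), np.nan
                )
            rows.append((rep, t, n_sel, _r2_score_vs_phenotype(score, y_rep[targ])))
    return pd.DataFrame(rows, columns=["repeat", "threshold", "n_snps", "r2"])


def cross_validated_r2(
    panel: GenotypePanel,
    phenotypes: PhenotypeTable,
    covariates: pd.DataFrame | None = None,
    params: ClumpParams = ClumpParams(),
    thresholds=DEFAULT_THRESHOLDS,
    n_repeats: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed polygenic-score profile (one row per repeat x threshold)."""
    y = phenotypes.line_means().reindex(panel.line_ids).to_numpy()
    C = None if covariates is None else covariates.loc[panel.line_ids].to_numpy(float)
    return _cv_engine(panel, y, C, params, thresholds, n_repeats, seed, permute=False)


def permuted_null_profile(
    panel: GenotypePanel,
    phenotypes: PhenotypeTable,
    covariates: pd.DataFrame | None = None,
    params: ClumpParams = ClumpParams(),
    thresholds=DEFAULT_THRESHOLDS,
    n_perm: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Null profile: line means shuffled once per repeat before splitting."""
    y = phenotypes.line_means().reindex(panel.line_ids).to_numpy()
    C = None if covariates is None else covariates.loc[panel.line_ids].to_numpy(float)
    return _cv_engine(panel, y, C, params, thresholds, n_perm, seed, permute=True)


def summarize_profiles(
    observed: pd.DataFrame, permuted: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Mean +/- SD of R^2 per threshold, plus a per-threshold Welch t-test
    (one-sided, observed > permuted) when a null profile is given."""
    summary = (
        observed.groupby("threshold")
        .agg(mean_r2=("r2", "mean"), sd_r2=("r2", "std"), mean_n_snps=("n_snps", "mean"))
        .reset_index()
        .sort_values("threshold", ascending=False)
        .reset_index(drop=True)
    )
    if permuted is not None:
        null_summary = (
            permuted.groupby("threshold")
            .agg(null_mean_r2=("r2", "mean"), null_sd_r2=("r2", "std"))
            .reset_index()
        )
        summary = summary.merge(null_summary, on="threshold", how="left")
        pvals = []
        for t in summary["threshold"]:
            a = observed.loc[observed["threshold"] == t, "r2"].dropna()
            b = permuted.loc[permuted["threshold"] == t, "r2"].dropna()
            if len(a) < 2 or len(b) < 2:
                pvals.append(np.nan)
            else:
                pvals.append(
                    stats.ttest_ind(a, b, equal_var=False, alternative="greater").pvalue
                )
        summary["welch_p"] = pvals
    return summary


class PolygenicScoreCV(BaseEstimator):
    """Estimator wrapper around the cross-validation engine.

    ``fit(panel, phenotypes, covariates)`` computes ``profile_`` and,
    when ``with_null`` is set, ``null_profile_`` and ``summary_``.
    """

    def __init__(
        self,
        r2_max: float = 0.25,
        window: int = 250_000,
        thresholds=DEFAULT_THRESHOLDS,
        n_repeats: int = 100,
        with_null: bool = True,
        seed: int = 0,
    ):
        self.r2_max = r2_max
        self.window = window
        self.thresholds = thresholds
        self.n_repeats = n_repeats
        self.with_null = with_null
        self.seed = seed

    def fit(self, panel: GenotypePanel, phenotypes: PhenotypeTable, covariates=None):
        params = ClumpParams(r2_max=self.r2_max, window=self.window)
        self.profile_ = cross_validated_r2(
            panel, phenotypes, covariates, params, self.thresholds,
            self.n_repeats, self.seed,
        )
        self.null_profile_ = None
        if self.with_null:
            self.null_profile_ = permuted_null_profile(
                panel, phenotypes, covariates, params, self.thresholds,
                self.n_repeats, self.seed + 1,
            )
        self.summary_ = summarize_profiles(self.profile_, self.null_profile_)
        return self
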