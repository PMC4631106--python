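"""Single-variant additive association on line means.

For every variant, ordinary least squares of the per-line mean lifespan
on [intercept, dosage, covariates] over the lines with a non-missing
genotype at that variant; a two-sided t-test on the dosage coefficient
with n_used - (k + 2) residual degrees of freedom.  Dosage is coded
0/2, so beta is in days per allele copy and the difference between
homozygous genotype classes is 2*beta.

The OLS is batched across variants (exact, not approximate): missing
genotypes are handled as 0/1 weights in the normal equations, which are
assembled with dense matrix products and solved per variant with the
Frisch-Waugh decomposition.  Agreement with a reference OLS
implementation is asserted in the test suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator

from .covariates import build_covariates  # noqa: F401  (re-export convenience)
from .datatypes import GenotypePanel, PhenotypeTable


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 1) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / n_tests


def _batched_ols(D: np.ndarray, y: np.ndarray, C: np.ndarray | None):
    """Exact per-variant OLS of y on [1, d, C] with per-variant missingness.

    Parameters
    ----------
    D : (n, m) dosage matrix, NaN = missing.
    y : (n,) response.
    C : (n, k) covariates or None.

    Returns
    -------
    DataFrame with beta, se, t, p, n_used, df; NaN where the dosage is
    constant/collinear among used lines or too few lines remain.
    """
    n, m = D.shape
    y = np.asarray(y, dtype=float)
    Z = np.ones((n, 1)) if C is None else np.column_stack([np.ones(n), C])
    q = Z.shape[1]

    W = (~np.isnan(D)).astype(float)
    D0 = np.nan_to_num(D, nan=0.0)

    n_used = W.sum(axis=0)
    # normal-equation pieces, all (m,)-shaped or (m, q)-shaped
    ZWZ = np.einsum("ia,ib,ij->jab", Z, Z, W, optimize=True)        # (m, q, q)
    ZWd = (Z.T @ (D0 * W)).T                                        # (m, q)
    ZWy = (Z.T @ (W * y[:, None])).T                                # (m, q)
    dWd = (D0 * D0).sum(axis=0)
    dWy = (D0 * y[:, None]).sum(axis=0)
    yWy = (y * y) @ W

    p_full = q + 1
    ok = n_used >= p_full + 1  # need at least 1 residual df
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    tstat = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    dof = np.where(ok, n_used - p_full, np.nan)

    idx = np.flatnonzero(ok)
    if idx.size:
        A = ZWZ[idx]
        try:
            gamma = np.linalg.solve(A, ZWy[idx][..., None])[..., 0]
            alpha_ = np.linalg.solve(A, ZWd[idx][..., None])[..., 0]
        except np.linalg.LinAlgError:  # singular covariate block for some variant
            gamma = np.full((idx.size, q), np.nan)
            alpha_ = np.full((idx.size, q), np.nan)
            for r, j in enumerate(idx):
                try:
                    gamma[r] = np.linalg.solve(ZWZ[j], ZWy[j])
                    alpha_[r] = np.linalg.solve(ZWZ[j], ZWd[j])
                except np.linalg.LinAlgError:
                    pass
        Sxx = dWd[idx] - np.einsum("ij,ij->i", ZWd[idx], alpha_)
        Sxy = dWy[idx] - np.einsum("ij,ij->i", ZWd[idx], gamma)
        scale = np.maximum(dWd[idx], 1.0)
        identifiable = Sxx > 1e-10 * scale
        with np.errstate(invalid="ignore", divide="ignore"):
            b = np.where(identifiable, Sxy / np.where(identifiable, Sxx, 1.0), np.nan)
            rss = yWy[idx] - np.einsum("ij,ij->i", ZWy[idx], gamma) - b * Sxy
            rss = np.maximum(rss, 0.0)
            df_i = n_used[idx] - p_full
            sigma2 = rss / df_i
            s = np.sqrt(sigma2 / np.where(identifiable, Sxx, np.nan))
            t = b / s
        beta[idx], se[idx], tstat[idx] = b, s, t
        with np.errstate(invalid="ignore"):
            pval[idx] = 2.0 * stats.t.sf(np.abs(t), df_i)
    # p-values live in (0, 1]: clamp exact zeros from extreme t
    tiny = np.finfo(float).tiny
    pval = np.where(np.isfinite(pval), np.maximum(pval, tiny), pval)
    return pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "t": tstat,
            "p": pval,
            "n_used": n_used.astype(int),
            "df": dof,
        }
    )


class AdditiveGWAS(BaseEstimator):
    """Per-variant additive linear model, estimator-style.

    ``fit(X, y, covariates=...)`` accepts the dosage matrix (NaN for
    missing calls), per-line response, and an optional covariate matrix;
    fitted results land in ``results_``.
    """

    def fit(self, X, y, covariates=None):
        if isinstance(X, GenotypePanel):
            X = X.dosages
        C = None if covariates is None else np.asarray(covariates, dtype=float)
        self.results_ = _batched_ols(np.asarray(X, dtype=float), y, C)
        return self


def run_gwas(
    panel: GenotypePanel,
    phenotypes: PhenotypeTable,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Associate every variant with line-mean lifespan.

    Returns the variant table joined with beta (days/allele), se, t, p,
    and n_used.  Lines are aligned by id; a covariate table (from
    :func:`linegwas.covariates.build_covariates`) is subset to the panel
    lines in panel order.
    """
    y = phenotypes.line_means().reindex(panel.line_ids)
    if y.isna().any():
        missing = [lid for lid in panel.line_ids if lid not in phenotypes.line_means().index]
        raise ValueError(f"lines without phenotypes: {missing[:10]}")
    C = None
    if covariates is not None:
        if not set(panel.line_ids) <= set(covariates.index):
            missing = sorted(set(panel.line_ids) - set(covariates.index))
            raise ValueError(f"lines without covariates: {missing[:10]}")
        C = covariates.loc[panel.line_ids].to_numpy(dtype=float)
    est = AdditiveGWAS().fit(panel.dosages, y.to_numpy(), covariates=C)
    out = pd.concat([panel.variants.reset_index(drop=True), est.results_], axis=1)
    return out


def power_additive(
    n_lines: int,
    maf: float,
    effect_diff: float,
    residual_sd: float,
    alpha: float,
    n_covariates: int = 0,
    method: str = "exact",
) -> float:
    """Power of the two-sided additive dosage test.

    Noncentrality lambda = (effect_diff/2)^2 * Var(dosage) * n / sigma^2
    with Var(dosage) = 4*maf*(1-maf) for homozygous lines
    (``effect_diff`` is the mean difference between the two homozygous
    genotype classes, in days).

    ``method="exact"`` evaluates the noncentral-F tail of the actual
    t-test with n - 2 - n_covariates residual df (power(effect=0) equals
    alpha exactly).  ``method="normal"`` uses the large-sample normal
    approximation Phi(sqrt(lambda) - z_{1-a/2}) + Phi(-sqrt(lambda) - z_{1-a/2}),
    the form used by conventional GWAS power calculators.
    """
    if not 0 < maf <= 0.5:
        raise ValueError("maf must lie in (0, 0.5]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if residual_sd <= 0:
        raise ValueError("residual_sd must be positive")
    lam = (effect_diff / 2.0) ** 2 * 4.0 * maf * (1.0 - maf) * n_lines / residual_sd**2
    if method == "normal":
        z = stats.norm.isf(alpha / 2.0)
        return float(stats.norm.cdf(np.sqrt(lam) - z) + stats.norm.cdf(-np.sqrt(lam) - z))
    if method == "exact":
        df = n_lines - 2 - n_covariates
        if df < 1:
            raise ValueError("not enough lines for the requested model")
        fcrit = stats.f.isf(alpha, 1, df)
        return float(1.0 - special.ncfdtr(1, df, lam, fcrit))
    raise ValueError(f"unknown method {method!r}")
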