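"""Covariate construction: genotype principal components + Wolbachia status.

The genotype matrix is normalised variant-wise the way population-
structure PCA normalises it: centre by the mean dosage and divide by
sqrt(p*(1-p)) with a shrunk allele-frequency estimate
p = (1 + sum(dosage)) / (2 + 2*n_nonmissing), which avoids zero scale at
rare alleles.  Missing entries are mean-imputed (i.e. set to zero after
centring) before the singular value decomposition.  Principal-component
signs are fixed by making the largest-magnitude score element positive,
so results are fully deterministic.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import GenotypePanel, PhenotypeTable


def _normalize_dosages(X: np.ndarray) -> np.ndarray:
    """Centre/scale a lines x variants dosage matrix, mean-imputing NaNs."""
    X = np.asarray(X, dtype=float)
    present = ~np.isnan(X)
    n_called = present.sum(axis=0)
    col_sum = np.nansum(X, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n_called > 0, col_sum / np.maximum(n_called, 1), 0.0)
        p_shrunk = (1.0 + col_sum) / (2.0 + 2.0 * np.maximum(n_called, 1))
    scale = np.sqrt(p_shrunk * (1.0 - p_shrunk))
    scale = np.where(scale > 0, scale, 1.0)
    Z = (X - mean) / scale
    Z[~present] = 0.0
    return Z


class GenotypePCA(BaseEstimator):
    """Principal components of the normalised genotype matrix.

    Parameters
    ----------
    n_components : int, default 4
        Number of leading components to keep.  If the matrix rank is
        smaller, the available components are returned with a warning.

    Attributes
    ----------
    scores_ : ndarray of shape (n_lines, k)
        Unit-variance PC scores, sign-fixed.
    explained_variance_ratio_ : ndarray of shape (k,)
        Fraction of total normalised variance per component.
    components_ : ndarray of shape (k, n_variants)
        Variant loadings (right singular vectors).
    """

    def __init__(self, n_components: int = 4):
        self.n_components = n_components

    def fit(self, X, y=None):
        if isinstance(X, GenotypePanel):
            X = X.dosages
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if self.n_components >= n:
            raise ValueError(
                f"n_components ({self.n_components}) must be < n_lines ({n})"
            )
        Z = _normalize_dosages(X)
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        tol = s.max() * max(Z.shape) * np.finfo(float).eps if s.size else 0.0
        rank = int((s > tol).sum())
        k = min(self.n_components, rank)
        if k < self.n_components:
            warnings.warn(
                f"requested {self.n_components} components but matrix rank is "
                f"{rank}; returning {k}"
            )
        scores = U[:, :k] * s[:k]
        # deterministic sign: largest-magnitude score element positive
        for j in range(k):
            i = np.argmax(np.abs(scores[:, j]))
            if scores[i, j] < 0:
                scores[:, j] = -scores[:, j]
                Vt[j] = -Vt[j]
        sd = scores.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        self.scores_ = scores / sd
        self.singular_values_ = s[:k]
        self.explained_variance_ratio_ = (s[:k] ** 2) / (s**2).sum()
        self.components_ = Vt[:k]
        self.n_components_ = k
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).scores_


def genotype_pca(panel: GenotypePanel, n_components: int = 4) -> pd.DataFrame:
    """PC score table (line_id x pc1..pck) — thin wrapper over GenotypePCA."""
    est = GenotypePCA(n_components=n_components).fit(panel)
    cols = [f"pc{j + 1}" for j in range(est.n_components_)]
    df = pd.DataFrame(est.scores_, index=pd.Index(panel.line_ids, name="line_id"), columns=cols)
    df.attrs["explained_variance_ratio"] = est.explained_variance_ratio_
    return df


def build_covariates(pcs: pd.DataFrame, phenotypes: PhenotypeTable) -> pd.DataFrame:
    """Assemble the design covariates: [wolbachia, pc1..pck], aligned by line id.

    Constant columns (e.g. all lines uninfected) are dropped with a
    warning rather than entering the regression.  Raises if the PC table
    and the phenotype table disagree on line ids.
    """
    wol = phenotypes.wolbachia()
    pcs_ids = set(pcs.index)
    phen_ids = set(wol.index)
    if pcs_ids != phen_ids:
        missing = sorted(pcs_ids ^ phen_ids)
        raise ValueError(f"unmatched line ids between genotypes and phenotypes: {missing[:10]}")
    wol = wol.reindex(pcs.index)
    out = pd.concat([wol.rename("wolbachia").astype(float), pcs], axis=1)
    constant = [c for c in out.columns if out[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping constant covariate column(s): {constant}")
        out = out.drop(columns=constant)
    return out
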