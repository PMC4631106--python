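"""Broad-sense heritability from the line/replicate structure.

One-way random-effects ANOVA with lines as the random factor, by the
method of moments: sigma2_within = MS_within, and
sigma2_line = (MS_between - MS_within) / n0 with n0 the unbalanced-
design average replicate count, n0 = (N - sum(n_i^2)/N) / (a - 1).
H^2 = sigma2_line / (sigma2_line + sigma2_within) at the level of
individual observations; a negative moment estimate of sigma2_line is
truncated to zero and flagged.  Vial nesting is collapsed into the
within-line variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import PhenotypeTable


@dataclass
class HeritabilityEstimate:
    sigma2_line: float           # days^2
    sigma2_within: float         # days^2
    H2: float
    n_lines: int
    mean_replicates: float
    grand_mean: float            # days
    mean_within_line_sd: float   # days
    truncated: bool = False

    def to_dict(self) -> dict:
        return {
            "sigma2_line": self.sigma2_line,
            "sigma2_within": self.sigma2_within,
            "H2": self.H2,
            "n_lines": self.n_lines,
            "mean_replicates": self.mean_replicates,
            "grand_mean": self.grand_mean,
            "mean_within_line_sd": self.mean_within_line_sd,
            "truncated": self.truncated,
        }


class HeritabilityAnova(BaseEstimator):
    """Method-of-moments variance components; ``fit(phenotypes)``."""

    def fit(self, phenotypes: PhenotypeTable):
        df = phenotypes.flies
        groups = df.groupby("line_id", sort=False)["lifespan_days"]
        n_i = groups.size().to_numpy(dtype=float)
        a = len(n_i)
        if a < 2:
            raise ValueError("need at least 2 lines to estimate heritability")
        if (n_i < 2).all():
            raise ValueError("need replicate measurements within lines")
        N = n_i.sum()
        means = groups.mean().to_numpy()
        grand = float(df["lifespan_days"].mean())

        ss_between = float((n_i * (means - grand) ** 2).sum())
        ss_within = float(
            ((df["lifespan_days"] - groups.transform("mean")) ** 2).sum()
        )
        ms_between = ss_between / (a - 1)
        ms_within = ss_within / (N - a)
        n0 = (N - (n_i**2).sum() / N) / (a - 1)

        sigma2_line = (ms_between - ms_within) / n0
        truncated = sigma2_line < 0
        sigma2_line = max(sigma2_line, 0.0)
        h2 = sigma2_line / (sigma2_line + ms_within) if sigma2_line + ms_within > 0 else 0.0

        within_sd = groups.std(ddof=1)
        self.estimate_ = HeritabilityEstimate(
            sigma2_line=float(sigma2_line),
            sigma2_within=float(ms_within),
            H2=float(h2),
            n_lines=a,
            mean_replicates=float(n_i.mean()),
            grand_mean=float(means.mean()),
            mean_within_line_sd=float(within_sd.mean()),
            truncated=bool(truncated),
        )
        return self


def estimate_h2(phenotypes: PhenotypeTable) -> HeritabilityEstimate:
    """Broad-sense heritability of the replicate design (see module docs)."""
    return HeritabilityAnova().fit(phenotypes).estimate_


def phenotype_summary(phenotypes: PhenotypeTable) -> dict:
    """Descriptive statistics: grand mean of line means, max line mean,
    and the average within-line SD (all in days)."""
    means = phenotypes.line_means()
    within_sd = phenotypes.flies.groupby("line_id", sort=False)["lifespan_days"].std(ddof=1)
    return {
        "grand_mean": float(means.mean()),
        "max_line_mean": float(means.max()),
        "min_line_mean": float(means.min()),
        "mean_within_line_sd": float(within_sd.mean()) if within_sd.notna().any() else 0.0,
        "n_lines": int(len(means)),
    }
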