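"""Core in-memory containers shared by every pipeline stage.

The central object is :class:`GenotypePanel`: a lines x variants dosage
matrix for fully inbred lines, so every genotype is a homozygote coded
0 or 2 (alt-allele copies), with ``NaN`` marking a missing call.  The
0/2 (rather than 0/1) convention keeps regression coefficients on the
per-allele-copy scale of an ordinary diploid GWAS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns required in the per-variant index table.
VARIANT_COLUMNS = ("variant_id", "chrom", "pos", "ref", "alt")

#: Columns required in the fly-level phenotype table.
PHENOTYPE_COLUMNS = ("line_id", "vial", "fly", "lifespan_days", "wolbachia")


class ValidationError(ValueError):
    """Raised when a container violates one of its structural invariants."""


@dataclass
class GenotypePanel:
    """Homozygous line genotypes.

    Parameters
    ----------
    line_ids
        Ordered line identifiers (rows of ``dosages``).
    variants
        Per-variant table with columns ``variant_id, chrom, pos, ref, alt``;
        positions are 1-based and must be strictly increasing within each
        chromosome.
    dosages
        ``(n_lines, n_variants)`` float array with values in {0, 2, NaN}.
    """

    line_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        missing_cols = set(VARIANT_COLUMNS) - set(self.variants.columns)
        if missing_cols:
            raise ValidationError(f"variant table lacks columns {sorted(missing_cols)}")
        n, m = self.dosages.shape
        if n != len(self.line_ids):
            raise ValidationError(
                f"dosage rows ({n}) != number of line ids ({len(self.line_ids)})"
            )
        if m != len(self.variants):
            raise ValidationError(
                f"dosage columns ({m}) != number of variants ({len(self.variants)})"
            )
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValidationError("duplicate line ids")
        if self.variants["variant_id"].duplicated().any():
            dup = self.variants.loc[self.variants["variant_id"].duplicated(), "variant_id"]
            raise ValidationError(f"duplicate variant ids, e.g. {dup.iloc[0]!r}")
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValidationError(f"positions not strictly increasing on {chrom}")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 2.0)).all():
            bad = vals[~np.isin(vals, (0.0, 2.0))][0]
            raise ValidationError(
                f"dosages must be 0, 2 or NaN for inbred lines (found {bad!r})"
            )

    # -- convenience ----------------------------------------------------
    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> pd.Index:
        return pd.Index(self.variants["variant_id"])

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def subset(self, *, lines=None, variants=None) -> "GenotypePanel":
        """Return a new panel restricted to the given row/column indices."""
        lines = np.arange(self.n_lines) if lines is None else np.asarray(lines)
        variants = np.arange(self.n_variants) if variants is None else np.asarray(variants)
        return GenotypePanel(
            line_ids=[self.line_ids[i] for i in lines],
            variants=self.variants.iloc[variants].reset_index(drop=True),
            dosages=self.dosages[np.ix_(lines, variants)].copy(),
        )


@dataclass
class PhenotypeTable:
    """Replicate (fly-level) lifespans plus per-line Wolbachia status.

    ``flies`` has one row per fly with columns
    ``line_id, vial, fly, lifespan_days, wolbachia``; Wolbachia status must
    be constant within a line.
    """

    flies: pd.DataFrame

    def __post_init__(self) -> None:
        self.flies = self.flies.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        missing_cols = set(PHENOTYPE_COLUMNS) - set(self.flies.columns)
        if missing_cols:
            raise ValidationError(f"phenotype table lacks columns {sorted(missing_cols)}")
        if len(self.flies) == 0:
            raise ValidationError("phenotype table is empty")
        if (self.flies["lifespan_days"] <= 0).any():
            bad = self.flies.loc[self.flies["lifespan_days"] <= 0].iloc[0]
            raise ValidationError(
                f"non-positive lifespan for line {bad['line_id']!r}: {bad['lifespan_days']}"
            )
        if not self.flies["wolbachia"].isin((0, 1)).all():
            raise ValidationError("wolbachia status must be 0/1")
        per_line = self.flies.groupby("line_id")["wolbachia"].nunique()
        if (per_line > 1).any():
            raise ValidationError(
                f"inconsistent wolbachia status within line {per_line.idxmax()!r}"
            )

    @property
    def line_ids(self) -> list[str]:
        return list(dict.fromkeys(self.flies["line_id"]))

    def line_means(self) -> pd.Series:
        """Mean lifespan per line, in first-appearance order (days)."""
        return self.flies.groupby("line_id", sort=False)["lifespan_days"].mean()

    def wolbachia(self) -> pd.Series:
        return self.flies.groupby("line_id", sort=False)["wolbachia"].first()

    def replicate_counts(self) -> pd.Series:
        return self.flies.groupby("line_id", sort=False)["lifespan_days"].size()


@dataclass
class GeneAnnotation:
    """Gene intervals, 1-based inclusive coordinates."""

    genes: pd.DataFrame  # gene_id, chrom, start, end

    def __post_init__(self) -> None:
        self.genes = self.genes.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        required = {"gene_id", "chrom", "start", "end"}
        if not required <= set(self.genes.columns):
            raise ValidationError(f"annotation lacks columns {sorted(required - set(self.genes.columns))}")
        if self.genes["gene_id"].duplicated().any():
            dup = self.genes.loc[self.genes["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValidationError(f"duplicate gene id {dup!r}")
        bad = self.genes["start"] > self.genes["end"]
        if bad.any():
            g = self.genes.loc[bad].iloc[0]
            raise ValidationError(f"inverted interval for {g['gene_id']!r}: {g['start']}>{g['end']}")
        if (self.genes["start"] < 1).any():
            raise ValidationError("1-based coordinates must be >= 1")

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.genes["gene_id"])

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways, GO/InterPro-like categories)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, members in self.sets.items():
            if len(set(members)) != len(members):
                self.sets[sid] = list(dict.fromkeys(members))

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, set_id: str) -> list[str]:
        return self.sets[set_id]

    def restrict_to(self, universe) -> tuple["GeneSetCollection", dict[str, list[str]]]:
        """Intersect every set with ``universe``; also report unknown members."""
        universe = set(universe)
        kept: dict[str, list[str]] = {}
        unknown: dict[str, list[str]] = {}
        for sid, members in self.sets.items():
            inside = [g for g in members if g in universe]
            outside = [g for g in members if g not in universe]
            kept[sid] = inside
            if outside:
                unknown[sid] = outside
        return GeneSetCollection(kept, dict(self.descriptions)), unknown
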