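"""Variant- and line-level quality control.

Filter order is call-rate, then MAF, then line missingness; a variant
failing several rules is counted against the first rule applied.  MAF
denominators exclude missing lines, with each inbred line contributing
two allele copies.  Thresholds are inclusive ("cut-off at 0.9" means a
call rate of exactly 0.9 passes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GenotypePanel


class QcError(ValueError):
    pass


@dataclass
class QcReport:
    n_input_variants: int
    n_pass: int
    n_fail_callrate: int
    n_fail_maf: int
    n_lines_removed: int
    line_missingness: pd.Series = field(repr=False, default=None)
    removed_line_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input_variants": self.n_input_variants,
            "n_pass": self.n_pass,
            "n_fail_callrate": self.n_fail_callrate,
            "n_fail_maf": self.n_fail_maf,
            "n_lines_removed": self.n_lines_removed,
            "removed_line_ids": list(self.removed_line_ids),
        }


def compute_variant_stats(panel: GenotypePanel) -> pd.DataFrame:
    """Per-variant call rate and folded minor allele frequency.

    Returns a DataFrame indexed like the variant table with columns
    ``variant_id, call_rate, maf, all_missing``.  A variant with all
    genotypes missing gets call_rate 0 and maf 0, flagged.
    """
    if panel.n_variants == 0:
        raise QcError("empty panel")
    D = panel.dosages
    present = ~np.isnan(D)
    n_called = present.sum(axis=0)
    call_rate = n_called / panel.n_lines
    alt_copies = np.nansum(D, axis=0)
    total_copies = 2.0 * n_called
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(total_copies > 0, alt_copies / np.maximum(total_copies, 1), 0.0)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    maf = np.where(n_called > 0, maf, 0.0)
    return pd.DataFrame(
        {
            "variant_id": panel.variants["variant_id"].to_numpy(),
            "call_rate": call_rate,
            "maf": maf,
            "all_missing": n_called == 0,
        }
    )


def apply_filters(
    panel: GenotypePanel,
    min_call_rate: float = 0.9,
    min_maf: float = 0.02,
    max_line_missing: float = 0.2,
) -> tuple[GenotypePanel, QcReport]:
    """Apply the standard panel filters and report the bookkeeping.

    Variants failing the call-rate threshold are removed first, then
    variants failing the MAF threshold; finally lines whose missingness
    across the surviving variants exceeds ``max_line_missing`` are
    dropped (variant statistics are not recomputed afterwards).
    """
    for name, value in (
        ("min_call_rate", min_call_rate),
        ("min_maf", min_maf),
        ("max_line_missing", max_line_missing),
    ):
        if not 0.0 <= value <= 1.0:
            raise QcError(f"{name} must lie in [0, 1] (got {value})")

    stats = compute_variant_stats(panel)
    fail_cr = stats["call_rate"].to_numpy() < min_call_rate
    fail_maf = (~fail_cr) & (stats["maf"].to_numpy() < min_maf)
    keep = ~(fail_cr | fail_maf)
    if not keep.any():
        raise QcError("all variants removed by QC filters")

    filtered = panel.subset(variants=np.flatnonzero(keep))
    line_missing = np.isnan(filtered.dosages).mean(axis=1)
    line_keep = line_missing <= max_line_missing
    removed_ids = [lid for lid, k in zip(filtered.line_ids, line_keep) if not k]
    if not line_keep.all():
        filtered = filtered.subset(lines=np.flatnonzero(line_keep))

    report = QcReport(
        n_input_variants=panel.n_variants,
        n_pass=int(keep.sum()),
        n_fail_callrate=int(fail_cr.sum()),
        n_fail_maf=int(fail_maf.sum()),
        n_lines_removed=len(removed_ids),
        line_missingness=pd.Series(line_missing, index=panel.line_ids),
        removed_line_ids=removed_ids,
    )
    return filtered, report
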