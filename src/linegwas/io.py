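"""Readers and writers for the standard formats the pipeline touches.

Internal coordinates are 1-based inclusive throughout; BED input/output
is converted at the boundary (BED is 0-based half-open).  VCF genotypes
for an inbred panel are expected homozygous; residual heterozygous
calls become missing with a warning by default (``het_policy="missing"``)
or raise in strict mode.  Multi-allelic and non-SNP records are dropped
and counted.  Missing dosages are an explicit NaN sentinel — never
imputed at I/O time.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    GeneAnnotation,
    GeneSetCollection,
    GenotypePanel,
    PhenotypeTable,
    ValidationError,
)

MISSING_TOKEN = "NA"


class ParseError(ValueError):
    pass


# ----------------------------------------------------------------------
# genotypes
# ----------------------------------------------------------------------

def read_genotypes(path, format: str = None, het_policy: str = "missing") -> GenotypePanel:
    """Read a genotype panel from VCF or the line x SNP TSV dialect.

    Parameters
    ----------
    path
        Input file; format inferred from the suffix when not given.
    format
        ``"vcf"`` or ``"tsv"``.
    het_policy
        ``"missing"`` converts heterozygous calls to missing with a
        warning; ``"strict"`` raises instead.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in (".vcf", ".gz", ".bcf") else "tsv"
    if format == "vcf":
        return _read_vcf(path, het_policy)
    if format == "tsv":
        return _read_genotype_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path, het_policy: str) -> GenotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    records, rows = [], []
    n_multiallelic = n_nonsnp = n_het = 0
    for i, v in enumerate(vcf):
        if len(v.ALT) != 1:
            n_multiallelic += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_nonsnp += 1
            continue
        dos = np.full(len(line_ids), np.nan)
        for s, gt in enumerate(v.genotypes):
            a1, a2 = gt[0], gt[1] if len(gt) > 1 else gt[0]
            if a1 < 0 or a2 < 0:
                continue
            if a1 != a2:
                if het_policy == "strict":
                    raise ParseError(
                        f"heterozygous call for sample {line_ids[s]} at "
                        f"{v.CHROM}:{v.POS} (record {i + 1}) in strict mode"
                    )
                n_het += 1
                continue
            dos[s] = 2.0 * a1
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}"
        records.append((vid, v.CHROM, v.POS, v.REF, v.ALT[0]))
        rows.append(dos)
    if n_multiallelic or n_nonsnp:
        warnings.warn(
            f"dropped {n_multiallelic} multi-allelic and {n_nonsnp} non-SNP records"
        )
    if n_het:
        warnings.warn(f"coerced {n_het} heterozygous calls to missing (inbred panel)")
    if not records:
        raise ParseError(f"no biallelic SNP records parsed from {path}")
    variants = pd.DataFrame(records, columns=["variant_id", "chrom", "pos", "ref", "alt"])
    panel = GenotypePanel(line_ids=line_ids, variants=variants,
                          dosages=np.vstack(rows).T)
    panel.dropped_multiallelic = n_multiallelic
    panel.dropped_nonsnp = n_nonsnp
    return panel


def _read_genotype_tsv(path: Path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=[MISSING_TOKEN])
    fixed = ["variant_id", "chrom", "pos", "ref", "alt"]
    for col in fixed:
        if col not in df.columns:
            raise ParseError(f"genotype TSV lacks column {col!r}")
    line_ids = [c for c in df.columns if c not in fixed]
    if not line_ids:
        raise ParseError("genotype TSV has no line columns")
    if len(df) == 0:
        raise ParseError("zero variants in genotype TSV")
    dosages = df[line_ids].to_numpy(dtype=float).T
    return GenotypePanel(line_ids=line_ids, variants=df[fixed].copy(), dosages=dosages)


def write_genotypes(panel: GenotypePanel, path, format: str = None) -> None:
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix == ".vcf" else "tsv"
    if format == "vcf":
        _write_vcf(panel, path)
    elif format == "tsv":
        _write_genotype_tsv(panel, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def _write_vcf(panel: GenotypePanel, path: Path) -> None:
    gt_code = {0.0: "0/0", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=linegwas\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(panel.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.line_ids) + "\n")
        for j, row in enumerate(panel.variants.itertuples(index=False)):
            calls = "\t".join(
                gt_code.get(d, "./.") for d in panel.dosages[:, j]
            )
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.variant_id}\t{row.ref}\t{row.alt}"
                f"\t.\t.\t.\tGT\t{calls}\n"
            )


def _write_genotype_tsv(panel: GenotypePanel, path: Path) -> None:
    df = panel.variants.copy()
    dosage = pd.DataFrame(panel.dosages.T, columns=panel.line_ids)
    out = pd.concat([df.reset_index(drop=True), dosage], axis=1)
    out.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN, float_format="%.0f")


# ----------------------------------------------------------------------
# phenotypes
# ----------------------------------------------------------------------

def read_phenotypes(path) -> PhenotypeTable:
    """Read a fly-level phenotype TSV (line_id, vial, fly, lifespan_days, wolbachia)."""
    df = pd.read_csv(path, sep="\t", dtype={"line_id": str})
    try:
        return PhenotypeTable(flies=df)
    except ValidationError as exc:
        raise ParseError(f"invalid phenotype table {path}: {exc}") from exc


def write_phenotypes(phenotypes: PhenotypeTable, path) -> None:
    phenotypes.flies.to_csv(path, sep="\t", index=False, float_format="%.6f")


# ----------------------------------------------------------------------
# annotation
# ----------------------------------------------------------------------

def read_annotation(path, format: str = None) -> GeneAnnotation:
    """Read gene intervals from BED4 (0-based half-open) or gene TSV (1-based)."""
    path = Path(path)
    if format is None:
        format = "bed" if path.suffix == ".bed" else "tsv"
    if format == "bed":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "gene_id"], dtype={"chrom": str},
        )
        if df[["start", "end", "gene_id"]].isna().any().any():
            raise ParseError(f"malformed BED4 file {path}")
        df["start"] = df["start"].astype(int) + 1  # 0-based half-open -> 1-based incl.
        df["end"] = df["end"].astype(int)
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        required = {"gene_id", "chrom", "start", "end"}
        if not required <= set(df.columns):
            raise ParseError(f"annotation TSV lacks columns {sorted(required - set(df.columns))}")
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    try:
        return GeneAnnotation(genes=df[["gene_id", "chrom", "start", "end"]].copy())
    except ValidationError as exc:
        raise ParseError(f"invalid annotation {path}: {exc}") from exc


def write_annotation(annotation: GeneAnnotation, path, format: str = None) -> None:
    path = Path(path)
    if format is None:
        format = "bed" if path.suffix == ".bed" else "tsv"
    if format == "bed":
        df = annotation.genes.copy()
        df["start"] = df["start"] - 1  # 1-based inclusive -> 0-based half-open
        df[["chrom", "start", "end", "gene_id"]].to_csv(
            path, sep="\t", index=False, header=False
        )
    else:
        annotation.genes.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# gene sets (GMT)
# ----------------------------------------------------------------------

def read_gene_sets(path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs id, description, >=1 gene")
            sid, desc, members = fields[0], fields[1], [g for g in fields[2:] if g]
            if sid in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set id {sid!r}")
            sets[sid] = members
            descriptions[sid] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for sid, members in collection.sets.items():
            desc = collection.descriptions.get(sid, "")
            fh.write("\t".join([sid, desc, *members]) + "\n")
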