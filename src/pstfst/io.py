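"""Readers and writers for the exchangeable text formats.

Genotypes come in as a VCF (v4.2, biallelic SNPs only) plus a two-column
population map; traits and sites as delimited text with a header; matrices
go out as full labelled TSV tables.  Only the GT field of the VCF is
consulted; phased and unphased separators are treated alike.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .types import (
    MISSING,
    GenotypeMatrix,
    SiteTable,
    SymmetricMatrix,
    TraitTable,
    ValidationError,
)

__all__ = [
    "read_genotypes",
    "read_popmap",
    "read_traits",
    "read_sites",
    "read_symmetric_matrix",
    "write_symmetric_matrix",
    "write_genotypes_vcf",
    "write_popmap",
    "write_traits",
    "write_sites",
]


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_popmap(path: str | Path) -> dict[str, str]:
    """Read a two-column sample -> population map (TSV or whitespace)."""
    popmap: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ValidationError(f"{path}:{lineno}: expected 'sample<TAB>population'")
            sample, pop = parts
            if sample in popmap:
                raise ValidationError(f"{path}:{lineno}: duplicate sample {sample!r}")
            popmap[sample] = pop
    if not popmap:
        raise ValidationError(f"{path}: empty population map")
    return popmap


def read_genotypes(vcf_path: str | Path, popmap_path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNP genotypes as ALT-allele dosages.

    Every sample in the VCF must appear in the popmap; non-biallelic
    records are a hard error (the expected input is an already-filtered
    SNP set, so a divergence from it should not pass silently).
    """
    popmap = read_popmap(popmap_path)
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    if not samples:
        raise ValidationError(f"{vcf_path}: no samples in VCF")
    absent = [s for s in samples if s not in popmap]
    if absent:
        raise ValidationError(
            f"{vcf_path}: samples missing from popmap {popmap_path}: {absent}"
        )

    loci: list[str] = []
    rows: list[np.ndarray] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValidationError(
                f"{vcf_path}: non-biallelic record at {variant.CHROM}:{variant.POS} "
                f"(ALT={variant.ALT})"
            )
        loci.append(f"{variant.CHROM}:{variant.POS}")
        # genotypes: [allele0, allele1, phased] per sample; -1 = uncalled
        gts = np.array([g[:2] for g in variant.genotypes], dtype=np.int16)
        dosage = (gts > 0).sum(axis=1).astype(np.int8)
        dosage[(gts < 0).any(axis=1)] = MISSING
        rows.append(dosage)
    if not loci:
        raise ValidationError(f"{vcf_path}: no variant records")
    dosages = np.column_stack(rows) if rows else np.empty((len(samples), 0), np.int8)
    return GenotypeMatrix(
        samples=samples,
        populations=[popmap[s] for s in samples],
        dosages=dosages,
        loci=loci,
    )


def read_traits(path: str | Path, na_string: str = "NA") -> TraitTable:
    """Read a delimited trait table: sample, population, then trait columns."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    for col in ("sample", "population"):
        if col not in df.columns:
            raise ValidationError(f"{path}: required column {col!r} missing from header")
    trait_cols = [c for c in df.columns if c not in ("sample", "population")]
    if not trait_cols:
        raise ValidationError(f"{path}: no trait columns found")
    if df["sample"].duplicated().any():
        dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise ValidationError(f"{path}: duplicate sample IDs: {dups}")

    values = pd.DataFrame(index=range(len(df)), columns=trait_cols, dtype=float)
    for col in trait_cols:
        for i, cell in enumerate(df[col]):
            cell = cell.strip()
            if cell == na_string or cell == "":
                values.loc[i, col] = np.nan
                continue
            try:
                values.loc[i, col] = float(cell)
            except ValueError:
                raise ValidationError(
                    f"{path}: non-numeric value {cell!r} in row {i + 2}, column {col!r}"
                ) from None
    return TraitTable(
        samples=df["sample"].tolist(),
        populations=df["population"].tolist(),
        data=values,
    )


def read_sites(path: str | Path) -> SiteTable:
    """Read per-population coordinates (decimal degrees) and elevation (m)."""
    df = pd.read_csv(path, sep=_sep_for(path))
    df.columns = [c.strip().lower() for c in df.columns]
    if "population" not in df.columns:
        raise ValidationError(f"{path}: required column 'population' missing")
    return SiteTable(df.set_index("population"))


def write_symmetric_matrix(m: SymmetricMatrix, path: str | Path) -> None:
    """Write a full labelled matrix as TSV; round-trips to 12+ sig. digits."""
    m.to_frame().to_csv(path, sep="\t", float_format="%.17g", index_label=m.kind)


def read_symmetric_matrix(path: str | Path, kind: str) -> SymmetricMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = [str(l) for l in df.index]
    if labels != [str(c) for c in df.columns]:
        raise ValidationError(f"{path}: row and column labels disagree")
    return SymmetricMatrix(labels=labels, values=df.to_numpy(float), kind=kind)


def write_popmap(g: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, pop in zip(g.samples, g.populations):
            fh.write(f"{sample}\t{pop}\n")


def write_genotypes_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF v4.2 with GT-only genotype fields.

    Loci named ``contig:pos`` are split back into CHROM/POS; REF/ALT are
    placeholder alleles (A/T) — only genotypes carry information here.
    """
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        contigs: dict[str, None] = {}
        for locus in g.loci:
            contigs.setdefault(locus.rsplit(":", 1)[0])
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.samples) + "\n")
        for j, locus in enumerate(g.loci):
            chrom, pos = locus.rsplit(":", 1)
            calls = "\t".join(gt_code[int(d)] for d in g.dosages[:, j])
            fh.write(f"{chrom}\t{pos}\t.\tA\tT\t.\tPASS\t.\tGT\t{calls}\n")


def write_traits(t: TraitTable, path: str | Path, na_string: str = "NA") -> None:
    df = t.data.copy()
    df.insert(0, "population", t.populations)
    df.insert(0, "sample", t.samples)
    df.to_csv(path, sep=_sep_for(path), index=False, na_rep=na_string,
              float_format="%.10g")


def write_sites(s: SiteTable, path: str | Path) -> None:
    s.data.to_csv(path, sep=_sep_for(path), index_label="population",
                  float_format="%.10g")
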