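"""Readers and writers for the genotype TSV and minimal VCF dialects.

Genotype tables are tab-separated with a ``snp_id`` index column and one
column per individual; cells are genotypes in {AA, AB, BB}.  Variant sets
are VCF v4.x with CHROM, POS, REF, ALT and the record type carried in the
INFO field as ``SVTYPE=`` (SUB, SNP, DEL or INS), read and written through
pysam.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import pandas as pd
import pysam

from .hamming import CHROM_INDEX, EncodingParams, VariantRecord

VALID_GENOTYPES = {"AA", "AB", "BB"}


class ParseError(ValueError):
    pass


def read_genotypes(path) -> pd.DataFrame:
    """Read one group's genotype table; validates every cell."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty genotype file") from None
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{path}: empty genotype table")
    for i, (snp, row) in enumerate(df.iterrows()):
        for col, val in row.items():
            if val not in VALID_GENOTYPES:
                raise ParseError(
                    f"{path}: line {i + 2}: bad genotype {val!r} "
                    f"(snp {snp}, individual {col})")
    return df


def write_genotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="snp_id")


def _vcf_header(params: EncodingParams) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    h.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,'
               'Description="Record type (SUB, SNP, DEL or INS)">')
    for name in CHROM_INDEX:
        h.contigs.add(name, length=params.L)
    return h


def write_vcf(records: Sequence[VariantRecord], path,
              params: EncodingParams | None = None) -> None:
    params = params or EncodingParams()
    header = _vcf_header(params)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in records:
            rec = out.new_record(contig=r.chrom, start=r.pos - 1,
                                 alleles=(r.ref, r.alt))
            rec.info["SVTYPE"] = r.svtype
            out.write(rec)


def read_vcf(path, *, infer_svtype: bool = False,
             unknown_chrom: str = "error") -> list[VariantRecord]:
    """Read variant records in file order.

    ``infer_svtype`` derives the type from allele lengths when INFO lacks
    SVTYPE (single-character REF and ALT => SNP, otherwise SUB); off by
    default, in which case a missing SVTYPE is an error.  Chromosome labels
    outside 1-22, X, Y are an error unless ``unknown_chrom="skip"``.
    """
    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            chrom = rec.chrom
            if chrom not in CHROM_INDEX:
                if unknown_chrom == "skip":
                    warnings.warn(f"{path}: skipping record on chromosome "
                                  f"{chrom!r}")
                    continue
                raise ParseError(f"{path}: chromosome {chrom!r} outside "
                                 "1-22, X, Y")
            ref = rec.ref
            alt = rec.alts[0] if rec.alts else ""
            try:
                sv = rec.info["SVTYPE"]
            except (KeyError, ValueError):  # absent or undeclared in header
                sv = None
            if isinstance(sv, tuple):
                sv = sv[0]
            if sv is None:
                if not infer_svtype:
                    raise ParseError(
                        f"{path}: record {chrom}:{rec.pos} lacks SVTYPE")
                sv = "SNP" if len(ref) == 1 and len(alt) == 1 else "SUB"
            if sv == "SNP" and (len(ref) != 1 or len(alt) != 1):
                warnings.warn(f"{path}: record {chrom}:{rec.pos} is typed SNP "
                              "but REF/ALT are not single characters")
            out.append(VariantRecord(chrom=chrom, pos=rec.pos, ref=ref,
                                     alt=alt, svtype=sv))
    return out


def write_gwas_output(result, path, snp_ids: Sequence[str] | None = None) -> None:
    """Write per-SNP MAF and chi-squared as TSV (snp_id, maf, chisq)."""
    n = len(result.maf)
    ids = list(snp_ids) if snp_ids is not None else [f"snp{i}" for i in range(n)]
    df = pd.DataFrame({
        "snp_id": ids,
        "maf": [float(m) for m in result.maf],
        "chisq": [float(c) if c is not None else float("nan")
                  for c in result.chisq],
    })
    df.to_csv(path, sep="\t", index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
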