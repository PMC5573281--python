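"""Readers and writers for the pipeline's plain-text artifacts.

Cohort variants travel either as a flat TSV (one row per record, list fields
comma-joined) or as VCF v4.2 with the annotations in INFO (GENE, CADD,
KNOWN, REGION, CSQ, GROUP), caller flags in FILTER and carriers as GT sample
columns.  Everything else (reference counts, feature matrices, citation
table, edge lists) is tab-separated with a header row; the ground truth is
JSON.
"""

from __future__ import annotations

import json
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from .filtering import AnnotatedVariant
from .synthetic import SyntheticTruth

_VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "genes", "region_class", "consequence",
    "cadd_phred", "known_in", "caller_filters", "carriers", "group",
    "rs_id", "exac_maf",
]


def _join(values: Iterable[str]) -> str:
    return ",".join(sorted(values))


def _split(value) -> tuple[str, ...]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return ()
    return tuple(str(value).split(","))


# ---------------------------------------------------------------------------
# flat TSV dialect

def write_variants_tsv(variants: Sequence[AnnotatedVariant], path: str) -> None:
    rows = []
    for v in variants:
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "genes": _join(v.genes) if len(v.genes) > 1 else v.genes[0],
                "region_class": v.region_class,
                "consequence": v.consequence,
                "cadd_phred": "" if v.cadd_phred is None else v.cadd_phred,
                "known_in": _join(v.known_in),
                "caller_filters": _join(v.caller_filters),
                "carriers": ",".join(v.carriers),
                "group": v.group,
                "rs_id": v.rs_id or "",
                "exac_maf": "" if v.exac_maf is None else v.exac_maf,
            }
        )
    pd.DataFrame(rows, columns=_VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path: str) -> list[AnnotatedVariant]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    variants = []
    for row in df.itertuples(index=False):
        variants.append(
            AnnotatedVariant(
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                genes=_split(row.genes),
                region_class=row.region_class,
                consequence=row.consequence,
                cadd_phred=None if pd.isna(row.cadd_phred) else float(row.cadd_phred),
                known_in=frozenset(_split(row.known_in)),
                caller_filters=frozenset(_split(row.caller_filters)),
                carriers=tuple(str(row.carriers).split(",")),
                group=row.group,
                rs_id=None if pd.isna(row.rs_id) else str(row.rs_id),
                exac_maf=None if pd.isna(row.exac_maf) else float(row.exac_maf),
            )
        )
    return variants


# ---------------------------------------------------------------------------
# VCF v4.2 dialect

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=.,Type=String,Description="Annotated gene symbol(s)">
##INFO=<ID=CADD,Number=1,Type=Float,Description="CADD phred deleteriousness score">
##INFO=<ID=KNOWN,Number=.,Type=String,Description="Known-variant database membership">
##INFO=<ID=REGION,Number=1,Type=String,Description="Region class (exonic/UTR/splicing/other)">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Coding consequence class">
##INFO=<ID=GROUP,Number=1,Type=String,Description="Phenotype group of the carriers">
##INFO=<ID=EXAC_MAF,Number=1,Type=Float,Description="Reference-population minor allele frequency">
##FILTER=<ID=QD,Description="Low quality-by-depth">
##FILTER=<ID=Q20,Description="Quality below 20">
##FILTER=<ID=badReads,Description="Low-quality supporting reads">
##FILTER=<ID=alleleBias,Description="Allele bias">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_variants_vcf(
    variants: Sequence[AnnotatedVariant], path: str, sample_ids: Sequence[str] | None = None
) -> None:
    """Write records in VCF v4.2 with carriers as 0/1 genotype columns."""
    if sample_ids is None:
        seen: dict[str, None] = {}
        for v in variants:
            for c in v.carriers:
                seen.setdefault(c, None)
        sample_ids = sorted(seen)
    records = sorted(variants, key=lambda v: (_chrom_key(v.chrom), v.pos, v.ref, v.alt))

    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in sorted({v.chrom for v in records}, key=_chrom_key):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids) + "\n"
        )
        for v in records:
            info = [f"GENE={_join(v.genes)}"]
            if v.cadd_phred is not None:
                info.append(f"CADD={v.cadd_phred}")
            if v.known_in:
                info.append(f"KNOWN={_join(v.known_in)}")
            info.append(f"REGION={v.region_class}")
            info.append(f"CSQ={v.consequence}")
            info.append(f"GROUP={v.group}")
            if v.exac_maf is not None:
                info.append(f"EXAC_MAF={v.exac_maf}")
            filt = ";".join(sorted(v.caller_filters)) if v.caller_filters else "PASS"
            carriers = set(v.carriers)
            gts = "\t".join("0/1" if s in carriers else "0/0" for s in sample_ids)
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.rs_id or '.'}\t{v.ref}\t{v.alt}\t.\t{filt}\t"
                f"{';'.join(info)}\tGT\t{gts}\n"
            )


def _chrom_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def read_variants_vcf(path: str) -> list[AnnotatedVariant]:
    """Read a VCF written by :func:`write_variants_vcf` (or any VCF carrying
    the same INFO keys) back into annotated records."""
    variants = []
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            info = rec.info
            genes = info.get("GENE")
            genes = tuple(genes) if isinstance(genes, tuple) else (str(genes),)
            known = info.get("KNOWN", ())
            known = frozenset(known) if isinstance(known, tuple) else frozenset({str(known)})
            carriers = tuple(
                s for s in samples if any(a == 1 for a in (rec.samples[s]["GT"] or ()) if a is not None)
            )
            filters = frozenset(f for f in rec.filter.keys() if f != "PASS")
            cadd = info.get("CADD")
            maf = info.get("EXAC_MAF")
            variants.append(
                AnnotatedVariant(
                    chrom=str(rec.chrom),
                    pos=int(rec.pos),
                    ref=rec.ref,
                    alt=rec.alts[0] if rec.alts else ".",
                    genes=genes,
                    region_class=str(info.get("REGION")),
                    consequence=str(info.get("CSQ", "missense")),
                    cadd_phred=None if cadd is None else float(cadd),
                    known_in=known,
                    caller_filters=filters,
                    carriers=carriers,
                    group=str(info.get("GROUP", "restricted")),
                    rs_id=rec.id,
                    exac_maf=None if maf is None else float(maf),
                )
            )
    return variants


# ---------------------------------------------------------------------------
# remaining tables

def write_table(df: pd.DataFrame, path: str, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_reference_counts(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_matrix(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=True)


def read_matrix(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_citations(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth(truth: SyntheticTruth, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth(path: str) -> SyntheticTruth:
    with open(path) as fh:
        return SyntheticTruth.from_dict(json.load(fh))


def read_gene_list(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Iterable[str], path: str) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")
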