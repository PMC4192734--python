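"""Readers and writers for the pipeline's interchange formats.

VCF v4.2 carries sequencing calls (one sample column per discovery line;
GT, DP, GQ format fields; INFO keys SAMCALL/GATKCALL for caller support,
CN for k-mer copy number, MQ0F for the mapping-quality-zero fraction).
Genes travel as BED (0-based half-open) or GFF3 (1-based inclusive);
intensities and sample sheets as TSV.  Reading uses cyvcf2/gffutils/pandas;
writing VCF is plain line records against a fixed header.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import HET, HOM_ALT, HOM_REF, MISSING, VariantCallSet
from .errors import ValidationError

_GT_STR = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}

_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total site depth">
##INFO=<ID=CN,Number=1,Type=Integer,Description="Genomic copy number from 16-kmer counts">
##INFO=<ID=MQ0F,Number=1,Type=Float,Description="Fraction of reads with mapping quality 0">
##INFO=<ID=SAMCALL,Number=0,Type=Flag,Description="Supported by the SAMtools caller">
##INFO=<ID=GATKCALL,Number=0,Type=Flag,Description="Supported by the GATK caller">
##INFO=<ID=VT,Number=1,Type=String,Description="Variant type (SNP or indel)">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""


def write_vcf(callset: VariantCallSet, path) -> None:
    """Write a :class:`VariantCallSet` as VCF v4.2."""
    sites = callset.sites
    with open(path, "w") as fh:
        fh.write(_HEADER)
        for chrom in pd.unique(sites["chrom"]):
            length = int(sites.loc[sites["chrom"] == chrom, "pos"].max()) + 1000
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(callset.samples) + "\n")
        for i in range(callset.n_sites):
            row = sites.iloc[i]
            flags = ""
            if row["samtools_call"]:
                flags += ";SAMCALL"
            if row["gatk_call"]:
                flags += ";GATKCALL"
            info = (
                f"DP={int(row['dp'])};CN={int(row['cn'])};MQ0F={row['mq0f']:.4f}"
                f";VT={row['vtype']}{flags}"
            )
            cols = [
                str(row["chrom"]),
                str(int(row["pos"])),
                str(row.get("variant_id", ".")),
                row["ref"],
                row["alt"],
                f"{row['qual']:.1f}",
                "PASS",
                info,
                "GT:DP:GQ",
            ]
            gts = callset.genotypes[i]
            dps = callset.depths[i]
            cols.extend(
                f"{_GT_STR[int(g)]}:{int(d)}:99" for g, d in zip(gts, dps)
            )
            fh.write("\t".join(cols) + "\n")


def read_vcf(path) -> VariantCallSet:
    """Read a VCF into a :class:`VariantCallSet` (multi-allelic sites kept)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, gts, dps = [], [], []
    for v in vcf:
        info = dict(v.INFO)
        rows.append(
            (
                v.ID or ".",
                v.CHROM,
                v.POS,
                v.REF,
                ",".join(v.ALT),
                info.get("VT", "SNP"),
                round(float(v.QUAL), 1) if v.QUAL is not None else np.nan,
                int(info.get("DP", 0)),
                int(info.get("CN", 0)),
                round(float(info.get("MQ0F", 0.0)), 4),
                bool(info.get("SAMCALL", False)),
                bool(info.get("GATKCALL", False)),
            )
        )
        gt = np.asarray(v.gt_types, dtype=np.int8)  # 0/1/2 = #alt copies, 3 = unknown
        gt[gt == 3] = MISSING
        gts.append(gt)
        depth = v.format("DP")
        dps.append(
            depth[:, 0].astype(np.int32) if depth is not None
            else np.zeros(len(samples), np.int32)
        )
    sites = pd.DataFrame(
        rows,
        columns=[
            "variant_id", "chrom", "pos", "ref", "alt", "vtype", "qual",
            "dp", "cn", "mq0f", "samtools_call", "gatk_call",
        ],
    )
    g = np.vstack(gts) if gts else np.zeros((0, len(samples)), np.int8)
    d = np.vstack(dps) if dps else np.zeros((0, len(samples)), np.int32)
    return VariantCallSet(sites, g, d, samples)


def write_genes_bed(genes: pd.DataFrame, path) -> None:
    """Genes (1-based inclusive) -> BED (0-based half-open)."""
    out = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["start"].astype(int) - 1,
            "end": genes["end"].astype(int),
            "name": genes["gene_id"],
            "score": 0,
            "strand": genes["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_genes_bed(path) -> pd.DataFrame:
    """BED (0-based half-open) -> gene table (1-based inclusive)."""
    bed = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    return pd.DataFrame(
        {
            "gene_id": bed["name"],
            "chrom": bed["chrom"],
            "start": bed["start"].astype(int) + 1,
            "end": bed["end"].astype(int),
            "strand": bed["strand"],
        }
    )


def read_genes_gff3(path) -> pd.DataFrame:
    """GFF3 gene models -> gene/feature table (1-based inclusive).

    Returns one row per gene plus one row per exon/CDS/UTR feature so that
    the annotator can distinguish coding, intron, and UTR hits.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for feat in db.all_features():
        if feat.featuretype not in (
            "gene", "exon", "CDS", "five_prime_UTR", "three_prime_UTR"
        ):
            continue
        if feat.featuretype == "gene":
            gid = feat.id
        else:
            parents = list(db.parents(feat, featuretype="gene"))
            gid = parents[0].id if parents else feat.id
        rows.append(
            (gid, feat.featuretype, feat.seqid, feat.start, feat.end, feat.strand)
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "feature", "chrom", "start", "end", "strand"]
    )


def read_intensity_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"variant_id", "sample_id", "signal_A", "signal_B"}
    if not required.issubset(table.columns):
        raise ValidationError(f"intensity table must have columns {sorted(required)}")
    return table


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"replicate_of": str,
                                               "parent1": str, "parent2": str})
    for col in ("replicate_of", "parent1", "parent2"):
        if col in sheet.columns:
            sheet[col] = sheet[col].fillna("")
    if "id" not in sheet.columns:
        raise ValidationError("sample sheet must have an 'id' column")
    return sheet
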