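"""File I/O: VCF, FASTA, FASTQ, BED and the pipeline's TSV tables.

All coordinate conversion is centralized here: VCF is 1-based inclusive,
BED is 0-based half-open, and the in-memory tables follow the convention of
the type that owns them (``InformativeSnp.pos`` is 1-based; gene-model
``start``/``end`` are BED-style).
"""

from __future__ import annotations

import os
from typing import Dict, List, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .variants import GenomeSeq, InformativeSnp, SnpRecord

_GT_CODE = {"hom_ref": (0, 0), "het": (0, 1), "hom_alt": (1, 1)}
_GT_NAME = {(0, 0): "hom_ref", (0, 1): "het", (1, 0): "het", (1, 1): "hom_alt"}


# ---------------------------------------------------------------- FASTA


def read_fasta(path: str | os.PathLike) -> GenomeSeq:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | os.PathLike, genome: GenomeSeq) -> None:
    records = [SeqRecord(Seq(seq), id=contig, description="") for contig, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------- FASTQ


def write_fastq(path: str | os.PathLike, reads: Sequence[tuple]) -> None:
    """Write (read_id, sequence) pairs with uniform high base quality."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | os.PathLike) -> List[tuple]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------- VCF


def write_vcf(
    path: str | os.PathLike,
    records: Sequence[SnpRecord],
    contig_lengths: Dict[str, int],
    sample: str = "parent",
) -> None:
    """Write SNP records as a minimal single-sample VCF v4.2."""
    header = pysam.VariantHeader()
    for contig, length in contig_lengths.items():
        header.contigs.add(contig, length=length)
    header.info.add("DP", 1, "Integer", "Read depth")
    header.info.add("AO", 1, "Integer", "Alternate allele observations")
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for r in sorted(records, key=lambda x: (x.contig, x.pos)):
            rec = vcf.new_record(
                contig=r.contig,
                start=r.pos - 1,
                stop=r.pos,
                alleles=(r.ref_allele, r.alt_allele),
                qual=r.qual,
            )
            rec.info["DP"] = r.depth
            rec.info["AO"] = r.alt_obs
            if r.ploidy == 1:
                rec.samples[sample]["GT"] = (1,) if r.genotype == "hom_alt" else (0,)
            else:
                rec.samples[sample]["GT"] = _GT_CODE[r.genotype]
            vcf.write(rec)


def read_vcf(path: str | os.PathLike, ploidy: int = 2) -> List[SnpRecord]:
    """Read a single-sample VCF into SNP records (multi-allelic records are
    split per alternate allele)."""
    out: List[SnpRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        sample = list(vcf.header.samples)[0]
        for rec in vcf:
            gt = rec.samples[sample].get("GT")
            for alt in rec.alts or ():
                if ploidy == 1:
                    genotype = "hom_alt" if gt and gt[0] == 1 else "hom_ref"
                else:
                    genotype = _GT_NAME.get(tuple(gt), "het") if gt else "het"
                out.append(
                    SnpRecord(
                        contig=rec.contig,
                        pos=rec.pos,
                        ref_allele=rec.ref,
                        alt_allele=alt,
                        qual=float(rec.qual) if rec.qual is not None else 0.0,
                        depth=int(rec.info.get("DP", 0)),
                        alt_obs=int(rec.info.get("AO", 0)),
                        genotype=genotype,
                        ploidy=ploidy,
                    )
                )
    return out


# ---------------------------------------------------------------- BED / TSV


def write_bed(path: str | os.PathLike, gene_models: pd.DataFrame) -> None:
    """Gene models (contig, start, end, gene_id), 0-based half-open."""
    gene_models[["contig", "start", "end", "gene_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["contig", "start", "end", "gene_id"]
    )


def write_informative_snps(path: str | os.PathLike, snps: Sequence[InformativeSnp]) -> None:
    pd.DataFrame(
        [
            {
                "contig": s.contig,
                "pos": s.pos,
                "parent": s.parent,
                "parent_allele": s.parent_allele,
                "other_allele": s.other_allele,
                "gene_id": s.gene_id if s.gene_id is not None else "",
            }
            for s in snps
        ]
    ).to_csv(path, sep="\t", index=False)


def read_informative_snps(path: str | os.PathLike) -> List[InformativeSnp]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        InformativeSnp(
            contig=str(r.contig),
            pos=int(r.pos),
            parent=r.parent,
            parent_allele=r.parent_allele,
            other_allele=r.other_allele,
            gene_id=str(r.gene_id) or None,
        )
        for r in df.itertuples()
    ]


def write_table(path: str | os.PathLike, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
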