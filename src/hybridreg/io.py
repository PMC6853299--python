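"""Plain-text I/O: TSV tables, minimal VCF 4.2 and FASTA.

Every stage artifact is a TSV or JSON file so stages can be re-run and
inspected in isolation.  Positions are 1-based in VCF and genotype
tables, 0-based in :class:`~hybridreg.alleles.SsSnpRecord`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .alleles import AlleleCountTable, SsSnpRecord


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_allele_counts(table: AlleleCountTable, path) -> None:
    table.table.to_csv(path, sep="\t", index=False)


def read_allele_counts(path) -> AlleleCountTable:
    return AlleleCountTable(pd.read_csv(path, sep="\t"))


def write_genotype_table(genotypes: pd.DataFrame, path) -> None:
    """Site x individual base calls; index (chrom, pos 1-based)."""
    genotypes.to_csv(path, sep="\t")


def read_genotype_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=[0, 1])
    df.index.names = ["chrom", "pos"]
    return df


# ---------------------------------------------------------------------------
# VCF (minimal 4.2 writer / reader for SNP sets)
# ---------------------------------------------------------------------------

def write_ss_snps_vcf(snps: Iterable[SsSnpRecord], path,
                      sample_names: Sequence[str] = ("SP1", "SP2"),
                      seed: int | None = None) -> None:
    """ss-SNPs as a minimal VCF 4.2: REF = species-1 allele, ALT =
    species-2 allele, one homozygous genotype column per species."""
    lines = ["##fileformat=VCFv4.2",
             "##source=hybridreg",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    if seed is not None:
        lines.append(f"##hybridreg_seed={seed}")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_names))
    for snp in snps:
        lines.append(f"{snp.chrom}\t{snp.pos + 1}\t.\t{snp.allele_sp1}\t"
                     f"{snp.allele_sp2}\t.\tPASS\t.\tGT\t0/0\t1/1")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ss_snps_vcf(path) -> list[SsSnpRecord]:
    snps = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        chrom, pos, _id, ref, alt = line.split("\t")[:5]
        snps.append(SsSnpRecord(chrom, int(pos) - 1, ref, alt))
    return snps


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str) + "\n")
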