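"""Readers and writers for the standard formats the pipeline speaks.

VCF via pysam, FASTA via Biopython, BED and TSV as plain text.  The
simulator emits a multi-sample VCF (parents + progeny over nuclear,
mitochondrial and element contigs) with GT/AD/DP/GQ per sample so the
analysis side exercises the same ingestion path as real data.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .layout import GenomeLayout
from .simulate import SimResult

__all__ = ["write_fasta", "read_fasta", "write_bed", "read_bed", "write_vcf"]


def write_fasta(sequences: dict[str, bytes], path: str,
                width: int = 70) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq.decode("ascii")), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, bytes]:
    from Bio import SeqIO

    return {rec.id: bytes(str(rec.seq).upper(), "ascii")
            for rec in SeqIO.parse(path, "fasta")}


def write_bed(intervals, path: str) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_bed(path: str) -> tuple[tuple[str, int, int], ...]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith(("#", "track")):
                chrom, start, end, *_ = line.split("\t")
                out.append((chrom, int(start), int(end)))
    return tuple(out)


def write_vcf(result: SimResult, path: str,
              parent_depth: int = 30) -> None:
    """Write the simulated cross as an uncompressed multi-sample VCF.

    Parents are clean haploid homozygotes at every diagnostic site; progeny
    genotypes carry the simulated allelic depths (AD), with GT set to the
    majority allele and missing where the clone has no coverage.
    """
    import pysam

    header = pysam.VariantHeader()
    for name, length in result.layout.all_contigs():
        header.add_line(f"##contig=<ID={name},length={length}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                    'Description="Allelic depths">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">')
    header.add_line('##FORMAT=<ID=GQ,Number=1,Type=Integer,'
                    'Description="Genotype quality">')
    parents = list(result.cfg.parent_names)
    progeny = result.progeny_ids
    for s in parents + progeny:
        header.add_sample(s)

    obs = result.obs.set_index(["chrom", "pos", "progeny"]).sort_index()
    with pysam.VariantFile(path, "w", header=header) as vf:
        for _, site in result.sites.iterrows():
            rec = vf.new_record(contig=site["chrom"], start=int(site["pos"]),
                                alleles=(site["ref"], site["alt"]))
            rec.qual = 1000
            for p in parents:
                is_alt = site[f"allele_{p}"] == site["alt"]
                smp = rec.samples[p]
                smp["GT"] = (1,) if is_alt else (0,)
                smp["AD"] = (0, parent_depth) if is_alt else (parent_depth, 0)
                smp["DP"] = parent_depth
                smp["GQ"] = 99
            key = (site["chrom"], int(site["pos"]))
            for pid in progeny:
                smp = rec.samples[pid]
                try:
                    row = obs.loc[key + (pid,)]
                except KeyError:
                    smp["GT"] = (None,)
                    continue
                n_ref, n_alt = int(row["n_ref"]), int(row["n_alt"])
                smp["AD"] = (n_ref, n_alt)
                smp["DP"] = n_ref + n_alt
                smp["GQ"] = 99
                if n_alt > n_ref:
                    smp["GT"] = (1,)
                elif n_ref > n_alt:
                    smp["GT"] = (0,)
                else:
                    smp["GT"] = (None,)
            vf.write(rec)
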