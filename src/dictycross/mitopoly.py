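"""Mitochondrial protein-coding polymorphism catalog.

Classifies SNPs in CDS features as synonymous or nonsynonymous under a
configurable genetic code (mold/protozoan mitochondrial, NCBI table 4, by
default — e.g. TGA encodes Trp), computes per-kilobase densities, and a
within-species pN/pS with Nei-Gojobori-style site counting: each codon
position contributes the fraction of its three possible changes that are
synonymous, averaged over the reference CDS.  Changes creating a stop
codon count as nonsynonymous.  Indels are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = ["GeneModel", "PolymorphismRecord", "classify_variants",
           "ng86_sites", "pnps", "rank_genes", "catalog_to_frame"]

MOLD_MITO_TABLE = 4


@dataclass
class GeneModel:
    """A protein-coding gene on the mitochondrial contig.

    ``start``/``end`` are 0-based half-open genomic coordinates; ``seq`` is
    the genomic (plus-strand) CDS sequence — the coding strand is obtained
    by reverse complement when ``strand`` is '-'.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    seq: str
    excluded: bool = False  # e.g. homing endonuclease genes

    def coding_seq(self) -> str:
        s = self.seq.upper()
        return s if self.strand == "+" else str(Seq(s).reverse_complement())


@dataclass
class PolymorphismRecord:
    gene_id: str
    cds_len: int
    n_syn: int
    n_nonsyn: int
    syn_sites: float
    nonsyn_sites: float
    excluded: bool = False
    skipped: bool = False
    n_skipped_variants: int = 0

    @property
    def nonsyn_per_kb(self) -> float:
        return self.n_nonsyn / (self.cds_len / 1000.0)

    @property
    def syn_per_kb(self) -> float:
        return self.n_syn / (self.cds_len / 1000.0)

    @property
    def pn(self) -> float:
        return self.n_nonsyn / self.nonsyn_sites if self.nonsyn_sites else float("nan")

    @property
    def ps(self) -> float:
        return self.n_syn / self.syn_sites if self.syn_sites else float("nan")


def _code(table_id: int) -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[table_id]


def _translate(codon: str, table: CodonTable.CodonTable) -> str:
    if codon in table.stop_codons:
        return "*"
    return table.forward_table[codon]


def classify_variants(genes: list[GeneModel], variants: pd.DataFrame,
                      table_id: int = MOLD_MITO_TABLE,
                      blacklist: set[str] | None = None,
                      ) -> list[PolymorphismRecord]:
    """Per-gene synonymous/nonsynonymous variant counts.

    ``variants`` needs columns chrom, pos (0-based), ref, alt; each row is
    one variant event (expand multi-allelic sites to one row per alternate
    allele upstream).  Classification is strand-aware: minus-strand genes
    are classified on the coding strand.  Genes whose CDS length is not a
    multiple of 3 are flagged and skipped; variants falling in no gene are
    ignored; variants whose ref disagrees with the gene sequence are
    skipped and counted.
    """
    table = _code(table_id)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    blacklist = blacklist or set()
    records = []
    for gene in genes:
        excluded = gene.excluded or gene.gene_id in blacklist
        cds = gene.coding_seq()
        if len(cds) % 3 != 0:
            records.append(PolymorphismRecord(
                gene_id=gene.gene_id, cds_len=len(cds), n_syn=0, n_nonsyn=0,
                syn_sites=0.0, nonsyn_sites=0.0, excluded=excluded,
                skipped=True))
            continue
        syn_sites, nonsyn_sites = ng86_sites(cds, table_id)
        n_syn = n_nonsyn = n_skip = 0
        sub = variants[(variants["chrom"] == gene.chrom)
                       & (variants["pos"] >= gene.start)
                       & (variants["pos"] < gene.end)]
        for _, v in sub.iterrows():
            ref, alt = str(v["ref"]).upper(), str(v["alt"]).upper()
            if len(ref) != 1 or len(alt) != 1:
                n_skip += 1
                continue
            if gene.strand == "+":
                cpos = int(v["pos"]) - gene.start
                cref, calt = ref, alt
            else:
                cpos = gene.end - 1 - int(v["pos"])
                cref, calt = comp[ref], comp[alt]
            if cds[cpos] != cref:
                n_skip += 1
                continue
            ci = cpos // 3
            off = cpos % 3
            codon = cds[3 * ci:3 * ci + 3]
            mutant = codon[:off] + calt + codon[off + 1:]
            if _translate(codon, table) == _translate(mutant, table):
                n_syn += 1
            else:
                n_nonsyn += 1
        records.append(PolymorphismRecord(
            gene_id=gene.gene_id, cds_len=len(cds), n_syn=n_syn,
            n_nonsyn=n_nonsyn, syn_sites=syn_sites,
            nonsyn_sites=nonsyn_sites, excluded=excluded,
            n_skipped_variants=n_skip))
    return records


def ng86_sites(cds: str, table_id: int = MOLD_MITO_TABLE,
               ) -> tuple[float, float]:
    """Nei-Gojobori synonymous/nonsynonymous site counts of a CDS.

    Each codon position contributes (fraction of the 3 possible nucleotide
    changes that are synonymous) synonymous sites; changes to or from stop
    codons count as nonsynonymous.  A trailing stop codon is ignored;
    internal stop codons contribute no sites.
    """
    table = _code(table_id)
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in table.stop_codons:
        codons = codons[:-1]
    syn = 0.0
    total = 0
    for codon in codons:
        if codon in table.stop_codons:
            continue
        aa = _translate(codon, table)
        for off in range(3):
            n_syn_changes = 0
            for b in "ACGT":
                if b == codon[off]:
                    continue
                mutant = codon[:off] + b + codon[off + 1:]
                if mutant not in table.stop_codons and \
                        _translate(mutant, table) == aa:
                    n_syn_changes += 1
            syn += n_syn_changes / 3.0
        total += 3
    return syn, total - syn


def pnps(record: PolymorphismRecord) -> float:
    """pN/pS ratio; NaN (never infinity) when pS or its sites are zero."""
    pn, ps = record.pn, record.ps
    if not ps or ps != ps:  # zero or NaN
        return float("nan")
    return pn / ps


def catalog_to_frame(records: list[PolymorphismRecord]) -> pd.DataFrame:
    rows = [{
        "gene": r.gene_id, "cds_len": r.cds_len, "n_syn": r.n_syn,
        "n_nonsyn": r.n_nonsyn, "syn_per_kb": r.syn_per_kb,
        "nonsyn_per_kb": r.nonsyn_per_kb, "syn_sites": r.syn_sites,
        "nonsyn_sites": r.nonsyn_sites, "pn": r.pn, "ps": r.ps,
        "pnps": pnps(r), "excluded": r.excluded, "skipped": r.skipped,
        "n_skipped_variants": r.n_skipped_variants,
    } for r in records]
    return pd.DataFrame(rows)


def rank_genes(records: list[PolymorphismRecord]) -> pd.DataFrame:
    """Genes ranked by nonsynonymous density, with min-rank ties and
    percentile (share of ranked genes at or below each gene's density);
    excluded and skipped genes are omitted."""
    kept = [r for r in records if not r.excluded and not r.skipped]
    if not kept:
        raise ValueError("no genes to rank")
    df = catalog_to_frame(kept).sort_values(
        "nonsyn_per_kb", ascending=False).reset_index(drop=True)
    df["rank"] = df["nonsyn_per_kb"].rank(method="min", ascending=False).astype(int)
    df["percentile"] = 100.0 * df["nonsyn_per_kb"].rank(
        method="max", pct=True)
    return df
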