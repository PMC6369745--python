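"""Genome layout: chromosome coordinate system for telocentric genomes.

All coordinates are 0-based, half-open.  Centromeres sit at coordinate 0 of
every nuclear chromosome (telocentric convention), so "centromere-proximal"
always means the left half of a chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenomeLayout", "dicty_layout"]


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome sizes plus masked intervals excluded from analysis.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs for the nuclear chromosomes.
    masks
        ``(chrom, start, end)`` half-open intervals excluded from variant
        simulation and analysis (e.g. a mis-assembled duplication).
    mito
        Optional ``(name, length_bp)`` for the mitochondrial contig.
    extra_contigs
        Optional extrachromosomal elements, e.g. the rDNA palindrome or a
        nuclear plasmid, as ``(name, length_bp)`` pairs.
    """

    chromosomes: tuple[tuple[str, int], ...]
    masks: tuple[tuple[str, int, int], ...] = ()
    mito: tuple[str, int] | None = None
    extra_contigs: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        names = [c[0] for c in self.chromosomes]
        if len(names) != len(set(names)):
            raise ValueError("chromosome names must be unique")
        for name, length in self.all_contigs():
            if length <= 0:
                raise ValueError(f"contig {name!r} has non-positive length")
        lengths = dict(self.chromosomes)
        for chrom, start, end in self.masks:
            if chrom not in lengths:
                raise ValueError(f"mask on unknown chromosome {chrom!r}")
            if not (0 <= start < end <= lengths[chrom]):
                raise ValueError(f"mask ({chrom},{start},{end}) out of bounds")

    # -- accessors -----------------------------------------------------

    def all_contigs(self) -> tuple[tuple[str, int], ...]:
        out = list(self.chromosomes)
        if self.mito is not None:
            out.append(self.mito)
        out.extend(self.extra_contigs)
        return tuple(out)

    @property
    def nuclear_names(self) -> tuple[str, ...]:
        return tuple(c[0] for c in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.all_contigs())

    @property
    def total_nuclear_bp(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def masks_for(self, chrom: str) -> list[tuple[int, int]]:
        return [(s, e) for c, s, e in self.masks if c == chrom]

    def masked_bp(self, chrom: str) -> int:
        # masks may not overlap in practice; merge defensively
        ivals = sorted(self.masks_for(chrom))
        total, prev_end = 0, -1
        for s, e in ivals:
            s = max(s, prev_end)
            if e > s:
                total += e - s
                prev_end = e
        return total

    def unmasked_length(self, chrom: str) -> int:
        return dict(self.chromosomes)[chrom] - self.masked_bp(chrom)

    def is_masked(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Boolean mask-membership for an array of positions on one chromosome."""
        pos = np.asarray(pos)
        hit = np.zeros(pos.shape, dtype=bool)
        for s, e in self.masks_for(chrom):
            hit |= (pos >= s) & (pos < e)
        return hit


#: Approximate nuclear chromosome sizes (bp) of the *D. discoideum* AX4
#: assembly; ~34 Mb over six telocentric chromosomes.
_DICTY_CHROMS = (
    ("chr1", 4_923_596),
    ("chr2", 8_484_197),
    ("chr3", 6_357_299),
    ("chr4", 5_450_249),
    ("chr5", 5_125_352),
    ("chr6", 3_602_379),
)


def dicty_layout(
    with_mito: bool = True,
    with_rdna: bool = False,
    with_plasmid: bool = False,
    mask_chr2_duplication: bool = True,
) -> GenomeLayout:
    """Default six-chromosome social-amoeba layout (~34 Mb nuclear genome).

    The chr2 mask emulates the assembly duplication that is excluded from
    variant analysis; the mitochondrial contig is ~55.6 kb.
    """
    masks: tuple = ()
    if mask_chr2_duplication:
        masks = (("chr2", 2_600_000, 3_000_000),)
    extra = []
    if with_rdna:
        extra.append(("rDNA", 88_000))
    if with_plasmid:
        extra.append(("plasmid", 14_000))
    return GenomeLayout(
        chromosomes=_DICTY_CHROMS,
        masks=masks,
        mito=("mito", 55_564) if with_mito else None,
        extra_contigs=tuple(extra),
    )
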