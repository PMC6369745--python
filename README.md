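# dictycross

Genome-wide crossover mapping and organelle-inheritance analysis for
multi-parent crosses of social amoebae (*Dictyostelium discoideum*), with a
matched synthetic cross simulator.

## The problem

Sex in *D. discoideum* is unusual. Gamete fusion is promiscuous: several
cells can fuse into a transient syncytium before one zygote forms, walls
itself into a macrocyst, cannibalizes its neighbours, and undergoes meiosis.
Only one meiotic product survives per macrocyst, so the haploid progeny
clones germinating from one cyst are genetically identical. Meiotic
recombination is very frequent (roughly one crossover per megabase) despite
the lineage having lost Spo11, the transesterase that normally initiates
meiotic double-strand breaks. And because cytoplasm from more than two cells
mixes in the syncytium, a progeny clone can inherit nuclear DNA from two
parents and mitochondria from a third — triparental inheritance.

Quantifying all of this from whole-genome sequencing of parents and progeny
requires a chain of analyses: selecting parent-diagnostic variants from a
multi-sample VCF, assigning a parental origin along each haploid progeny
genome, segmenting those origins into haplotype blocks, localizing
crossovers, estimating the genetic map and its spatial biases, measuring
per-clone mitotype composition, and testing for lateral (third-parent)
contributions. `dictycross` implements that chain for geneticists working
with amoebozoan (or other haploid-progeny) crosses, plus a generative
simulator so every stage can be validated against known ground truth
without sequencing data.

## Models and statistics

**Haplotype segmentation.** A progeny chromosome is a sequence of origin
calls at ordered informative sites. The caller returns the partition into
parental blocks minimizing, lexicographically, (total discordant sites,
number of blocks), requiring every block to contain at least `min_support`
sites of its own parent; ties resolve to leftmost switches. The dynamic
program is verified in the test suite against an exhaustive search over
*every* segmentation of every 2-parent sequence up to length 15. A
crossover is the interval between the last supporting site of one block
and the first of the next.

**Genetic map.** With haploid products, each crossover is one recombination
event per meiosis, so a chromosome's genetic size over *n* progeny is
100 · (crossovers observed)/n centimorgans. Centromere-proximal bias
(centromeres at coordinate 0 of the telocentric chromosomes) and crossover
spacing (interference produces regular spacing; an interference-free class
produces close pairs < 50 kb) are tested with exact binomial statistics.
The G+C composition of crossover intervals is regressed on interval length
(OLS on intervals < 300 bp, quadratic loess over all); the y-intercept
estimates the base composition at true crossover points.

**Organelle inheritance.** Mitotype fractions are pooled read fractions at
mitotype-diagnostic sites; a clone is classified `predominant(p)` /
`near-equal` / `mixed` by thresholds on the top fraction, and lateral
transfer of third-parent mtDNA is a one-sided binomial test of third-parent
reads against a noise floor derived from the nuclear false-assignment rate.
Extrachromosomal elements (the rDNA palindrome, plasmids) are genotyped by
majority reads or relative coverage, and a genome scan reports chromosomal
intervals whose haplotype cosegregates perfectly with element genotype.

**Mitochondrial polymorphism.** CDS variants are classified
synonymous/nonsynonymous under the mold-mitochondrial genetic code (NCBI
table 4, configurable) and summarized as per-kb densities and pN/pS with
Nei–Gojobori site counting.

**Simulator.** Crossover counts are Poisson(rate × length); positions mix a
gamma-renewal interfering class (shape ν) with a uniform interference-free
class (probability `p_ni`), re-weighted so the proximal half carries mass
`w_prox` exactly and optionally thinned against local G+C. Mitotype
mixtures drift by Wright–Fisher multinomial resampling toward fixation.
Reads mis-assign parents at rate ε. One meiotic product survives per
simulated macrocyst; clones of a macrocyst share identical truth.

## Worked example

```python
from dictycross import dicty_layout, SimConfig, simulate_cross
from dictycross.crossovers import segment_progeny
from dictycross.recombstats import genetic_map, proximal_distal, spacing

layout = dicty_layout()                      # 6 chromosomes, ~34 Mb, chr2 mask
cfg = SimConfig(n_macrocysts=20, snp_density=1/5000, seed=1)
res = simulate_cross(layout, cfg)            # 20 haploid progeny clones
events, blocks = segment_progeny(res.obs, cfg.nuclear_parents)
gm = genetic_map(events, n_progeny=20, layout=layout)
prox = proximal_distal(events, layout)
sp = spacing(events)
```

This prints, via the obvious f-strings:

```
diagnostic sites: 6609
crossovers called: 658 in 20 progeny
total genetic map: 32.9 Morgans
chromosome sizes (cM): chr1=530, chr2=820, chr3=625, chr4=530, chr5=405, chr6=380
chromosomes with proximal excess: 6/6
close crossover pairs (<50 kb): 18/539
```

So this 20-progeny cohort recombines at ~1 crossover/Mb (32.9 Morgans over
~34 Mb), every chromosome has more crossovers in its centromere-proximal
half, and ~3% of consecutive crossover pairs fall within 50 kb — the
signature of a minor interference-free pathway.

The same analysis runs from the shell on real or simulated files
(multi-sample VCF + FASTA + BED), driven by a YAML config:

```bash
dictycross run --config config.yaml --seed 7 --outdir out/
```

which writes per-stage TSVs (`sites.tsv`, `blocks.tsv`, `crossovers.tsv`,
`genetic_map.tsv`, `mitotype_profiles.tsv`, ...) and a `report.yaml` with
provenance and per-module summaries.

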