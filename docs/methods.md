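# Methods

This note documents the generative models, estimators, and numerical
choices in `dictycross`, and what the simulation-based tests do and do not
demonstrate about real sequencing data.

## Coordinate conventions

All internal coordinates are 0-based, half-open; VCF is emitted and read
1-based. *D. discoideum* chromosomes are telocentric and the centromere is
placed at coordinate 0 of every nuclear chromosome, so "proximal" always
means the left half `[0, L/2)`. A BED mask (by default a 400-kb stand-in
for the mis-assembled chromosome-2 duplication) removes intervals from site
simulation and from every analysis stage. Genomic bins are half-open
`[start, start+size)`: a site at an exact boundary belongs to the
right-hand bin.

## The synthetic cross generator

The simulator is first-class, tested code: it defines the statistical
conditions under which the estimators are validated.

**Diagnostic sites.** Per contig, the site count is Poisson(density ×
unmasked length); positions are uniform outside masks with collisions
resolved by rejection. Each site is diagnostic for exactly one parent
(that parent carries ALT, the others REF). Defaults: 1 nuclear site per
5 kb (≈6,800 sites over 34 Mb — "thousands of informative sites") and
~110 mitochondrial sites over the 55.6-kb mito contig.

**Meiosis.** Per chromosome of length L, the crossover count is
Poisson(`xo_rate` · L/1 Mb) with `xo_rate` = 1/Mb by default. Each event
belongs to the non-interfering class with probability `p_ni` (default 0.1)
and is placed uniformly; interfering events are placed by normalized
Gamma(ν) spacings conditioned on the count (ν = 5). Because the spacings
are exchangeable, the aggregate marginal of positions is exactly uniform,
which makes the subsequent re-weighting well defined: each position is
accepted with probability proportional to a side weight (`w_prox` for the
proximal half, default 0.6) times, when `gc_beta` > 0, exp(−`gc_beta` ·
local G+C); rejected positions are redrawn from the discretized target
density. With `gc_beta` = 0 the proximal mass is therefore *exactly*
`w_prox`; redraws do, however, break the renewal structure, so tests that
require pure gamma spacing (exact noise-free round trips, interference
CV comparisons) set `w_prox` = 0.5. Only the two nuclear parents ever
contribute nuclear DNA; requesting the third parent as a nuclear donor is
a configuration error.

**Reference and G+C landscape.** When needed, a reference sequence is
synthesized from a windowed G+C profile (1-kb windows, clipped
Normal(0.25, 0.08) — low-G+C like the organism's genome); bases are drawn
i.i.d. within windows. The same profile drives placement thinning, so the
expected composition at crossover points has a closed-form oracle:
Σ gc·w / Σ w over windows with w = side-weight · exp(−β·gc).

**Organelles.** Each macrocyst's mitotype mixture starts at `theta0` and
drifts by `n_gen` rounds of multinomial resampling at size `n_eff`
(Wright–Fisher). The defaults — theta0 = (0.85, 0.15) two-way and
(0.75, 0.15, 0.10) three-way, `n_eff` = 30, `n_gen` = 60 — were chosen so
that residual heterozygosity ≈ exp(−n_gen/n_eff) = e⁻² leaves a minority
of macrocysts unfixed (near-equal or mixed) while most show a single
predominant mitotype, the qualitative pattern seen in real cohorts. The
true bottleneck size and timing in this system are unknown; this drift
model is one plausible generator, not a measurement. rDNA genotype can be
tied to a chromosomal template locus (`rdna_locus`) to exercise the
cosegregation scan; a plasmid contig can be marked so progeny carry only
residual (1%) coverage.

**Reads.** Depth per (site, clone) is Poisson(`depth_lambda`, default 20).
Each read supports the clone's true parent with probability 1−ε, else a
uniformly chosen wrong parent, whose allele it then shows (ε = 0.005).
Mitochondrial sites draw the supported parent from the clone's mitotype
fractions. Note the distinction between read-level ε and site-level error:
at depth 20 a majority vote is almost never wrong, so site-level noise is
far below ε; site-level error approaches ε only at depth 1.

**Determinism.** One master seed spawns independent child streams for
parents, meioses, mitotypes, and reads (`numpy` `SeedSequence`), so
identical configs give byte-identical outputs and stages are independently
reproducible. One meiotic product survives per macrocyst; clones of one
macrocyst share identical truth and differ only in reads.

## Variant ingestion

Diagnostic-site selection keeps biallelic SNPs at which every parent is
confidently homozygous (defaults: parent GQ ≥ 30, parent depth ≥ 10,
progeny depth thresholds configurable), parents are not all identical, and
the site lies outside masks. The exact thresholds used in any given
sequencing project belong in the YAML config; the defaults are
conventional, conservative stand-ins. The site's diagnostic parent is the
unique carrier of the minority allele, preferring the ALT carrier (in a
two-way cross both carriers are unique and the ALT labels the site).

Origin calls are majority votes on allelic depths; ties and
heterozygous-looking calls in haploid progeny are ambiguous and excluded
from tallies and segmentation rather than randomly broken — haploid clones
should not be heterozygous, so such sites are noise. At
third-parent-diagnostic sites a REF majority is ambiguous by construction
(both nuclear parents carry REF).

## Haplotype segmentation and crossover calling

The segmentation objective is: among partitions into blocks with
alternating parent labels in which every block contains at least
`min_support` (default 2) sites matching its own parent, minimize
lexicographically (total discordant sites, number of blocks); among
optima, take leftmost switch positions, then the lexicographically
smallest label sequence. This treats isolated discordant calls as the
mapping/calling noise they almost always are, while two adjacent
concordant sites suffice to detect a genuine double crossover.

Block boundaries of an optimal solution always coincide with boundaries of
runs of equal calls (moving a boundary within a run strictly changes the
discordant count whenever the run's label matches exactly one adjacent
block, and the leftmost rule settles the remaining case), so the dynamic
program works on the run-compressed sequence: a suffix table of optimal
(discordants, blocks) per (run, label), then a forward pass fixing each
switch as early as possible, then a label pass. The test suite proves the
implementation equal to an exhaustive search over *all* segmentations for
every 2-parent sequence of length ≤ 15 and property-tests longer random
sequences.

A crossover event spans (last supporting site of the left block, first
supporting site of the right block); no event is emitted before the first
or after the last informative site, where crossovers are undetectable by
design. Chromosomes with no parent reaching `min_support` return a single
majority block flagged `low_support`.

## Recombination statistics

- Genetic size: cM = 100 × events/n_progeny per chromosome; total Morgans
  is the cM sum / 100 (one crossover per meiosis = 100 cM = 1 M).
- Proximal/distal: event position = interval midpoint (an unbiased point
  estimate within the flanking interval); a midpoint exactly at L/2 counts
  distal. A two-sided exact binomial test against 0.5 is reported per
  chromosome.
- Spacing: distances between consecutive midpoints per progeny-chromosome;
  close pairs are < 50 kb. Chromosomes with < 2 events contribute nothing.
- Interval G+C: counted strictly between the flanking variant positions
  (the variant bases themselves are excluded — the crossover lies between
  informative sites); N bases are excluded from numerator and denominator,
  and empty intervals are flagged undefined.
- Composition bias: OLS of G+C on interval length over intervals < 300 bp
  (skipped with a warning below 3 points), reporting the y-intercept and
  99% CIs, plus a local quadratic (loess) smooth over all intervals with
  tricube weights and span 0.75. The local regression is implemented
  in-package because the required fit is degree-2; span and degree are
  arguments.

## Organelle analyses

Mitotype fractions pool supporting reads over each mitotype's own
diagnostic sites and divide by the pooled depth at those sites, then
normalize across mitotypes; pooling depth per mitotype makes the estimator
insensitive to how many diagnostic sites each mitotype happens to have
(with ~100 sites at depth 50 the standard error is ≈0.01). Classification
thresholds: predominant if the top fraction ≥ 0.8; near-equal if ≤ 0.6
(boundary inclusive); mixed between. The words are qualitative in origin,
so both thresholds are exposed in config and echoed in output; cohort
counts can shift slightly with them.

Lateral (triparental) mtDNA transfer is a one-sided binomial test of the
pooled third-parent read count against a noise floor, by default 3× the
nuclear false-assignment rate estimated from segmentation discordance of
control progeny — an in-silico analog of a "no third parent" control lane.
The third-parent *nuclear* scan is the same logic at
third-parent-diagnostic nuclear sites, Bonferroni-corrected across progeny
(few hypotheses, conservative).

The cosegregation scan reads each progeny's local haplotype off its block
segmentation at every informative site and classifies sites as supporting
(all progeny known and matching the element genotype, directly or under a
global label swap — element-to-parent phase is arbitrary) or contradicting
(all known, any mismatching). It reports maximal intervals containing at
least one supporting and no contradicting site, with bounds extending to
the nearest contradicting sites; unknown stretches (e.g. inside a
crossover interval) are tolerated, which is what lets the scan retain a
template locus that happens to fall between blocks in one clone. With all
progeny sharing one element genotype the scan is degenerate and flagged
uninformative. Plasmid presence is a coverage call (absent below 0.05× of
the sample's median nuclear coverage) because absence is the signal.

## Mitochondrial polymorphism

Variants in CDS features are classified codon-by-codon under NCBI
translation table 4 (mold/protozoan mitochondrial, where TGA reads through
as Trp), configurable; minus-strand genes are classified on the coding
strand, and classifying a gene and its reverse complement with flipped
strand gives identical counts. Sites are counted Nei–Gojobori style: each
codon position contributes the fraction of its three possible changes that
are synonymous; changes to or from stop codons count as nonsynonymous, a
trailing stop is ignored. pN/pS is flagged undefined (never infinite) when
synonymous sites or counts are zero. Indels and genes whose CDS length is
not a multiple of 3 are excluded with flags; multi-allelic sites count one
event per alternate allele; a configurable blacklist drops homing
endonuclease genes from rankings. Model-based (ML) dN/dS is out of scope —
the quantities of interest are simple densities and ratios.

## Pipeline

A single YAML config drives `simulate`, `analyze`, or `both`; `both`
round-trips through the standard formats (multi-sample VCF via pysam,
FASTA, BED, TSV truth tables), so the analysis path exercised on simulated
data is the same one used on real files. Outputs are per-stage TSVs plus a
`report.yaml` carrying a config hash, package version, seed, per-module
summaries, and warnings. Config errors (bad mode, role conflicts, missing
inputs) surface before any compute; the CLI distinguishes config (exit 2)
from data (exit 3) errors.

## Problem sizes and what the tests show

The acceptance-grade checks run at these sizes, chosen to give stable
statistics at desk scale: 200 progeny for map recovery (total map inside
the Monte-Carlo 99% interval [30.2, 36.8] M; ≥ 95% of true crossovers
inside their called interval) and proximal-bias recovery; 1,000 replicate
clones for the lateral-transfer classifier (≥ 99% sensitivity and
specificity at a 5% minor fraction vs zero); 60 progeny on a dense-marker
4-Mb genome for the G+C intercept (±0.02 of the placement-density oracle);
100 runs of 8 progeny for locus recovery by the cosegregation scan
(≥ 95%). `scripts/acceptance.py` uses 48, 60, and 42 progeny for its three
simulated cohorts.

Passing these tests shows the estimators are correct and well calibrated
*under the generator's assumptions*: Poisson crossover counts, uniform
site placement, independent Poisson depth, symmetric read mis-assignment,
homogeneous drift. Real sequencing data violate several of these —
mapping error clusters near repeats, depth is overdispersed and
GC-correlated, index hopping contaminates low-level heteroplasmy
estimates, and reference bias is asymmetric — so on real data the variant
filters and noise floors need to be set from the data (control lanes,
two-way crosses) rather than taken from these defaults. The drift
parameters shape the simulated mitotype cohort tables; cohort-level counts
are therefore illustrative of the analysis, not predictions about any real
cross.

## Known limitations

- No gene-conversion (non-crossover) detection; only crossovers are
  called, and a double crossover between adjacent informative sites is
  invisible.
- The segmentation objective is a design choice consistent with the
  observable block structure; other callers (e.g. HMMs) may localize
  boundaries differently within the same flanking interval.
- No genotype-likelihood modeling: origin calls are majority votes on
  allelic depths.
- No FASTQ simulation, read alignment, or primary variant calling; the
  pipeline consumes variant-level data.
- The formal interference model (gamma shape estimation) is deliberately
  omitted; only descriptive spacing statistics are reported.
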