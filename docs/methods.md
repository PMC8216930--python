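# Methods

## Coordinate and strand conventions

Genomes are stored linearized on the majority (J) strand, starting at
`trnM` with the A+T-rich region (NCR) last — the standard presentation for
lepidopteran mitogenomes. Coordinates are 1-based inclusive; any half-open
form is converted at the boundary. Minority-strand (N) features report
their *sense* sequence as the reverse complement of the J-strand slice.
Origin-spanning features are out of scope: the NCR runs exactly to the end
of the linearization, and the circular NCR→trnM junction is computed
separately from the linear intergenic profile rather than folded into the
overlap/spacer censuses.

The intergenic nucleotide count between adjacent genes is signed:
IGN(i) = from(i+1) − to(i) − 1. Negative values are overlaps (counted with
their magnitude), positive values are spacers, and zero means abutting
genes; zeros count in neither census. Blank cells in published gene tables
are treated as 0 — the only convention under which coordinates are exactly
recoverable from sizes plus IGN values (a bijection the test suite checks
on the three packaged architectures and on randomized annotations).

## Start/stop codon classification

Start codons are read as the first sense triplet and checked against the
whitelist {ATA, ATT, ATG, ATC, CGA}; CGA (the universal cox1 initiator in
these genomes) is treated as valid, and anything else is flagged rather
than rejected. The stop is read off the sequence length modulo 3: 0
requires a complete TAA/TAG, 1 a single trailing T, 2 a trailing TA —
incomplete stops being completed to TAA by polyadenylation in vivo.
Anomalies are returned as issue records, never exceptions, so a survey
over many genomes does not abort on one odd gene.

Gene sizes *include* incomplete stop nucleotides (matching how organization
tables are printed), while the pooled PCG sequence used for composition,
codon-position striping and codon counting *excludes* them. This is the
only convention that reconciles per-gene sizes with pooled PCG totals and
makes the pool divisible by 3: for the three skipper genomes,
11194/11206/11191 summed sizes minus one nucleotide per single-T stop
(cox1, cox2, nad5, nad4 in each genome) give 11190/11202/11187, i.e.
3730/3734/3729 codons.

## Composition and skew

AT-skew = (A − T)/(A + T) and GC-skew = (G − C)/(G + C), computed on raw
counts. Full-genome statistics use the J strand; PCG, tRNA and rRNA pools
use sense-strand sequences (codon columns are only meaningful on the sense
strand; pooling N-strand genes on the J strand would scramble
codon-position statistics). Whether published pooled tRNA/rRNA statistics
used sense or J-strand text is generally not stated; sense-strand is
chosen here and affects skew signs for minority-strand genes, not A+T
content. Percentages are rounded to one decimal and skews to three —
the usual print precision — with raw counts retained on the stats objects.
A region with no A+T (or no G+C) has an undefined skew, reported as NaN.

## RSCU

RSCU(c) = n(c) · |F| / Σ n(c′) over the codon's synonymous family F, so
values within a family with nonzero usage average to exactly 1. Families
follow the invertebrate mitochondrial code (translation table 5, via
Biopython) with the six-fold amino acids split by codon box: Leu1 = CUN,
Leu2 = UUR, Ser1 = AGN, Ser2 = UCN — 62 sense codons in 22 families.
Complete stop codons are tallied but excluded from families (standard
practice; publications rarely state this, so it is made explicit here),
and start codons are counted as ordinary codons since no special-casing is
ever reported. Internals are DNA-alphabet; the RNA alphabet (UUA) appears
only at report boundaries. Ranking ties break by raw count, then
alphabetically, making reports deterministic.

## A+T-rich region runs

A poly-run of base b is a maximal window that starts and ends on b,
contains at least `min_pure` copies of it (default 10), and is never
interrupted by more than `max_consecutive_interruptions` other bases in a
row (default 1). Equivalently: maximal clusters of b-blocks merged across
tolerably short gaps — which makes returned runs provably maximal and
mutually disjoint, and reduces to classical homopolymer detection at zero
allowed interruptions. The defaults are documented assumptions chosen so
that 16–22 bp poly-T and 12–24 bp T-interrupted poly-A stretches are
called as single runs while the ~90% A+T background of a control region is
not; both are tunable on the command line since the literature describes
ranges, not a detection rule. Conserved sequence motifs of the control
region are not modeled; only run statistics are computed.

## Supermatrix assembly

Schemes: PCG = 13 protein-coding genes, all codon positions; PRT = PCG
plus 22 tRNAs and 2 rRNAs; 12PRT = PRT minus all third codon positions,
giving the identity len(12PRT) = len(PRT) − len(PCG)/3. Genes concatenate
in the canonical gene order, taxa sort by identifier, and taxa missing a
gene are padded with `-` (configurable). Codon-position indexing is always
relative to each gene's own reading frame after incomplete-stop trimming,
never to supermatrix coordinates. Each protein-coding gene contributes
per-codon-position partitions (`gene_pos1 = a-b\3`, or `\2` striping after
third positions are removed); RNA genes contribute one partition each —
a finer scheme than some studies use, but one that downstream model
selection can always merge, whereas merged partitions cannot be split.
Column provenance (gene, source column, codon position) is tracked as a
bijection onto included columns. Alignment itself (MAFFT) and block
filtering (Gblocks) are external upstream steps; the module consumes
aligned FASTA and applies no trimming of its own.

## Synthetic genomes

The generator separates *architecture* from *content*. The architecture —
gene order, coordinates, strands, declared codons — is an input spec,
checked for internal consistency (monotone starts, stop completeness
matching size mod 3) and realized exactly; packaged specs replicate the
three skipper genomes at the coordinate level, so every architecture-
derived statistic is reproducible offline. Content is then filled in:

- Non-coding regions draw i.i.d. bases from per-region composition
  targets. The packaged targets are the published region percentages of
  each genome; profiles built from a single A+T fraction are available for
  controlled experiments (and parameter recovery holds within ±0.02 at
  15 kb, a binomial-sampling bound the tests check).
- Protein-coding genes are written codon-by-codon on the sense strand:
  declared start and stop codons are locked first across all genes, then
  interiors are sampled from a codon model with per-position base
  probabilities (the published codon-position compositions), restricted to
  sense codons — so no premature in-frame stop can occur.
- Overlaps are resolved by locking bases as written: protein-coding
  constraints take priority over RNA-gene content, and a later gene's
  codons are sampled conditional on already-locked bases. The rare case
  where sampled bases make an overlap unsatisfiable triggers a bounded,
  seed-deterministic retry; structurally contradictory specs raise a
  constraint error instead.
- The control region gets one planted poly-T run and one T-interrupted
  poly-A run (spans per genome chosen within the described 16–22 / 12–24
  bp ranges), after background stretches that the default detector would
  call are scrubbed — so run detection on replicas has a known answer.
- Codon usage can be enriched per codon; enrichment redistributes mass
  *within* each synonymous family while preserving the family's total, so
  RSCU rises without moving composition off its targets. Replicas enrich
  UUA/UCU/CGA five-fold within their families.

What the replicas do **not** emulate: real sequence content (only summary
composition), J/N strand compositional asymmetry (published tables give
only pooled sense-strand skews, so per-strand profiles are
underdetermined — replica full-genome GC-skew is therefore near zero
rather than strongly negative), tRNA secondary structure, and conserved
control-region motifs. Under the position-marginal codon model a two-fold
family codon like UUA cannot exceed RSCU 2, so replicas put UCU and CGA at
the top of the RSCU ranking but not UUA; the dedicated usage-recovery test
constructs a flat-composition profile where the enriched triple provably
leads. Passing tests on replicas therefore demonstrate correct
*arithmetic and conventions*, not agreement with deposited sequence data.

Aligned gene sets for supermatrix testing are generated by i.i.d.
substitution of each taxon from a shared random ancestor at per-site
probability d (to a uniformly chosen different base), giving expected
pairwise difference 2d(1 − d) + (2/3)d² — no tree structure, rate
heterogeneity or indels, which dataset assembly does not depend on.

## Problem sizes and determinism

All randomness flows through `numpy.random.default_rng` seeded from a
single user-supplied integer; identical seeds give byte-identical outputs
(GenBank records carry a fixed date for this reason). The analysis drivers
and the acceptance script synthesize three ~15.3 kb genomes and complete
in seconds; property suites use a few dozen to 1,000 randomized cases
each, sizes at which the checked identities are already exercised across
their full structural range.

## Known limitations

- Origin-spanning features are unsupported (v1 linearizes at trnM).
- GenBank reading maps labels through a synonym table and skips unknowns
  with a warning; ambiguous plain `trnL`/`trnS` labels without a codon-box
  qualifier are skipped rather than guessed.
- Ambiguity codes (N etc.) are rejected outright, since every composition
  formula here assumes a four-letter alphabet.
- Feature coordinates with to < from are rejected at construction (a type
  invariant); annotation-level validation reports missing genes, duplicate
  names, order violations and out-of-bounds ends without throwing.
- The published prose reports 11 overlapping regions for *A. virgata* and
  an overall 1–10 bp overlap size range; the coordinates of the
  corresponding gene table imply 10 overlaps and contain a 25 bp
  trnL1–rrnL overlap in *H. nephele*. This toolkit reports what the
  coordinates imply and documents the discrepancy rather than patching
  either number.
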