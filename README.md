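# mitoarch

A toolkit for comparative analysis of annotated circular mitochondrial
genomes, built around the three Aeromachini skipper butterflies *Ampittia
virgata* (15,333 bp), *Halpe nephele* (15,291 bp) and *Onryza maga*
(15,381 bp). It is aimed at researchers doing mitogenome descriptions and
mitogenome-based phylogenetics who want the standard comparative numbers —
the gene organization table, composition/skew statistics, codon usage, the
A+T-rich region structure, and concatenated phylogenetic datasets —
recomputed reproducibly from an annotation rather than assembled by hand.

## What it computes

Given a genome on its majority (J) strand and a 37-gene + NCR annotation
(13 protein-coding genes, 22 tRNAs, 2 rRNAs, and the noncoding A+T-rich
region) with 1-based inclusive coordinates:

- **Architecture** — gene sizes (to − from + 1), signed intergenic
  nucleotides IGN = from(i+1) − to(i) − 1 (negative = overlap, positive =
  spacer), overlap/spacer censuses, strand counts, start/stop codon
  classification including the incomplete `T`/`TA` stops completed by
  polyadenylation, and overlap junctions conserved across genomes.
- **Composition** — per-region base percentages, A+T content, and strand
  skews, AT-skew = (A − T)/(A + T), GC-skew = (G − C)/(G + C), for the
  full genome, the pooled sense-strand PCGs (incomplete stop nucleotides
  excluded), each codon position, the tRNA and rRNA pools, and the NCR.
- **Codon usage** — frame-0 codon counts and relative synonymous codon
  usage, RSCU(c) = n(c) · |F| / Σ_{c'∈F} n(c'), under the invertebrate
  mitochondrial code (table 5) with Leu and Ser split by codon box
  (Leu1 = CUN, Leu2 = UUR, Ser1 = AGN, Ser2 = UCN).
- **A+T-rich region** — poly-T / poly-A stretch detection as maximal
  interrupted homopolymer runs.
- **Supermatrices** — the three standard concatenated datasets: PCG (13
  protein-coding genes, all codon positions), PRT (PCG + 22 tRNAs + 2
  rRNAs) and 12PRT (PRT minus all third codon positions), with
  RAxML-style and NEXUS partition definitions.

A synthetic-data module generates annotated genomes realizing any
architecture spec — including exact replicas of the three skipper
architectures — so the whole pipeline runs offline with no downloads.
Protein-coding genes are synthesized codon-by-codon, so they carry their
declared start and stop codons and contain no premature in-frame stops.

## Worked example

```
$ mitoarch simulate --genome omaga --seed 2 --out work
MW288059_O_maga: 15381 bp written to work (seed=2)
$ mitoarch report work/MW288059_O_maga.gb --out work
MW288059_O_maga: 23 J / 14 N genes, 5 overlaps, 19 spacers
MW288059_O_maga: 15381 bp, A+T 79.0%
MW288059_O_maga: 3729 codons, top CGA,TCT,CCA
MW288059_O_maga: NCR 369 bp, 2 runs
```

The first line recovers the shared strand economy of these genomes (23
genes on the majority strand, 14 on the minority strand) and *O. maga*'s
five gene overlaps and nineteen intergenic spacers. The composition line
shows the strong A+T bias (~80%) typical of lepidopteran mitogenomes; the
codon line confirms that the 11,187 bp PCG pool divides into exactly 3,729
codons; and the control-region line reports the poly-T and interrupted
poly-A stretches. The TSV reports written to `work/` mirror the standard
mitogenome organization and composition tables row for row.

The numbered scripts under `analysis/` run the same stages over all three
genomes and write their tables under `results/`:

```
$ python analysis/01_simulate_replicas.py
$ python analysis/02_gene_architecture.py
MW288057_A_virgata: 23 J / 14 N genes | 10 overlaps (longest 10 bp at nad4-nad4L) | 13 spacers (longest 53 bp at trnQ-nad2)
MW288058_H_nephele: 23 J / 14 N genes | 8 overlaps (longest 25 bp at trnL1-rrnL) | 16 spacers (longest 78 bp at trnQ-nad2)
MW288059_O_maga: 23 J / 14 N genes | 5 overlaps (longest 8 bp at trnW-trnC) | 19 spacers (longest 77 bp at trnQ-nad2)
overlaps conserved in all three genomes: nad2-trnW, trnW-trnC, atp8-atp6, atp6-cox3
```

## Layout

- `src/mitoarch/` — the library: `model`, `architecture`, `composition`,
  `codon_usage`, `control_region`, `supermatrix`, `simulate`, `formats`,
  `cli`; packaged architecture specs under `src/mitoarch/data/`.
- `analysis/` — numbered drivers reproducing the comparative analysis.
- `tests/` — pytest suite (unit, hypothesis property tests, acceptance).
- `docs/methods.md` — models, conventions, parameter defaults, limitations.
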