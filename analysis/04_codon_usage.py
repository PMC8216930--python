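#!/usr/bin/env python
"""Codon usage and RSCU over the 13 pooled protein-coding genes.

Counts frame-0 codons of the sense-strand PCG pool (incomplete stops
trimmed, complete stops excluded from synonymous families) and reports
per-codon RSCU under the invertebrate mitochondrial code with Leu/Ser
split by codon box.
"""

from pathlib import Path

from mitoarch.codon_usage import count_codons, rscu, top_codons, usage_frame
from mitoarch.composition import trim_incomplete_stop
from mitoarch.formats import read_genbank, write_tsv
from mitoarch.model import sense_sequence
from mitoarch.simulate import REPLICA_KEYS

GENOMES = Path("results/genomes")
OUT = Path("results/codon_usage")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for key in REPLICA_KEYS:
        genome, annotation = read_genbank(GENOMES / f"{key}.gb")
        seqs = {f.name: trim_incomplete_stop(sense_sequence(genome, f))
                for f in annotation.pcgs}
        usage = count_codons(seqs)
        values = rscu(usage)
        write_tsv(usage_frame(usage), OUT / f"{key}.rscu.tsv", {"step": "04"})
        top = [(c.replace("T", "U"), round(values[c], 2))
               for c in top_codons(usage, 5)]
        print(f"{key}: {usage.total} codons; top RSCU {top}")


if __name__ == "__main__":
    main()
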