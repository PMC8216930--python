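#!/usr/bin/env python
"""Gene architecture: sizes, intergenic nucleotides, censuses, shared overlaps.

Reads the replica GenBank files written by 01_simulate_replicas.py and
recomputes the comparative organization table: per-gene sizes and signed
intergenic nucleotide (IGN) values, overlap/spacer censuses, strand counts,
and the overlap junctions conserved across all three genomes. The three
genomes share 23 majority-strand and 14 minority-strand genes and exactly
four conserved overlaps (nad2-trnW 2 bp, trnW-trnC 8 bp, atp8-atp6 7 bp,
atp6-cox3 1 bp).
"""

from pathlib import Path

import pandas as pd

from mitoarch.architecture import architecture_report, report_frame, shared_overlaps
from mitoarch.formats import read_genbank, write_tsv
from mitoarch.simulate import REPLICA_KEYS

GENOMES = Path("results/genomes")
OUT = Path("results/architecture")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    profiles = {}
    for key in REPLICA_KEYS:
        genome, annotation = read_genbank(GENOMES / f"{key}.gb")
        report = architecture_report(annotation)
        profiles[key] = report.profile
        write_tsv(report_frame(report), OUT / f"{key}.architecture.tsv",
                  {"tool": "mitoarch", "step": "02_gene_architecture"})
        c = report.census
        print(f"{key}: {report.j_count} J / {report.n_count} N genes | "
              f"{c.n_overlaps} overlaps (longest {-c.longest_overlap.ign} bp "
              f"at {c.longest_overlap.label}) | {c.n_spacers} spacers "
              f"(longest {c.longest_spacer.ign} bp at {c.longest_spacer.label})")
    shared = shared_overlaps(profiles)
    frame = pd.DataFrame([{"junction": j, **bp} for j, bp in shared.items()])
    write_tsv(frame, OUT / "shared_overlaps.tsv", {"step": "02"})
    print(f"overlaps conserved in all three genomes: {', '.join(shared)}")


if __name__ == "__main__":
    main()
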