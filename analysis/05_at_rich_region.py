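#!/usr/bin/env python
"""A+T-rich region structure: poly-T and poly-A stretches.

Extracts the control region of each replica and calls interrupted
homopolymer runs with the default rule (>= 10 pure bases, at most one
other base in a row). Each genome carries one poly-T stretch and one
T-interrupted poly-A stretch; spans fall in the 16-22 bp (poly-T) and
12-24 bp (poly-A) ranges.
"""

from pathlib import Path

from mitoarch.control_region import extract_ncr, find_poly_runs, runs_frame
from mitoarch.formats import read_genbank, write_tsv
from mitoarch.simulate import REPLICA_KEYS

GENOMES = Path("results/genomes")
OUT = Path("results/at_rich_region")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for key in REPLICA_KEYS:
        genome, annotation = read_genbank(GENOMES / f"{key}.gb")
        ncr = extract_ncr(genome, annotation)
        runs = find_poly_runs(ncr, "T") + find_poly_runs(ncr, "A")
        write_tsv(runs_frame(runs), OUT / f"{key}.runs.tsv", {"step": "05"})
        described = ", ".join(
            f"poly-{r.base} {r.length} bp ({r.interruptions} interruption"
            f"{'s' if r.interruptions != 1 else ''})" for r in runs)
        print(f"{key}: NCR {len(ncr)} bp | {described}")


if __name__ == "__main__":
    main()
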