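"""A+T-rich (control) region analysis: extraction and poly-A/poly-T runs.

Insect control regions carry a poly-T stretch and a (frequently
T-interrupted) poly-A stretch near the replication origin. A run here is a
maximal window that starts and ends on the run base, contains at least
``min_pure`` copies of it, and is never interrupted by more than
``max_consecutive_interruptions`` other bases in a row. With zero allowed
interruptions this reduces to classical homopolymer detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model import AnnotationTable, Genome, MitoError, sense_sequence

__all__ = ["PolyRun", "extract_ncr", "find_poly_runs", "runs_frame",
           "DEFAULT_MIN_PURE", "DEFAULT_MAX_INTERRUPTIONS"]

DEFAULT_MIN_PURE = 10
DEFAULT_MAX_INTERRUPTIONS = 1


@dataclass(frozen=True)
class PolyRun:
    """One detected run; positions are 1-based within the searched sequence."""

    base: str
    start: int
    end: int
    pure_count: int
    interruptions: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def extract_ncr(genome: Genome, annotation: AnnotationTable) -> str:
    """J-strand sequence of the annotated A+T-rich region."""
    return sense_sequence(genome, annotation.ncr)


def find_poly_runs(sequence: str, base: str, min_pure: int = DEFAULT_MIN_PURE,
                   max_consecutive_interruptions: int = DEFAULT_MAX_INTERRUPTIONS,
                   ) -> list[PolyRun]:
    """Maximal interrupted homopolymer runs of ``base``, left to right.

    Consecutive blocks of the run base are merged whenever the gap between
    them is at most ``max_consecutive_interruptions``; merged clusters are
    therefore maximal, mutually disjoint, and flanked by non-run context.
    Clusters with fewer than ``min_pure`` copies of the base are dropped.
    """
    if min_pure < 1:
        raise MitoError("min_pure must be >= 1")
    # locate maximal pure blocks of the run base
    blocks: list[tuple[int, int]] = []  # 0-based [start, end] inclusive
    i = 0
    while i < len(sequence):
        if sequence[i] == base:
            j = i
            while j + 1 < len(sequence) and sequence[j + 1] == base:
                j += 1
            blocks.append((i, j))
            i = j + 1
        else:
            i += 1
    # merge blocks separated by tolerably short gaps
    runs: list[PolyRun] = []
    k = 0
    while k < len(blocks):
        start, end = blocks[k]
        while (k + 1 < len(blocks)
               and blocks[k + 1][0] - end - 1 <= max_consecutive_interruptions):
            k += 1
            end = blocks[k][1]
        length = end - start + 1
        pure = sequence[start : end + 1].count(base)
        if pure >= min_pure:
            runs.append(PolyRun(base=base, start=start + 1, end=end + 1,
                                pure_count=pure, interruptions=length - pure))
        k += 1
    return runs


def runs_frame(runs: list[PolyRun]) -> pd.DataFrame:
    return pd.DataFrame([
        {"base": r.base, "start": r.start, "end": r.end, "length": r.length,
         "pure_count": r.pure_count, "interruptions": r.interruptions}
        for r in runs
    ], columns=["base", "start", "end", "length", "pure_count", "interruptions"])
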