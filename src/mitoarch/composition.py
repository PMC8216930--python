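"""Nucleotide composition, A+T content, and strand skew statistics.

AT-skew = (A - T) / (A + T); GC-skew = (G - C) / (G + C), computed on raw
counts (Perna-Kocher convention). Percentages are reported to one decimal
and skews to three, matching the usual print precision of mitogenome
composition tables; raw counts are retained on the stats object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .model import (
    AlphabetError, AnnotationTable, EmptyInputError, Genome,
    PCG, RRNA, TRNA, sense_sequence,
)

__all__ = [
    "RegionStats", "base_composition", "at_content", "region_stats",
    "pooled_pcg_sequence", "trim_incomplete_stop", "composition_frame",
    "REGION_LABELS",
]

REGION_LABELS = (
    "PCGs", "1st codon position", "2nd codon position", "3rd codon position",
    "NCR", "tRNAs", "rRNAs", "Full genome",
)


@dataclass(frozen=True)
class RegionStats:
    """Composition and skews for one named region."""

    region: str
    size: int
    counts: dict[str, int]

    @property
    def t_pct(self) -> float:
        return round(100 * self.counts["T"] / self.size, 1)

    @property
    def c_pct(self) -> float:
        return round(100 * self.counts["C"] / self.size, 1)

    @property
    def a_pct(self) -> float:
        return round(100 * self.counts["A"] / self.size, 1)

    @property
    def g_pct(self) -> float:
        return round(100 * self.counts["G"] / self.size, 1)

    @property
    def at_pct(self) -> float:
        return round(100 * (self.counts["A"] + self.counts["T"]) / self.size, 1)

    @property
    def at_skew(self) -> float:
        a, t = self.counts["A"], self.counts["T"]
        if a + t == 0:
            return math.nan
        return round((a - t) / (a + t), 3)

    @property
    def gc_skew(self) -> float:
        g, c = self.counts["G"], self.counts["C"]
        if g + c == 0:
            return math.nan
        return round((g - c) / (g + c), 3)


def base_composition(sequence: str, region: str = "sequence") -> RegionStats:
    """Composition stats for one sequence; rejects empty or ambiguous input."""
    if not sequence:
        raise EmptyInputError(f"{region}: empty sequence")
    counts = {b: sequence.count(b) for b in "TCAG"}
    if sum(counts.values()) != len(sequence):
        raise AlphabetError(f"{region}: sequence contains non-ACGT characters")
    return RegionStats(region=region, size=len(sequence), counts=counts)


def at_content(stats: RegionStats) -> float:
    """A% + T% at print precision."""
    return round(stats.a_pct + stats.t_pct, 1)


def trim_incomplete_stop(sense_seq: str) -> str:
    """Drop the trailing T / TA of a PCG with an incomplete stop codon.

    Leaves sequences whose length is already divisible by 3 untouched; the
    result is always frame-complete (length divisible by 3).
    """
    return sense_seq[: len(sense_seq) - len(sense_seq) % 3]


def pooled_pcg_sequence(genome: Genome, annotation: AnnotationTable) -> str:
    """All 13 PCG sense sequences concatenated, incomplete stops excluded.

    Genes are concatenated in annotation order; because each trimmed gene is
    frame-complete, codon positions stripe consistently across the pool.
    """
    return "".join(
        trim_incomplete_stop(sense_sequence(genome, f))
        for f in annotation.pcgs
    )


def region_stats(genome: Genome, annotation: AnnotationTable
                 ) -> dict[str, RegionStats]:
    """One RegionStats per standard region row.

    Full genome uses the J strand; PCG, tRNA and rRNA pools use sense-strand
    sequences; codon positions stripe the trimmed PCG pool.
    """
    out: dict[str, RegionStats] = {}
    pool = pooled_pcg_sequence(genome, annotation)
    if pool:
        out["PCGs"] = base_composition(pool, "PCGs")
        for k, label in enumerate(REGION_LABELS[1:4]):
            out[label] = base_composition(pool[k::3], label)
    try:
        ncr = annotation.ncr
        out["NCR"] = base_composition(sense_sequence(genome, ncr), "NCR")
    except Exception:
        pass  # missing region: row omitted
    for cls, label in ((TRNA, "tRNAs"), (RRNA, "rRNAs")):
        feats = annotation.of_class(cls)
        if feats:
            pooled = "".join(sense_sequence(genome, f) for f in feats)
            out[label] = base_composition(pooled, label)
    out["Full genome"] = base_composition(genome.sequence, "Full genome")
    return out


def composition_frame(stats: dict[str, RegionStats]) -> pd.DataFrame:
    """Composition table mirroring the standard region-stats layout."""
    rows = []
    for label in REGION_LABELS:
        if label not in stats:
            continue
        s = stats[label]
        rows.append({
            "region": label, "size_bp": s.size,
            "T_pct": s.t_pct, "C_pct": s.c_pct,
            "A_pct": s.a_pct, "G_pct": s.g_pct,
            "AT_pct": s.at_pct, "AT_skew": s.at_skew, "GC_skew": s.gc_skew,
        })
    return pd.DataFrame(rows)
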