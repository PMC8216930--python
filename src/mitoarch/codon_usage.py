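"""Codon counting and relative synonymous codon usage (RSCU).

RSCU(c) = count(c) * family_size / family_total, i.e. the observed count
divided by the mean count of the codon's synonymous family. Families follow
the invertebrate mitochondrial code with Leu and Ser split by codon box
(Leu1 = CUN, Leu2 = UUR, Ser1 = AGN, Ser2 = UCN). Complete stop codons are
tallied but excluded from families, so they carry no RSCU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .model import CodonTable, FrameError, invertebrate_mito_table

__all__ = ["CodonUsageTable", "count_codons", "rscu", "top_codons",
           "usage_frame", "to_rna"]


def to_rna(codon: str) -> str:
    """Display form: DNA internals -> RNA alphabet (TTA -> UUA)."""
    return codon.replace("T", "U")


@dataclass
class CodonUsageTable:
    """Codon counts over pooled sense-strand PCGs, with RSCU values."""

    counts: dict[str, int]
    table: CodonTable = field(default_factory=invertebrate_mito_table)
    rscu_values: dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def family_total(self, family: str) -> int:
        return sum(self.counts.get(c, 0) for c in self.table.family_members(family))


def count_codons(pcg_sense_sequences: dict[str, str],
                 codon_table: CodonTable | None = None) -> CodonUsageTable:
    """Frame-0 codon tally over trimmed PCG sense sequences.

    Every input must already be trimmed of its incomplete stop (length
    divisible by 3); a frame violation is reported naming the gene.
    """
    table = codon_table or invertebrate_mito_table()
    counts = {c: 0 for c in table.sense_codons}
    counts.update({c: 0 for c in sorted(table.stop_codons)})
    for gene, seq in pcg_sense_sequences.items():
        if len(seq) % 3:
            raise FrameError(
                f"{gene}: length {len(seq)} not divisible by 3 "
                "(trim the incomplete stop first)"
            )
        for i in range(0, len(seq), 3):
            counts[seq[i : i + 3]] += 1
    return CodonUsageTable(counts=counts, table=table)


def rscu(usage: CodonUsageTable) -> dict[str, float]:
    """Per-codon RSCU; families with zero total get NaN (undefined).

    Within any family with a nonzero total the values average to 1 exactly.
    """
    values: dict[str, float] = {}
    for family in usage.table.families:
        members = usage.table.family_members(family)
        total = usage.family_total(family)
        for codon in members:
            if total == 0:
                values[codon] = math.nan
            else:
                values[codon] = usage.counts.get(codon, 0) * len(members) / total
    usage.rscu_values = values
    return values


def top_codons(usage: CodonUsageTable, k: int) -> list[str]:
    """Codons ranked by RSCU (ties by count, then alphabetical), length <= k."""
    values = usage.rscu_values or rscu(usage)
    ranked = sorted(
        (c for c, v in values.items() if not math.isnan(v)),
        key=lambda c: (-values[c], -usage.counts.get(c, 0), c),
    )
    return ranked[: max(k, 0)]


def usage_frame(usage: CodonUsageTable) -> pd.DataFrame:
    """Report table: codon (RNA alphabet), family, count, RSCU."""
    values = usage.rscu_values or rscu(usage)
    rows = []
    for codon in usage.table.sense_codons:
        rows.append({
            "codon": to_rna(codon),
            "family": usage.table.family_of[codon],
            "count": usage.counts.get(codon, 0),
            "rscu": round(values[codon], 3) if not math.isnan(values[codon]) else float("nan"),
        })
    for codon in sorted(usage.table.stop_codons):
        rows.append({"codon": to_rna(codon), "family": "Stop",
                     "count": usage.counts.get(codon, 0), "rscu": float("nan")})
    return pd.DataFrame(rows)
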