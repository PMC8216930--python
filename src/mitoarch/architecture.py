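"""Gene-architecture arithmetic: sizes, intergenic nucleotides, censuses.

All quantities derive from 1-based inclusive coordinates. The intergenic
nucleotide (IGN) count between adjacent genes is signed: negative values
are overlaps, positive values are spacers, zero means abutting genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model import (
    NCR, PCG, AnnotationTable, ComparabilityError, GeneFeature,
    OrderError, START_CODON_WHITELIST, invertebrate_mito_table,
)

__all__ = [
    "Junction", "CodonClassification", "Census", "ArchitectureReport",
    "gene_size", "intergenic_profile", "circular_junction_ign",
    "overlap_spacer_census", "strand_census", "classify_codons",
    "internal_stops", "shared_overlaps", "architecture_report",
    "report_frame", "coordinates_from_profile",
]


@dataclass(frozen=True)
class Junction:
    """Adjacency between two genes with its signed IGN value."""

    left: str
    right: str
    ign: int

    @property
    def label(self) -> str:
        return f"{self.left}-{self.right}"


@dataclass(frozen=True)
class CodonClassification:
    start_codon: str
    stop_codon: str
    complete: bool
    issues: tuple[str, ...] = ()


@dataclass(frozen=True)
class Census:
    n_overlaps: int
    n_spacers: int
    longest_overlap: Junction | None
    longest_spacer: Junction | None
    total_overlap_bp: int
    total_spacer_bp: int


@dataclass(frozen=True)
class ArchitectureReport:
    """Per-genome architecture summary (the derived columns of a gene table)."""

    genome_id: str
    annotation: AnnotationTable
    profile: tuple[Junction, ...]
    census: Census
    j_count: int
    n_count: int


def gene_size(feature: GeneFeature) -> int:
    """Feature length in bp (inclusive coordinates: to - from + 1)."""
    return feature.end - feature.start + 1


def intergenic_profile(annotation: AnnotationTable) -> tuple[Junction, ...]:
    """Signed IGN for every adjacent pair, in gene order.

    IGN(i) = from(i+1) - to(i) - 1. Requires features sorted by start.
    """
    feats = annotation.features
    for a, b in zip(feats, feats[1:]):
        if b.start <= a.start:
            raise OrderError(
                f"{annotation.genome_id}: {b.name} not after {a.name}; "
                "sort the annotation by start coordinate first"
            )
    return tuple(
        Junction(a.name, b.name, b.start - a.end - 1)
        for a, b in zip(feats, feats[1:])
    )


def circular_junction_ign(annotation: AnnotationTable) -> Junction:
    """IGN across the origin, from the last feature back to the first."""
    first, last = annotation.features[0], annotation.features[-1]
    ign = first.start + annotation.genome_length - last.end - 1
    return Junction(last.name, first.name, ign)


def overlap_spacer_census(profile: tuple[Junction, ...]) -> Census:
    """Count overlaps (IGN < 0) and spacers (IGN > 0); zeros count in neither.

    Longest overlap/spacer ties break by first occurrence in gene order.
    """
    overlaps = [j for j in profile if j.ign < 0]
    spacers = [j for j in profile if j.ign > 0]
    longest_overlap = max(overlaps, key=lambda j: -j.ign, default=None)
    longest_spacer = max(spacers, key=lambda j: j.ign, default=None)
    return Census(
        n_overlaps=len(overlaps),
        n_spacers=len(spacers),
        longest_overlap=longest_overlap,
        longest_spacer=longest_spacer,
        total_overlap_bp=sum(-j.ign for j in overlaps),
        total_spacer_bp=sum(j.ign for j in spacers),
    )


def strand_census(annotation: AnnotationTable, gene_class: str | None = None
                  ) -> tuple[int, int]:
    """(J count, N count) over genes, excluding the NCR.

    Restrict to one class (e.g. tRNA) with ``gene_class``.
    """
    feats = [f for f in annotation.features if f.gene_class != NCR]
    if gene_class is not None:
        feats = [f for f in feats if f.gene_class == gene_class]
    j = sum(1 for f in feats if f.strand == "J")
    return j, len(feats) - j


def classify_codons(cds_sense_sequence: str) -> CodonClassification:
    """Start/stop classification of a sense-strand protein-coding sequence.

    The stop is read off the length modulo 3: remainder 0 requires a complete
    TAA/TAG final codon, remainder 1 a single trailing T, remainder 2 a
    trailing TA (both completed to TAA by polyadenylation in vivo).
    Anomalies are recorded as issue strings, never raised.
    """
    issues: list[str] = []
    if len(cds_sense_sequence) < 6:
        return CodonClassification("", "", False, ("sequence shorter than 6 nt",))
    start = cds_sense_sequence[:3]
    if start not in START_CODON_WHITELIST:
        issues.append(f"non-canonical start codon {start}")
    rem = len(cds_sense_sequence) % 3
    if rem == 0:
        stop = cds_sense_sequence[-3:]
        complete = True
        if stop not in ("TAA", "TAG"):
            issues.append(f"final codon {stop} is not a stop codon")
    elif rem == 1:
        stop = cds_sense_sequence[-1:]
        complete = False
        if stop != "T":
            issues.append(f"trailing base {stop} is not an incomplete T stop")
    else:
        stop = cds_sense_sequence[-2:]
        complete = False
        if stop != "TA":
            issues.append(f"trailing bases {stop} are not an incomplete TA stop")
    return CodonClassification(start, stop, complete, tuple(issues))


def internal_stops(cds_sense_sequence: str) -> tuple[int, ...]:
    """0-based codon indices of premature in-frame stops (final codon excluded)."""
    stops = invertebrate_mito_table().stop_codons
    n_codons = len(cds_sense_sequence) // 3
    last_full = n_codons - 1 if len(cds_sense_sequence) % 3 == 0 else n_codons
    return tuple(
        i for i in range(last_full)
        if cds_sense_sequence[3 * i : 3 * i + 3] in stops
    )


def shared_overlaps(profiles: dict[str, tuple[Junction, ...]]
                    ) -> dict[str, dict[str, int]]:
    """Junctions overlapping (IGN < 0) in every genome.

    Returns {junction label: {genome id: overlap bp}}. All profiles must
    share the same gene order.
    """
    if len(profiles) < 2:
        raise ComparabilityError("need at least two genomes to intersect overlaps")
    orders = [tuple(j.label for j in prof) for prof in profiles.values()]
    if any(o != orders[0] for o in orders):
        raise ComparabilityError("gene orders differ between genomes")
    shared: dict[str, dict[str, int]] = {}
    for idx, label in enumerate(orders[0]):
        igns = {gid: prof[idx].ign for gid, prof in profiles.items()}
        if all(v < 0 for v in igns.values()):
            shared[label] = {gid: -v for gid, v in igns.items()}
    return shared


def architecture_report(annotation: AnnotationTable) -> ArchitectureReport:
    profile = intergenic_profile(annotation)
    j, n = strand_census(annotation)
    return ArchitectureReport(
        genome_id=annotation.genome_id,
        annotation=annotation,
        profile=profile,
        census=overlap_spacer_census(profile),
        j_count=j,
        n_count=n,
    )


def report_frame(report: ArchitectureReport) -> pd.DataFrame:
    """Gene-table DataFrame mirroring the standard mitogenome organization table."""
    ign_by_right = {j.right: j.ign for j in report.profile}
    rows = []
    for feat in report.annotation.features:
        rows.append({
            "gene": feat.name,
            "class": feat.gene_class,
            "from": feat.start,
            "to": feat.end,
            "size": feat.size,
            "ign": ign_by_right.get(feat.name, pd.NA),
            "start_codon": feat.start_codon or "",
            "stop_codon": feat.stop_codon or "",
            "strand": feat.strand,
        })
    return pd.DataFrame(rows)


def coordinates_from_profile(first_start: int, sizes: list[int],
                             igns: list[int]) -> list[tuple[int, int]]:
    """Reconstruct (from, to) pairs from sizes + IGN values + first start.

    Inverse of ``intergenic_profile`` + ``gene_size``: from(i+1) =
    to(i) + IGN(i) + 1. ``igns`` has one fewer entry than ``sizes``.
    """
    if len(igns) != len(sizes) - 1:
        raise ComparabilityError("need exactly one IGN per adjacent pair")
    coords = []
    start = first_start
    for i, size in enumerate(sizes):
        end = start + size - 1
        coords.append((start, end))
        if i < len(igns):
            start = end + igns[i] + 1
    return coords
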