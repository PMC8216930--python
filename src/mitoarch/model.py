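"""Core domain types for annotated circular mitogenomes.

Coordinates are 1-based inclusive throughout, on the majority (J) strand,
with the genome linearized at trnM and the A+T-rich region (NCR) last —
the standard presentation for lepidopteran mitogenomes. Minority-strand
features carry strand ``N`` and their coding ("sense") sequence is the
reverse complement of the J-strand slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

from Bio.Data import CodonTable as _BioCodonTable
from Bio.Seq import Seq

__all__ = [
    "MitoError", "AlphabetError", "BoundsError", "OrderError", "FrameError",
    "MissingRegionError", "ConstraintError", "ComparabilityError",
    "DimensionError", "SpecError", "EmptyInputError",
    "Genome", "GeneFeature", "AnnotationTable", "CodonTable", "Issue",
    "PCG", "TRNA", "RRNA", "NCR", "GENE_CLASSES", "CANONICAL_ORDER",
    "PCG_NAMES", "TRNA_NAMES", "RRNA_NAMES", "START_CODON_WHITELIST",
    "canonical_gene_order", "sense_sequence", "validate_annotation",
    "reverse_complement", "invertebrate_mito_table",
]


class MitoError(Exception):
    """Base class for all toolkit errors."""


class AlphabetError(MitoError):
    """Sequence contains characters outside {A, C, G, T}."""


class BoundsError(MitoError):
    """Feature coordinates fall outside the genome."""


class OrderError(MitoError):
    """Features are not sorted by start coordinate."""


class FrameError(MitoError):
    """Coding sequence length is not compatible with a codon frame."""


class MissingRegionError(MitoError):
    """A required annotated region is absent."""


class ConstraintError(MitoError):
    """Sequence constraints (overlaps, codons) cannot be satisfied."""


class ComparabilityError(MitoError):
    """Cross-genome comparison attempted on incompatible annotations."""


class DimensionError(MitoError):
    """Ragged alignment or mismatched matrix dimensions."""


class SpecError(MitoError):
    """An architecture spec is internally inconsistent."""


class EmptyInputError(MitoError):
    """An operation received an empty sequence or collection."""


# ---------------------------------------------------------------------------
# gene naming

PCG = "PCG"
TRNA = "tRNA"
RRNA = "rRNA"
NCR = "NCR"

PCG_NAMES = (
    "nad2", "cox1", "cox2", "atp8", "atp6", "cox3", "nad3",
    "nad5", "nad4", "nad4L", "nad6", "cytb", "nad1",
)
TRNA_NAMES = (
    "trnM", "trnI", "trnQ", "trnW", "trnC", "trnY", "trnL2", "trnK",
    "trnD", "trnG", "trnA", "trnR", "trnN", "trnS1", "trnE", "trnF",
    "trnH", "trnT", "trnP", "trnS2", "trnL1", "trnV",
)
RRNA_NAMES = ("rrnL", "rrnS")

#: Lepidopteran gene order, linearized at trnM with the NCR last.
CANONICAL_ORDER = (
    "trnM", "trnI", "trnQ", "nad2", "trnW", "trnC", "trnY", "cox1",
    "trnL2", "cox2", "trnK", "trnD", "atp8", "atp6", "cox3", "trnG",
    "nad3", "trnA", "trnR", "trnN", "trnS1", "trnE", "trnF", "nad5",
    "trnH", "nad4", "nad4L", "trnT", "trnP", "nad6", "cytb", "trnS2",
    "nad1", "trnL1", "rrnL", "trnV", "rrnS", "NCR",
)

GENE_CLASSES = {name: PCG for name in PCG_NAMES}
GENE_CLASSES.update({name: TRNA for name in TRNA_NAMES})
GENE_CLASSES.update({name: RRNA for name in RRNA_NAMES})
GENE_CLASSES["NCR"] = NCR

#: Mitochondrial PCG initiators: the ATN family plus the cox1 CGA start.
START_CODON_WHITELIST = frozenset({"ATA", "ATT", "ATG", "ATC", "CGA"})

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def canonical_gene_order() -> tuple[str, ...]:
    """The fixed 38-entry lepidopteran gene order (37 genes + NCR)."""
    return CANONICAL_ORDER


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Genome:
    """A circular mitogenome stored on the majority (J) strand."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise AlphabetError(
                f"{self.id}: sequence contains non-ACGT characters "
                f"{sorted(bad)} (ambiguity codes are rejected)"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene (or the NCR), 1-based inclusive J-strand coordinates."""

    name: str
    gene_class: str
    start: int
    end: int
    strand: str
    start_codon: str | None = None
    stop_codon: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("J", "N"):
            raise SpecError(f"{self.name}: strand must be J or N, got {self.strand!r}")
        if not 1 <= self.start <= self.end:
            raise BoundsError(
                f"{self.name}: invalid coordinates {self.start}..{self.end}"
            )
        if self.gene_class not in (PCG, TRNA, RRNA, NCR):
            raise SpecError(f"{self.name}: unknown gene class {self.gene_class!r}")

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AnnotationTable:
    """Ordered gene list for one genome."""

    genome_id: str
    features: tuple[GeneFeature, ...]
    genome_length: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", tuple(self.features))

    def __iter__(self) -> Iterator[GeneFeature]:
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def get(self, name: str) -> GeneFeature:
        for feat in self.features:
            if feat.name == name:
                return feat
        raise MissingRegionError(f"{self.genome_id}: no feature named {name!r}")

    def of_class(self, gene_class: str) -> tuple[GeneFeature, ...]:
        return tuple(f for f in self.features if f.gene_class == gene_class)

    @property
    def pcgs(self) -> tuple[GeneFeature, ...]:
        return self.of_class(PCG)

    @property
    def trnas(self) -> tuple[GeneFeature, ...]:
        return self.of_class(TRNA)

    @property
    def rrnas(self) -> tuple[GeneFeature, ...]:
        return self.of_class(RRNA)

    @property
    def ncr(self) -> GeneFeature:
        regions = self.of_class(NCR)
        if not regions:
            raise MissingRegionError(f"{self.genome_id}: no NCR annotated")
        return regions[0]

    def sorted_by_start(self) -> "AnnotationTable":
        return replace(self, features=tuple(sorted(self.features, key=lambda f: f.start)))


# ---------------------------------------------------------------------------
# genetic code


@dataclass(frozen=True)
class CodonTable:
    """A genetic code plus the synonymous-family index used for RSCU.

    Families follow the convention of splitting the six-fold amino acids by
    codon box: Leu1 = CUN, Leu2 = UUR, Ser1 = AGN, Ser2 = UCN. Every sense
    codon belongs to exactly one family; stop codons belong to none.
    """

    table_id: int
    forward: dict[str, str] = field(repr=False)      # codon -> 1-letter aa
    stop_codons: frozenset[str] = field(repr=False)
    family_of: dict[str, str] = field(repr=False)    # codon -> family label

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(sorted(self.forward))

    def family_members(self, family: str) -> tuple[str, ...]:
        return tuple(sorted(c for c, f in self.family_of.items() if f == family))

    @property
    def families(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.family_of.values())))


_AA3 = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe", "G": "Gly",
    "H": "His", "I": "Ile", "K": "Lys", "L": "Leu", "M": "Met", "N": "Asn",
    "P": "Pro", "Q": "Gln", "R": "Arg", "S": "Ser", "T": "Thr", "V": "Val",
    "W": "Trp", "Y": "Tyr",
}


def invertebrate_mito_table() -> CodonTable:
    """The invertebrate mitochondrial genetic code (translation table 5)."""
    bio = _BioCodonTable.unambiguous_dna_by_id[5]
    family_of: dict[str, str] = {}
    for codon, aa in bio.forward_table.items():
        label = _AA3[aa]
        if aa == "L":
            label = "Leu2" if codon.startswith("TT") else "Leu1"
        elif aa == "S":
            label = "Ser1" if codon.startswith("AG") else "Ser2"
        family_of[codon] = label
    return CodonTable(
        table_id=5,
        forward=dict(bio.forward_table),
        stop_codons=frozenset(bio.stop_codons),
        family_of=family_of,
    )


# ---------------------------------------------------------------------------
# operations


def sense_sequence(genome: Genome, feature: GeneFeature) -> str:
    """Coding-strand sequence of a feature (reverse complement for strand N)."""
    if feature.end > genome.length:
        raise BoundsError(
            f"{feature.name}: end {feature.end} beyond genome length {genome.length}"
        )
    segment = genome.sequence[feature.start - 1 : feature.end]
    return reverse_complement(segment) if feature.strand == "N" else segment


@dataclass(frozen=True)
class Issue:
    """One validation finding; ``kind`` is a stable machine-readable label."""

    kind: str
    message: str


def validate_annotation(annotation: AnnotationTable) -> list[Issue]:
    """Check an annotation for completeness and internal consistency.

    Never raises; returns an empty list for a complete, consistent table.
    """
    issues: list[Issue] = []
    names = [f.name for f in annotation.features]
    seen: set[str] = set()
    for name in names:
        if name in seen:
            issues.append(Issue("duplicate", f"duplicate feature {name}"))
        seen.add(name)
    for required in CANONICAL_ORDER:
        if required not in seen:
            issues.append(Issue("missing", f"missing gene {required}"))
    prev = None
    for feat in annotation.features:
        if feat.end > annotation.genome_length:
            issues.append(
                Issue("bounds", f"{feat.name} ends at {feat.end} beyond "
                                f"genome length {annotation.genome_length}")
            )
        if prev is not None and feat.start <= prev.start:
            issues.append(
                Issue("order", f"{feat.name} start {feat.start} not after "
                               f"{prev.name} start {prev.start}")
            )
        if feat.gene_class == PCG:
            if feat.start_codon is None or feat.stop_codon is None:
                issues.append(
                    Issue("codon", f"{feat.name}: PCG lacks start/stop codon")
                )
            elif feat.stop_codon not in ("TAA", "TAG", "TA", "T"):
                issues.append(
                    Issue("codon", f"{feat.name}: invalid stop {feat.stop_codon!r}")
                )
        elif feat.start_codon is not None or feat.stop_codon is not None:
            issues.append(
                Issue("codon", f"{feat.name}: non-PCG carries codons")
            )
        prev = feat
    ncr_count = len(annotation.of_class(NCR))
    if ncr_count > 1:
        issues.append(Issue("duplicate", f"{ncr_count} NCR features (expected 1)"))
    return issues


def feature_from_row(name: str, gene_class: str, start: int, end: int,
                     strand: str, start_codon: str | None = None,
                     stop_codon: str | None = None) -> GeneFeature:
    """Convenience constructor normalizing '.'/'' placeholders to None."""
    norm = lambda v: None if v in (None, "", ".", "-") else v
    return GeneFeature(name, gene_class, start, end, strand,
                       norm(start_codon), norm(stop_codon))


def translate_codon(codon: str, table: CodonTable | None = None) -> str | None:
    """1-letter amino acid under table 5, or None for a stop codon."""
    table = table or invertebrate_mito_table()
    return table.forward.get(codon)


def _check_biopython_agreement() -> bool:  # pragma: no cover - sanity hook
    return str(Seq("ATA").translate(table=5)) == "M"
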