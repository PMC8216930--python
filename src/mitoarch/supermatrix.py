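"""Phylogenetic dataset assembly: PCG, PRT and 12PRT supermatrices.

Schemes: PCG = the 13 protein-coding genes, all codon positions; PRT = PCG
plus the 22 tRNAs and 2 rRNAs; 12PRT = PRT with every third codon position
of the protein-coding genes removed. Genes concatenate in canonical order,
taxa sort by identifier, and missing taxa are padded with gaps. Codon
position indexing is relative to each gene's own reading frame (after
incomplete-stop trimming), never to supermatrix coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .composition import trim_incomplete_stop
from .model import (
    CANONICAL_ORDER, AnnotationTable, DimensionError, EmptyInputError,
    FrameError, GENE_CLASSES, Genome, MissingRegionError, PCG, RRNA, TRNA,
    sense_sequence,
)

__all__ = [
    "GeneAlignment", "Partition", "Supermatrix", "SCHEMES",
    "extract_gene_set", "stripe_codon_positions", "build_dataset",
]

SCHEMES = ("PCG", "PRT", "12PRT")

_ORDER_INDEX = {name: i for i, name in enumerate(CANONICAL_ORDER)}


@dataclass(frozen=True)
class GeneAlignment:
    """One per-gene alignment: equal-length rows keyed by taxon."""

    gene: str
    rows: dict[str, str]
    gene_class: str = ""

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise DimensionError(f"{self.gene}: ragged alignment rows {sorted(lengths)}")
        if not self.gene_class:
            object.__setattr__(
                self, "gene_class", GENE_CLASSES.get(self.gene, PCG)
            )

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(sorted(self.rows))


@dataclass(frozen=True)
class Partition:
    """A named 1-based column range, optionally codon-striped.

    ``stride`` > 1 selects columns start, start+stride, ... up to end
    (RAxML ``start-end\\stride`` notation).
    """

    name: str
    start: int
    end: int
    stride: int = 1

    def columns(self) -> tuple[int, ...]:
        return tuple(range(self.start, self.end + 1, self.stride))


@dataclass
class Supermatrix:
    """Concatenated character matrix with partitions and column provenance."""

    scheme: str
    rows: dict[str, str]
    partitions: list[Partition]
    # per matrix column: (gene, 1-based column in the source gene alignment,
    # codon position 1/2/3 for PCGs else 0)
    provenance: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(sorted(self.rows))


def extract_gene_set(genomes: dict[str, tuple[Genome, AnnotationTable]],
                     gene_names: list[str] | None = None,
                     ) -> tuple[dict[str, dict[str, str]], list[tuple[str, str]]]:
    """Unaligned sense-strand sequences per gene across genomes.

    PCGs are trimmed of incomplete stop nucleotides. Returns
    ({gene: {taxon: sequence}}, [(taxon, gene) missing pairs]).
    """
    if gene_names is None:
        gene_names = [n for n in CANONICAL_ORDER if n != "NCR"]
    out: dict[str, dict[str, str]] = {g: {} for g in gene_names}
    missing: list[tuple[str, str]] = []
    for taxon, (genome, annotation) in genomes.items():
        for gene in gene_names:
            try:
                feat = annotation.get(gene)
            except MissingRegionError:
                missing.append((taxon, gene))
                continue
            seq = sense_sequence(genome, feat)
            if feat.gene_class == PCG:
                seq = trim_incomplete_stop(seq)
            out[gene][taxon] = seq
    return out, missing


def stripe_codon_positions(pcg_alignment: GeneAlignment
                           ) -> tuple[GeneAlignment, GeneAlignment, GeneAlignment]:
    """Split a frame-complete PCG alignment into its three codon positions."""
    if pcg_alignment.length % 3:
        raise FrameError(
            f"{pcg_alignment.gene}: alignment length {pcg_alignment.length} "
            "not divisible by 3"
        )
    subs = []
    for k in range(3):
        subs.append(GeneAlignment(
            gene=f"{pcg_alignment.gene}_pos{k + 1}",
            rows={t: s[k::3] for t, s in pcg_alignment.rows.items()},
            gene_class=pcg_alignment.gene_class or PCG,
        ))
    return tuple(subs)  # type: ignore[return-value]


def _gene_sort_key(gene: str) -> tuple[int, str]:
    return (_ORDER_INDEX.get(gene, len(CANONICAL_ORDER)), gene)


def _scheme_genes(gene_alignments: dict[str, GeneAlignment], scheme: str
                  ) -> list[GeneAlignment]:
    classes = {"PCG": (PCG,), "PRT": (PCG, TRNA, RRNA), "12PRT": (PCG, TRNA, RRNA)}
    if scheme not in classes:
        raise EmptyInputError(f"unknown scheme {scheme!r}; choose one of {SCHEMES}")
    keep = classes[scheme]
    selected = [a for a in gene_alignments.values() if a.gene_class in keep]
    if not selected:
        raise EmptyInputError(f"no gene alignments available for scheme {scheme}")
    return sorted(selected, key=lambda a: _gene_sort_key(a.gene))


def build_dataset(gene_alignments: dict[str, GeneAlignment], scheme: str,
                  gap_char: str = "-") -> Supermatrix:
    """Concatenate per-gene alignments into the requested dataset.

    Partitions: PCGs carry per-gene codon-position partitions (striped);
    tRNAs/rRNAs one partition per gene. For 12PRT the third positions are
    dropped and PCG partitions stripe with period 2.
    """
    genes = _scheme_genes(gene_alignments, scheme)
    taxa = sorted({t for a in genes for t in a.rows})
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    partitions: list[Partition] = []
    provenance: list[tuple[str, int, int]] = []
    offset = 0  # columns already emitted
    for aln in genes:
        is_pcg = aln.gene_class == PCG
        if is_pcg and aln.length % 3:
            raise FrameError(f"{aln.gene}: PCG alignment length {aln.length} "
                             "not divisible by 3")
        if is_pcg and scheme == "12PRT":
            keep_cols = [c for c in range(aln.length) if c % 3 != 2]
        else:
            keep_cols = list(range(aln.length))
        width = len(keep_cols)
        for taxon in taxa:
            row = aln.rows.get(taxon)
            if row is None:
                chunks[taxon].append(gap_char * width)
            else:
                chunks[taxon].append("".join(row[c] for c in keep_cols))
        for c in keep_cols:
            provenance.append((aln.gene, c + 1, (c % 3) + 1 if is_pcg else 0))
        if is_pcg:
            if scheme == "12PRT":
                partitions.append(Partition(f"{aln.gene}_pos1", offset + 1,
                                            offset + width, stride=2))
                partitions.append(Partition(f"{aln.gene}_pos2", offset + 2,
                                            offset + width, stride=2))
            else:
                for k in range(3):
                    partitions.append(Partition(f"{aln.gene}_pos{k + 1}",
                                                offset + 1 + k, offset + width,
                                                stride=3))
        else:
            partitions.append(Partition(aln.gene, offset + 1, offset + width))
        offset += width
    rows = {t: "".join(parts) for t, parts in chunks.items()}
    return Supermatrix(scheme=scheme, rows=rows, partitions=partitions,
                       provenance=provenance)
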