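"""Readers and writers for the formats the pipeline touches.

GenBank flatfiles and FASTA go through Biopython; the NCBI 5-column feature
table (TBL), RAxML-style partition text and TSV reports are written here.
Writer/reader pairs are lossless on the fields each format can carry.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .architecture import classify_codons
from .model import (
    AnnotationTable, DimensionError, GENE_CLASSES, GeneFeature, Genome,
    MitoError, NCR, PCG, RRNA, TRNA, sense_sequence,
)
from .supermatrix import Partition, Supermatrix

log = logging.getLogger("mitoarch")

__all__ = [
    "ParseError", "canonical_name", "read_genbank", "write_genbank",
    "write_feature_table", "read_feature_table", "read_fasta", "write_fasta",
    "write_alignment", "read_alignment", "write_partition_file", "write_tsv",
]


class ParseError(MitoError):
    """A file could not be parsed; the message carries the line number."""


# ---------------------------------------------------------------------------
# gene-name synonyms

_AA1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

_SYNONYMS = {
    "COX1": "cox1", "COI": "cox1", "CO1": "cox1", "COXI": "cox1",
    "COX2": "cox2", "COII": "cox2", "CO2": "cox2", "COXII": "cox2",
    "COX3": "cox3", "COIII": "cox3", "CO3": "cox3", "COXIII": "cox3",
    "CYTB": "cytb", "COB": "cytb", "CYB": "cytb",
    "ATP6": "atp6", "ATPASE6": "atp6", "ATP8": "atp8", "ATPASE8": "atp8",
    "RRNL": "rrnL", "16S": "rrnL", "16SRRNA": "rrnL", "LRRNA": "rrnL",
    "LSU": "rrnL", "16SRIBOSOMALRNA": "rrnL",
    "RRNS": "rrnS", "12S": "rrnS", "12SRRNA": "rrnS", "SRRNA": "rrnS",
    "SSU": "rrnS", "12SRIBOSOMALRNA": "rrnS",
    "DLOOP": "NCR", "CONTROLREGION": "NCR", "ATRICHREGION": "NCR",
    "A+TRICHREGION": "NCR", "NCR": "NCR",
}
for _i in (1, 2, 3, 4, 5, 6):
    _SYNONYMS[f"ND{_i}"] = f"nad{_i}"
    _SYNONYMS[f"NAD{_i}"] = f"nad{_i}"
    _SYNONYMS[f"NADH{_i}"] = f"nad{_i}"
    _SYNONYMS[f"NADHDEHYDROGENASESUBUNIT{_i}"] = f"nad{_i}"
_SYNONYMS.update({"ND4L": "nad4L", "NAD4L": "nad4L", "NADH4L": "nad4L"})
for _c in range(1, 4):
    _SYNONYMS[f"CYTOCHROMECOXIDASESUBUNIT{_c}"] = f"cox{_c}"

_TRNA_BOX = {"UUR": "trnL2", "CUN": "trnL1", "TTR": "trnL2", "CTN": "trnL1",
             "AGN": "trnS1", "UCN": "trnS2", "TCN": "trnS2"}


def canonical_name(label: str) -> str | None:
    """Map a GenBank gene/product label to its canonical name, or None."""
    raw = label.strip()
    squeezed = re.sub(r"[\s_\-]", "", raw).upper()
    if squeezed in _SYNONYMS:
        return _SYNONYMS[squeezed]
    if raw in GENE_CLASSES:
        return raw
    lowered = raw.lower()
    if lowered in {n.lower(): n for n in GENE_CLASSES}:
        return {n.lower(): n for n in GENE_CLASSES}[lowered]
    m = re.match(r"TRNA?([A-Z]{1,3})(\d?)(?:\((\w{3})\))?$", squeezed)
    if m:
        aa, digit, box = m.groups()
        if box and box in _TRNA_BOX:
            return _TRNA_BOX[box]
        one = _AA1.get(aa, aa if len(aa) == 1 else None)
        if one is None:
            return None
        name = f"trn{one}{digit}"
        return name if name in GENE_CLASSES else (f"trn{one}" if f"trn{one}" in GENE_CLASSES else None)
    return None


# ---------------------------------------------------------------------------
# GenBank

_CLASS_TO_GB = {PCG: "CDS", TRNA: "tRNA", RRNA: "rRNA", NCR: "misc_feature"}
_GB_TO_CLASS = {"CDS": PCG, "tRNA": TRNA, "rRNA": RRNA,
                "misc_feature": NCR, "D-loop": NCR}


def write_genbank(genome: Genome, annotation: AnnotationTable,
                  path: str | Path) -> None:
    """Minimal but valid flatfile: LOCUS / FEATURES / ORIGIN."""
    record = SeqRecord(Seq(genome.sequence), id=genome.id,
                       name=genome.id[:16].replace(" ", "_"),
                       description="mitochondrial genome")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if genome.circular else "linear"
    record.annotations["accessions"] = [genome.id]
    record.annotations["date"] = "01-JAN-2021"  # fixed: outputs stay byte-stable
    for feat in annotation.features:
        loc = FeatureLocation(feat.start - 1, feat.end,
                              strand=1 if feat.strand == "J" else -1)
        quals = {"gene": [feat.name]}
        if feat.gene_class == NCR:
            quals = {"note": ["A+T-rich region (control region)"]}
        record.features.append(SeqFeature(loc, type="gene", qualifiers=dict(quals))
                               if feat.gene_class != NCR else
                               SeqFeature(loc, type="misc_feature",
                                          qualifiers=dict(quals)))
        if feat.gene_class != NCR:
            record.features.append(
                SeqFeature(loc, type=_CLASS_TO_GB[feat.gene_class],
                           qualifiers=dict(quals)))
    SeqIO.write(record, str(path), "genbank")


def read_genbank(path: str | Path) -> tuple[Genome, AnnotationTable]:
    """Parse a flatfile; unmappable feature labels are skipped with a warning."""
    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if not record.seq or len(record.seq) == 0:
        raise ParseError(f"{path}: missing ORIGIN sequence")
    genome = Genome(id=record.id, sequence=str(record.seq).upper())
    feats: dict[str, GeneFeature] = {}
    for sf in record.features:
        if sf.type not in _GB_TO_CLASS:
            continue
        labels = (sf.qualifiers.get("gene", []) + sf.qualifiers.get("product", [])
                  + sf.qualifiers.get("note", []))
        name = None
        if sf.type in ("misc_feature", "D-loop"):
            joined = " ".join(labels).lower()
            if ("a+t" in joined or "control" in joined or "d-loop" in joined
                    or canonical_name(" ".join(labels) or "") == "NCR"):
                name = "NCR"
        else:
            for label in labels:
                name = canonical_name(label)
                if name:
                    break
        if name is None:
            log.warning("%s: skipping unmappable %s feature %r",
                        path, sf.type, labels[:1])
            continue
        start = int(sf.location.start) + 1
        end = int(sf.location.end)
        strand = "N" if sf.location.strand == -1 else "J"
        feat = GeneFeature(name=name, gene_class=_GB_TO_CLASS[sf.type],
                           start=start, end=end, strand=strand)
        if feat.gene_class == PCG:
            cls = classify_codons(sense_sequence(genome, feat))
            feat = GeneFeature(name=name, gene_class=PCG, start=start, end=end,
                               strand=strand, start_codon=cls.start_codon,
                               stop_codon=cls.stop_codon)
        feats[name] = feat  # CDS/tRNA/rRNA rows override bare gene rows
    ordered = tuple(sorted(feats.values(), key=lambda f: f.start))
    return genome, AnnotationTable(genome_id=genome.id, features=ordered,
                                   genome_length=genome.length)


# ---------------------------------------------------------------------------
# NCBI 5-column feature table

_TBL_PRODUCT = {PCG: "CDS", TRNA: "tRNA", RRNA: "rRNA", NCR: "misc_feature"}


def write_feature_table(annotation: AnnotationTable) -> str:
    """5-column TBL text; N-strand features emit reversed coordinate pairs."""
    lines = [f">Feature {annotation.genome_id}"]
    for feat in annotation.features:
        a, b = feat.start, feat.end
        if feat.strand == "N":
            a, b = b, a
        lines.append(f"{a}\t{b}\tgene")
        lines.append(f"\t\t\tgene\t{feat.name}")
        lines.append(f"{a}\t{b}\t{_TBL_PRODUCT[feat.gene_class]}")
        if feat.gene_class == NCR:
            lines.append("\t\t\tnote\tA+T-rich region")
    return "\n".join(lines) + "\n"


def read_feature_table(text: str, genome: Genome | None = None
                       ) -> AnnotationTable:
    """Parse TBL text back into an annotation.

    If the genome is supplied, PCG start/stop codons are re-derived from the
    sequence; otherwise they are left unset.
    """
    genome_id = ""
    feats: list[GeneFeature] = []
    pending: tuple[int, int, str, str] | None = None  # start, end, strand, type
    pending_name: str | None = None

    def flush() -> None:
        nonlocal pending, pending_name
        if pending is None:
            return
        start, end, strand, ftype = pending
        name = pending_name
        if ftype == "misc_feature" and name is None:
            name = "NCR"
        if name is not None and ftype != "gene":
            cls = {v: k for k, v in _TBL_PRODUCT.items()}[ftype]
            feat = GeneFeature(name=name, gene_class=cls, start=start, end=end,
                               strand=strand)
            if cls == PCG and genome is not None:
                c = classify_codons(sense_sequence(genome, feat))
                feat = GeneFeature(name=name, gene_class=cls, start=start,
                                   end=end, strand=strand,
                                   start_codon=c.start_codon,
                                   stop_codon=c.stop_codon)
            feats.append(feat)
        pending = None

    last_gene_name: str | None = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith(">Feature"):
            parts = line.split(maxsplit=1)
            genome_id = parts[1].strip() if len(parts) > 1 else ""
            continue
        if line.startswith("\t"):
            cols = line.split("\t")
            if len(cols) >= 5 and cols[3] == "gene":
                pending_name = cols[4].strip()
                if pending is not None and pending[3] == "gene":
                    last_gene_name = pending_name
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise ParseError(f"line {lineno}: expected 3 tab-separated columns")
        try:
            a, b = int(cols[0]), int(cols[1])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-numeric coordinates") from exc
        flush()
        strand = "J" if a <= b else "N"
        start, end = min(a, b), max(a, b)
        ftype = cols[2].strip()
        pending = (start, end, strand, ftype)
        pending_name = last_gene_name if ftype != "gene" else None
    flush()
    ordered = tuple(sorted(feats, key=lambda f: f.start))
    length = genome.length if genome is not None else (
        max((f.end for f in ordered), default=0))
    return AnnotationTable(genome_id=genome_id or (genome.id if genome else ""),
                           features=ordered, genome_length=length)


# ---------------------------------------------------------------------------
# FASTA / alignments / partitions


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_ALN_FORMATS = {"phylip": "phylip-relaxed", "phylip-relaxed": "phylip-relaxed",
                "nexus": "nexus", "fasta": "fasta"}


def write_alignment(matrix: Supermatrix | dict[str, str], path: str | Path,
                    dialect: str = "phylip") -> None:
    """Write a character matrix as relaxed PHYLIP, NEXUS or FASTA."""
    rows = matrix.rows if isinstance(matrix, Supermatrix) else matrix
    lengths = {len(s) for s in rows.values()}
    if len(lengths) > 1:
        raise DimensionError(f"ragged matrix rows: lengths {sorted(lengths)}")
    records = [SeqRecord(Seq(seq), id=taxon, description="",
                         annotations={"molecule_type": "DNA"})
               for taxon, seq in sorted(rows.items())]
    AlignIO.write(MultipleSeqAlignment(records), str(path),
                  _ALN_FORMATS[dialect])


def read_alignment(path: str | Path, dialect: str = "phylip") -> dict[str, str]:
    aln = AlignIO.read(str(path), _ALN_FORMATS[dialect])
    return {rec.id: str(rec.seq).upper() for rec in aln}


def write_partition_file(partitions: Iterable[Partition], path: str | Path,
                         dialect: str = "raxml") -> None:
    """RAxML-style (``DNA, name = a-b\\3``) or NEXUS sets-block partition text.

    An empty scheme produces an empty file with no header.
    """
    partitions = list(partitions)
    with open(path, "w") as fh:
        if not partitions:
            return
        if dialect == "raxml":
            for p in partitions:
                stripe = f"\\{p.stride}" if p.stride != 1 else ""
                fh.write(f"DNA, {p.name} = {p.start}-{p.end}{stripe}\n")
        elif dialect == "nexus":
            fh.write("#nexus\nbegin sets;\n")
            for p in partitions:
                stripe = f"\\{p.stride}" if p.stride != 1 else ""
                fh.write(f"    charset {p.name} = {p.start}-{p.end}{stripe};\n")
            fh.write("end;\n")
        else:
            raise MitoError(f"unknown partition dialect {dialect!r}")


def write_tsv(frame: pd.DataFrame, path: str | Path,
              header: dict[str, object] | None = None) -> None:
    """TSV report with ``# key=value`` provenance comment lines on top."""
    with open(path, "w") as fh:
        for key, value in (header or {}).items():
            fh.write(f"# {key}={value}\n")
        frame.to_csv(fh, sep="\t", index=False)
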