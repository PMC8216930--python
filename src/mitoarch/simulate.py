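"""Synthetic annotated mitogenomes with controlled statistical structure.

The generator fixes an architecture (gene order, coordinates, strands,
start/stop codons) and fills in sequence content: protein-coding genes are
built codon-by-codon from a codon-frequency model (so reading frames carry
their declared start, their declared complete or incomplete stop, and no
premature in-frame stop), RNA genes and the A+T-rich region draw bases from
per-region composition targets, and the A+T-rich region receives planted
poly-T and poly-A stretches. Overlap regions are resolved by locking bases
as they are written, with protein-coding codon constraints taking priority
over RNA-gene content.

Packaged architecture specs replicate the three Aeromachini skipper
mitogenomes (Ampittia virgata, Halpe nephele, Onryza maga) exactly at the
coordinate level, so every architecture-derived statistic is reproducible
offline; sequence content is synthetic and only matches the deposited
genomes in its summary composition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .architecture import classify_codons, internal_stops
from .composition import trim_incomplete_stop
from .control_region import find_poly_runs
from .model import (
    AnnotationTable, CANONICAL_ORDER, ConstraintError, GENE_CLASSES,
    GeneFeature, Genome, NCR, PCG, RRNA, SpecError, TRNA,
    feature_from_row, invertebrate_mito_table, sense_sequence,
)
from .supermatrix import GeneAlignment

__all__ = [
    "REPLICA_KEYS", "SynthProfile", "load_architecture_spec",
    "load_replica_profile", "replicate_architecture", "random_mitogenome",
    "random_annotation", "generate_aligned_genes", "resolve_replica_key",
]

REPLICA_KEYS = (
    "MW288057_A_virgata",
    "MW288058_H_nephele",
    "MW288059_O_maga",
)

_ALIASES = {
    "avirgata": REPLICA_KEYS[0], "a_virgata": REPLICA_KEYS[0],
    "mw288057": REPLICA_KEYS[0],
    "hnephele": REPLICA_KEYS[1], "h_nephele": REPLICA_KEYS[1],
    "mw288058": REPLICA_KEYS[1],
    "omaga": REPLICA_KEYS[2], "o_maga": REPLICA_KEYS[2],
    "mw288059": REPLICA_KEYS[2],
}

#: Codons whose within-family usage is boosted by default, emulating the
#: strong UUA / UCU / CGA preference of lepidopteran mitogenomes.
DEFAULT_ENRICHMENT = {"TTA": 5.0, "TCT": 5.0, "CGA": 5.0}

_BASES = np.array(list("TCAG"))


def resolve_replica_key(name: str) -> str:
    key = name.strip()
    if key in REPLICA_KEYS:
        return key
    low = key.lower().replace("-", "_").replace(".", "_")
    if low in _ALIASES:
        return _ALIASES[low]
    raise KeyError(f"unknown replica {name!r}; choose from {REPLICA_KEYS}")


def load_architecture_spec(key: str) -> AnnotationTable:
    """Packaged architecture spec (coordinates, strands, codons) by replica key."""
    key = resolve_replica_key(key)
    text = (resources.files("mitoarch") / "data" / f"{key}.tsv").read_text()
    length = None
    feats = []
    for line in text.splitlines():
        if line.startswith("#"):
            if "(" in line and "bp" in line and length is None:
                length = int(line.split("(")[1].split("bp")[0].replace(",", "").strip())
            continue
        if not line.strip() or line.startswith("gene\t"):
            continue
        name, cls, frm, to, strand, sc, st = line.split("\t")
        feats.append(feature_from_row(name, cls, int(frm), int(to), strand, sc, st))
    if length is None:
        length = max(f.end for f in feats)
    table = AnnotationTable(genome_id=key, features=tuple(feats),
                            genome_length=length)
    _check_spec(table)
    return table


def _check_spec(annotation: AnnotationTable) -> None:
    """Reject internally inconsistent architecture specs, naming the row."""
    prev = None
    for feat in annotation.features:
        if feat.end > annotation.genome_length:
            raise SpecError(f"{feat.name}: end {feat.end} beyond genome length")
        if prev is not None and feat.start <= prev.start:
            raise SpecError(f"{feat.name}: start {feat.start} not after {prev.name}")
        if feat.gene_class == PCG:
            if feat.start_codon is None or feat.stop_codon is None:
                raise SpecError(f"{feat.name}: PCG without start/stop codon")
            rem = feat.size % 3
            want = {0: ("TAA", "TAG"), 1: ("T",), 2: ("TA",)}[rem]
            if feat.stop_codon not in want:
                raise SpecError(
                    f"{feat.name}: size {feat.size} (mod 3 = {rem}) inconsistent "
                    f"with declared stop {feat.stop_codon!r}"
                )
        prev = feat


def _load_targets() -> dict:
    text = (resources.files("mitoarch") / "data" /
            "composition_targets.json").read_text()
    return json.loads(text)


@dataclass(frozen=True)
class SynthProfile:
    """Everything the generator needs besides a seed.

    ``region_targets`` maps region labels (genome, pcg_pos1..3, ncr, trna,
    rrna) to base percentages; ``ncr_runs`` gives the spans (bp) of the
    planted poly-T and poly-A stretches (poly-A carries one T interruption);
    ``codon_enrichment`` multiplies within-family codon weights.
    """

    annotation: AnnotationTable
    region_targets: dict[str, dict[str, float]]
    ncr_runs: dict[str, int] | None = None
    codon_enrichment: dict[str, float] = field(default_factory=dict)

    @classmethod
    def uniform(cls, annotation: AnnotationTable, at_fraction: float = 0.80,
                **kwargs) -> "SynthProfile":
        at, gc = 50 * at_fraction, 50 * (1 - at_fraction)
        comp = {"T": at, "C": gc, "A": at, "G": gc}
        targets = {label: dict(comp) for label in
                   ("genome", "pcg_pos1", "pcg_pos2", "pcg_pos3",
                    "ncr", "trna", "rrna")}
        return cls(annotation=annotation, region_targets=targets, **kwargs)


def load_replica_profile(key: str) -> SynthProfile:
    key = resolve_replica_key(key)
    spec = load_architecture_spec(key)
    entry = _load_targets()[key]
    return SynthProfile(
        annotation=spec,
        region_targets=entry["regions"],
        ncr_runs=dict(entry["ncr_runs"]),
        codon_enrichment=dict(DEFAULT_ENRICHMENT),
    )


# ---------------------------------------------------------------------------
# sequence synthesis

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _probs(target: dict[str, float]) -> np.ndarray:
    p = np.array([max(float(target[b]), 0.0) for b in "TCAG"])
    return p / p.sum()


class _SenseWriter:
    """Base-level access to a J-strand array through a feature's sense frame."""

    def __init__(self, seq: list[str], locked: bytearray):
        self.seq = seq
        self.locked = locked

    def j_index(self, feat: GeneFeature, offset: int) -> int:
        if feat.strand == "J":
            return feat.start - 1 + offset
        return feat.end - 1 - offset

    def read(self, feat: GeneFeature, offset: int) -> str:
        base = self.seq[self.j_index(feat, offset)]
        return base if feat.strand == "J" else _COMP[base]

    def is_locked(self, feat: GeneFeature, offset: int) -> bool:
        return bool(self.locked[self.j_index(feat, offset)])

    def write(self, feat: GeneFeature, offset: int, sense_base: str,
              lock: bool = True) -> None:
        idx = self.j_index(feat, offset)
        value = sense_base if feat.strand == "J" else _COMP[sense_base]
        if self.locked[idx] and self.seq[idx] != value:
            raise ConstraintError(
                f"{feat.name}: sense offset {offset} conflicts with a "
                f"previously locked base at position {idx + 1}"
            )
        self.seq[idx] = value
        if lock:
            self.locked[idx] = 1


def _codon_model(profile: SynthProfile) -> tuple[list[str], np.ndarray]:
    table = invertebrate_mito_table()
    p1 = _probs(profile.region_targets["pcg_pos1"])
    p2 = _probs(profile.region_targets["pcg_pos2"])
    p3 = _probs(profile.region_targets["pcg_pos3"])
    idx = {b: i for i, b in enumerate("TCAG")}
    codons = list(table.sense_codons)
    base = np.array([
        p1[idx[c[0]]] * p2[idx[c[1]]] * p3[idx[c[2]]] for c in codons
    ])
    # enrichment redistributes usage within each synonymous family but keeps
    # the family's total mass, so position marginals stay near their targets
    weights = base.copy()
    pos = {c: i for i, c in enumerate(codons)}
    for family in table.families:
        members = [pos[c] for c in table.family_members(family)]
        total = base[members].sum()
        if total <= 0:
            continue
        boosted = np.array([
            base[m] * profile.codon_enrichment.get(codons[m], 1.0)
            for m in members
        ])
        weights[members] = boosted * total / boosted.sum()
    return codons, weights


def _fill_pcg_interior(writer: _SenseWriter, feat: GeneFeature,
                       codons: list[str], weights: np.ndarray,
                       rng: np.random.Generator) -> None:
    tail = feat.size % 3
    stop_span = 3 if tail == 0 else tail
    interior_end = feat.size - stop_span  # exclusive
    for off in range(3, interior_end, 3):
        locked = [writer.read(feat, off + k) if writer.is_locked(feat, off + k)
                  else None for k in range(3)]
        mask = np.array([
            all(l is None or c[k] == l for k, l in enumerate(locked))
            for c in codons
        ])
        if not mask.any():
            raise ConstraintError(
                f"{feat.name}: no sense codon satisfies locked bases at "
                f"sense offset {off}"
            )
        w = weights * mask
        if w.sum() <= 0:
            w = mask.astype(float)
        choice = codons[rng.choice(len(codons), p=w / w.sum())]
        for k in range(3):
            writer.write(feat, off + k, choice[k])


def _plant_ncr_runs(seq: list[str], ncr: GeneFeature,
                    runs: dict[str, int]) -> None:
    start0 = ncr.start - 1
    length = ncr.size
    # Scrub background stretches the default detector would call, so the
    # planted runs are the only calls with >= 10 pure bases. A two-base
    # break defeats the single-interruption merge rule; breaking with the
    # complementary A/T base preserves the region's A+T content, with C/G
    # as a guaranteed-progress fallback for pathological backgrounds.
    other = {"A": "T", "T": "A"}
    for iteration in range(20):
        dirty = False
        for base in "AT":
            region = "".join(seq[start0 : start0 + length])
            for run in find_poly_runs(region, base, min_pure=9,
                                      max_consecutive_interruptions=1):
                mid = start0 + (run.start + run.end) // 2 - 1
                pair = (other[base], other[base]) if iteration < 5 else ("C", "G")
                seq[mid], seq[mid + 1] = pair
                dirty = True
        if not dirty:
            break
    poly_t, poly_a = int(runs["poly_t"]), int(runs["poly_a"])
    if length < poly_t + poly_a + 60:
        raise ConstraintError(
            f"NCR of {length} bp too short for planted runs "
            f"({poly_t} + {poly_a} bp)"
        )
    t0 = start0 + 25
    seq[t0 - 2 : t0] = ["G", "G"]
    seq[t0 : t0 + poly_t] = ["T"] * poly_t
    seq[t0 + poly_t : t0 + poly_t + 2] = ["G", "G"]
    a0 = start0 + length - 25 - poly_a
    seq[a0 - 2 : a0] = ["G", "G"]
    seq[a0 : a0 + poly_a] = ["A"] * poly_a
    seq[a0 + poly_a // 2] = "T"  # characteristic single-T interruption
    seq[a0 + poly_a : a0 + poly_a + 2] = ["G", "G"]


def _synthesize_once(profile: SynthProfile, rng: np.random.Generator) -> Genome:
    ann = profile.annotation
    L = ann.genome_length
    seq = list(rng.choice(_BASES, size=L,
                          p=_probs(profile.region_targets["genome"])))
    locked = bytearray(L)
    writer = _SenseWriter(seq, locked)
    # RNA genes and NCR: background from their region class target
    class_target = {TRNA: "trna", RRNA: "rrna", NCR: "ncr"}
    for feat in ann.features:
        if feat.gene_class == PCG:
            continue
        draws = rng.choice(_BASES, size=feat.size,
                           p=_probs(profile.region_targets[class_target[feat.gene_class]]))
        for off, base in enumerate(draws):
            writer.write(feat, off, str(base), lock=False)
    if profile.ncr_runs:
        _plant_ncr_runs(seq, ann.ncr, profile.ncr_runs)
    # PCG boundary constraints first (starts and stops across all genes) ...
    for feat in ann.pcgs:
        for k, base in enumerate(feat.start_codon):
            writer.write(feat, k, base)
        stop = feat.stop_codon
        for k, base in enumerate(stop):
            writer.write(feat, feat.size - len(stop) + k, base)
    # ... then interiors, sampled from the codon model under the locks
    codons, weights = _codon_model(profile)
    for feat in ann.pcgs:
        _fill_pcg_interior(writer, feat, codons, weights, rng)
        for off in range(feat.size):  # freeze the finished gene
            locked[writer.j_index(feat, off)] = 1
    return Genome(id=ann.genome_id, sequence="".join(seq))


def _verify(genome: Genome, annotation: AnnotationTable) -> None:
    for feat in annotation.pcgs:
        sense = sense_sequence(genome, feat)
        cls = classify_codons(sense)
        if cls.issues or cls.start_codon != feat.start_codon \
                or cls.stop_codon != feat.stop_codon:
            raise ConstraintError(
                f"{feat.name}: generated sequence classifies as "
                f"{cls.start_codon}/{cls.stop_codon} with issues {cls.issues}"
            )
        if internal_stops(trim_incomplete_stop(sense)):
            raise ConstraintError(f"{feat.name}: premature in-frame stop")


def random_mitogenome(profile: SynthProfile, seed: int
                      ) -> tuple[Genome, AnnotationTable]:
    """Deterministic synthesis of a genome realizing the profile's architecture.

    Retries with fresh draws if an overlap constraint happens to become
    unsatisfiable under the sampled bases; a profile whose constraints are
    structurally contradictory raises ``ConstraintError``.
    """
    _check_spec(profile.annotation)
    last_error: ConstraintError | None = None
    for attempt in range(10):
        rng = np.random.default_rng([int(seed) % (2**31), attempt])
        try:
            genome = _synthesize_once(profile, rng)
            _verify(genome, profile.annotation)
            return genome, profile.annotation
        except ConstraintError as exc:
            last_error = exc
    raise ConstraintError(
        f"could not satisfy sequence constraints after 10 attempts: {last_error}"
    )


def replicate_architecture(spec: str | AnnotationTable, seed: int,
                           ) -> tuple[Genome, AnnotationTable]:
    """Synthesize a genome whose architecture report equals the spec exactly.

    ``spec`` is a replica key (accession or species alias) or a full
    AnnotationTable; replica keys also carry their published composition
    targets and control-region run structure.
    """
    if isinstance(spec, str):
        profile = load_replica_profile(spec)
    else:
        _check_spec(spec)
        profile = SynthProfile.uniform(spec,
                                       codon_enrichment=dict(DEFAULT_ENRICHMENT))
    return random_mitogenome(profile, seed)


# ---------------------------------------------------------------------------
# random architectures and aligned gene sets


def random_annotation(seed: int | np.random.Generator,
                      genome_id: str = "synthetic") -> AnnotationTable:
    """A random but valid 37-gene + NCR annotation in canonical order.

    Gene sizes, intergenic spacers and overlaps vary within realistic
    lepidopteran ranges; strand assignment follows the canonical layout.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    strands = {f.name: f.strand
               for f in load_architecture_spec(REPLICA_KEYS[0]).features}
    feats: list[GeneFeature] = []
    start = 1
    prev_end = 0
    for name in CANONICAL_ORDER:
        cls = GENE_CLASSES[name]
        start_codon = stop_codon = None
        if cls == TRNA:
            size = int(rng.integers(60, 73))
        elif cls == RRNA:
            size = int(rng.integers(1300, 1401)) if name == "rrnL" \
                else int(rng.integers(730, 791))
        elif cls == NCR:
            size = int(rng.integers(320, 401))
        else:
            n_codons = int(rng.integers(60, 501))
            stop_codon = str(rng.choice(["TAA", "TAG", "T", "TA"]))
            size = 3 * n_codons + {"TAA": 0, "TAG": 0, "T": 1, "TA": 2}[stop_codon]
            start_codon = str(rng.choice(["ATA", "ATT", "ATG", "CGA"]))
        if feats:
            # PCG-PCG junctions never overlap here: deep overlaps can force a
            # stop codon into the neighbour's frame, which has no solution
            lo = -min(8, feats[-1].size - 1)
            if cls in (NCR,) or (cls == PCG and feats[-1].gene_class == PCG):
                lo = 0
            ign = int(rng.integers(lo, 61))
            start = prev_end + ign + 1
        end = start + size - 1
        feats.append(GeneFeature(name=name, gene_class=cls, start=start,
                                 end=end, strand=strands[name],
                                 start_codon=start_codon,
                                 stop_codon=stop_codon))
        prev_end = end
    return AnnotationTable(genome_id=genome_id, features=tuple(feats),
                           genome_length=prev_end)


def generate_aligned_genes(n_taxa: int, genes: dict[str, int],
                           divergence: float, seed: int
                           ) -> dict[str, GeneAlignment]:
    """Gap-free per-gene alignments of ``n_taxa`` rows by i.i.d. substitution.

    Each taxon derives from a shared random ancestor with per-site
    substitution probability ``divergence`` (to a uniformly chosen different
    base), so the expected pairwise difference between two taxa is
    2d(1-d) + (2/3)d^2. Gene classes resolve from canonical names; unknown
    names default to PCG.
    """
    if n_taxa < 2:
        raise ConstraintError("need at least two taxa")
    rng = np.random.default_rng(int(seed) % (2**31))
    taxa = [f"taxon{i + 1:02d}" for i in range(n_taxa)]
    out: dict[str, GeneAlignment] = {}
    for gene, length in genes.items():
        ancestor = rng.choice(_BASES, size=length,
                              p=np.array([0.4, 0.1, 0.4, 0.1]))
        rows = {}
        for taxon in taxa:
            derived = ancestor.copy()
            hits = rng.random(length) < divergence
            for i in np.nonzero(hits)[0]:
                others = [b for b in "TCAG" if b != derived[i]]
                derived[i] = others[int(rng.integers(3))]
            rows[taxon] = "".join(derived)
        out[gene] = GeneAlignment(
            gene=gene, rows=rows,
            gene_class=GENE_CLASSES.get(gene, PCG),
        )
    return out
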