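"""Supermatrix assembly: extraction, codon striping, dataset schemes."""

import numpy as np
import pytest

from mitoarch.model import FrameError, reverse_complement
from mitoarch.simulate import REPLICA_KEYS, generate_aligned_genes
from mitoarch.supermatrix import (
    GeneAlignment, build_dataset, extract_gene_set, stripe_codon_positions,
)

AV, HN, OM = REPLICA_KEYS


def toy_alignments():
    return {
        "gene1": GeneAlignment("gene1", {"t1": "ATGATG", "t2": "ATGATA"},
                               gene_class="PCG"),
        "gene2": GeneAlignment("gene2", {"t1": "ATGAAATTT", "t2": "ATGAAATTC"},
                               gene_class="PCG"),
        "trnA": GeneAlignment("trnA", {"t1": "ACGTA", "t2": "ACGTT"}),
    }


class TestExtractGeneSet:
    def test_nad2_across_replicas(self, replicas):
        genomes = {k: v for k, v in replicas.items()}
        seqs, missing = extract_gene_set(genomes, ["nad2"])
        assert missing == []
        assert {len(s) for s in seqs["nad2"].values()} == {1014}

    def test_incomplete_stop_trimmed(self, replicas):
        genomes = {k: v for k, v in replicas.items()}
        seqs, _ = extract_gene_set(genomes, ["cox1"])
        # printed size 1531 minus the single-T stop
        assert {len(s) for s in seqs["cox1"].values()} == {1530}

    def test_minority_strand_is_reverse_complement(self, replicas):
        genome, annotation = replicas[AV]
        feat = annotation.get("nad5")
        seqs, _ = extract_gene_set({AV: (genome, annotation)}, ["nad5"])
        j_slice = genome.sequence[feat.start - 1:feat.end]
        assert seqs["nad5"][AV] == reverse_complement(j_slice)[:-1]  # T stop off

    def test_missing_gene_recorded_not_fatal(self, replicas):
        from mitoarch.model import AnnotationTable
        genome, annotation = replicas[AV]
        pruned = AnnotationTable(
            annotation.genome_id,
            tuple(f for f in annotation.features if f.name != "nad3"),
            annotation.genome_length)
        genomes = {AV: (genome, pruned), HN: replicas[HN]}
        seqs, missing = extract_gene_set(genomes, ["nad3"])
        assert missing == [(AV, "nad3")]
        assert list(seqs["nad3"]) == [HN]


class TestStripeCodonPositions:
    def test_nine_columns_split_three_ways(self):
        aln = GeneAlignment("nad2", {"t1": "ATGAAATTT"}, gene_class="PCG")
        p1, p2, p3 = stripe_codon_positions(aln)
        assert p1.rows["t1"] == "AAT"
        assert p2.rows["t1"] == "TAT"
        assert p3.rows["t1"] == "GAT"

    def test_reinterleaving_is_identity(self):
        aln = GeneAlignment("nad2", {"t1": "ATGAAATTTCCC"}, gene_class="PCG")
        p1, p2, p3 = stripe_codon_positions(aln)
        rebuilt = "".join(a + b + c for a, b, c in zip(
            p1.rows["t1"], p2.rows["t1"], p3.rows["t1"]))
        assert rebuilt == aln.rows["t1"]

    def test_frame_error(self):
        with pytest.raises(FrameError):
            stripe_codon_positions(GeneAlignment("nad2", {"t1": "ATGA"},
                                                 gene_class="PCG"))


class TestBuildDataset:
    def test_scheme_lengths(self):
        genes = toy_alignments()
        pcg = build_dataset(genes, "PCG")
        prt = build_dataset(genes, "PRT")
        twelve = build_dataset(genes, "12PRT")
        assert pcg.length == 15
        assert prt.length == 20
        assert twelve.length == prt.length - pcg.length // 3 == 15

    def test_12prt_drops_third_positions(self):
        genes = {"gene1": GeneAlignment("gene1", {"t1": "ATGAAATTT"},
                                        gene_class="PCG")}
        matrix = build_dataset(genes, "12PRT")
        assert matrix.rows["t1"] == "ATAATT"  # positions 1+2 of each codon

    def test_missing_taxon_padded_with_gaps(self):
        genes = toy_alignments()
        genes["trnA"] = GeneAlignment("trnA", {"t1": "ACGTA"})
        matrix = build_dataset(genes, "PRT")
        part = next(p for p in matrix.partitions if p.name == "trnA")
        assert matrix.rows["t2"][part.start - 1:part.end] == "-----"
        assert "-" not in matrix.rows["t1"]

    def test_partitions_disjoint_and_covering(self):
        for scheme in ("PCG", "PRT", "12PRT"):
            matrix = build_dataset(toy_alignments(), scheme)
            seen = sorted(c for p in matrix.partitions for c in p.columns())
            assert seen == list(range(1, matrix.length + 1))

    def test_provenance_is_bijection(self):
        matrix = build_dataset(toy_alignments(), "12PRT")
        assert len(matrix.provenance) == matrix.length
        assert len(set(matrix.provenance)) == matrix.length
        # no third positions survive in 12PRT
        assert all(pos != 3 for _, _, pos in matrix.provenance)

    def test_deterministic_order(self):
        genes = toy_alignments()
        a = build_dataset(genes, "PRT")
        b = build_dataset(dict(reversed(list(genes.items()))), "PRT")
        assert a.rows == b.rows
        assert [p.name for p in a.partitions] == [p.name for p in b.partitions]

    def test_12prt_identity_on_random_gene_sets(self):
        rng = np.random.default_rng(17)
        for trial in range(10):
            genes = {}
            for g in range(int(rng.integers(2, 6))):
                length = 3 * int(rng.integers(2, 40))
                genes[f"gene{g}"] = GeneAlignment(
                    f"gene{g}",
                    {"t1": "A" * length, "t2": "C" * length},
                    gene_class="PCG")
            for t in range(int(rng.integers(0, 3))):
                length = int(rng.integers(50, 80))
                genes[f"trn{t}"] = GeneAlignment(
                    f"trn{t}", {"t1": "A" * length, "t2": "G" * length},
                    gene_class="tRNA")
            pcg = build_dataset(genes, "PCG")
            prt = build_dataset(genes, "PRT")
            twelve = build_dataset(genes, "12PRT")
            assert twelve.length == prt.length - pcg.length // 3


class TestGeneratedAlignmentsFeedIn:
    def test_four_taxa_toy_matrix(self):
        genes = generate_aligned_genes(4, {"gene1": 6, "gene2": 9},
                                       divergence=0.1, seed=3)
        matrix = build_dataset(genes, "PCG")
        assert matrix.length == 15 and len(matrix.taxa) == 4
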