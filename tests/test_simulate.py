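"""Synthetic genome generator: architecture fidelity, determinism, recovery."""

import numpy as np
import pytest

from mitoarch.architecture import classify_codons, internal_stops
from mitoarch.composition import base_composition, trim_incomplete_stop
from mitoarch.model import (AnnotationTable, GeneFeature, SpecError,
                            sense_sequence, validate_annotation)
from mitoarch.simulate import (
    REPLICA_KEYS, SynthProfile, generate_aligned_genes, load_architecture_spec,
    random_annotation, random_mitogenome, replicate_architecture,
    resolve_replica_key,
)

AV, HN, OM = REPLICA_KEYS

GENOME_LENGTHS = {AV: 15333, HN: 15291, OM: 15381}


class TestReplicateArchitecture:
    @pytest.mark.parametrize("key", [AV, HN, OM])
    def test_architecture_equals_spec(self, replicas, specs, key):
        genome, annotation = replicas[key]
        assert genome.length == GENOME_LENGTHS[key]
        assert annotation.features == specs[key].features

    def test_alias_resolution(self):
        assert resolve_replica_key("avirgata") == AV
        assert resolve_replica_key("MW288059") == OM
        with pytest.raises(KeyError):
            resolve_replica_key("nosuch")

    def test_generated_pcgs_classify_cleanly(self, replicas):
        for genome, annotation in replicas.values():
            for feat in annotation.pcgs:
                sense = sense_sequence(genome, feat)
                cls = classify_codons(sense)
                assert cls.issues == ()
                assert cls.start_codon == feat.start_codon
                assert cls.stop_codon == feat.stop_codon
                assert internal_stops(trim_incomplete_stop(sense)) == ()

    def test_seed_determinism(self):
        g1, _ = replicate_architecture(AV, seed=5)
        g2, _ = replicate_architecture(AV, seed=5)
        assert g1.sequence == g2.sequence

    def test_seed_changes_sequence_not_architecture(self, specs):
        g1, a1 = replicate_architecture(AV, seed=5)
        g2, a2 = replicate_architecture(AV, seed=6)
        assert g1.sequence != g2.sequence
        assert a1.features == a2.features == specs[AV].features

    def test_inconsistent_spec_rejected(self, specs):
        table = specs[AV]
        feats = list(table.features)
        bad = feats[3]  # nad2, complete TAA stop, size divisible by 3
        feats[3] = GeneFeature(bad.name, bad.gene_class, bad.start,
                               bad.end - 1, bad.strand, bad.start_codon,
                               bad.stop_codon)
        # shrinking a TAA-stopped gene by 1 bp breaks frame consistency ...
        with pytest.raises(SpecError, match="nad2"):
            replicate_architecture(
                AnnotationTable(table.genome_id, tuple(feats),
                                table.genome_length), seed=1)


class TestRandomAnnotation:
    def test_generator_output_validates_clean(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            assert validate_annotation(random_annotation(rng)) == []

    def test_deterministic_under_seed(self):
        assert random_annotation(4).features == random_annotation(4).features


class TestRandomMitogenome:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_at_fraction_recovered_at_15kb(self, seed, specs):
        profile = SynthProfile.uniform(specs[AV], at_fraction=0.80)
        genome, _ = random_mitogenome(profile, seed)
        assert genome.length == 15333
        stats = base_composition(genome.sequence)
        assert abs(stats.at_pct / 100 - 0.80) < 0.02

    def test_strand_census_follows_annotation(self):
        from mitoarch.architecture import strand_census
        profile = SynthProfile.uniform(random_annotation(8))
        _, annotation = random_mitogenome(profile, 8)
        assert strand_census(annotation) == (23, 14)


class TestAlignedGenes:
    def test_zero_divergence_identical_rows(self):
        genes = generate_aligned_genes(4, {"gene1": 60}, divergence=0.0, seed=2)
        rows = list(genes["gene1"].rows.values())
        assert all(r == rows[0] for r in rows)

    def test_deterministic(self):
        a = generate_aligned_genes(3, {"gene1": 50}, 0.1, seed=5)
        b = generate_aligned_genes(3, {"gene1": 50}, 0.1, seed=5)
        assert a["gene1"].rows == b["gene1"].rows

    def test_pairwise_divergence_matches_expectation(self):
        d, n = 0.1, 3000
        genes = generate_aligned_genes(2, {"gene1": n}, d, seed=13)
        r1, r2 = genes["gene1"].rows.values()
        diff = sum(a != b for a, b in zip(r1, r2)) / n
        expected = 2 * d * (1 - d) + (2 / 3) * d * d  # both taxa mutated
        sd = (expected * (1 - expected) / n) ** 0.5
        assert abs(diff - expected) < 4 * sd

    def test_gene_classes_resolve(self):
        genes = generate_aligned_genes(2, {"nad2": 30, "trnA": 60, "gene9": 9},
                                       0.05, seed=1)
        assert genes["nad2"].gene_class == "PCG"
        assert genes["trnA"].gene_class == "tRNA"
        assert genes["gene9"].gene_class == "PCG"


class TestSpecLoader:
    def test_all_replica_specs_load(self):
        for key in REPLICA_KEYS:
            table = load_architecture_spec(key)
            assert len(table.features) == 38
            assert validate_annotation(table) == []
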