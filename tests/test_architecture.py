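"""Architecture arithmetic against the published gene tables."""

import numpy as np
import pytest

from mitoarch.architecture import (
    circular_junction_ign, classify_codons, coordinates_from_profile,
    gene_size, intergenic_profile, internal_stops, overlap_spacer_census,
    shared_overlaps, strand_census,
)
from mitoarch.model import ComparabilityError, GeneFeature
from mitoarch.simulate import REPLICA_KEYS, random_annotation

AV, HN, OM = REPLICA_KEYS

# printed per-genome census expectations derived from the gene tables
CENSUS = {
    AV: dict(overlaps=10, spacers=13, longest_overlap=("nad4-nad4L", 10),
             longest_spacer=("trnQ-nad2", 53)),
    HN: dict(overlaps=8, spacers=16, longest_overlap=("trnL1-rrnL", 25),
             longest_spacer=("trnQ-nad2", 78)),
    OM: dict(overlaps=5, spacers=19, longest_overlap=("trnW-trnC", 8),
             longest_spacer=("trnQ-nad2", 77)),
}


class TestGeneSize:
    @pytest.mark.parametrize("start,end,size", [
        (250, 1263, 1014),     # nad2, A. virgata
        (5, 5, 1),             # single base
        (14241, 15012, 772),   # rrnS, O. maga
    ])
    def test_inclusive_size(self, start, end, size):
        assert gene_size(GeneFeature("nad2", "PCG", start, end, "J",
                                     "ATT", "TAA")) == size


class TestIntergenicProfile:
    def test_published_junction_values(self, specs):
        ign_av = {j.label: j.ign for j in intergenic_profile(specs[AV])}
        assert ign_av["atp8-atp6"] == -7
        assert ign_av["cox1-trnL2"] == 0       # abutting genes
        ign_om = {j.label: j.ign for j in intergenic_profile(specs[OM])}
        assert ign_om["trnM-trnI"] == 30
        assert ign_om["rrnL-trnV"] == 0

    def test_circular_junction_reported_separately(self, specs):
        table = specs[AV]
        wrap = circular_junction_ign(table)
        assert (wrap.left, wrap.right) == ("NCR", "trnM")
        assert wrap.ign == 0  # NCR runs to the origin, trnM starts at 1
        labels = [j.label for j in intergenic_profile(table)]
        assert "NCR-trnM" not in labels

    def test_sum_identity(self, specs):
        # sum(sizes) + sum(IGN) telescopes to the outer span
        for table in specs.values():
            sizes = sum(f.size for f in table.features)
            igns = sum(j.ign for j in intergenic_profile(table))
            outer = table.features[-1].end - table.features[0].start + 1
            assert sizes + igns == outer


class TestCensus:
    @pytest.mark.parametrize("key", [AV, HN, OM])
    def test_overlap_spacer_counts(self, specs, key):
        census = overlap_spacer_census(intergenic_profile(specs[key]))
        expect = CENSUS[key]
        assert census.n_overlaps == expect["overlaps"]
        assert census.n_spacers == expect["spacers"]
        label, bp = expect["longest_overlap"]
        assert (census.longest_overlap.label, -census.longest_overlap.ign) == (label, bp)
        label, bp = expect["longest_spacer"]
        assert (census.longest_spacer.label, census.longest_spacer.ign) == (label, bp)

    def test_all_zero_profile(self, specs):
        from mitoarch.architecture import Junction
        profile = (Junction("a", "b", 0), Junction("b", "c", 0))
        census = overlap_spacer_census(profile)
        assert (census.n_overlaps, census.n_spacers) == (0, 0)
        assert census.longest_overlap is None and census.longest_spacer is None


class TestStrandCensus:
    def test_23_J_and_14_N_genes(self, specs):
        for table in specs.values():
            assert strand_census(table) == (23, 14)

    def test_trna_strand_split(self, specs):
        for table in specs.values():
            assert strand_census(table, gene_class="tRNA") == (14, 8)

    def test_all_majority_toy(self):
        feats = tuple(
            GeneFeature(n, "tRNA", 10 * i + 1, 10 * i + 5, "J")
            for i, n in enumerate(["trnM", "trnI", "trnQ", "trnW", "trnC"])
        )
        from mitoarch.model import AnnotationTable
        assert strand_census(AnnotationTable("toy", feats, 100)) == (5, 0)


class TestClassifyCodons:
    def test_complete_orf(self):
        cls = classify_codons("ATG" + "AAA" * 4 + "TAA")
        assert (cls.start_codon, cls.stop_codon, cls.complete) == ("ATG", "TAA", True)
        assert cls.issues == ()

    def test_cox1_style_incomplete(self):
        seq = "CGA" + "AAA" * 4 + "T"  # length = 1 mod 3
        cls = classify_codons(seq)
        assert (cls.start_codon, cls.stop_codon, cls.complete) == ("CGA", "T", False)
        assert cls.issues == ()

    def test_tag_stop(self):
        cls = classify_codons("ATTAAATAG")
        assert (cls.start_codon, cls.stop_codon) == ("ATT", "TAG")

    def test_non_stop_final_codon_is_issue_not_exception(self):
        cls = classify_codons("ATGAAAGGG")
        assert any("not a stop codon" in msg for msg in cls.issues)

    def test_internal_stop_scan(self):
        assert internal_stops("ATGTAAAAATAA") == (1,)
        assert internal_stops("ATGAAAAAATAA") == ()


class TestSharedOverlaps:
    def test_four_conserved_overlaps(self, specs):
        profiles = {k: intergenic_profile(t) for k, t in specs.items()}
        shared = shared_overlaps(profiles)
        assert set(shared) == {"nad2-trnW", "trnW-trnC", "atp8-atp6", "atp6-cox3"}
        assert shared["trnW-trnC"] == {AV: 8, HN: 8, OM: 8}
        assert shared["nad2-trnW"] == {AV: 2, HN: 2, OM: 2}
        assert shared["atp8-atp6"] == {AV: 7, HN: 7, OM: 7}
        assert shared["atp6-cox3"] == {AV: 1, HN: 1, OM: 1}

    def test_self_comparison_idempotent(self, specs):
        profile = intergenic_profile(specs[AV])
        own = {j.label for j in profile if j.ign < 0}
        assert set(shared_overlaps({"a": profile, "b": profile})) == own

    def test_mismatched_orders_rejected(self, specs):
        profile = intergenic_profile(specs[AV])
        with pytest.raises(ComparabilityError):
            shared_overlaps({"a": profile, "b": profile[::-1]})


class TestCoordinateReconstruction:
    def test_bijection_on_published_tables(self, specs):
        for table in specs.values():
            sizes = [f.size for f in table.features]
            igns = [j.ign for j in intergenic_profile(table)]
            coords = coordinates_from_profile(table.features[0].start, sizes, igns)
            assert coords == [(f.start, f.end) for f in table.features]

    def test_bijection_on_random_annotations(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            table = random_annotation(rng)
            sizes = [f.size for f in table.features]
            igns = [j.ign for j in intergenic_profile(table)]
            coords = coordinates_from_profile(table.features[0].start, sizes, igns)
            assert coords == [(f.start, f.end) for f in table.features]
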