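import numpy as np
import pytest

from neopam.genome_io import ReferenceGenome, SomaticVariant, reverse_complement
from neopam.pam_discovery import (
    discover_sample,
    is_novel_pam,
    derive_protospacer,
    scan_indel_for_novel_pams,
    scan_snv_for_novel_pams,
)

from conftest import make_random_genome
from _oracles import snv_pam_oracle


def snv(contig, pos_1based, ref, alt, sample="s1"):
    return SomaticVariant(contig, pos_1based, ref, alt, "SNV", sample)


class TestScanSnv:
    def test_plus_strand_creation(self):
        # alt G at 1-based 22 next to the reference G at 23 creates T-G-G
        genome = ReferenceGenome({"c1": "CCCCCCCCCCCCCCCCCCCCTAGAA"})
        cands = scan_snv_for_novel_pams(snv("c1", 22, "A", "G"), genome)
        assert len(cands) == 1
        c = cands[0]
        assert c.strand == "+"
        assert (c.gg_start, c.n_position) == (21, 20)
        assert c.pam_3mer == "TGG"
        assert c.protospacer == "C" * 20
        assert c.is_novel

    def test_non_gc_alt_never_creates(self):
        genome = ReferenceGenome({"c1": "A" * 60})
        assert scan_snv_for_novel_pams(snv("c1", 30, "A", "T"), genome) == []

    def test_both_neighbours_emit_two_candidates(self):
        # GAG -> GGG: the left and the right dinucleotide are both new
        genome = ReferenceGenome({"c1": "A" * 21 + "GAG" + "A" * 21})
        cands = scan_snv_for_novel_pams(snv("c1", 23, "A", "G"), genome)
        assert len(cands) == 2
        assert {(c.gg_start, c.strand) for c in cands} == {(21, "+"), (22, "+")}

    def test_minus_strand_creation_matches_oracle(self):
        genome = ReferenceGenome({"c1": "TACTTAAAAAAAAAAAAAAAAAAAAAA"})
        var = snv("c1", 2, "A", "C")
        cands = scan_snv_for_novel_pams(var, genome)
        assert len(cands) == 1
        c = cands[0]
        assert (c.gg_start, c.strand) == (1, "-")
        assert c.pam_3mer == "AGG"
        # oracle-recomputed value: revcomp of 1-based positions 5-24
        assert c.protospacer == reverse_complement(genome.fetch("c1", 4, 24))
        assert c.protospacer == "TTTTTTTTTTTTTTTTTTTA"
        assert snv_pam_oracle(genome, var) == {(1, "-")}

    def test_rejects_non_snv(self, small_genome):
        with pytest.raises(ValueError):
            scan_snv_for_novel_pams(
                SomaticVariant("chr1", 50, "A", "AG", "INS"), small_genome
            )

    def test_short_flank_drops_candidate(self):
        # GG would form at the very contig start: no room for a protospacer
        genome = ReferenceGenome({"c1": "GA" + "T" * 40})
        assert scan_snv_for_novel_pams(snv("c1", 2, "A", "G"), genome) == []


class TestIsNovelPam:
    @pytest.mark.parametrize(
        "dinuc,strand,expected",
        [("AG", "+", True), ("GG", "+", False), ("CC", "-", False),
         ("AG", "-", True)],
    )
    def test_reference_dinucleotide_rule(self, dinuc, strand, expected):
        genome = ReferenceGenome({"c1": "T" * 10 + dinuc + "T" * 10})
        assert is_novel_pam(genome, "c1", 10, strand) is expected


class TestDeriveProtospacer:
    def test_plus_window(self):
        genome = ReferenceGenome({"c1": "CCCCCCCCCCCCCCCCCCCCTGGAA"})
        assert derive_protospacer(genome, "c1", 20, "+") == "C" * 20

    def test_minus_window(self):
        genome = ReferenceGenome({"c1": "TCCTAAAAAAAAAAAAAAAAAAAAAAA"})
        # N of the minus-strand PAM at plus coordinate 3
        assert derive_protospacer(genome, "c1", 3, "-") == reverse_complement(
            genome.fetch("c1", 4, 24)
        )

    def test_insufficient_flank_raises(self):
        genome = ReferenceGenome({"c1": "A" * 30})
        with pytest.raises(ValueError):
            derive_protospacer(genome, "c1", 10, "+")


class TestScanIndel:
    def test_insertion_creates_junction_gg(self):
        genome = ReferenceGenome({"c1": "T" * 25 + "G" + "A" * 25})
        var = SomaticVariant("c1", 26, "G", "GG", "INS", "s1")
        cands = scan_indel_for_novel_pams(var, genome)
        assert len(cands) == 1
        c = cands[0]
        assert c.strand == "+" and c.indel_derived
        assert c.gg_start == 25
        assert c.protospacer == genome.fetch("c1", 4, 24)

    def test_deletion_juxtaposes_gg(self):
        # ...AG [CTT deleted] GT... -> AG|GT junction forms GG
        genome = ReferenceGenome({"c1": "A" * 24 + "AG" + "CTT" + "GT" + "A" * 24})
        var = SomaticVariant("c1", 26, "GCTT", "G", "DEL", "s1")
        cands = scan_indel_for_novel_pams(var, genome)
        assert len(cands) == 1
        assert cands[0].strand == "+"
        assert cands[0].pam_3mer == "AGG"

    def test_neutral_insertion(self):
        genome = ReferenceGenome({"c1": "A" * 60})
        var = SomaticVariant("c1", 30, "A", "ATTTT", "INS", "s1")
        assert scan_indel_for_novel_pams(var, genome) == []

    def test_rejects_snv(self, small_genome):
        with pytest.raises(ValueError):
            scan_indel_for_novel_pams(snv("chr1", 50, "A", "G"), small_genome)


class TestDiscoverSample:
    def test_planted_fixture_recovered_exactly(self):
        from neopam.fixtures import FixtureSpec, generate

        bundle = generate(FixtureSpec(seed=1, n_pam_snvs_plus=5,
                                      n_pam_snvs_minus=5, n_neutral_snvs=90))
        result = discover_sample(bundle.variants, bundle.genome)
        found = {(c.contig, c.gg_start, c.strand) for c in result}
        planted = {(t.contig, t.gg_start, t.strand) for t in bundle.ground_truth}
        assert found == planted
        assert result.n_variants == 100
        assert result.n_variants_with_pam == 10
        proto = {(t.contig, t.gg_start, t.strand): t.protospacer
                 for t in bundle.ground_truth}
        for c in result:
            assert c.protospacer == proto[(c.contig, c.gg_start, c.strand)]

    def test_empty_input(self, small_genome):
        result = discover_sample([], small_genome)
        assert len(result) == 0 and result.n_variants == 0

    def test_duplicate_variants_deduplicate_with_provenance(self):
        genome = ReferenceGenome({"c1": "CCCCCCCCCCCCCCCCCCCCTAGAA"})
        var = snv("c1", 22, "A", "G")
        result = discover_sample([var, var], genome)
        assert len(result) == 1
        assert len(result.candidates[0].provenance) == 2


class TestDiscoveryProperties:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_oracle_equivalence_on_random_genomes(self, seed):
        """Scanner output equals the brute-force ref-vs-alt window diff."""
        genome = make_random_genome(seed=seed, length=20_000)
        rng = np.random.default_rng(seed + 1000)
        for _ in range(300):
            p = int(rng.integers(30, 20_000 - 30))
            ref = genome.fetch("chr1", p, p + 1)
            alt = "ACGT"[int(rng.integers(4))]
            if alt == ref:
                continue
            var = snv("chr1", p + 1, ref, alt)
            got = {(c.gg_start, c.strand)
                   for c in scan_snv_for_novel_pams(var, genome)}
            expected = {(g, s) for g, s in snv_pam_oracle(genome, var)}
            assert got == expected, f"disagreement for {var}"

    def test_strand_symmetry(self):
        """Mirrored genome + mirrored variants give mirrored candidates."""
        length = 5_000
        genome = make_random_genome(seed=9, length=length)
        mirrored = ReferenceGenome(
            {"chr1": reverse_complement(genome.sequence("chr1"))}
        )
        comp = dict(zip("ACGT", "TGCA"))
        rng = np.random.default_rng(99)
        flip = {"+": "-", "-": "+"}
        for _ in range(200):
            p = int(rng.integers(30, length - 30))
            ref = genome.fetch("chr1", p, p + 1)
            alt = "ACGT"[int(rng.integers(4))]
            if alt == ref:
                continue
            fwd = scan_snv_for_novel_pams(snv("chr1", p + 1, ref, alt), genome)
            mvar = snv("chr1", length - p, comp[ref], comp[alt])
            rev = scan_snv_for_novel_pams(mvar, mirrored)
            assert {(length - 2 - c.gg_start, flip[c.strand]) for c in fwd} == {
                (c.gg_start, c.strand) for c in rev
            }

    def test_snv_protospacer_occurs_in_reference(self):
        """For SNV candidates, tumour specificity is carried by the PAM
        alone: the protospacer exists verbatim in the reference."""
        from neopam.fixtures import FixtureSpec, generate

        bundle = generate(FixtureSpec(seed=4))
        plus_seq = bundle.genome.sequence("chr1")
        for c in discover_sample(bundle.variants, bundle.genome):
            probe = c.protospacer if c.strand == "+" else reverse_complement(
                c.protospacer
            )
            assert probe in plus_seq

    def test_no_emitted_candidate_is_non_novel(self):
        from neopam.fixtures import FixtureSpec, generate

        bundle = generate(FixtureSpec(seed=6, n_indel_pams=3))
        for c in discover_sample(bundle.variants, bundle.genome):
            assert c.is_novel
            if not c.indel_derived:
                assert is_novel_pam(bundle.genome, c.contig, c.gg_start, c.strand)
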