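import numpy as np
import pytest

from neopam.breakpoint_pam import (
    FLANK,
    Breakpoint,
    JunctionWindow,
    analyze_cohort_breakpoints,
    build_junction_window,
    detect_junction_pam,
    detect_spanning_guides,
    index_to_junction_pos,
    is_junction_pam_novel,
    junction_pos_to_index,
    load_breakpoints,
)
from neopam.genome_io import ReferenceGenome, reverse_complement

from conftest import make_random_genome
from _oracles import junction_oracle


def make_window(left, right, after_left="T", before_right="T"):
    """Window from explicit flanks (padded to 30 nt with A on the far side)."""
    left = left.rjust(FLANK, "A")
    right = right.ljust(FLANK, "A")
    bkp = Breakpoint("s1", "c1", 1000, "+", "c1", 2000, "+", "deletion")
    return JunctionWindow(bkp, left, right, after_left, before_right)


class TestCoordinateMapping:
    def test_round_trip_all_positions(self):
        positions = list(range(-FLANK, 0)) + list(range(1, FLANK + 1))
        indices = [junction_pos_to_index(p) for p in positions]
        assert indices == list(range(60))  # bijective, no position 0
        assert [index_to_junction_pos(i) for i in indices] == positions

    def test_invalid_positions_rejected(self):
        for bad in (0, 31, -31):
            with pytest.raises(ValueError):
                junction_pos_to_index(bad)
        with pytest.raises(ValueError):
            index_to_junction_pos(60)


class TestBuildJunctionWindow:
    def test_plain_deletion_flanks(self):
        genome = make_random_genome(seed=1, length=5_000)
        # junction joins c1:...1000] to c1:[2001... (1-based retained bases)
        bkp = Breakpoint("s1", "chr1", 1000, "+", "chr1", 2001, "+", "deletion")
        w = build_junction_window(bkp, genome)
        assert w.left == genome.fetch("chr1", 970, 1000)
        assert w.right == genome.fetch("chr1", 2000, 2030)
        assert w.native_after_left == genome.fetch("chr1", 1000, 1001)
        assert w.native_before_right == genome.fetch("chr1", 1999, 2000)
        assert w.joined == w.left + w.right

    def test_inverted_side_is_reverse_complemented(self):
        genome = make_random_genome(seed=2, length=5_000)
        bkp = Breakpoint("s1", "chr1", 1000, "+", "chr1", 3000, "-", "inversion")
        w = build_junction_window(bkp, genome)
        assert w.right == reverse_complement(genome.fetch("chr1", 2970, 3000))
        assert w.native_before_right == reverse_complement(
            genome.fetch("chr1", 3000, 3001)
        )

    def test_contig_end_padding(self):
        genome = ReferenceGenome({"c1": "ACGT" * 500})
        bkp = Breakpoint("s1", "c1", 10, "+", "c1", 100, "+", "deletion")
        with pytest.warns(UserWarning, match="padding"):
            w = build_junction_window(bkp, genome)
        assert w.left.startswith("N" * 20)
        assert len(w.left) == FLANK


class TestDetectJunctionPam:
    def test_gg_junction_yields_ngg_candidate(self):
        w = make_window("GTCCTAAGCGAGGAGAATGCATCAG", "GTTAAACC",
                        after_left="T", before_right="C")
        cands = detect_junction_pam(w)
        assert len(cands) == 1
        c = cands[0]
        assert c.motif == "NGG" and c.kind == "junction_pam"
        assert c.pam_position == -2
        assert c.grna == w.joined[8:28]
        assert (c.left_overlap, c.right_overlap) == (20, 0)

    def test_no_motif_no_candidate(self):
        assert detect_junction_pam(make_window("TTTTA", "TCCCC")) == []

    def test_cc_junction_yields_ccn_candidate(self):
        w = make_window("TTTTC", "CTTTT", after_left="A", before_right="G")
        cands = detect_junction_pam(w)
        assert len(cands) == 1
        c = cands[0]
        assert c.motif == "CCN"
        assert c.grna == reverse_complement(w.joined[32:52])
        assert (c.left_overlap, c.right_overlap) == (0, 20)

    def test_preexisting_context_suppresses_candidate(self):
        # wild-type continuation after the left flank is already G
        w = make_window("TTTTG", "GTTTT", after_left="G", before_right="C")
        assert detect_junction_pam(w) == []
        assert not is_junction_pam_novel(w, "NGG")

    def test_n_at_junction_gives_no_call(self):
        bkp = Breakpoint("s1", "c1", 1000, "+", "c1", 2000, "+", "deletion")
        w = JunctionWindow(bkp, "A" * 29 + "N", "G" * 30, "T", "T")
        assert detect_junction_pam(w) == []


class TestNoveltyRule:
    @pytest.mark.parametrize(
        "after_left,before_right,expected",
        [("T", "C", True), ("G", "C", False), ("T", "G", False),
         ("G", "G", False)],
    )
    def test_gg_novelty(self, after_left, before_right, expected):
        w = make_window("TTTTG", "GTTTT", after_left, before_right)
        assert is_junction_pam_novel(w, "NGG") is expected


class TestSpanningGuides:
    def test_ngg_with_n_at_plus6(self):
        # N at +6 => guide spans −15…+5: overlaps (15, 5)
        right = "TCTTA" + "TGG" + "T" * 22  # N of the PAM at +6
        w = make_window("ATCGATCGATCGATCGATCG", right)
        cands = [c for c in detect_spanning_guides(w) if c.motif == "NGG"]
        assert len(cands) == 1
        c = cands[0]
        assert c.pam_position == 6
        assert (c.left_overlap, c.right_overlap) == (15, 5)
        assert len(c.grna) == 20

    def test_ngg_with_n_at_plus16(self):
        right = ("T" * 15 + "AGG" + "T" * 12)
        w = make_window("ATCGATCGATCGATCGATCG", right)
        cands = [c for c in detect_spanning_guides(w) if c.motif == "NGG"]
        assert any((c.left_overlap, c.right_overlap) == (5, 15) for c in cands)

    def test_no_g_or_c_in_ranges_gives_empty(self):
        w = make_window("T" * 25, "T" * 25)
        assert detect_spanning_guides(w) == []

    def test_every_guide_satisfies_geometry(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            joined = "".join("ACGT"[i] for i in rng.integers(0, 4, size=60))
            w = make_window(joined[:30], joined[30:])
            for c in detect_spanning_guides(w):
                assert len(c.grna) == 20
                assert c.left_overlap >= 4 and c.right_overlap >= 4
                assert c.left_overlap + c.right_overlap == 20

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_60mer_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(250):
            joined = "".join("ACGT"[i] for i in rng.integers(0, 4, size=60))
            w = make_window(joined[:30], joined[30:],
                            after_left="T", before_right="T")
            expected = junction_oracle(joined)
            created = {(c.motif, c.grna) for c in detect_junction_pam(w)}
            assert created == set(expected["created"])
            spanning = {(c.motif, c.grna, c.left_overlap, c.right_overlap,
                         c.pam_position) for c in detect_spanning_guides(w)}
            assert spanning == set(expected["spanning"])

    def test_strand_mirror_symmetry(self):
        """Reverse-complementing the window (and swapping sides) maps NGG
        candidates to CCN candidates one-to-one."""
        rng = np.random.default_rng(5)
        for _ in range(200):
            joined = "".join("ACGT"[i] for i in rng.integers(0, 4, size=60))
            w = make_window(joined[:30], joined[30:])
            mirrored_joined = reverse_complement(joined)
            wm = make_window(mirrored_joined[:30], mirrored_joined[30:])
            fwd = {(c.motif, c.grna) for c in detect_spanning_guides(w)}
            rev = {(c.motif, c.grna) for c in detect_spanning_guides(wm)}
            flip = {"NGG": "CCN", "CCN": "NGG"}
            assert {(flip[m], g) for m, g in fwd} == rev


class TestCohortAnalysis:
    def test_planted_junctions_recovered(self):
        from neopam.fixtures import FixtureSpec, generate

        bundle = generate(FixtureSpec(seed=8, n_junction_breakpoints=5,
                                      n_neutral_breakpoints=5))
        result = analyze_cohort_breakpoints(bundle.breakpoints, bundle.genome)
        created = [c for c in result.candidates if c.kind == "junction_pam"]
        assert len(created) == 5
        truth = {t.protospacer for t in bundle.ground_truth
                 if t.kind == "junction_pam"}
        assert {c.grna for c in created} == truth

    def test_empty_breakpoint_list(self, small_genome):
        result = analyze_cohort_breakpoints([], small_genome)
        assert result.candidates == [] and len(result.table) == 0

    def test_counts_split_by_source_class(self):
        from neopam.fixtures import FixtureSpec, generate

        bundle = generate(FixtureSpec(seed=8, n_junction_breakpoints=4))
        result = analyze_cohort_breakpoints(bundle.breakpoints, bundle.genome)
        classes = set(result.per_sample["svclass"])
        assert len(classes) > 1  # fixture cycles through SV classes

    def test_breakpoint_tsv_round_trip(self, tmp_path):
        from neopam.fixtures import _write_breakpoints_tsv

        bkps = [Breakpoint("s1", "c1", 100, "+", "c2", 500, "-", "ecDNA")]
        path = tmp_path / "bkp.tsv"
        _write_breakpoints_tsv(bkps, path)
        assert load_breakpoints(path) == bkps
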