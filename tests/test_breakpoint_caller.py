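"""Breakpoint caller: loading, assignment, per-class calls, consensus, alignment."""

import numpy as np
import pytest

from casbreak.breakpoint_caller import (
    AlignedSegment,
    AlignmentInputError,
    ReadAlignmentGroup,
    assign_reads_to_targets,
    build_custom_reference,
    call_deletion,
    call_insertion,
    call_inversion,
    clipped_consensus,
    compute_target_coverage,
    genotype_target,
    load_alignments,
    local_align,
)
from casbreak.genome_io import GenomeSequence, GenomicInterval
from casbreak.guide_design import GuideSet, Protospacer
from casbreak.sv_catalog import SVRecord
from conftest import random_dna


def _guide(cut, chrom="chr12", strand="+"):
    return Protospacer(
        GenomicInterval(chrom, cut, cut + 20), strand,
        "ACGTACGTACGTACGTACGT", "AGG", cut_coord=cut,
    )


def _seg(read_id, chrom, ref_start, ref_end, read_start, read_end, strand="+",
         left_clip=0, right_clip=0, seq=None, cigar=None):
    ref_len = ref_end - ref_start
    if cigar is None:
        cigar = (("M", ref_len),)
    return AlignedSegment(
        read_id=read_id,
        ref_interval=GenomicInterval(chrom, ref_start, ref_end),
        read_interval=(read_start, read_end),
        strand=strand,
        cigar=tuple(cigar),
        left_clip=left_clip,
        right_clip=right_clip,
        is_supplementary=False,
        seq=seq,
    )


class TestLoadAlignments:
    def test_sam_grouping_with_supplementary(self, tmp_path):
        p = tmp_path / "two.sam"
        p.write_text(
            "@HD\tVN:1.6\tSO:coordinate\n"
            "@SQ\tSN:c\tLN:10000\n"
            "r1\t0\tc\t101\t60\t50M50S\t*\t0\t0\t" + "A" * 100 + "\t*\tSA:Z:c,201,+,50S50M,60,0;\n"
            "r1\t2048\tc\t201\t60\t50S50M\t*\t0\t0\t" + "A" * 100 + "\t*\tSA:Z:c,101,+,50M50S,60,0;\n"
        )
        groups = load_alignments(p)
        assert len(groups) == 1
        (g,) = groups
        assert len(g.segments) == 2
        assert {s.is_supplementary for s in g.segments} == {False, True}
        assert g.segments[0].supplementary_links

    def test_paf_without_cigar_rejected(self, tmp_path):
        p = tmp_path / "bad.paf"
        p.write_text("r1\t100\t0\t100\t+\tc\t1000\t0\t100\t100\t100\t60\n")
        with pytest.raises(AlignmentInputError, match="cg"):
            load_alignments(p, "paf")

    def test_paf_with_cigar(self, tmp_path):
        p = tmp_path / "ok.paf"
        p.write_text(
            "r1\t120\t10\t110\t+\tc\t1000\t200\t300\t100\t100\t60\tcg:Z:100M\n"
        )
        (g,) = load_alignments(p, "paf")
        (seg,) = g.segments
        assert seg.ref_interval == GenomicInterval("c", 200, 300)
        assert seg.read_interval == (10, 110)

    def test_truth_sam_round_trip_geometry(self, toy_world, toy_design,
                                           toy_haplotypes, tmp_path):
        from casbreak.digest_model import cut_sites_from_guides
        from casbreak.sim_reads import emit_truth_alignments, simulate_reads, write_sam

        cuts = cut_sites_from_guides(toy_design.guide_sets["ins1"])
        rs = simulate_reads(toy_haplotypes, cuts, toy_world.reference,
                            n_reads_per_target=3, error_rates=(0, 0, 0),
                            on_target_fraction=1.0, seed=9)
        records = emit_truth_alignments(rs, toy_world.reference)
        path = tmp_path / "ins.sam"
        write_sam(records, toy_world.reference, path)
        groups = load_alignments(path)
        for g in groups:
            (seg,) = g.segments
            # flank cut .. insertion point aligned, element tail clipped
            assert seg.ref_interval.end == 95_000
            assert seg.right_clip > 0


class TestAssignment:
    def _guide_sets(self):
        return {"sv1": GuideSet("sv1", [("flank_5p", _guide(10_000, "c")),
                                        ("internal", _guide(13_500, "c"))])}

    def test_exact_cut_start_assigned(self):
        g = ReadAlignmentGroup("r", [_seg("r", "c", 10_000, 13_500, 0, 3_500)])
        (out,) = assign_reads_to_targets([g], self._guide_sets(), tol=100)
        assert out.assigned_sv == "sv1"

    def test_outside_tolerance_background(self):
        g = ReadAlignmentGroup("r", [_seg("r", "c", 10_150, 13_340, 0, 3_190)])
        (out,) = assign_reads_to_targets([g], self._guide_sets(), tol=100)
        assert out.assigned_sv is None

    def test_simulated_assignment_accuracy(self, toy_world, toy_design,
                                           toy_haplotypes, tmp_path):
        from casbreak.digest_model import cut_sites_from_guides
        from casbreak.sim_reads import emit_truth_alignments, simulate_reads, write_sam

        cuts = [c for gs in toy_design.guide_sets.values()
                for c in cut_sites_from_guides(gs)]
        rs = simulate_reads(toy_haplotypes, cuts, toy_world.reference,
                            n_reads_per_target=5, error_rates=(0, 0, 0),
                            on_target_fraction=0.7, seed=13)
        records = emit_truth_alignments(rs, toy_world.reference)
        path = tmp_path / "mix.sam"
        write_sam(records, toy_world.reference, path)
        groups = assign_reads_to_targets(load_alignments(path),
                                         toy_design.guide_sets)
        correct = total = 0
        for g in groups:
            truth_sv = rs.truth[g.read_id].sv_id
            # on-target reads must be assigned to their SV
            if truth_sv != "background":
                total += 1
                correct += g.assigned_sv == truth_sv
        assert total and correct == total


class TestCallDeletion:
    def _sv_and_guides(self):
        sv = SVRecord("del", GenomicInterval("chr12", 45_504_426, 45_517_614),
                      "deletion", zygosity="het")
        gs = GuideSet("del", [
            ("flank_5p", _guide(45_507_940)),
            ("internal", _guide(45_511_479)),
            ("flank_3p", _guide(45_518_921)),
        ])
        return sv, gs

    def test_fig2_fixture_breakpoint(self):
        """Split reads whose 5' segments end at the printed deletion
        breakpoint must yield exactly that coordinate."""
        sv, gs = self._sv_and_guides()
        groups = []
        for i in range(5):
            s1 = _seg(f"a{i}", "chr12", 45_507_940, 45_509_371, 0, 1_431)
            s2 = _seg(f"a{i}", "chr12", 45_514_800, 45_518_921, 1_431, 5_552)
            groups.append(ReadAlignmentGroup(f"a{i}", [s1, s2], assigned_sv="del"))
        for i in range(5):  # reference-allele reads between cutA and cutB
            s = _seg(f"r{i}", "chr12", 45_507_940, 45_511_479, 0, 3_539)
            groups.append(ReadAlignmentGroup(f"r{i}", [s], assigned_sv="del"))
        call = call_deletion(groups, sv, gs)
        assert call.genotype == "het"
        assert call.breakpoints[0] == ("chr12", 45_509_371, "high")
        assert call.breakpoints[1][1] == 45_514_801
        assert call.support == {"ref": 5, "alt": 5}
        assert call.sv_length == 45_514_801 - 45_509_371 - 1

    def test_cigar_deletion_representation(self):
        sv, gs = self._sv_and_guides()
        cigar = (("M", 1_431), ("D", 5_429), ("M", 4_121))
        groups = [
            ReadAlignmentGroup(
                f"c{i}",
                [_seg(f"c{i}", "chr12", 45_507_940, 45_518_921, 0, 5_552, cigar=cigar)],
                assigned_sv="del",
            )
            for i in range(4)
        ]
        call = call_deletion(groups, sv, gs)
        assert call.genotype == "hom_alt"
        assert call.breakpoints[0][1] == 45_507_940 + 1_431
        assert call.breakpoints[1][1] == 45_507_940 + 1_431 + 5_429 + 1

    def test_no_reads_no_call(self):
        sv, gs = self._sv_and_guides()
        call = call_deletion([], sv, gs)
        assert call.genotype == "no_call"
        assert call.breakpoints == []

    def test_unaligned_middle_downgrades_confidence(self):
        """Reads with a soft-clipped unaligned chunk between the segments
        (the reference-N situation) still support the call, at low confidence."""
        sv, gs = self._sv_and_guides()
        groups = []
        for i in range(4):
            s1 = _seg(f"n{i}", "chr12", 45_507_940, 45_509_371, 0, 1_431,
                      right_clip=4_121 + 800)
            s2 = _seg(f"n{i}", "chr12", 45_515_600, 45_518_921, 2_231, 5_552,
                      left_clip=2_231)
            groups.append(ReadAlignmentGroup(f"n{i}", [s1, s2], assigned_sv="del"))
        call = call_deletion(groups, sv, gs)
        assert call.support["alt"] == 4
        assert call.breakpoints[0][2] == "low"
        assert call.sv_length is None

    def test_reference_n_gap_flag(self, rng):
        sv = SVRecord("del", GenomicInterval("c", 4_000, 12_000), "deletion")
        gs = GuideSet("del", [
            ("flank_5p", _guide(3_000, "c")),
            ("internal", _guide(6_500, "c")),
            ("flank_3p", _guide(13_000, "c")),
        ])
        seq = random_dna(6_000, rng) + "N" * 50 + random_dna(14_000, rng)
        ref = {"c": GenomeSequence("c", seq)}
        groups = [
            ReadAlignmentGroup(
                f"g{i}",
                [_seg(f"g{i}", "c", 3_000, 4_500, 0, 1_500),
                 _seg(f"g{i}", "c", 11_500, 13_000, 1_500, 3_000)],
                assigned_sv="del",
            )
            for i in range(3)
        ]
        call = call_deletion(groups, sv, gs, reference=ref)
        assert "reference_N_gap" in call.flags


class TestCallInsertion:
    def _sv_and_guides(self):
        sv = SVRecord("ins", GenomicInterval("chr12", 33_854_179, 33_867_084),
                      "insertion", size_estimate=6_000, zygosity="hom")
        gs = GuideSet("ins", [
            ("flank_5p", _guide(33_854_858)),
            ("element", _guide(5_500, chrom="EL")),
        ], element_name="EL")
        return sv, gs

    def test_fig3_fixture_breakpoint(self, rng):
        """Reads aligned up to the printed insertion breakpoint with clipped
        tails must reproduce that coordinate."""
        sv, gs = self._sv_and_guides()
        element = random_dna(6_000, rng)
        groups = []
        for i in range(5):
            aligned = random_dna(600, rng)
            seq = aligned + element[:5_500]
            s = _seg(f"t{i}", "chr12", 33_863_803, 33_864_403, 0, 600,
                     right_clip=5_500, seq=seq)
            groups.append(ReadAlignmentGroup(f"t{i}", [s], assigned_sv="ins"))
        call = call_insertion(groups, sv, gs,
                              element_consensus=GenomeSequence("EL", element))
        assert call.breakpoints == [("chr12", 33_864_403, "high")]
        assert call.genotype == "hom_alt"
        assert "element_confirmed" in call.flags
        assert call.inserted_consensus == element[:5_500]

    def test_random_tails_not_element_confirmed(self, rng):
        sv, gs = self._sv_and_guides()
        element = random_dna(6_000, rng)
        groups = []
        for i in range(4):
            seq = random_dna(600, rng) + random_dna(3_000, rng)
            s = _seg(f"x{i}", "chr12", 33_863_803, 33_864_403, 0, 600,
                     right_clip=3_000, seq=seq)
            groups.append(ReadAlignmentGroup(f"x{i}", [s], assigned_sv="ins"))
        call = call_insertion(groups, sv, gs,
                              element_consensus=GenomeSequence("EL", element))
        assert "element_confirmed" not in call.flags

    def test_no_clipped_evidence_no_call(self):
        sv, gs = self._sv_and_guides()
        groups = [
            ReadAlignmentGroup(
                "p", [_seg("p", "chr12", 33_854_858, 33_858_000, 0, 3_142)],
                assigned_sv="ins",
            )
        ]
        call = call_insertion(groups, sv, gs)
        assert call.genotype == "no_call"


class TestCallInversion:
    def _sv_and_guides(self):
        sv = SVRecord("inv", GenomicInterval("chr12", 17_770_249, 17_859_681),
                      "inversion", zygosity="hom")
        gs = GuideSet("inv", [
            ("flank_5p", _guide(17_765_568)),
            ("internal", _guide(17_857_700)),
        ])
        return sv, gs

    def test_fig4_fixture_both_breakpoints(self):
        """Dual-orientation segments anchored as in the printed example must
        reproduce both printed breakpoints."""
        sv, gs = self._sv_and_guides()
        groups = []
        for i in range(6):
            # reference-orientation segment inside the inversion (5'->3')
            s1 = _seg(f"v{i}", "chr12", 17_857_720, 17_861_570, 0, 3_850)
            # same read continues in inverted orientation at the other junction
            s2 = _seg(f"v{i}", "chr12", 17_765_568, 17_768_358, 3_850, 6_640,
                      strand="-")
            groups.append(ReadAlignmentGroup(f"v{i}", [s1, s2], assigned_sv="inv"))
        call = call_inversion(groups, sv, gs)
        positions = sorted(p for _, p, _ in call.breakpoints)
        assert positions == [17_768_358, 17_861_570]
        assert call.genotype == "hom_alt"
        assert not call.flags

    def test_inverted_repeat_ambiguity_flagged(self):
        sv, gs = self._sv_and_guides()
        groups = []
        for i in range(4):
            s1 = _seg(f"w{i}", "chr12", 17_857_720, 17_861_570, 0, 3_850)
            s2 = _seg(f"w{i}", "chr12", 17_765_568, 17_768_358, 3_850, 6_640,
                      strand="-")
            # the same tail also aligns acceptably at the opposite junction
            s3 = _seg(f"w{i}", "chr12", 17_861_570, 17_864_360, 3_850, 6_640,
                      strand="-")
            groups.append(ReadAlignmentGroup(f"w{i}", [s1, s2, s3], assigned_sv="inv"))
        call = call_inversion(groups, sv, gs)
        assert "inverted_repeat_ambiguity" in call.flags
        assert len(call.breakpoints) > 2

    def test_no_opposite_strand_no_call(self):
        sv, gs = self._sv_and_guides()
        groups = [
            ReadAlignmentGroup(
                "z", [_seg("z", "chr12", 17_857_720, 17_861_570, 0, 3_850)],
                assigned_sv="inv",
            )
        ]
        call = call_inversion(groups, sv, gs)
        assert call.genotype == "no_call"


class TestClippedConsensus:
    def test_identical_tails(self):
        cons, support = clipped_consensus(["ACGTT"] * 3)
        assert cons == "ACGTT"
        assert support == [3] * 5

    def test_plurality_and_tie(self):
        cons, support = clipped_consensus(["ACGT", "ACGA", "ACGT"])
        assert cons == "ACGT"
        assert support == [3, 3, 3, 2]

    def test_single_tail_below_min_coverage(self):
        cons, support = clipped_consensus(["ACGT"], cons_min=2)
        assert cons == "NNNN"
        assert support == [1] * 4

    def test_empty_input(self):
        with pytest.raises(ValueError):
            clipped_consensus([])


def dp_local_align_score(q, t, match=2, mismatch=-4, open_=-4, extend=-2):
    """Independent quadratic Gotoh DP (gap of length k costs |open|+k|extend|)."""
    n, m = len(q), len(t)
    neg = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), neg)  # gap in target (consume query)
    F = np.full((n + 1, m + 1), neg)  # gap in query (consume target)
    best = 0.0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] + open_ + extend, E[i - 1][j] + extend)
            F[i][j] = max(H[i][j - 1] + open_ + extend, F[i][j - 1] + extend)
            s = match if qi == t[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


class TestLocalAlign:
    def test_perfect_match_closed_form(self, rng):
        s = random_dna(80, rng)
        aln = local_align(s, s)
        assert aln.score == 160
        assert aln.identity == 1.0
        assert aln.query_interval == (0, 80)

    def test_disjoint_alphabets(self):
        aln = local_align("AAAA", "GGGG")
        assert aln.score == 0
        assert aln.cigar == ()

    def test_against_dp_oracle(self, rng):
        for _ in range(40):
            q = random_dna(int(rng.integers(20, 200)), rng)
            t = random_dna(int(rng.integers(20, 200)), rng)
            assert local_align(q, t).score == pytest.approx(dp_local_align_score(q, t))

    def test_related_sequences_identity(self, rng):
        t = random_dna(400, rng)
        # query = target with a deletion and a few substitutions
        q = list(t[50:350])
        del q[100:120]
        for pos in (10, 50, 200):
            q[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[pos]]
        aln = local_align("".join(q), t)
        assert aln.identity > 0.9
        assert aln.target_interval[0] >= 40


class TestCustomReference:
    def test_small_example(self):
        ref = {"c": GenomeSequence("c", "AAAA")}
        mod, lift = build_custom_reference(ref, "c", 2, "CC")
        assert mod["c"].seq == "AACCAA"
        assert lift.orig_to_mod(2) == 2
        assert lift.orig_to_mod(3) == 5

    def test_liftover_round_trip(self, rng):
        ref = {"c": GenomeSequence("c", random_dna(10_000, rng))}
        mod, lift = build_custom_reference(ref, "c", 4_000, random_dna(500, rng))
        for pos in map(int, rng.integers(0, 10_000, size=100)):
            assert lift.mod_to_orig(lift.orig_to_mod(pos)) == pos

    def test_custom_reference_equals_insertion_haplotype(self, toy_world,
                                                         toy_haplotypes):
        """Splicing the true inserted sequence at the true breakpoint must
        reproduce the simulated haplotype (modulo the het deletion), so alt
        reads realign contiguously."""
        ins = next(sv for sv in toy_world.truth_svs if sv.sv_type == "insertion")
        mod, _ = build_custom_reference(
            toy_world.reference, "chr_t", ins.truth_breakpoints[0], ins.inserted_seq
        )
        hap1 = toy_haplotypes.haplotypes["hap1"]["chr_t"].seq.seq
        # hap1 carries the insertion and the hom inversion; compare the
        # insertion-containing region only
        lo, hi = 90_000, 105_000
        assert mod["chr_t"].seq[lo:hi + 6_000] == hap1[lo:hi + 6_000]

    def test_breakpoint_out_of_range(self):
        ref = {"c": GenomeSequence("c", "ACGT")}
        with pytest.raises(ValueError):
            build_custom_reference(ref, "c", 10, "AA")


class TestGenotypeAndCoverage:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [(171, 5, "het"), (0, 12, "hom_alt"), (2, 2, "no_call"), (8, 0, "hom_ref")],
    )
    def test_genotype_rules(self, ref, alt, expected):
        assert genotype_target({"ref": ref, "alt": alt}) == expected

    def test_uniform_coverage(self):
        gs = {"t": GuideSet("t", [("flank_5p", _guide(1_000, "c")),
                                  ("internal", _guide(2_000, "c"))])}
        groups = [
            ReadAlignmentGroup(
                f"r{i}", [_seg(f"r{i}", "c", 1_000, 2_000, 0, 1_000)],
                assigned_sv="t",
            )
            for i in range(10)
        ]
        cov = compute_target_coverage(groups, gs)
        assert cov["t"]["median"] == 10

    def test_no_reads_zero(self):
        gs = {"t": GuideSet("t", [("flank_5p", _guide(1_000, "c")),
                                  ("internal", _guide(2_000, "c"))])}
        cov = compute_target_coverage([], gs)
        assert cov["t"]["median"] == 0

    def test_matches_brute_force_pileup(self, rng):
        gs = {"t": GuideSet("t", [("flank_5p", _guide(500, "c")),
                                  ("internal", _guide(1_500, "c"))])}
        groups = []
        intervals = []
        for i in range(30):
            a = int(rng.integers(300, 1_400))
            b = a + int(rng.integers(50, 600))
            intervals.append((a, b))
            groups.append(
                ReadAlignmentGroup(f"r{i}", [_seg(f"r{i}", "c", a, b, 0, b - a)],
                                   assigned_sv="t")
            )
        cov = compute_target_coverage(groups, gs)
        depth = np.zeros(1_000)
        for a, b in intervals:
            lo, hi = max(a, 500), min(b, 1_500)
            if hi > lo:
                depth[lo - 500 : hi - 500] += 1
        assert cov["t"]["median"] == float(np.median(depth))
        assert cov["t"]["mean"] == pytest.approx(float(depth.mean()))
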