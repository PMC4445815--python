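"""Genome breakpoint resolution, classification, ranking, reporting."""

import csv
import itertools
import random

import pytest

from fusiondart.fusioncand import TumourSequence, select_multigene
from fusiondart.genoclass import (
    HIGH,
    LOW,
    MEDIUM,
    READTHROUGH,
    ClassParams,
    ClassifiedFusion,
    GenomicBreakpoints,
    KnownFusions,
    build_genome_index,
    classify,
    flag_known,
    map_breakpoints_to_genome,
    merge_same_genomic_breakpoint,
    predict_frame,
    rank,
    write_results,
)
from fusiondart.seedalign import AlignParams, SeedIndex, align_many
from fusiondart.seqio import Read
from fusiondart.support import SupportCounts

from conftest import fusion_read, two_gene_reference

TILE = 15
APARAMS = AlignParams(tile_size=TILE)


def _candidate(ref, cut_a=600, cut_b=200, prefix=80, suffix=80):
    """cut offsets are spliced-transcript junction offsets (exon edges are
    multiples of 200 in the two-gene reference)."""
    _, index, tx = ref
    r = fusion_read(tx, "GA.t1", "GB.t1", cut_a, cut_b, prefix, suffix)
    t = TumourSequence(r.rid, r.seq)
    alns = align_many([(r.rid, r.seq)], SeedIndex(tx, TILE), APARAMS,
                      query_step=TILE)[r.rid]
    cands = select_multigene(t, alns, index, transcript_seqs=tx)
    assert len(cands) == 1
    return cands[0]


class TestBreakpointMapping:
    def test_exon_edge_junction_projects_to_annotated_boundaries(self):
        ref = two_gene_reference(distance=50_000)
        genome, index, tx = ref
        c = _candidate(ref)  # junction after gene A exon 3, before gene B exon 2
        bp = map_breakpoints_to_genome(c, build_genome_index(genome), index)
        # gene A: exons at 1000..1200,1600..1800,2200..2400 (+): offset 600 -> base 2400
        # gene B: exons start at 2400+50000; offset 200 -> first base of exon 2
        assert (bp.chrom_a, bp.pos_a, bp.strand_a) == ("chr1", 2400, "+")
        assert bp.pos_b == 2400 + 50_000 + 600 + 1
        assert bp.boundary_aligned
        assert bp.gap == abs(bp.pos_b - bp.pos_a)

    def test_interchromosomal_gap_absent(self):
        ref = two_gene_reference(same_chrom=False)
        genome, index, tx = ref
        bp = map_breakpoints_to_genome(_candidate(ref), build_genome_index(genome), index)
        assert bp.chrom_a != bp.chrom_b and bp.gap is None
        assert bp.rearrangement_evidence

    def test_mid_exon_junction_not_boundary_aligned(self):
        ref = two_gene_reference()
        genome, index, tx = ref
        c = _candidate(ref, cut_a=650, cut_b=250)
        bp = map_breakpoints_to_genome(c, build_genome_index(genome), index)
        assert not bp.boundary_aligned

    def test_candidate_from_paralog_locus_dropped(self):
        """A candidate whose sequence aligns only outside the partner gene
        spans (paralog) is dropped."""
        ref = two_gene_reference()
        genome, index, tx = ref
        c = _candidate(ref)
        # restrict the genome to a copy lacking both gene loci
        decoy = {"chrX": genome["chr1"][:900]}
        assert map_breakpoints_to_genome(c, build_genome_index(decoy), index) is None

    def test_minus_strand_partner_positions(self):
        ref = two_gene_reference(strand_b="-")
        genome, index, tx = ref
        c = _candidate(ref)
        bp = map_breakpoints_to_genome(c, build_genome_index(genome), index)
        assert bp.boundary_aligned
        assert bp.strand_b == "-"


class TestRearrangement:
    def _bp(self, **kw):
        d = dict(chrom_a="chr1", pos_a=2400, strand_a="+", junction_a=2400,
                 chrom_b="chr1", pos_b=60001, strand_b="+", junction_b=60000,
                 gap=57601)
        d.update(kw)
        return GenomicBreakpoints(**d)

    def _index(self, strand_a="+", strand_b="+"):
        return two_gene_reference(strand_a=strand_a, strand_b=strand_b)[1]

    def test_colinear_adjacent_genes_compatible_with_readthrough(self):
        from fusiondart.genoclass import rearrangement_evidence

        assert not rearrangement_evidence(self._bp(), self._index(), "GA", "GB")

    def test_opposite_segment_orientation_is_evidence(self):
        from fusiondart.genoclass import rearrangement_evidence

        bp = self._bp(strand_b="-")
        assert rearrangement_evidence(bp, self._index(strand_b="-"), "GA", "GB")

    def test_antisense_relative_orientation_is_evidence(self):
        from fusiondart.genoclass import rearrangement_evidence

        # gene B annotated -, candidate aligned + on both sides: inversion
        assert rearrangement_evidence(self._bp(), self._index(strand_b="-"), "GA", "GB")

    def test_order_against_transcription_is_evidence(self):
        from fusiondart.genoclass import rearrangement_evidence

        bp = self._bp(junction_b=1000, pos_b=1001)  # B upstream of A on + strand
        assert rearrangement_evidence(bp, self._index(), "GA", "GB")

    def test_interchromosomal_is_evidence(self):
        from fusiondart.genoclass import rearrangement_evidence

        bp = self._bp(chrom_b="chr2", gap=None)
        assert rearrangement_evidence(bp, self._index(), "GA", "GB")


def _bpts(gap, boundary, rearr):
    if gap is None:
        return GenomicBreakpoints("chr1", 100, "+", 100, "chr2", 500, "+", 499,
                                  None, boundary, rearr)
    return GenomicBreakpoints("chr1", 100, "+", 100, "chr1", 100 + gap, "+",
                              99 + gap, gap, boundary, rearr)


def _ordered_rule_oracle(gap, boundary, sr, sp, rearr, params, paired):
    """Independent statement of the ordered decision list."""
    sp_n = (sp or 0) if paired else 0
    if gap is not None and gap < params.min_gap_keep:
        return None
    if gap is not None and gap < params.readthrough_gap and not rearr:
        return READTHROUGH
    if boundary:
        return HIGH if (sr >= 1 and sp_n >= 1) else MEDIUM
    if sp_n >= 1 and sr >= params.low_conf_min_spanning_reads:
        return LOW
    return None


class TestClassify:
    params = ClassParams()

    @pytest.mark.parametrize("gap,boundary,sr,sp,rearr,expected", [
        (None, True, 5, 3, True, HIGH),
        (None, True, 1, 0, True, MEDIUM),
        (None, False, 1, 2, True, None),    # one spanning read only
        (None, False, 2, 1, True, LOW),
        (5_000, True, 9, 9, True, None),    # tiny gap: homology artifact
        (150_000, True, 9, 9, False, READTHROUGH),
        (150_000, True, 9, 9, True, HIGH),  # rearranged: genuine local fusion
        (10_000, True, 1, 1, True, HIGH),   # exactly 10 kb survives
        (200_000, True, 1, 1, False, HIGH), # exactly 200 kb reported
    ])
    def test_decision_examples(self, gap, boundary, sr, sp, rearr, expected):
        got = classify(SupportCounts(sr, sp), _bpts(gap, boundary, rearr), self.params)
        assert got == expected

    def test_exhaustive_truth_table(self):
        """The decision procedure is total and matches the ordered rules on
        the full cross product of its inputs."""
        for boundary, sr, sp, gap, rearr, paired in itertools.product(
            (False, True), (0, 1, 2), (0, 1), (5_000, 50_000, 500_000, None),
            (False, True), (False, True),
        ):
            support = SupportCounts(sr, sp if paired else None)
            got = classify(support, _bpts(gap, boundary, rearr), self.params, paired)
            want = _ordered_rule_oracle(gap, boundary, sr, sp, rearr, self.params, paired)
            assert got == want, (boundary, sr, sp, gap, rearr, paired)

    def test_single_end_capped_at_medium(self):
        support = SupportCounts(9, None)
        assert classify(support, _bpts(None, True, True), self.params, paired_end=False) == MEDIUM
        assert classify(support, _bpts(None, False, True), self.params, paired_end=False) is None


class TestFrame:
    def test_matching_phases_in_frame(self):
        ref = two_gene_reference()
        genome, index, tx = ref
        c = _candidate(ref, cut_a=600, cut_b=201 * 0 + 200)
        bp = map_breakpoints_to_genome(c, build_genome_index(genome), index)
        # phases: gene A offset 600 coding (cds 0..600) -> 0; gene B offset 200,
        # cds 0..600 -> 200 mod 3 = 2
        assert predict_frame(c, bp, index) == ("yes" if (600 % 3) == (200 % 3) else "no")

    def test_mid_exon_break_unknown(self):
        ref = two_gene_reference()
        genome, index, tx = ref
        c = _candidate(ref, cut_a=650, cut_b=250)
        bp = map_breakpoints_to_genome(c, build_genome_index(genome), index)
        assert predict_frame(c, bp, index) == "unknown"


def _call(name, cls, sr=1, sp=0, gap=50_000, sample="s", cand=None, ref=None):
    cand = cand or _candidate(ref or two_gene_reference())
    a, b = name.split(":")
    return ClassifiedFusion(
        sample=sample,
        fusion_name=name,
        gene_a=a,
        gene_b=b,
        breakpoints=_bpts(gap, True, True),
        support=SupportCounts(sr, sp),
        classification=cls,
        in_frame="unknown",
        known=False,
        candidate=cand,
    )


@pytest.fixture(scope="module")
def shared_candidate():
    return _candidate(two_gene_reference())


class TestRank:
    def test_class_outranks_support(self, shared_candidate):
        c = shared_candidate
        high = _call("A:B", HIGH, sr=1, sp=1, cand=c)
        med = _call("C:D", MEDIUM, sr=9, sp=1, cand=c)
        assert rank([med, high]) == [high, med]

    def test_smaller_gap_first_then_interchromosomal(self, shared_candidate):
        c = shared_candidate
        near = _call("A:B", HIGH, sr=2, sp=0, gap=50_000, cand=c)
        far = _call("C:D", HIGH, sr=2, sp=0, gap=5_000_000, cand=c)
        inter = _call("E:F", HIGH, sr=2, sp=0, gap=None, cand=c)
        assert rank([inter, far, near]) == [near, far, inter]

    def test_order_invariant_under_permutation(self, shared_candidate):
        c = shared_candidate
        calls = [
            _call(n, cl, sr=s, sp=p, gap=g, cand=c)
            for n, cl, s, p, g in (
                ("A:B", HIGH, 1, 1, 100_000), ("C:D", MEDIUM, 5, 0, None),
                ("E:F", HIGH, 3, 0, 100_000), ("G:H", LOW, 2, 2, 20_000),
                ("I:J", HIGH, 1, 3, 400_000), ("K:L", MEDIUM, 5, 0, 70_000),
            )
        ]
        expected = rank(calls)
        rnd = random.Random(7)
        for _ in range(10):
            shuffled = calls[:]
            rnd.shuffle(shuffled)
            assert rank(shuffled) == expected


class TestMerge:
    def test_same_breakpoint_support_aggregates_and_upgrades(self, shared_candidate):
        c = shared_candidate
        f1 = _call("A:B", MEDIUM, sr=1, sp=0, cand=c)
        f2 = _call("A:B", MEDIUM, sr=1, sp=1, cand=c)
        (merged,) = merge_same_genomic_breakpoint([f1, f2])
        assert merged.support.spanning_reads == 2
        assert merged.support.spanning_pairs == 1
        assert merged.classification == HIGH

    def test_distinct_breakpoints_kept_separate(self, shared_candidate):
        c = shared_candidate
        f1 = _call("A:B", MEDIUM, gap=50_000, cand=c)
        f2 = _call("A:B", MEDIUM, gap=60_000, cand=c)
        assert len(merge_same_genomic_breakpoint([f1, f2])) == 2

    def test_singleton_unchanged(self, shared_candidate):
        f = _call("A:B", MEDIUM, cand=shared_candidate)
        assert merge_same_genomic_breakpoint([f]) == [f]

    def test_merge_never_downgrades(self, shared_candidate):
        c = shared_candidate
        order = {HIGH: 0, MEDIUM: 1, LOW: 2, READTHROUGH: 3}
        f1 = _call("A:B", HIGH, sr=2, sp=2, cand=c)
        f2 = _call("A:B", MEDIUM, sr=1, sp=0, cand=c)
        (merged,) = merge_same_genomic_breakpoint([f1, f2])
        assert order[merged.classification] <= min(order[f1.classification],
                                                   order[f2.classification])


class TestKnown:
    def test_unordered_match(self, tmp_path):
        p = tmp_path / "known.csv"
        p.write_text("gene1,gene2\nBCR,ABL1\n")
        known = KnownFusions.load(p)
        assert ("ABL1", "BCR") in known and ("BCR", "ABL1") in known

    def test_alias_expansion(self, tmp_path):
        p = tmp_path / "known.csv"
        p.write_text("BCR,ABL1,ABL=ABL1\n")
        known = KnownFusions.load(p)
        assert ("BCR", "ABL") in known

    def test_empty_or_missing_list(self, tmp_path, shared_candidate):
        assert ("A", "B") not in KnownFusions()
        missing = KnownFusions.load(tmp_path / "nope.csv")
        assert flag_known(_call("A:B", HIGH, cand=shared_candidate), missing) is False


class TestWriteResults:
    def test_empty_results_header_only(self, tmp_path):
        write_results([], str(tmp_path / "out"))
        rows = list(csv.reader(open(tmp_path / "out.csv")))
        assert len(rows) == 1 and rows[0][0] == "sample"
        assert (tmp_path / "out.fasta").read_text() == ""

    def test_single_end_pairs_column_dash(self, tmp_path, shared_candidate):
        f = _call("A:B", MEDIUM, cand=shared_candidate)
        f.support = SupportCounts(3, None)
        write_results([f], str(tmp_path / "out"))
        row = list(csv.DictReader(open(tmp_path / "out.csv")))[0]
        assert row["spanning_pairs"] == "-" and row["spanning_reads"] == "3"

    def test_readthrough_excluded_by_default(self, tmp_path, shared_candidate):
        f = _call("A:B", READTHROUGH, cand=shared_candidate)
        write_results([f], str(tmp_path / "d"))
        assert len(list(csv.reader(open(tmp_path / "d.csv")))) == 1
        write_results([f], str(tmp_path / "i"), include_readthrough=True)
        assert len(list(csv.reader(open(tmp_path / "i.csv")))) == 2
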