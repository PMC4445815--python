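"""Read preprocessing and fusion-candidate discovery."""

import numpy as np
import pytest

from fusiondart.fusioncand import (
    CandidateParams,
    TumourSequence,
    apply_homology_filter,
    dedupe,
    homology_overlap,
    mask_exons,
    prefilter_reads,
    select_multigene,
    select_unmapped_reads,
)
from fusiondart.refmodel import ExonInterval, TranscriptModel, TranscriptomeIndex
from fusiondart.seedalign import AlignParams, SeedIndex, align_many
from fusiondart.seqio import Read, revcomp

from conftest import build_reference, fusion_read, two_gene_reference


TILE = 15
APARAMS = AlignParams(tile_size=TILE)


def _tx_index(tx_seqs):
    return SeedIndex(tx_seqs, TILE, step=1)


def _aln(reads, tx_seqs):
    return align_many(((r.rid, r.seq) for r in reads), _tx_index(tx_seqs), APARAMS,
                      query_step=TILE)


class TestMaskExons:
    def test_exonic_bases_masked(self):
        t = TranscriptModel("T", "G", "G", "c", "+", (ExonInterval("c", 3, 6, "+"),))
        masked = mask_exons({"c": "AAACCCGGG"}, TranscriptomeIndex([t]))
        assert masked == {"c": "AAANNNGGG"}

    def test_overlapping_exons_masked_once(self):
        ts = [
            TranscriptModel("T1", "G", "G", "c", "+", (ExonInterval("c", 2, 6, "+"),)),
            TranscriptModel("T2", "G", "G", "c", "+", (ExonInterval("c", 4, 8, "+"),)),
        ]
        masked = mask_exons({"c": "ACGTACGTAC"}, TranscriptomeIndex(ts))
        assert masked == {"c": "ACNNNNNNAC"}

    def test_no_annotation_unchanged(self):
        assert mask_exons({"c": "ACGT"}, TranscriptomeIndex([])) == {"c": "ACGT"}


class TestDedupe:
    def test_identical_reads_collapse(self):
        p = (Read("a", "ACGT" * 20), None)
        assert dedupe([p, (Read("b", "ACGT" * 20), None), p]) == [p]

    def test_swapped_mates_kept_distinct(self):
        r1, r2 = Read("x/1", "ACGT" * 20), Read("x/2", "TTTT" * 20)
        pairs = [(r1, r2), (Read("y/1", r2.seq), Read("y/2", r1.seq))]
        assert len(dedupe(pairs)) == 2

    def test_empty_and_idempotent(self, rng):
        assert dedupe([]) == []
        pairs = [
            (Read(f"r{i}", "".join(rng.choice(list("ACGT"), 30))), None)
            for i in range(10)
        ]
        once = dedupe(pairs)
        assert dedupe(once) == once


@pytest.fixture(scope="module")
def ref():
    return two_gene_reference()


class TestPrefilter:
    def _masked_index(self, ref):
        genome, index, _ = ref
        masked = mask_exons(genome, index)
        return SeedIndex(masked, 11, step=11)

    def test_concordant_transcript_pair_retained_stage1(self, ref):
        genome, index, tx = ref
        ta = tx["GA.t1"]
        pair = (Read("p/1", ta[0:100]), Read("p/2", revcomp(ta[300:400])))
        aln = _aln([pair[0], pair[1]], tx)
        kept, stats = prefilter_reads([pair], aln, None, APARAMS)
        assert kept == [pair] and stats["concordant_transcriptome"] == 1

    def test_intronic_pair_discarded_by_masked_genome(self, ref):
        genome, index, tx = ref
        intron = genome["chr1"][1210:1390]  # inside gene A's first intron
        pair = (Read("i/1", intron[:80]), Read("i/2", revcomp(intron[80:160])))
        aln = _aln([pair[0], pair[1]], tx)
        kept, stats = prefilter_reads(
            [pair], aln, self._masked_index(ref), AlignParams(tile_size=11, min_score=20)
        )
        assert kept == [] and stats["discarded_genomic"] == 1

    def test_fusion_spanning_pair_survives_both_stages(self, ref):
        genome, index, tx = ref
        r1 = fusion_read(tx, "GA.t1", "GB.t1", 200, 200, 50, 50, "f/1")
        pair = (r1, Read("f/2", revcomp(tx["GB.t1"][400:500])))
        aln = _aln([pair[0], pair[1]], tx)
        kept, _ = prefilter_reads(
            [pair], aln, self._masked_index(ref), AlignParams(tile_size=11, min_score=20)
        )
        assert kept == [pair]

    def test_missing_masked_genome_keeps_stage1_failures(self, ref):
        _, _, tx = ref
        junk = (Read("j/1", "ACGT" * 25), Read("j/2", "TGCA" * 25))
        aln = _aln([junk[0], junk[1]], tx)
        kept, _ = prefilter_reads([junk], aln, None, APARAMS)
        assert kept == [junk]


class TestSelectUnmapped:
    def test_transcript_read_excluded(self, ref):
        _, _, tx = ref
        r = Read("r", tx["GA.t1"][50:150])
        assert select_unmapped_reads([r], _aln([r], tx)) == []

    def test_split_fusion_read_included(self, ref):
        """Each half is < 98% of the read, so the read is not wholly
        explained by either transcript."""
        _, _, tx = ref
        r = fusion_read(tx, "GA.t1", "GB.t1", 200, 200, 50, 50)
        (t,) = select_unmapped_reads([r], _aln([r], tx))
        assert t.seq_id == "fread" and t.origin == "read"

    def test_hybrid_contig_containing_read_excluded(self, ref):
        _, _, tx = ref
        r = fusion_read(tx, "GA.t1", "GB.t1", 200, 200, 50, 50)
        contigs = SeedIndex({"c1": r.seq + "ACGTACGT"}, TILE)
        assert select_unmapped_reads([r], _aln([r], tx), contigs, APARAMS) == []

    def test_short_reads_refused(self, ref):
        _, _, tx = ref
        with pytest.raises(ValueError, match="contigs"):
            select_unmapped_reads([Read("s", "ACGT" * 10)], {})


class TestSelectMultigene:
    def _candidates(self, ref, prefix, suffix, params=CandidateParams()):
        _, index, tx = ref
        r = fusion_read(tx, "GA.t1", "GB.t1", 300, 100, prefix, suffix)
        t = TumourSequence(r.rid, r.seq)
        alns = _aln([r], tx)[r.rid]
        return select_multigene(t, alns, index, params, tx)

    def test_even_split_candidate(self, ref):
        (c,) = self._candidates(ref, 50, 50)
        assert (c.gene_a, c.gene_b) == ("GA", "GB")
        assert c.breakpoint_on_sequence == 50
        assert (c.pos_a_tx, c.pos_b_tx) == (300, 100)

    @pytest.mark.parametrize("prefix,suffix,expected", [
        (29, 70, 0), (30, 70, 1), (70, 29, 0), (70, 30, 1),
    ])
    def test_flank_minimum_is_30(self, ref, prefix, suffix, expected):
        assert len(self._candidates(ref, prefix, suffix)) == expected

    def test_same_gene_isoforms_yield_nothing(self):
        genes = [
            dict(gene_id="G", transcript_id="Ta", chrom="chr1", strand="+",
                 exons=[(1000, 1400)], alphabet="AC"),
            dict(gene_id="G", transcript_id="Tb", chrom="chr1", strand="+",
                 exons=[(60_000, 60_400)], alphabet="GT"),
        ]
        genome, index, tx = build_reference(genes, {"chr1": 70_000})
        r = Read("r", tx["Ta"][:50] + tx["Tb"][100:150])
        t = TumourSequence(r.rid, r.seq)
        assert select_multigene(t, _aln([r], tx)[r.rid], index) == []

    @pytest.mark.parametrize("distance,expected", [(999, 0), (1000, 1)])
    def test_gene_separation_minimum_1kb(self, distance, expected):
        ref = two_gene_reference(distance=distance)
        assert len(self._candidates(ref, 60, 60)) == expected

    def test_reverse_orientation_read_canonicalised(self, ref):
        """A read sequenced from the antisense strand of the fusion yields
        the same candidate, with the sequence reverse complemented."""
        _, index, tx = ref
        fwd = fusion_read(tx, "GA.t1", "GB.t1", 300, 100, 60, 60)
        rev = Read("rev", revcomp(fwd.seq))
        t = TumourSequence(rev.rid, rev.seq)
        (c,) = select_multigene(t, _aln([rev], tx)[rev.rid], index, transcript_seqs=tx)
        assert (c.gene_a, c.gene_b) == ("GA", "GB")
        assert c.sequence == fwd.seq
        assert c.breakpoint_on_sequence == 60


def _shared_block_reference(h):
    """Transcripts sharing exactly ``h`` bases at the junction: gene A ends
    its exon with the shared block H, gene B starts its exon 2 with H."""
    rng = np.random.default_rng(9)
    H = "".join(rng.choice(list("ACGT"), h)) if h else ""
    a_seq = "".join(rng.choice(list("AC"), 300))
    b_seq = "".join(rng.choice(list("GT"), 300))
    genes = [
        dict(gene_id="GA", chrom="chr1", strand="+", exons=[(1000, 1300 + h)]),
        dict(gene_id="GB", chrom="chr1", strand="+", exons=[(80_000, 80_000 + h + 300)]),
    ]
    genome, index, tx = build_reference(genes, {"chr1": 90_000}, seed=9)
    # overwrite exon sequence deterministically
    g = list(genome["chr1"])
    g[1000:1300 + h] = list(a_seq + H)
    g[80_000:80_000 + h + 300] = list(H + b_seq)
    genome = {"chr1": "".join(g)}
    from fusiondart.refmodel import extract_transcript_sequences

    tx = extract_transcript_sequences(index, genome)
    return genome, index, tx, h


class TestHomology:
    def _candidate(self, h, read_flank=60):
        genome, index, tx, _ = _shared_block_reference(h)
        # fusion read: end of gene A (incl. shared block) + start of gene B after it
        r = Read("r", tx["GA.t1"][300 - read_flank : 300 + h] + tx["GB.t1"][h : h + read_flank])
        t = TumourSequence(r.rid, r.seq)
        cands = select_multigene(
            t, _aln([r], tx)[r.rid], index, transcript_seqs=tx
        )
        return cands, tx

    def test_no_shared_bases(self):
        cands, tx = self._candidate(0)
        assert len(cands) == 1
        assert homology_overlap(cands[0], tx) == 0

    def test_constructed_microhomology_counted_exactly(self):
        from _oracles import breakpoint_shift_homology

        cands, tx = self._candidate(4)
        assert len(cands) == 1
        got = homology_overlap(cands[0], tx)
        # oracle: exhaustive enumeration of breakpoint shifts on the transcripts
        expect = breakpoint_shift_homology(tx["GA.t1"], tx["GB.t1"], 304, 4)
        assert got == expect == 4

    @pytest.mark.parametrize("h,kept", [(13, 1), (14, 0)])
    def test_filter_boundary_at_13(self, h, kept):
        cands, tx = self._candidate(h)
        assert len(apply_homology_filter(cands, tx)) == kept

    def test_assembly_chimera_through_19_base_window_removed(self):
        """A false chimera joining two transcripts through a >= 19-base
        shared window is always rejected."""
        cands, tx = self._candidate(19)
        assert apply_homology_filter(cands, tx) == []


def test_candidate_flanks_never_below_minimum(rng):
    """Randomised fusion reads never yield a candidate with < 30-base flanks."""
    ref = two_gene_reference()
    _, index, tx = ref
    for _ in range(25):
        prefix = int(rng.integers(10, 90))
        suffix = int(rng.integers(10, 90))
        cut_a = int(rng.integers(100, 500))
        cut_b = int(rng.integers(50, 400))
        r = fusion_read(tx, "GA.t1", "GB.t1", cut_a, cut_b, prefix, suffix)
        t = TumourSequence(r.rid, r.seq)
        for c in select_multigene(t, _aln([r], tx)[r.rid], index, transcript_seqs=tx):
            bp = c.breakpoint_on_sequence
            assert bp - c.aln_a.q_start >= 30
            assert c.aln_b.q_end - bp >= 30


def test_candidate_tsv_writer(ref, tmp_path):
    from fusiondart.fusioncand import write_candidates_tsv, CANDIDATE_TSV_COLUMNS

    _, index, tx = ref
    r = fusion_read(tx, "GA.t1", "GB.t1", 300, 100, 60, 60)
    t = TumourSequence(r.rid, r.seq)
    cands = select_multigene(t, _aln([r], tx)[r.rid], index, transcript_seqs=tx)
    cands = apply_homology_filter(cands, tx)
    out = tmp_path / "cand.tsv"
    write_candidates_tsv(cands, out)
    lines = out.read_text().splitlines()
    assert lines[0].split("\t") == CANDIDATE_TSV_COLUMNS
    row = dict(zip(CANDIDATE_TSV_COLUMNS, lines[1].split("\t")))
    assert (row["gene_a"], row["gene_b"], row["breakpoint_on_sequence"]) == ("GA", "GB", "60")


def test_prefilter_never_loses_fusion_spanning_reads(ref):
    """Every error-free read carrying >= 30 bases either side of a fusion
    junction survives the two-stage prefilter."""
    genome, index, tx = ref
    masked = mask_exons(genome, index)
    masked_idx = SeedIndex(masked, 11, step=11)
    fusion = tx["GA.t1"][:300] + tx["GB.t1"][100:400]
    pairs = []
    for start in range(210, 271, 10):  # junction at 300 with >= 30-base flanks
        r1 = Read(f"f{start}/1", fusion[start : start + 120])
        r2 = Read(f"f{start}/2", revcomp(fusion[start + 180 : start + 300]))
        pairs.append((r1, r2))
    aln = _aln([r for p in pairs for r in p], tx)
    kept, _ = prefilter_reads(pairs, aln, masked_idx,
                              AlignParams(tile_size=11, min_score=20))
    assert kept == pairs
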