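"""Read preprocessing and initial fusion-candidate discovery.

Tumour sequences (reads or contigs) that align to two genes are the raw
material of fusion calling.  This module filters the read set down to the
informative remainder (concordant-to-transcriptome or not-genomic reads,
deduplicated, not wholly explained by a known transcript) and turns
multigene alignments into breakpoint candidates, rejecting chimeric
artifacts whose partner transcripts share sequence at the junction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .refmodel import TranscriptomeIndex
from .seedalign import AlignParams, LocalAlignment, SeedIndex, align
from .seqio import Read, revcomp

log = logging.getLogger(__name__)

Pair = tuple[Read, Optional[Read]]


@dataclass
class TumourSequence:
    """A candidate-bearing sequence: a raw read or a pre-assembled contig."""

    seq_id: str
    sequence: str
    origin: str = "read"  # {"read", "contig"}
    mate_of: Optional[str] = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.seq_id}: empty sequence")
        if self.origin not in ("read", "contig"):
            raise ValueError(f"{self.seq_id}: origin must be 'read' or 'contig'")


@dataclass(frozen=True)
class CandidateParams:
    """Candidate-selection thresholds.

    ``min_flank`` 30 bases of aligned sequence are required either side of
    the breakpoint; partner genes must be >= ``min_gene_separation`` (1 kb)
    apart on the genome; candidates whose partner transcripts share more
    than ``max_homology_overlap`` (13) bases at the junction are chimeric
    artifacts and rejected; up to ``max_query_insert`` unaligned query
    bases are tolerated between the two partner alignments (untemplated
    insertion).  ``whole_read_fraction`` defines "maps to a known
    transcript": at least this fraction of the read's bases matching one
    transcript (an end-to-end alignment surrogate).
    """

    min_flank: int = 30
    min_gene_separation: int = 1000
    max_homology_overlap: int = 13
    max_query_insert: int = 10
    whole_read_fraction: float = 0.98
    max_fragment: int = 1000

    def __post_init__(self):
        for name in ("min_flank", "min_gene_separation", "max_homology_overlap", "max_query_insert"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class FusionCandidate:
    """A tumour sequence split between two genes.

    ``sequence`` is the tumour sequence in fusion orientation (reverse
    complemented when the transcriptome alignments were on the minus
    strand), so ``gene_a`` always contributes the prefix (5' partner).
    ``breakpoint_on_sequence`` is the 0-based position of the first base
    from ``gene_b``, placed at the 3'-most point compatible with the
    prefix alignment so identical fusions discovered from different reads
    coincide.  ``pos_a_tx``/``pos_b_tx`` are the junction offsets on the
    partner transcripts (half-open, transcript orientation).
    """

    tumour_seq_id: str
    sequence: str
    origin: str
    gene_a: str
    gene_b: str
    transcript_a: str
    transcript_b: str
    breakpoint_on_sequence: int
    pos_a_tx: int
    pos_b_tx: int
    aln_a: LocalAlignment
    aln_b: LocalAlignment
    homology_overlap: Optional[int] = None

    def __post_init__(self):
        if self.gene_a == self.gene_b:
            raise ValueError("fusion partners must be distinct genes")


def whole_read_matches(
    alignments: Iterable[LocalAlignment], read_length: int, fraction: float = 0.98
) -> Optional[LocalAlignment]:
    """Best alignment explaining (almost) the whole read, or None.

    A read "maps to a known transcript" when one alignment matches at least
    ``fraction`` of its bases — the local-aligner analogue of an accepted
    end-to-end mapping.
    """
    need = fraction * read_length
    best = None
    for a in alignments:
        if a.matches >= need and (best is None or a.matches > best.matches):
            best = a
    return best


def _concordant(
    a1: Sequence[LocalAlignment],
    a2: Sequence[LocalAlignment],
    len1: int,
    len2: int,
    fraction: float,
    max_fragment: int,
) -> bool:
    """Both mates whole-mapped to one subject, opposite strands, fragment bound."""
    by_subj: dict[str, list[LocalAlignment]] = {}
    for a in a1:
        if a.matches >= fraction * len1:
            by_subj.setdefault(a.subject_id, []).append(a)
    for b in a2:
        if b.matches < fraction * len2:
            continue
        for a in by_subj.get(b.subject_id, ()):
            if a.strand == b.strand:
                continue
            frag = max(a.s_end, b.s_end) - min(a.s_start, b.s_start)
            if frag <= max_fragment:
                return True
    return False


def mask_exons(genome: Mapping[str, str], index: TranscriptomeIndex) -> dict[str, str]:
    """Replace every annotated exonic base with N; lengths preserved."""
    masked = {chrom: bytearray(seq, "ascii") for chrom, seq in genome.items()}
    for t in index.transcripts.values():
        buf = masked.get(t.chrom)
        if buf is None:
            continue
        for e in t.exons:
            buf[e.start : e.end] = b"N" * (e.end - e.start)
    return {chrom: buf.decode("ascii") for chrom, buf in masked.items()}


def prefilter_reads(
    pairs: Sequence[Pair],
    tx_aln: Mapping[str, list[LocalAlignment]],
    masked_genome_index: Optional[SeedIndex],
    align_params: AlignParams,
    params: CandidateParams = CandidateParams(),
) -> tuple[list[Pair], dict[str, int]]:
    """Two-stage preliminary filter removing intronic/intergenic fragments.

    Stage 1 retains pairs mapping concordantly to the reference
    transcriptome (``tx_aln`` holds each read's transcriptome alignments).
    Stage 2 maps the remainder against the exon-masked genome and retains
    only those that fail to map there — fragments that are neither regular
    transcript pieces nor genomic background, which is where fusion
    evidence lives.  Single-end units pass stage 1 on a whole-read match.
    """
    retained: list[Pair] = []
    stage2: list[Pair] = []
    frac = params.whole_read_fraction
    for pair in pairs:
        r1, r2 = pair
        if r2 is None:
            ok = whole_read_matches(tx_aln.get(r1.rid, ()), len(r1.seq), frac) is not None
        else:
            ok = _concordant(
                tx_aln.get(r1.rid, ()),
                tx_aln.get(r2.rid, ()),
                len(r1.seq),
                len(r2.seq),
                frac,
                params.max_fragment,
            )
        (retained if ok else stage2).append(pair)
    n_stage1 = len(retained)
    if masked_genome_index is None:
        if stage2:
            log.warning(
                "no exon-masked genome supplied; retaining all %d stage-1 failures",
                len(stage2),
            )
        retained.extend(stage2)
        n_genomic = 0
    else:
        n_genomic = 0
        for pair in stage2:
            aln = {
                r.rid: align(r.seq, masked_genome_index, align_params, query_step=1, query_id=r.rid)
                for r in pair
                if r is not None
            }
            r1, r2 = pair
            if r2 is None:
                genomic = (
                    whole_read_matches(aln[r1.rid], len(r1.seq), frac) is not None
                )
            else:
                genomic = _concordant(
                    aln[r1.rid], aln[r2.rid], len(r1.seq), len(r2.seq), frac, params.max_fragment
                )
            if genomic:
                n_genomic += 1
            else:
                retained.append(pair)
    stats = {
        "input_pairs": len(pairs),
        "concordant_transcriptome": n_stage1,
        "discarded_genomic": n_genomic,
        "retained": len(retained),
    }
    return retained, stats


def dedupe(pairs: Sequence[Pair]) -> list[Pair]:
    """Remove exact-sequence duplicate fragments, keeping first occurrence.

    Pairs are keyed on the ordered (mate1, mate2) sequences, so swapped-mate
    pairs are distinct fragment representations and both survive.
    """
    seen: set[tuple[str, str]] = set()
    out: list[Pair] = []
    for pair in pairs:
        r1, r2 = pair
        key = (r1.seq, r2.seq if r2 is not None else "")
        if key in seen:
            continue
        seen.add(key)
        out.append(pair)
    return out


MIN_READ_LENGTH = 60


def select_unmapped_reads(
    reads: Sequence[Read],
    tx_aln: Mapping[str, list[LocalAlignment]],
    contig_index: Optional[SeedIndex] = None,
    align_params: Optional[AlignParams] = None,
    params: CandidateParams = CandidateParams(),
) -> list[TumourSequence]:
    """Reads with no whole-read transcriptome match become tumour sequences.

    In Hybrid mode (``contig_index`` supplied) a read must additionally
    fail to map to the assembled contigs before being kept.  Reads shorter
    than 60 bases cannot carry the required breakpoint flanks and are
    refused.
    """
    short = [r for r in reads if len(r.seq) < MIN_READ_LENGTH]
    if short:
        raise ValueError(
            f"{len(short)} reads are shorter than {MIN_READ_LENGTH} bases; "
            "reads this short cannot hold the breakpoint flanks — assemble "
            "them and supply contigs (Assembly-mode input) instead"
        )
    frac = params.whole_read_fraction
    out: list[TumourSequence] = []
    for r in reads:
        if whole_read_matches(tx_aln.get(r.rid, ()), len(r.seq), frac) is not None:
            continue
        if contig_index is not None and align_params is not None:
            contig_hits = align(r.seq, contig_index, align_params, query_id=r.rid)
            if whole_read_matches(contig_hits, len(r.seq), frac) is not None:
                continue
        out.append(TumourSequence(r.rid, r.seq, origin="read"))
    return out


def _best_per_gene(
    alignments: Sequence[LocalAlignment], index: TranscriptomeIndex
) -> dict[str, LocalAlignment]:
    """Best alignment per gene: most matches, longest query span, lexicographic id."""
    best: dict[str, LocalAlignment] = {}
    for a in alignments:
        gene = index.gene_of(a.subject_id)
        cur = best.get(gene)
        if cur is None or (a.matches, a.q_span, cur.subject_id) > (
            cur.matches,
            cur.q_span,
            a.subject_id,
        ):
            best[gene] = a
    return best


def _gene_distance(index: TranscriptomeIndex, gene_a: str, gene_b: str) -> Optional[int]:
    ca, sa, ea, _ = index.gene_span[gene_a]
    cb, sb, eb, _ = index.gene_span[gene_b]
    if ca != cb:
        return None  # different chromosomes: unbounded separation
    return max(sb - ea, sa - eb, 0)


def _refine_breakpoint(
    sequence: str,
    a: LocalAlignment,
    b: LocalAlignment,
    transcript_seqs: Optional[Mapping[str, str]],
) -> int:
    """3'-most breakpoint position exactly compatible with the prefix alignment.

    When the two partner alignments overlap on the query (microhomology, or
    prefix over-extension through a near-match), the breakpoint is walked
    forward from the suffix alignment's start for as long as the tumour
    sequence still matches transcript A *exactly*.  Under h bases of true
    junction microhomology this yields the canonical 3'-most placement
    (start + h); a mismatch — over-extension, not homology — stops the walk
    at the real junction.
    """
    bp = a.q_end
    if transcript_seqs is None or b.q_start >= a.q_end:
        return bp
    ta = transcript_seqs.get(a.subject_id)
    if ta is None:
        return bp
    q = b.q_start
    while q < a.q_end:
        s = a.s_start + (q - a.q_start)
        if s >= len(ta) or sequence[q] != ta[s]:
            break
        q += 1
    return q


def select_multigene(
    tseq: TumourSequence,
    alignments: Sequence[LocalAlignment],
    index: TranscriptomeIndex,
    params: CandidateParams = CandidateParams(),
    transcript_seqs: Optional[Mapping[str, str]] = None,
) -> list[FusionCandidate]:
    """Turn a tumour sequence's transcriptome alignments into fusion candidates.

    The best alignment per gene is kept; a candidate is emitted for each
    gene pair whose alignments partition the query into a >= min_flank
    prefix from one gene and a >= min_flank suffix from another, with the
    junction overlap/insert within bounds and the genes >= 1 kb apart on
    the genome (or on different chromosomes).  The breakpoint is placed at
    the 3'-most position compatible with exact prefix-transcript matching
    (supplying ``transcript_seqs`` enables the exact-match refinement under
    alignment overlap; without them the prefix alignment's end is used).
    """
    per_gene = _best_per_gene(alignments, index)
    if len(per_gene) < 2:
        return []
    items = sorted(per_gene.items(), key=lambda kv: kv[1].q_start)
    out: list[FusionCandidate] = []
    for gene_a, a in items:
        for gene_b, b in items:
            if gene_a == gene_b or a.strand != b.strand:
                continue
            if not (a.q_start < b.q_start and a.q_end < b.q_end):
                continue
            gap = b.q_start - a.q_end  # negative = alignment overlap
            if gap > params.max_query_insert or -gap > params.max_homology_overlap:
                continue
            strand = a.strand
            sequence = tseq.sequence if strand == "+" else revcomp(tseq.sequence)
            sequence = sequence.upper()
            bp = _refine_breakpoint(sequence, a, b, transcript_seqs)
            if bp - a.q_start < params.min_flank or b.q_end - bp < params.min_flank:
                continue
            dist = _gene_distance(index, gene_a, gene_b)
            if dist is not None and dist < params.min_gene_separation:
                continue
            pos_b_tx = b.s_start + max(0, bp - b.q_start)
            out.append(
                FusionCandidate(
                    tumour_seq_id=tseq.seq_id,
                    sequence=sequence.upper(),
                    origin=tseq.origin,
                    gene_a=gene_a,
                    gene_b=gene_b,
                    transcript_a=a.subject_id,
                    transcript_b=b.subject_id,
                    breakpoint_on_sequence=bp,
                    pos_a_tx=a.s_start + (bp - a.q_start),
                    pos_b_tx=pos_b_tx,
                    aln_a=a,
                    aln_b=b,
                )
            )
    return out


def homology_overlap(candidate: FusionCandidate, transcript_seqs: Mapping[str, str]) -> int:
    """Bases the partner transcripts share at the breakpoint.

    The count is the length of the interval over which the breakpoint
    could slide with both partner alignments still exact: bases of
    transcript A continuing past the junction that equal the start of the
    gene-B segment, plus bases of transcript B preceding its junction that
    equal the end of the gene-A segment.  Candidates exceeding the 13-base
    cap are chimeric artifacts of shared sequence.
    """
    ta = transcript_seqs[candidate.transcript_a]
    tb = transcript_seqs[candidate.transcript_b]
    pa, pb = candidate.pos_a_tx, candidate.pos_b_tx
    fwd = 0
    while pa + fwd < len(ta) and pb + fwd < len(tb) and ta[pa + fwd] == tb[pb + fwd]:
        fwd += 1
    back = 0
    while back < pa and back < pb and ta[pa - 1 - back] == tb[pb - 1 - back]:
        back += 1
    return fwd + back


CANDIDATE_TSV_COLUMNS = [
    "tumour_seq_id",
    "origin",
    "gene_a",
    "gene_b",
    "transcript_a",
    "transcript_b",
    "breakpoint_on_sequence",
    "pos_a_tx",
    "pos_b_tx",
    "homology_overlap",
]


def write_candidates_tsv(candidates: Sequence[FusionCandidate], path) -> None:
    """Intermediate candidate table (one row per candidate, tab-separated)."""
    with open(path, "w") as fh:
        fh.write("\t".join(CANDIDATE_TSV_COLUMNS) + "\n")
        for c in candidates:
            fh.write(
                "\t".join(
                    "-" if (v := getattr(c, col)) is None else str(v)
                    for col in CANDIDATE_TSV_COLUMNS
                )
                + "\n"
            )


def apply_homology_filter(
    candidates: Sequence[FusionCandidate],
    transcript_seqs: Mapping[str, str],
    params: CandidateParams = CandidateParams(),
) -> list[FusionCandidate]:
    """Annotate candidates with their junction homology and drop the chimeras."""
    kept = []
    for c in candidates:
        c.homology_overlap = homology_overlap(c, transcript_seqs)
        if c.homology_overlap <= params.max_homology_overlap:
            kept.append(c)
    return kept
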