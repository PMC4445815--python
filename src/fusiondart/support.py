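"""Spanning-read and spanning-pair support for candidate breakpoints.

Two counting semantics exist.  In contig mode the sample's reads are
re-mapped to the candidate sequence itself: spanning reads cover the
breakpoint with a 15-base flank either side, spanning pairs straddle it.
In Direct mode the candidate *is* a read (one spanning read by
construction, with a 30-base flank enforced upstream) and pairs are found
among transcriptome alignments that are discordant in exactly the way the
predicted fusion implies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .fusioncand import FusionCandidate, Pair, whole_read_matches
from .seedalign import AlignParams, LocalAlignment, SeedIndex, align


@dataclass
class SupportCounts:
    """Breakpoint support.  ``spanning_pairs`` is None for single-end data
    (pairs are not computable, which is different from observing zero)."""

    spanning_reads: int
    spanning_pairs: Optional[int]

    def __post_init__(self):
        if self.spanning_reads < 0 or (
            self.spanning_pairs is not None and self.spanning_pairs < 0
        ):
            raise ValueError("support counts must be >= 0")

    @property
    def total(self) -> int:
        return self.spanning_reads + (self.spanning_pairs or 0)


@dataclass(frozen=True)
class SupportParams:
    """``spanning_read_flank``: bases required either side of the break for a
    re-mapped read to count (15, contig mode; Direct mode discovery already
    demands the 30-base candidate flank).  ``pair_window``: a Direct-mode
    mate must sit within this many bases of the breakpoint on its
    transcript to be fragment-length-consistent with the fusion."""

    spanning_read_flank: int = 15
    pair_window: int = 1000
    min_identity_percent: float = 95.0

    def __post_init__(self):
        if self.spanning_read_flank <= 0:
            raise ValueError("spanning_read_flank must be > 0")


def count_support_contig(
    candidate: FusionCandidate,
    pairs: Sequence[Pair],
    params: SupportParams = SupportParams(),
    tile_size: int = 15,
) -> SupportCounts:
    """Re-map reads to the candidate sequence and count spanning evidence.

    Reads take their best single alignment (min identity 95%, ungapped);
    pairs are counted only when concordant on the candidate (both mates
    aligned, opposite strands) with the mates entirely on opposite sides
    of the breakpoint.
    """
    bp = candidate.breakpoint_on_sequence
    seq = candidate.sequence
    index = SeedIndex({"candidate": seq}, tile_size, step=1)
    aln_params = AlignParams(
        tile_size=tile_size,
        min_identity_percent=params.min_identity_percent,
        min_score=tile_size,
        max_gap_on_subject=0,
    )
    flank = params.spanning_read_flank
    spanning_reads = 0
    spanning_pairs = 0
    paired = any(r2 is not None for _, r2 in pairs)
    for r1, r2 in pairs:
        best: dict[str, LocalAlignment] = {}
        for r in (r1, r2):
            if r is None:
                continue
            hits = align(r.seq, index, aln_params, query_step=tile_size, query_id=r.rid)
            if hits:
                best[r.rid] = hits[0]
        for r in (r1, r2):
            if r is None or r.rid not in best:
                continue
            a = best[r.rid]
            if a.s_start <= bp - flank and a.s_end >= bp + flank:
                spanning_reads += 1
        if r2 is not None and r1.rid in best and r2.rid in best:
            a, b = best[r1.rid], best[r2.rid]
            if a.strand != b.strand:
                left, right = (a, b) if a.s_start <= b.s_start else (b, a)
                if left.s_end <= bp and right.s_start >= bp:
                    spanning_pairs += 1
    return SupportCounts(spanning_reads, spanning_pairs if paired else None)


def count_support_direct(
    candidate: FusionCandidate,
    pairs: Sequence[Pair],
    tx_aln: Mapping[str, list[LocalAlignment]],
    params: SupportParams = SupportParams(),
    whole_read_fraction: float = 0.98,
    n_discoveries: int = 1,
) -> SupportCounts:
    """Direct-mode support: the discovering read(s) plus discordant pairs.

    Each Direct candidate starts with one spanning read per read that
    discovered this exact breakpoint.  Spanning pairs are read pairs whose
    mates whole-map to the two partner transcripts on opposite sides of
    the predicted junction with fusion-consistent orientation: the gene-A
    mate reads towards the break (+ on transcript A, ending at or before
    it) and the gene-B mate reads back towards it (- on transcript B,
    starting at or after it).  Pairs near a transcript end cannot be found.
    """
    pa, pb = candidate.pos_a_tx, candidate.pos_b_tx
    ta, tb = candidate.transcript_a, candidate.transcript_b
    win = params.pair_window
    paired = any(r2 is not None for _, r2 in pairs)
    spanning_pairs = 0
    for r1, r2 in pairs:
        if r2 is None:
            continue
        found = False
        for x, y in ((r1, r2), (r2, r1)):
            ax = _whole_to(tx_aln.get(x.rid, ()), ta, len(x.seq), whole_read_fraction)
            ay = _whole_to(tx_aln.get(y.rid, ()), tb, len(y.seq), whole_read_fraction)
            if (
                ax is not None
                and ay is not None
                and ax.strand == "+"
                and ay.strand == "-"
                and ax.s_end <= pa
                and ay.s_start >= pb
                and pa - ax.s_start <= win
                and ay.s_end - pb <= win
            ):
                found = True
                break
        if found:
            spanning_pairs += 1
    return SupportCounts(n_discoveries, spanning_pairs if paired else None)


def _whole_to(alignments, subject_id, read_len, fraction):
    subset = [a for a in alignments if a.subject_id == subject_id]
    return whole_read_matches(subset, read_len, fraction)


def aggregate_support(
    candidates: Sequence[tuple[FusionCandidate, SupportCounts]],
) -> tuple[FusionCandidate, SupportCounts]:
    """Merge candidates predicting the same breakpoint.

    Spanning reads and pairs are summed; the representative sequence is
    the one with the most spanning reads (ties: longest sequence, then
    lexicographic id).  Aggregation is associative and order-independent.
    """
    if not candidates:
        raise ValueError("aggregate_support requires at least one candidate")
    sr = sum(s.spanning_reads for _, s in candidates)
    if all(s.spanning_pairs is None for _, s in candidates):
        sp = None
    else:
        sp = sum(s.spanning_pairs or 0 for _, s in candidates)
    rep = max(
        candidates,
        key=lambda cs: (
            cs[1].spanning_reads,
            len(cs[0].sequence),
            _neg_lex(cs[0].tumour_seq_id),
        ),
    )[0]
    return rep, SupportCounts(sr, sp)


def write_support_tsv(
    rows: Sequence[tuple[FusionCandidate, SupportCounts]], path
) -> None:
    """Intermediate support table: seq_id, genes, breakpoint, counts."""
    with open(path, "w") as fh:
        fh.write(
            "seq_id\tgene_a\tgene_b\tbreak_pos\tspanning_reads\tspanning_pairs\n"
        )
        for cand, counts in rows:
            sp = "-" if counts.spanning_pairs is None else counts.spanning_pairs
            fh.write(
                f"{cand.tumour_seq_id}\t{cand.gene_a}\t{cand.gene_b}\t"
                f"{cand.breakpoint_on_sequence}\t{counts.spanning_reads}\t{sp}\n"
            )


class _neg_lex(str):
    """Reverse lexicographic comparison wrapper (smallest id wins ties)."""

    def __lt__(self, other):
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)
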