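"""Internal seed-and-extend local aligner and PSL codec.

This is the pipeline's stand-in for BLAT: queries are seeded with exact
k-mer tiles against an indexed subject database, seeds on compatible
diagonals are clustered and extended ungapped to the maximal-scoring
segment (match +1, mismatch -1), and co-linear segments may be chained
with subject-side gaps (introns) when the caller allows them.  Alignments
are expressed as PSL-style blocked records so externally produced BLAT
output can be substituted bit-for-bit through :func:`read_psl`.

Divergences from BLAT are deliberate and small: ``min_score`` counts
matched bases (close to BLAT's score for the near-exact hits this pipeline
cares about), extension is ungapped per block, and there is no spliced
scoring model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .seqio import revcomp


@dataclass(frozen=True)
class AlignParams:
    """Alignment acceptance thresholds (transcriptome-mode defaults).

    ``tile_size`` 15 suits reads under 100 bases; 18 is used for longer
    reads or contigs.  ``min_identity_percent`` 98 and ``min_score`` 30
    matched bases reproduce the transcriptome alignment acceptance the
    pipeline is built around.  ``max_gap_on_subject`` 0 forbids intronic
    gaps (transcripts are already spliced); ``None`` means unlimited, for
    genome alignment.
    """

    tile_size: int = 15
    min_identity_percent: float = 98.0
    min_score: int = 30
    max_gap_on_subject: Optional[int] = 0
    max_query_gap: int = 10
    diagonal_tolerance: int = 5

    def __post_init__(self):
        if self.tile_size < 8:
            raise ValueError("tile_size must be >= 8")
        if not 0 < self.min_identity_percent <= 100:
            raise ValueError("min_identity_percent must be in (0, 100]")
        if self.min_score < self.tile_size:
            raise ValueError("min_score must be >= tile_size")


def auto_tile_size(query_length: int, is_contig: bool = False) -> int:
    """Tile-size policy: 18 for contigs or queries >= 100 bases, else 15."""
    return 18 if (is_contig or query_length >= 100) else 15


@dataclass
class LocalAlignment:
    """A blocked, strand-aware local alignment of a query against a subject.

    Block query coordinates (and ``q_start``/``q_end``) are in the *aligned
    orientation* of the query — i.e. on the reverse complement when
    ``strand`` is '-', matching the PSL negative-strand convention for
    ``qStarts``.  Subject coordinates are always forward.
    """

    query_id: str
    subject_id: str
    strand: str
    blocks: tuple[tuple[int, int, int], ...]  # (query_start, subject_start, length)
    matches: int
    mismatches: int
    query_length: int
    subject_length: int

    @property
    def q_start(self) -> int:
        return self.blocks[0][0]

    @property
    def q_end(self) -> int:
        qs, _, ln = self.blocks[-1]
        return qs + ln

    @property
    def s_start(self) -> int:
        return self.blocks[0][1]

    @property
    def s_end(self) -> int:
        _, ss, ln = self.blocks[-1]
        return ss + ln

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start

    @property
    def identity_percent(self) -> float:
        aligned = self.matches + self.mismatches
        return 100.0 * self.matches / aligned if aligned else 0.0

    def project_query_to_subject(self, qpos: int) -> Optional[int]:
        """Subject coordinate of an aligned-orientation query base, or None."""
        for qs, ss, ln in self.blocks:
            if qs <= qpos < qs + ln:
                return ss + (qpos - qs)
        return None


class SeedIndex:
    """k-mer tile index over a subject sequence database.

    ``step`` controls tile sampling on the subject: 1 (every position, the
    transcriptome default, letting queries be scanned sparsely) or
    ``tile_size`` (non-overlapping tiles, the genome default, with queries
    scanned at every position).
    """

    def __init__(self, subjects: Mapping[str, str], tile_size: int, step: int = 1):
        if tile_size < 8:
            raise ValueError("tile_size must be >= 8")
        self.tile_size = tile_size
        self.step = step
        self.subjects = {sid: seq.upper() for sid, seq in subjects.items()}
        self.arrays = {
            sid: np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            for sid, seq in self.subjects.items()
        }
        tiles: dict[str, list[tuple[str, int]]] = {}
        k = tile_size
        for sid, seq in self.subjects.items():
            for off in range(0, len(seq) - k + 1, step):
                tile = seq[off : off + k]
                if "N" in tile:
                    continue
                tiles.setdefault(tile, []).append((sid, off))
        self.tiles = tiles

    def __contains__(self, tile: str) -> bool:
        return tile in self.tiles


def build_seed_index(
    subject_db: Mapping[str, str], tile_size: int, step: int = 1
) -> SeedIndex:
    return SeedIndex(subject_db, tile_size, step)


def _extend_cluster(qarr, sarr, diag, seed_lo, seed_hi, penalty: int = 1):
    """Maximal-scoring ungapped segment on one diagonal containing the seeds.

    Scoring is match +1 / mismatch -``penalty``; the optimal interval is
    found exactly with prefix sums, so block edges always land on matching
    bases.
    """
    lo = max(0, -diag)
    hi = min(len(qarr), len(sarr) - diag)
    if hi <= lo:
        return None
    eq = qarr[lo:hi] == sarr[lo + diag : hi + diag]
    score = np.where(eq, np.int32(1), np.int32(-penalty))
    prefix = np.empty(len(score) + 1, dtype=np.int64)
    prefix[0] = 0
    np.cumsum(score, out=prefix[1:])
    a = max(seed_lo - lo, 0)
    b = min(seed_hi - lo, hi - lo)
    if b <= a:
        return None
    # ties break toward the shortest optimal interval (last minimum, first
    # maximum), so zero-scoring junk is never absorbed at the edges
    head = prefix[: a + 1]
    i = a - int(np.argmin(head[::-1]))
    j = b + int(np.argmax(prefix[b:]))
    if j <= i:
        return None
    matches = int(np.count_nonzero(eq[i:j]))
    length = j - i
    return (lo + i, lo + i + diag, length, matches)


def _cluster_diagonals(diag_hits: dict[int, list[int]], tolerance: int):
    """Group diagonals within ``tolerance`` of each other; yield
    (representative_diag, min_qpos, max_qpos) per group."""
    diags = sorted(diag_hits)
    group: list[int] = []
    for d in diags:
        if group and d - group[-1] > tolerance:
            yield _summarise_group(group, diag_hits)
            group = []
        group.append(d)
    if group:
        yield _summarise_group(group, diag_hits)


def _summarise_group(group, diag_hits):
    rep = max(group, key=lambda d: (len(diag_hits[d]), -abs(d)))
    qpos = [p for d in group for p in diag_hits[d]]
    return rep, min(qpos), max(qpos)


def _chain_blocks(blocks, params: AlignParams):
    """Greedy best-chain extraction over co-linear blocks (one subject/strand).

    Returns chains (lists of blocks) ordered by total matches.  With
    ``max_gap_on_subject == 0`` every block is its own chain.
    """
    if params.max_gap_on_subject == 0 or len(blocks) == 1:
        return [[b] for b in blocks]
    remaining = sorted(blocks, key=lambda b: (b[0], b[1]))
    chains = []
    max_gap = params.max_gap_on_subject
    while remaining:
        n = len(remaining)
        best = [None] * n
        score = [0] * n
        for i, (qs, ss, ln, m) in enumerate(remaining):
            score[i] = m
            for j in range(i):
                pqs, pss, pln, _ = remaining[j]
                q_gap = qs - (pqs + pln)
                s_gap = ss - (pss + pln)
                if (
                    -params.diagonal_tolerance <= q_gap <= params.max_query_gap
                    and s_gap >= -params.diagonal_tolerance
                    and (max_gap is None or s_gap <= max_gap)
                    and score[j] + m > score[i]
                ):
                    score[i] = score[j] + m
                    best[i] = j
        end = max(range(n), key=lambda i: score[i])
        chain = []
        i = end
        while i is not None:
            chain.append(remaining[i])
            i = best[i]
        chain.reverse()
        used = set(id(b) for b in chain)
        remaining = [b for b in remaining if id(b) not in used]
        chains.append(chain)
    return chains


def _trim_chain_overlaps(chain, qarr, sarr):
    """Resolve block overlaps so chained blocks are strictly ascending.

    Where adjacent blocks overlap (fuzzy over-extension into an intron, or
    shared junction sequence), the split point inside the contested query
    window is chosen to maximise total matches, ties toward extending the
    earlier block (3'-most placement)."""
    out: list[tuple[int, int, int, int]] = []
    for qs, ss, ln, matches in chain:
        if out:
            pqs, pss, pln, _pm = out[-1]
            if pqs + pln > qs:  # query overlap: pick the best split point
                win_lo, win_hi = qs, pqs + pln
                diag_p, diag_n = pss - pqs, ss - qs
                eq_p = qarr[win_lo:win_hi] == sarr[win_lo + diag_p : win_hi + diag_p]
                eq_n = qarr[win_lo:win_hi] == sarr[win_lo + diag_n : win_hi + diag_n]
                cum_p = np.concatenate(([0], np.cumsum(eq_p)))
                cum_n = np.concatenate(([0], np.cumsum(eq_n)))
                gain = cum_p + (cum_n[-1] - cum_n)
                t = len(gain) - 1 - int(np.argmax(gain[::-1]))  # last argmax
                split = win_lo + t
                new_pln = split - pqs
                if new_pln <= 0:
                    out.pop()
                else:
                    pm2 = int(
                        np.count_nonzero(qarr[pqs:split] == sarr[pss : pss + new_pln])
                    )
                    out[-1] = (pqs, pss, new_pln, pm2)
                cut = split - qs
                qs, ss, ln = qs + cut, ss + cut, ln - cut
                if ln <= 0:
                    continue
                matches = int(
                    np.count_nonzero(qarr[qs : qs + ln] == sarr[ss : ss + ln])
                )
            if out:  # residual subject-side overlap: trim the next head
                pqs, pss, pln, _pm = out[-1]
                sov = pss + pln - ss
                if sov > 0:
                    qs, ss, ln = qs + sov, ss + sov, ln - sov
                    if ln <= 0:
                        continue
                    matches = int(
                        np.count_nonzero(qarr[qs : qs + ln] == sarr[ss : ss + ln])
                    )
        out.append((qs, ss, ln, matches))
    return out


def align(
    query: str,
    index: SeedIndex,
    params: AlignParams,
    query_step: int = 1,
    query_id: str = "query",
) -> list[LocalAlignment]:
    """Align a query against the indexed subjects, both orientations.

    ``query_step`` sets the query k-mer sampling stride; the final window is
    always sampled so end-anchored segments as short as the tile size can
    seed.  Alignments failing ``min_score`` matched bases or the identity
    threshold are dropped; survivors are sorted by matches descending, ties
    by (subject_id, s_start).
    """
    query = query.upper()
    k = index.tile_size
    L = len(query)
    out: list[LocalAlignment] = []
    if L < k:
        return out
    tiles = index.tiles
    for strand in ("+", "-"):
        qseq = query if strand == "+" else revcomp(query)
        qarr = np.frombuffer(qseq.encode("ascii"), dtype=np.uint8)
        positions = list(range(0, L - k + 1, query_step))
        if positions[-1] != L - k:
            positions.append(L - k)
        by_subject: dict[str, dict[int, list[int]]] = {}
        for qpos in positions:
            hits = tiles.get(qseq[qpos : qpos + k])
            if not hits:
                continue
            for sid, off in hits:
                by_subject.setdefault(sid, {}).setdefault(off - qpos, []).append(qpos)
        min_frac = params.min_identity_percent / 100.0
        strict_penalty = (
            10**6
            if params.min_identity_percent >= 100
            else max(1, round(min_frac / (1 - min_frac)))
        )
        for sid, diag_hits in by_subject.items():
            sarr = index.arrays[sid]
            slen = len(sarr)
            blocks = []
            seen = set()
            for diag, qlo, qhi in _cluster_diagonals(diag_hits, params.diagonal_tolerance):
                ext = _extend_cluster(qarr, sarr, diag, qlo, qhi + k)
                if ext is not None and ext[3] < min_frac * ext[2]:
                    # score-optimal interval fails the identity threshold
                    # (junk absorbed beyond the homologous region): re-extract
                    # under a mismatch penalty consistent with that threshold
                    ext = _extend_cluster(
                        qarr, sarr, diag, qlo, qhi + k, penalty=strict_penalty
                    )
                if ext is None or ext[:3] in seen:
                    continue
                seen.add(ext[:3])
                blocks.append(ext)
            for chain in _chain_blocks(blocks, params):
                chain = _trim_chain_overlaps(chain, qarr, sarr)
                if not chain:
                    continue
                matches = sum(b[3] for b in chain)
                mismatches = sum(b[2] - b[3] for b in chain)
                if matches < params.min_score:
                    continue
                identity = 100.0 * matches / (matches + mismatches)
                if identity < params.min_identity_percent:
                    continue
                out.append(
                    LocalAlignment(
                        query_id=query_id,
                        subject_id=sid,
                        strand=strand,
                        blocks=tuple((qs, ss, ln) for qs, ss, ln, _ in chain),
                        matches=matches,
                        mismatches=mismatches,
                        query_length=L,
                        subject_length=slen,
                    )
                )
    out.sort(key=lambda a: (-a.matches, a.subject_id, a.s_start))
    return out


def align_many(
    queries: Iterable[tuple[str, str]],
    index: SeedIndex,
    params: AlignParams,
    query_step: int = 1,
) -> dict[str, list[LocalAlignment]]:
    """Align many (id, sequence) queries; returns id -> alignments."""
    return {
        qid: align(seq, index, params, query_step=query_step, query_id=qid)
        for qid, seq in queries
    }


# ---------------------------------------------------------------------------
# PSL I/O (21-column BLAT dialect, 0-based half-open)

PSL_HEADER = (
    "psLayout version 3\n\n"
    "match\tmis- \trep. \tN's\tQ gap\tQ gap\tT gap\tT gap\tstrand\tQ        \t"
    "Q   \tQ    \tQ  \tT        \tT   \tT    \tT  \tblock\tblockSizes \tqStarts\t tStarts\n"
    "     \tmatch\tmatch\t   \tcount\tbases\tcount\tbases\t      \tname     \t"
    "size\tstart\tend\tname     \tsize\tstart\tend\tcount\n"
    + "-" * 159
    + "\n"
)


def _insert_counts(blocks):
    qnum = qbases = tnum = tbases = 0
    for (pq, pt, pl), (q, t, _l) in zip(blocks, blocks[1:]):
        qgap = q - (pq + pl)
        tgap = t - (pt + pl)
        if qgap > 0:
            qnum += 1
            qbases += qgap
        if tgap > 0:
            tnum += 1
            tbases += tgap
    return qnum, qbases, tnum, tbases


def write_psl(alignments: Sequence[LocalAlignment], path, header: bool = False) -> None:
    """Write alignments as 21-column PSL, optionally with the 5-line header."""
    with open(path, "w") as fh:
        if header:
            fh.write(PSL_HEADER)
        for a in alignments:
            qnum, qbases, tnum, tbases = _insert_counts(a.blocks)
            if a.strand == "+":
                q_start, q_end = a.q_start, a.q_end
            else:
                q_start, q_end = a.query_length - a.q_end, a.query_length - a.q_start
            sizes = ",".join(str(ln) for _, _, ln in a.blocks) + ","
            qstarts = ",".join(str(qs) for qs, _, _ in a.blocks) + ","
            tstarts = ",".join(str(ss) for _, ss, _ in a.blocks) + ","
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        a.matches,
                        a.mismatches,
                        0,
                        0,
                        qnum,
                        qbases,
                        tnum,
                        tbases,
                        a.strand,
                        a.query_id,
                        a.query_length,
                        q_start,
                        q_end,
                        a.subject_id,
                        a.subject_length,
                        a.s_start,
                        a.s_end,
                        len(a.blocks),
                        sizes,
                        qstarts,
                        tstarts,
                    )
                )
                + "\n"
            )


def read_psl(path) -> list[LocalAlignment]:
    """Parse a PSL file (with or without header) into LocalAlignment records."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if lineno <= 5 and not fields[0].strip().isdigit():
                continue  # header block
            if len(fields) != 21:
                raise ValueError(
                    f"{path}:{lineno}: expected 21 PSL columns, got {len(fields)}"
                )
            try:
                matches, mismatches = int(fields[0]), int(fields[1])
                strand = fields[8]
                qid, qlen = fields[9], int(fields[10])
                sid, slen = fields[13], int(fields[14])
                nblocks = int(fields[17])
                sizes = [int(x) for x in fields[18].rstrip(",").split(",")]
                qstarts = [int(x) for x in fields[19].rstrip(",").split(",")]
                tstarts = [int(x) for x in fields[20].rstrip(",").split(",")]
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed PSL fields") from None
            if not (len(sizes) == len(qstarts) == len(tstarts) == nblocks):
                raise ValueError(f"{path}:{lineno}: block list length mismatch")
            blocks = tuple(zip(qstarts, tstarts, sizes))
            out.append(
                LocalAlignment(
                    query_id=qid,
                    subject_id=sid,
                    strand=strand[0],
                    blocks=blocks,
                    matches=matches,
                    mismatches=mismatches,
                    query_length=qlen,
                    subject_length=slen,
                )
            )
    return out
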