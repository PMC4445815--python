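"""Reference genome and transcript annotation model.

The pipeline compares tumour sequences against a reference *transcriptome*,
so this module owns the mapping between spliced transcript coordinates and
the genome: exon models, transcript sequence extraction, exon-boundary
lookup (used to decide whether a transcriptional breakpoint coincides with
an annotated splice junction) and reading-frame phase queries.

Coordinates are 0-based, half-open throughout; user-facing tables convert
to 1-based positions at the reporting layer.
"""

from __future__ import annotations

import re
from bisect import bisect_left
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np

from .seqio import revcomp, write_fasta


@dataclass(frozen=True)
class ExonInterval:
    """A genomic exon: 0-based half-open interval on a stranded chromosome."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"exon start {self.start} >= end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """One transcript isoform: exons ordered 5'->3' in transcript orientation.

    ``cds_start_offset``/``cds_end_offset`` are 0-based offsets of the coding
    region within the spliced transcript; both absent for non-coding
    transcripts.
    """

    transcript_id: str
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    exons: tuple[ExonInterval, ...]
    cds_start_offset: Optional[int] = None
    cds_end_offset: Optional[int] = None

    def __post_init__(self):
        self.exons = tuple(self.exons)
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        starts = [e.start for e in self.exons]
        expected = sorted(starts, reverse=self.strand == "-")
        if starts != expected:
            raise ValueError(
                f"{self.transcript_id}: exon order inconsistent with strand"
            )
        ivs = sorted((e.start, e.end) for e in self.exons)
        for (s1, e1), (s2, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start_offset is not None

    def spliced_offset_of_boundary(self, genomic_pos: int) -> Optional[int]:
        """Spliced-transcript offset of an exon-edge genomic coordinate.

        The boundary is interpreted as a junction point: an exon's
        transcript-3' edge maps to the cumulative length through that exon
        and its transcript-5' edge to the cumulative length before it.
        Returns None when the coordinate is not an edge of any exon.
        """
        cum = 0
        for exon in self.exons:
            five, three = (
                (exon.start, exon.end) if self.strand == "+" else (exon.end, exon.start)
            )
            if genomic_pos == five:
                return cum
            if genomic_pos == three:
                return cum + len(exon)
            cum += len(exon)
        return None


class TranscriptomeIndex:
    """Indexed collection of transcript models for one annotation."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        ordered = sorted(transcripts, key=lambda t: (t.gene_id, t.transcript_id))
        self.transcripts: dict[str, TranscriptModel] = {
            t.transcript_id: t for t in ordered
        }
        if len(self.transcripts) != len(ordered):
            raise ValueError("duplicate transcript_id in annotation")
        self.gene_transcripts: dict[str, list[str]] = defaultdict(list)
        self.gene_name: dict[str, str] = {}
        bounds: dict[str, set[int]] = defaultdict(set)
        span: dict[str, list] = {}
        for t in ordered:
            self.gene_transcripts[t.gene_id].append(t.transcript_id)
            self.gene_name.setdefault(t.gene_id, t.gene_name)
            for e in t.exons:
                bounds[e.chrom].add(e.start)
                bounds[e.chrom].add(e.end)
            lo = min(e.start for e in t.exons)
            hi = max(e.end for e in t.exons)
            if t.gene_id in span:
                s = span[t.gene_id]
                s[1], s[2] = min(s[1], lo), max(s[2], hi)
            else:
                span[t.gene_id] = [t.chrom, lo, hi, t.strand]
        self.boundaries: dict[str, np.ndarray] = {
            c: np.array(sorted(v), dtype=np.int64) for c, v in bounds.items()
        }
        self.gene_span: dict[str, tuple[str, int, int, str]] = {
            g: tuple(v) for g, v in span.items()
        }

    def __len__(self) -> int:
        return len(self.transcripts)

    def gene_of(self, transcript_id: str) -> str:
        return self.transcripts[transcript_id].gene_id

    def is_exon_boundary(self, chrom: str, pos: int, tolerance: int = 0) -> bool:
        """True iff an annotated exon start/end lies within ``tolerance`` of pos."""
        if tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        arr = self.boundaries.get(chrom)
        if arr is None or len(arr) == 0:
            return False
        i = bisect_left(arr, pos)
        for j in (i - 1, i):
            if 0 <= j < len(arr) and abs(int(arr[j]) - pos) <= tolerance:
                return True
        return False

    def gene_common_frame(self, gene_id: str, genomic_breakpoint: int) -> Optional[int]:
        """Modal coding-frame phase of the gene's isoforms at an exon boundary.

        For every coding isoform for which the breakpoint is an exon edge and
        falls inside the coding region, the phase is the spliced coding
        offset mod 3.  Ties go to the smallest phase; None when no coding
        isoform covers the boundary.
        """
        if gene_id not in self.gene_transcripts:
            raise KeyError(f"unknown gene {gene_id!r}")
        phases: Counter[int] = Counter()
        for tid in self.gene_transcripts[gene_id]:
            t = self.transcripts[tid]
            if not t.is_coding:
                continue
            off = t.spliced_offset_of_boundary(genomic_breakpoint)
            if off is None:
                continue
            coding = off - t.cds_start_offset
            cds_end = (
                t.cds_end_offset if t.cds_end_offset is not None else t.spliced_length
            )
            if coding < 0 or off > cds_end:
                continue
            phases[coding % 3] += 1
        if not phases:
            return None
        return max(phases.items(), key=lambda kv: (kv[1], -kv[0]))[0]


# ---------------------------------------------------------------------------
# annotation parsing

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf(lines, path) -> list[TranscriptModel]:
    exons: dict[str, list[ExonInterval]] = defaultdict(list)
    cds: dict[str, list[tuple[int, int]]] = defaultdict(list)
    meta: dict[str, tuple[str, str, str, str]] = {}
    for lineno, line in enumerate(lines, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"{path}:{lineno}: expected 9 GTF columns, got {len(fields)}")
        chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields
        if feature not in ("exon", "CDS"):
            continue
        try:
            start_i, end_i = int(start) - 1, int(end)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
        a = dict(_GTF_ATTR.findall(attrs))
        tid = a.get("transcript_id")
        if tid is None:
            raise ValueError(f"{path}:{lineno}: missing transcript_id attribute")
        gid = a.get("gene_id", tid)
        meta.setdefault(tid, (gid, a.get("gene_name", gid), chrom, strand))
        if feature == "exon":
            exons[tid].append(ExonInterval(chrom, start_i, end_i, strand))
        else:
            cds[tid].append((start_i, end_i))
    out = []
    for tid, (gid, gname, chrom, strand) in meta.items():
        if tid not in exons:
            continue
        exs = sorted(exons[tid], key=lambda e: e.start, reverse=strand == "-")
        t = TranscriptModel(tid, gid, gname, chrom, strand, tuple(exs))
        if tid in cds:
            lo = min(s for s, _ in cds[tid])
            hi = max(e for _, e in cds[tid])
            five = t.spliced_offset_of_boundary(lo if strand == "+" else hi)
            three = t.spliced_offset_of_boundary(hi if strand == "+" else lo)
            if five is None or three is None:
                # CDS edges inside an exon: project through exon walk
                five = _project_genomic(t, lo if strand == "+" else hi - 1, left=True)
                three = _project_genomic(t, hi - 1 if strand == "+" else lo, left=False)
            t.cds_start_offset, t.cds_end_offset = five, three
        out.append(t)
    return out


def _project_genomic(t: TranscriptModel, gpos: int, left: bool) -> int:
    """Spliced offset of a genomic base inside an exon (junction side per ``left``)."""
    cum = 0
    for e in t.exons:
        if e.start <= gpos < e.end:
            within = gpos - e.start if t.strand == "+" else e.end - 1 - gpos
            return cum + within + (0 if left else 1)
        cum += len(e)
    raise ValueError(f"{t.transcript_id}: genomic position {gpos} not exonic")


def _parse_tabular(lines, path) -> list[TranscriptModel]:
    """refFlat-style table: geneID txID chrom strand exonStarts exonEnds [cdsStart cdsEnd]."""
    out = []
    for lineno, line in enumerate(lines, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) not in (6, 8):
            raise ValueError(
                f"{path}:{lineno}: expected 6 or 8 tab-separated columns, got {len(fields)}"
            )
        gid, tid, chrom, strand = fields[:4]
        try:
            starts = [int(x) for x in fields[4].rstrip(",").split(",")]
            ends = [int(x) for x in fields[5].rstrip(",").split(",")]
        except ValueError:
            raise ValueError(f"{path}:{lineno}: malformed exon coordinate list") from None
        if len(starts) != len(ends):
            raise ValueError(f"{path}:{lineno}: exon starts/ends length mismatch")
        pairs = sorted(zip(starts, ends), reverse=strand == "-")
        exs = tuple(ExonInterval(chrom, s, e, strand) for s, e in pairs)
        t = TranscriptModel(tid, gid, gid, chrom, strand, exs)
        if len(fields) == 8 and fields[6] != "" and fields[6] != "-":
            lo, hi = int(fields[6]), int(fields[7])
            t.cds_start_offset = _project_genomic(
                t, lo if strand == "+" else hi - 1, left=True
            )
            t.cds_end_offset = _project_genomic(
                t, hi - 1 if strand == "+" else lo, left=False
            )
        out.append(t)
    return out


def load_annotation(path, genome: Optional[Mapping[str, str]] = None) -> TranscriptomeIndex:
    """Load a GTF or tabular annotation into a :class:`TranscriptomeIndex`.

    The dialect is sniffed from the first data line (9 columns with a
    feature field = GTF).  When a genome is supplied, every exon is checked
    against chromosome bounds.
    """
    with open(path) as fh:
        lines = fh.readlines()
    first = next((l for l in lines if l.strip() and not l.startswith("#")), None)
    if first is None:
        return TranscriptomeIndex([])
    ncol = len(first.rstrip("\n").split("\t"))
    transcripts = _parse_gtf(lines, path) if ncol == 9 else _parse_tabular(lines, path)
    if genome is not None:
        for t in transcripts:
            if t.chrom not in genome:
                raise ValueError(
                    f"{t.transcript_id}: chromosome {t.chrom!r} absent from genome"
                )
            clen = len(genome[t.chrom])
            for e in t.exons:
                if e.end > clen:
                    raise ValueError(
                        f"{t.transcript_id}: exon [{e.start},{e.end}) outside "
                        f"{t.chrom} (length {clen})"
                    )
    return TranscriptomeIndex(transcripts)


def extract_transcript_sequences(
    index: TranscriptomeIndex, genome: Mapping[str, str]
) -> dict[str, str]:
    """Spliced transcript sequences in transcript orientation.

    Minus-strand transcripts are reverse complemented exon by exon so the
    returned string always reads 5'->3'.
    """
    seqs = {}
    for tid, t in index.transcripts.items():
        if t.chrom not in genome:
            raise KeyError(f"{tid}: chromosome {t.chrom!r} missing from genome")
        chrom_seq = genome[t.chrom]
        parts = []
        for e in t.exons:
            piece = chrom_seq[e.start : e.end]
            parts.append(piece if t.strand == "+" else revcomp(piece))
        seqs[tid] = "".join(parts).upper()
    return seqs


def write_transcriptome_fasta(
    seqs: Mapping[str, str], index: TranscriptomeIndex, path
) -> None:
    """Write the reference transcriptome with ``transcript_id|gene_name`` headers."""
    recs = (
        (f"{tid}|{index.transcripts[tid].gene_name}", seq) for tid, seq in seqs.items()
    )
    write_fasta(recs, path)
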