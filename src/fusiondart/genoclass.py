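"""Genome breakpoint resolution, classification, ranking and reporting.

A candidate's two genomic breakpoints decide its fate: a tiny gap (< 10 kb)
marks a paralog/repeat artifact and is discarded; a modest gap (< 200 kb)
with no evidence of rearrangement looks like read-through transcription
between adjacent genes and is flagged rather than reported; breakpoints on
annotated exon-exon boundaries mark the confident classes, split by whether
both spanning reads and spanning pairs support the call.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

from .fusioncand import FusionCandidate
from .refmodel import TranscriptomeIndex
from .seedalign import AlignParams, SeedIndex, align
from .seqio import write_fasta
from .support import SupportCounts, aggregate_support

log = logging.getLogger(__name__)

HIGH = "HighConfidence"
MEDIUM = "MediumConfidence"
LOW = "LowConfidence"
READTHROUGH = "PotentialRegularTranscript"


@dataclass(frozen=True)
class ClassParams:
    """Classification thresholds: candidates with a genomic gap below
    ``min_gap_keep`` (10 kb) are discarded as homology artifacts; gaps
    below ``readthrough_gap`` (200 kb) without rearrangement evidence are
    flagged as potential regular transcripts; breakpoints off exon
    boundaries need ``low_conf_min_spanning_reads`` (2) spanning reads to
    survive as LowConfidence."""

    min_gap_keep: int = 10_000
    readthrough_gap: int = 200_000
    low_conf_min_spanning_reads: int = 2
    boundary_tolerance: int = 0

    def __post_init__(self):
        if self.min_gap_keep >= self.readthrough_gap:
            raise ValueError("min_gap_keep must be < readthrough_gap")


@dataclass
class GenomicBreakpoints:
    """Genome-resolved breakpoints of a candidate.

    ``pos_a`` is the 1-based last genomic base of the gene-A side,
    ``pos_b`` the 1-based first base of the gene-B side.  ``junction_a``/
    ``junction_b`` are the same points expressed as half-open boundary
    coordinates, directly comparable with annotated exon starts/ends.
    ``strand_a``/``strand_b`` orient the candidate sequence against the
    genome.  ``gap`` is absent (None) for interchromosomal events.
    """

    chrom_a: str
    pos_a: int
    strand_a: str
    junction_a: int
    chrom_b: str
    pos_b: int
    strand_b: str
    junction_b: int
    gap: Optional[int]
    boundary_aligned: bool = False
    rearrangement_evidence: bool = False

    def __post_init__(self):
        if self.gap is not None and self.gap < 0:
            raise ValueError("gap must be >= 0 when present")


@dataclass
class ClassifiedFusion:
    """A final fusion call: one output row."""

    sample: str
    fusion_name: str
    gene_a: str
    gene_b: str
    breakpoints: GenomicBreakpoints
    support: SupportCounts
    classification: str
    in_frame: str  # {"yes", "no", "unknown"}
    known: bool
    candidate: FusionCandidate


def genome_align_params() -> AlignParams:
    """Genome-side alignment defaults: small tile, permissive thresholds,
    unlimited subject gaps (introns)."""
    return AlignParams(
        tile_size=11,
        min_identity_percent=90.0,
        min_score=20,
        max_gap_on_subject=None,
    )


def build_genome_index(genome: Mapping[str, str], params: Optional[AlignParams] = None) -> SeedIndex:
    params = params or genome_align_params()
    return SeedIndex(genome, params.tile_size, step=params.tile_size)


def _locate(alignments, qpos, chrom, span_lo, span_hi, qlen, slack=13):
    """Genomic (0-based base, strand) of a candidate-sequence base, restricted
    to blocks inside the expected gene locus; best-matched alignment wins.

    When no in-span block covers the position exactly — junction bases
    assigned to the partner's block because they match both loci — the
    nearest in-span block edge within ``slack`` bases is extrapolated along
    its diagonal, which is exact for such ambiguous bases.
    """
    exact = None
    near = None
    for a in alignments:
        if a.subject_id != chrom:
            continue
        p = qpos if a.strand == "+" else qlen - 1 - qpos
        for qs, ss, ln in a.blocks:
            g = ss + (p - qs)
            if not (span_lo <= g < span_hi):
                continue
            if qs <= p < qs + ln:
                if exact is None or a.matches > exact[2]:
                    exact = (g, a.strand, a.matches)
            else:
                dist = qs - p if p < qs else p - (qs + ln - 1)
                if 0 < dist <= slack and 0 <= g < a.subject_length:
                    key = (dist, -a.matches)
                    if near is None or key < near[0]:
                        near = (key, (g, a.strand, a.matches))
    if exact is not None:
        return exact
    return near[1] if near is not None else None


def map_breakpoints_to_genome(
    candidate: FusionCandidate,
    genome_index: SeedIndex,
    index: TranscriptomeIndex,
    align_params: Optional[AlignParams] = None,
    boundary_tolerance: int = 0,
) -> Optional[GenomicBreakpoints]:
    """Align the candidate sequence to the genome and project the breakpoint.

    The last prefix base and first suffix base are projected through
    alignment blocks lying within the respective partner gene's annotated
    span; a side with no such alignment (e.g. the sequence really comes
    from a paralog locus) drops the candidate.
    """
    align_params = align_params or genome_align_params()
    alignments = align(
        candidate.sequence,
        genome_index,
        align_params,
        query_step=1,
        query_id=candidate.tumour_seq_id,
    )
    bp = candidate.breakpoint_on_sequence
    qlen = len(candidate.sequence)
    ca, sa_lo, sa_hi, _ = index.gene_span[candidate.gene_a]
    cb, sb_lo, sb_hi, _ = index.gene_span[candidate.gene_b]
    loc_a = _locate(alignments, bp - 1, ca, sa_lo, sa_hi, qlen)
    loc_b = _locate(alignments, bp, cb, sb_lo, sb_hi, qlen)
    if loc_a is None or loc_b is None:
        log.info(
            "%s: no genomic alignment for %s side of %s:%s; candidate dropped",
            candidate.tumour_seq_id,
            "prefix" if loc_a is None else "suffix",
            candidate.gene_a,
            candidate.gene_b,
        )
        return None
    ga, strand_a, _ = loc_a
    gb, strand_b, _ = loc_b
    junction_a = ga + 1 if strand_a == "+" else ga
    junction_b = gb if strand_b == "+" else gb + 1
    pos_a, pos_b = ga + 1, gb + 1
    gap = abs(pos_b - pos_a) if ca == cb else None
    bpts = GenomicBreakpoints(
        chrom_a=ca,
        pos_a=pos_a,
        strand_a=strand_a,
        junction_a=junction_a,
        chrom_b=cb,
        pos_b=pos_b,
        strand_b=strand_b,
        junction_b=junction_b,
        gap=gap,
    )
    bpts.boundary_aligned = index.is_exon_boundary(
        ca, junction_a, boundary_tolerance
    ) and index.is_exon_boundary(cb, junction_b, boundary_tolerance)
    bpts.rearrangement_evidence = rearrangement_evidence(
        bpts, index, candidate.gene_a, candidate.gene_b
    )
    return bpts


def rearrangement_evidence(
    bpts: GenomicBreakpoints,
    index: TranscriptomeIndex,
    gene_a: str,
    gene_b: str,
) -> bool:
    """True iff the two genomic segments cannot be one co-linear transcript.

    Evidence of rearrangement: partners on different chromosomes; segments
    in opposite genomic orientation; candidate orientation relative to the
    annotated gene strand differing between the sides (inversion); or the
    gene-B side lying upstream of the gene-A side along the transcription
    direction.  Read-through transcription between adjacent co-linear
    genes produces none of these.
    """
    if bpts.chrom_a != bpts.chrom_b:
        return True
    if bpts.strand_a != bpts.strand_b:
        return True
    ga = index.gene_span[gene_a][3]
    gb = index.gene_span[gene_b][3]
    ra = bpts.strand_a == ga
    rb = bpts.strand_b == gb
    if ra != rb:
        return True
    # here ga == gb: co-linear sense requires B downstream of A along the strand
    forward = (ga == "+") if ra else (ga == "-")
    if forward:
        return bpts.junction_b < bpts.junction_a
    return bpts.junction_b > bpts.junction_a


def classify(
    support: SupportCounts,
    bpts: GenomicBreakpoints,
    params: ClassParams = ClassParams(),
    paired_end: bool = True,
) -> Optional[str]:
    """Ordered classification decision; None means discard.

    1. gap < 10 kb: discard (gene-family/repeat artifact);
    2. gap < 200 kb without rearrangement evidence: potential regular
       transcript (read-through);
    3. breakpoints on exon boundaries: HighConfidence with both spanning
       reads and pairs, else MediumConfidence;
    4. off-boundary: LowConfidence with >= 1 spanning pair and >= 2
       spanning reads, else discard.
    Single-end data has no spanning pairs, capping calls at Medium.
    """
    sp = support.spanning_pairs if paired_end else None
    sp_n = sp or 0
    if bpts.gap is not None and bpts.gap < params.min_gap_keep:
        return None
    if (
        bpts.gap is not None
        and bpts.gap < params.readthrough_gap
        and not bpts.rearrangement_evidence
    ):
        return READTHROUGH
    if bpts.boundary_aligned:
        if support.spanning_reads >= 1 and sp_n >= 1:
            return HIGH
        return MEDIUM
    if sp_n >= 1 and support.spanning_reads >= params.low_conf_min_spanning_reads:
        return LOW
    return None


def predict_frame(
    candidate: FusionCandidate,
    bpts: GenomicBreakpoints,
    index: TranscriptomeIndex,
) -> str:
    """In-frame call: both genes must break at an exon boundary inside their
    coding regions; the fusion preserves frame when the modal phases agree."""
    if not bpts.boundary_aligned:
        return "unknown"
    fa = index.gene_common_frame(candidate.gene_a, bpts.junction_a)
    fb = index.gene_common_frame(candidate.gene_b, bpts.junction_b)
    if fa is None or fb is None:
        return "unknown"
    return "yes" if fa == fb else "no"


_CLASS_ORDER = {HIGH: 0, MEDIUM: 1, LOW: 2, READTHROUGH: 3}


def rank(fusions: Sequence[ClassifiedFusion]) -> list[ClassifiedFusion]:
    """Sort calls: class, then total support descending, then genomic gap
    ascending (interchromosomal after any finite gap), then name."""
    return sorted(
        fusions,
        key=lambda f: (
            _CLASS_ORDER[f.classification],
            -f.support.total,
            f.breakpoints.gap if f.breakpoints.gap is not None else float("inf"),
            f.fusion_name,
        ),
    )


def merge_same_genomic_breakpoint(
    fusions: Sequence[ClassifiedFusion],
    params: ClassParams = ClassParams(),
    paired_end: bool = True,
) -> list[ClassifiedFusion]:
    """Group calls predicting the same genomic breakpoint, aggregate their
    support and recompute the classification on the merged counts (support
    only grows, so merging never lowers the class)."""
    groups: dict[tuple, list[ClassifiedFusion]] = {}
    for f in fusions:
        b = f.breakpoints
        key = (b.chrom_a, b.pos_a, b.chrom_b, b.pos_b)
        groups.setdefault(key, []).append(f)
    out = []
    for group in groups.values():
        if len(group) == 1:
            out.append(group[0])
            continue
        rep_cand, support = aggregate_support([(f.candidate, f.support) for f in group])
        rep = next(f for f in group if f.candidate is rep_cand)
        cls = classify(support, rep.breakpoints, params, paired_end)
        if cls is None:
            continue
        out.append(replace(rep, support=support, classification=cls))
    return out


class KnownFusions:
    """User-supplied known-fusion gene-pair list (unordered match, aliases).

    CSV rows hold two gene names (optional extra columns may carry
    ``alias=canonical`` entries, as may dedicated alias rows).
    """

    def __init__(self, pairs: Iterable[tuple[str, str]] = (), aliases: Mapping[str, str] = ()):
        self.aliases = dict(aliases)
        self.pairs = {self._key(a, b) for a, b in pairs}

    def _canon(self, name: str) -> str:
        return self.aliases.get(name, name)

    def _key(self, a: str, b: str):
        return frozenset((self._canon(a), self._canon(b)))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return self._key(*pair) in self.pairs

    @classmethod
    def load(cls, path) -> "KnownFusions":
        pairs: list[tuple[str, str]] = []
        aliases: dict[str, str] = {}
        try:
            fh = open(path)
        except OSError:
            log.warning("known-fusion list %s unreadable; flagging nothing", path)
            return cls()
        with fh:
            for row in csv.reader(fh):
                row = [c.strip() for c in row if c.strip()]
                if not row or row[0].lower() in ("gene1", "genea"):
                    continue
                genes = []
                for cell in row:
                    if "=" in cell:
                        alias, canon = cell.split("=", 1)
                        aliases[alias.strip()] = canon.strip()
                    else:
                        genes.append(cell)
                if len(genes) >= 2:
                    pairs.append((genes[0], genes[1]))
        return cls(pairs, aliases)


def flag_known(fusion: ClassifiedFusion, known: Optional[KnownFusions]) -> bool:
    if known is None:
        return False
    name_a = fusion.gene_a
    name_b = fusion.gene_b
    return (name_a, name_b) in known


RESULT_COLUMNS = [
    "sample",
    "fusion_genes",
    "chrom1",
    "base1",
    "strand1",
    "chrom2",
    "base2",
    "strand2",
    "gap",
    "spanning_pairs",
    "spanning_reads",
    "inframe",
    "aligns_to_exon_boundary",
    "known",
    "classification",
    "contig_or_read_id",
]


def result_row(f: ClassifiedFusion) -> list:
    b = f.breakpoints
    return [
        f.sample,
        f.fusion_name,
        b.chrom_a,
        b.pos_a,
        b.strand_a,
        b.chrom_b,
        b.pos_b,
        b.strand_b,
        b.gap if b.gap is not None else "-",
        f.support.spanning_pairs if f.support.spanning_pairs is not None else "-",
        f.support.spanning_reads,
        f.in_frame,
        "yes" if b.boundary_aligned else "no",
        "yes" if f.known else "no",
        f.classification,
        f.candidate.tumour_seq_id,
    ]


def write_results(
    fusions: Sequence[ClassifiedFusion],
    out_prefix: str,
    include_readthrough: bool = False,
) -> None:
    """Write the results CSV and the representative breakpoint-sequence FASTA.

    Read-through-flagged rows (PotentialRegularTranscript) are excluded
    unless requested.
    """
    rows = [
        f
        for f in fusions
        if include_readthrough or f.classification != READTHROUGH
    ]
    with open(f"{out_prefix}.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(RESULT_COLUMNS)
        for f in rows:
            w.writerow(result_row(f))
    write_fasta(
        (
            (f"{f.sample}|{f.fusion_name}|{f.candidate.tumour_seq_id}", f.candidate.sequence)
            for f in rows
        ),
        f"{out_prefix}.fasta",
    )
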