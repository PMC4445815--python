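"""Pipeline orchestration: per-sample execution and multi-sample merging.

``run_sample`` composes the stages — preliminary filtering, duplicate
removal, tumour-sequence construction (mode-dependent), transcriptome
alignment, multigene selection, homology filtering, support counting,
genome mapping and classification — and records per-stage counts, which
are the pipeline's debugging surface.  Samples are independent units of
work: results do not depend on what else runs alongside.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import asdict, dataclass, field
from typing import Mapping, Optional, Sequence

from .fusioncand import (
    CandidateParams,
    Pair,
    TumourSequence,
    apply_homology_filter,
    dedupe,
    mask_exons,
    prefilter_reads,
    select_multigene,
    select_unmapped_reads,
)
from .genoclass import (
    READTHROUGH,
    ClassParams,
    ClassifiedFusion,
    KnownFusions,
    build_genome_index,
    classify,
    flag_known,
    genome_align_params,
    map_breakpoints_to_genome,
    merge_same_genomic_breakpoint,
    predict_frame,
    rank,
    result_row,
    write_results,
    RESULT_COLUMNS,
)
from .refmodel import TranscriptomeIndex
from .seedalign import AlignParams, SeedIndex, align_many, auto_tile_size
from .seqio import write_fasta
from .support import (
    SupportCounts,
    SupportParams,
    aggregate_support,
    count_support_contig,
    count_support_direct,
)

log = logging.getLogger(__name__)

MODES = ("direct", "assembly", "hybrid")


def choose_mode(read_length: int) -> str:
    """Mode policy by read length: <60 assembly, 60-99 hybrid, >=100 direct."""
    if read_length >= 100:
        return "direct"
    if read_length >= 60:
        return "hybrid"
    return "assembly"


@dataclass
class RunConfig:
    """All knobs for a run; the parameter snapshot reproduces it exactly."""

    mode: str = "direct"
    align_params: Optional[AlignParams] = None  # None: tile size chosen from input
    candidate_params: CandidateParams = field(default_factory=CandidateParams)
    support_params: SupportParams = field(default_factory=SupportParams)
    class_params: ClassParams = field(default_factory=ClassParams)
    include_readthrough: bool = False
    known_path: Optional[str] = None

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    def snapshot(self) -> dict:
        return {
            "mode": self.mode,
            "align_params": asdict(self.align_params) if self.align_params else None,
            "candidate_params": asdict(self.candidate_params),
            "support_params": asdict(self.support_params),
            "class_params": asdict(self.class_params),
            "include_readthrough": self.include_readthrough,
            "known_path": self.known_path,
        }


@dataclass
class SampleResult:
    sample: str
    fusions: list[ClassifiedFusion]
    stats: dict[str, int]
    params: dict


class ReferenceBundle:
    """Shared per-reference state: indices are built once and reused across
    samples (the transcriptome tile index keyed by tile size, the exon-masked
    and plain genome indices lazily)."""

    def __init__(
        self,
        genome: Mapping[str, str],
        index: TranscriptomeIndex,
        tx_seqs: Mapping[str, str],
    ):
        self.genome = genome
        self.index = index
        self.tx_seqs = dict(tx_seqs)
        self._tx_seed: dict[int, SeedIndex] = {}
        self._masked_index: Optional[SeedIndex] = None
        self._genome_index: Optional[SeedIndex] = None

    def tx_seed_index(self, tile_size: int) -> SeedIndex:
        if tile_size not in self._tx_seed:
            self._tx_seed[tile_size] = SeedIndex(self.tx_seqs, tile_size, step=1)
        return self._tx_seed[tile_size]

    def masked_genome_index(self) -> SeedIndex:
        if self._masked_index is None:
            gp = genome_align_params()
            masked = mask_exons(self.genome, self.index)
            self._masked_index = SeedIndex(masked, gp.tile_size, step=gp.tile_size)
        return self._masked_index

    def genome_index(self) -> SeedIndex:
        if self._genome_index is None:
            self._genome_index = build_genome_index(self.genome)
        return self._genome_index


def run_sample(
    sample: str,
    pairs: Sequence[Pair],
    reference: ReferenceBundle,
    config: RunConfig = RunConfig(),
    contigs: Optional[Sequence[tuple[str, str]]] = None,
    known: Optional[KnownFusions] = None,
) -> SampleResult:
    """Run the full fusion-detection pipeline on one sample.

    ``pairs`` are (mate1, mate2) read tuples (mate2 None for single-end);
    ``contigs`` are (id, sequence) tuples required by assembly/hybrid
    modes.  Raises on malformed input; per-stage counts are returned in
    ``SampleResult.stats``.
    """
    mode = config.mode
    if mode in ("assembly", "hybrid") and not contigs:
        raise ValueError(f"{mode} mode requires pre-assembled contigs")
    stats: dict[str, int] = {}
    read_lengths = [len(r.seq) for p in pairs for r in p if r is not None]
    if not read_lengths and mode == "direct":
        raise ValueError("direct mode requires reads")
    max_read = max(read_lengths, default=0)
    if mode == "direct" and read_lengths and min(read_lengths) < 100:
        log.warning(
            "%s: direct mode with reads shorter than 100 bases; "
            "hybrid or assembly mode is the nominal choice",
            sample,
        )
    tile = (
        config.align_params.tile_size
        if config.align_params
        else auto_tile_size(max_read, is_contig=mode == "assembly" and not read_lengths)
    )
    aparams = config.align_params or AlignParams(tile_size=tile)
    cparams = config.candidate_params
    paired_end = any(r2 is not None for _, r2 in pairs) if pairs else False

    tx_index = reference.tx_seed_index(tile)
    all_reads = [r for p in pairs for r in p if r is not None]
    aln_cache = align_many(
        ((r.rid, r.seq) for r in all_reads), tx_index, aparams, query_step=tile
    )
    stats["input_pairs"] = len(pairs)

    retained, pre_stats = prefilter_reads(
        pairs, aln_cache, reference.masked_genome_index(), genome_align_params(), cparams
    )
    stats.update({f"prefilter_{k}": v for k, v in pre_stats.items()})

    retained = dedupe(retained)
    stats["deduped_pairs"] = len(retained)

    # ----- tumour sequences -----
    reads = [r for p in retained for r in p if r is not None]
    tumour: list[TumourSequence] = []
    contig_aln: dict[str, list] = {}
    if mode == "direct":
        tumour = select_unmapped_reads(reads, aln_cache, params=cparams)
    else:
        tumour = [
            TumourSequence(cid, seq.upper(), origin="contig") for cid, seq in contigs
        ]
        contig_tile = auto_tile_size(0, is_contig=True)
        contig_aparams = (
            config.align_params or AlignParams(tile_size=contig_tile)
        )
        contig_index = reference.tx_seed_index(contig_aparams.tile_size)
        contig_aln = align_many(
            ((t.seq_id, t.sequence) for t in tumour),
            contig_index,
            contig_aparams,
            query_step=contig_aparams.tile_size,
        )
        if mode == "hybrid" and reads:
            own_contigs = SeedIndex({t.seq_id: t.sequence for t in tumour}, tile)
            tumour.extend(
                select_unmapped_reads(
                    reads, aln_cache, own_contigs, aparams, params=cparams
                )
            )
    stats["tumour_sequences"] = len(tumour)

    # ----- candidate discovery -----
    candidates = []
    for t in tumour:
        alns = contig_aln.get(t.seq_id) if t.origin == "contig" else aln_cache.get(t.seq_id)
        if not alns:
            continue
        candidates.extend(
            select_multigene(t, alns, reference.index, cparams, reference.tx_seqs)
        )
    stats["multigene_candidates"] = len(candidates)
    candidates = apply_homology_filter(candidates, reference.tx_seqs, cparams)
    stats["after_homology_filter"] = len(candidates)

    # ----- support -----
    supported: list[tuple] = []  # (candidate, SupportCounts)
    if mode == "direct":
        groups: dict[tuple, list] = {}
        for c in candidates:
            key = (c.transcript_a, c.pos_a_tx, c.transcript_b, c.pos_b_tx)
            groups.setdefault(key, []).append(c)
        for group in groups.values():
            rep = max(group, key=lambda c: (len(c.sequence), c.tumour_seq_id))
            counts = count_support_direct(
                rep,
                retained,
                aln_cache,
                config.support_params,
                cparams.whole_read_fraction,
                n_discoveries=len({c.tumour_seq_id for c in group}),
            )
            supported.append((rep, counts))
    else:
        for c in candidates:
            counts = count_support_contig(c, retained, config.support_params)
            supported.append((c, counts))
    stats["supported_candidates"] = len(supported)

    # ----- genome resolution + classification -----
    genome_index = reference.genome_index() if supported else None
    calls: list[ClassifiedFusion] = []
    bp_cache: dict[tuple, object] = {}
    n_unmapped = n_discarded = 0
    for cand, counts in supported:
        key = (cand.transcript_a, cand.pos_a_tx, cand.transcript_b, cand.pos_b_tx)
        if key not in bp_cache:
            bp_cache[key] = map_breakpoints_to_genome(
                cand,
                genome_index,
                reference.index,
                boundary_tolerance=config.class_params.boundary_tolerance,
            )
        bpts = bp_cache[key]
        if bpts is None:
            n_unmapped += 1
            continue
        cls = classify(counts, bpts, config.class_params, paired_end)
        if cls is None:
            n_discarded += 1
            continue
        name_a = reference.index.gene_name[cand.gene_a]
        name_b = reference.index.gene_name[cand.gene_b]
        calls.append(
            ClassifiedFusion(
                sample=sample,
                fusion_name=f"{name_a}:{name_b}",
                gene_a=name_a,
                gene_b=name_b,
                breakpoints=bpts,
                support=counts,
                classification=cls,
                in_frame=predict_frame(cand, bpts, reference.index),
                known=False,
                candidate=cand,
            )
        )
    stats["no_genome_alignment"] = n_unmapped
    stats["discarded_by_classifier"] = n_discarded

    calls = merge_same_genomic_breakpoint(calls, config.class_params, paired_end)
    for f in calls:
        f.known = flag_known(f, known)
    calls = rank(calls)
    stats["readthrough_flagged"] = sum(
        1 for f in calls if f.classification == READTHROUGH
    )
    stats["reported_fusions"] = len(calls) - stats["readthrough_flagged"]
    log.info("%s: stage counts %s", sample, stats)
    return SampleResult(sample, calls, stats, config.snapshot())


def merge_samples(results: Sequence[SampleResult]) -> list[ClassifiedFusion]:
    """Combine per-sample results into one table ordered by sample then rank."""
    if not results:
        raise ValueError("merge_samples requires at least one result")
    names = [r.sample for r in results]
    if len(set(names)) != len(names):
        raise ValueError("duplicate sample names")
    combined: list[ClassifiedFusion] = []
    for r in sorted(results, key=lambda r: r.sample):
        combined.extend(rank(r.fusions))
    return combined


def write_merged(
    results: Sequence[SampleResult], out_prefix: str, include_readthrough: bool = False
) -> None:
    combined = merge_samples(results)
    rows = [
        f
        for f in combined
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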