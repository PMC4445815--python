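"""Synthetic-data generator for fusion-detection validation at desk scale.

Emulates the validation designs the pipeline is built for: a toy reference
(random genome with well-separated multi-exon coding genes), fusion
transcripts made by joining the 5' portion of one coding transcript to the
3' portion of another at exon edges, paired-end reads over coverage tiers
with a normal fragment-length distribution and uniform substitution
errors, and expression-weighted background reads from non-fusion
transcripts (which never produce chimeric fragments).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .refmodel import (
    ExonInterval,
    TranscriptModel,
    TranscriptomeIndex,
    extract_transcript_sequences,
)
from .seqio import Read, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for the simulated validation experiments.

    Defaults mirror the validation design this generator reproduces at
    desk scale: 250 bp paired-end reads with fragment length 500 +- 100,
    20 fusions at each coverage tier of {1,2,5,10,50,100}x, mixed with
    expression-weighted background pairs.  The error model is a uniform
    0.4% per-base substitution rate standing in for a position-dependent
    sequencer profile.  Genes are mutually separated by more than 200 kb
    so genuine fusions never look like read-through transcription;
    ``n_adjacent_pairs`` gene pairs are instead placed close together for
    read-through testing.
    """

    seed: int = 0
    n_genes: int = 20
    n_chroms: int = 4
    exons_per_gene: tuple[int, int] = (3, 8)
    exon_length: tuple[int, int] = (100, 400)
    intron_length: tuple[int, int] = (200, 2000)
    gene_separation: int = 250_000
    n_adjacent_pairs: int = 0
    adjacent_separation: int = 5_000
    coverage_tiers: Sequence[tuple[float, int]] = (
        (100, 20),
        (50, 20),
        (10, 20),
        (5, 20),
        (2, 20),
        (1, 20),
    )
    read_length: int = 250
    fragment_mean: float = 500.0
    fragment_sd: float = 100.0
    error_rate: float = 0.004
    n_background_pairs: int = 50_000
    max_junction_homology: int = 0

    def __post_init__(self):
        if self.fragment_mean <= self.read_length:
            raise ValueError("fragment_mean must exceed read_length")
        if any(cov <= 0 for cov, _ in self.coverage_tiers):
            raise ValueError("coverage must be > 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TruthRecord:
    """Ground truth for one simulated fusion: partner genes, genomic
    breakpoints (1-based, last prefix base / first suffix base, both at
    exon edges), coverage tier and the full fusion transcript."""

    fusion_id: str
    gene_a: str
    gene_b: str
    transcript_a: str
    transcript_b: str
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    coverage: float
    sequence: str


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, n).tobytes().decode("ascii")


def make_reference(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[dict[str, str], TranscriptomeIndex, dict[str, str]]:
    """Random toy genome + annotation: returns (genome, index, transcript seqs).

    Genes are multi-exon, coding, on random strands, spread over
    ``n_chroms`` chromosomes with ``gene_separation`` intergenic spacers
    (well above the read-through gap); the trailing ``n_adjacent_pairs``
    gene pairs are placed ``adjacent_separation`` apart instead.
    Everything is reproducible from the seed.
    """
    rng = rng if rng is not None else config.rng()
    if config.n_genes < 1:
        raise ValueError("need at least one gene")
    if 2 * config.n_adjacent_pairs > config.n_genes:
        raise ValueError("adjacent pairs exceed gene count")
    genes_per_chrom = -(-config.n_genes // config.n_chroms)
    transcripts: list[TranscriptModel] = []
    chrom_parts: dict[str, list[str]] = {}
    chrom_pos: dict[str, int] = {}
    adjacent_first = config.n_genes - 2 * config.n_adjacent_pairs
    for g in range(config.n_genes):
        chrom = f"chr{g // genes_per_chrom + 1}"
        if chrom not in chrom_parts:
            chrom_parts[chrom] = []
            chrom_pos[chrom] = 0
        adjacent = g > adjacent_first and (g - adjacent_first) % 2 == 1
        sep = config.adjacent_separation if adjacent else config.gene_separation
        chrom_parts[chrom].append(_random_seq(rng, sep))
        start = chrom_pos[chrom] + sep
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = start
        for i in range(n_exons):
            elen = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
            exons.append((pos, pos + elen))
            pos += elen
            if i < n_exons - 1:
                pos += int(
                    rng.integers(config.intron_length[0], config.intron_length[1] + 1)
                )
        gene_seq_len = pos - start
        chrom_parts[chrom].append(_random_seq(rng, gene_seq_len))
        chrom_pos[chrom] = pos
        gid = f"GENE{g + 1:02d}"
        ivs = [ExonInterval(chrom, s, e, strand) for s, e in exons]
        if strand == "-":
            ivs = ivs[::-1]
        spliced = sum(e - s for s, e in exons)
        cds_start = int(rng.integers(0, 31))
        cds_len = 3 * ((spliced - cds_start - int(rng.integers(0, 31))) // 3)
        t = TranscriptModel(
            transcript_id=f"{gid}.t1",
            gene_id=gid,
            gene_name=gid,
            chrom=chrom,
            strand=strand,
            exons=tuple(ivs),
            cds_start_offset=cds_start,
            cds_end_offset=cds_start + cds_len,
        )
        transcripts.append(t)
    genome = {c: "".join(parts) for c, parts in chrom_parts.items()}
    index = TranscriptomeIndex(transcripts)
    tx_seqs = extract_transcript_sequences(index, genome)
    return genome, index, tx_seqs


def _junction_info(t: TranscriptModel, exon_i: int, side: str) -> tuple[int, int]:
    """(spliced offset, 1-based genomic position) of a junction.

    ``side='end'``: junction after transcript exon ``exon_i`` (position of
    the last retained base); ``side='start'``: junction before exon
    ``exon_i`` (position of the first retained base).
    """
    cum = 0
    for i, e in enumerate(t.exons):
        if side == "end" and i == exon_i:
            off = cum + len(e)
            pos = e.end if t.strand == "+" else e.start + 1
            return off, pos
        if side == "start" and i == exon_i:
            off = cum
            pos = e.start + 1 if t.strand == "+" else e.end
            return off, pos
        cum += len(e)
    raise IndexError(exon_i)


def _junction_homology(prefix_tx: str, suffix_tx: str, off_a: int, off_b: int) -> int:
    fwd = 0
    while (
        off_a + fwd < len(prefix_tx)
        and off_b + fwd < len(suffix_tx)
        and prefix_tx[off_a + fwd] == suffix_tx[off_b + fwd]
    ):
        fwd += 1
    back = 0
    while (
        back < off_a
        and back < off_b
        and prefix_tx[off_a - 1 - back] == suffix_tx[off_b - 1 - back]
    ):
        back += 1
    return fwd + back


def simulate_fusions(
    index: TranscriptomeIndex,
    tx_seqs: dict[str, str],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict[str, str], list[TruthRecord]]:
    """Build fusion transcripts by joining coding transcripts at exon edges.

    Each fusion joins the 5' portion of one transcript (cut after a random
    internal exon) to the 3' portion of another (cut before a random
    non-first exon).  Partner gene pairs are distinct and >= 1 kb apart;
    junctions are resampled until the partners share at most
    ``max_junction_homology`` bases there, so the transcriptional
    breakpoint is unambiguous and truth coordinates are exact.
    """
    rng = rng if rng is not None else config.rng()
    coding = [
        tid
        for tid, t in index.transcripts.items()
        if t.is_coding and len(t.exons) >= 2
    ]
    if len(coding) < 2:
        raise ValueError("need at least two coding multi-exon transcripts")
    wanted = [cov for cov, n in config.coverage_tiers for _ in range(n)]
    used_pairs: set[frozenset] = set()
    fusion_seqs: dict[str, str] = {}
    truth: list[TruthRecord] = []
    for i, cov in enumerate(wanted):
        for _attempt in range(1000):
            ta_id, tb_id = rng.choice(coding, 2, replace=False)
            ta, tb = index.transcripts[ta_id], index.transcripts[tb_id]
            pair = frozenset((ta.gene_id, tb.gene_id))
            if len(pair) < 2 or pair in used_pairs:
                continue
            dist = _gene_distance(index, ta.gene_id, tb.gene_id)
            if dist is not None and dist < 1000:
                continue
            exon_a = int(rng.integers(0, len(ta.exons) - 1))  # keep exons 0..exon_a
            exon_b = int(rng.integers(1, len(tb.exons)))  # keep exons exon_b..
            off_a, pos_a = _junction_info(ta, exon_a, "end")
            off_b, pos_b = _junction_info(tb, exon_b, "start")
            seq_a, seq_b = tx_seqs[ta_id], tx_seqs[tb_id]
            if off_a + (len(seq_b) - off_b) < config.read_length:
                # a fusion transcript shorter than one read yields no data
                continue
            if (
                _junction_homology(seq_a, seq_b, off_a, off_b)
                > config.max_junction_homology
            ):
                continue
            fid = f"fusion{i + 1:03d}"
            seq = seq_a[:off_a] + seq_b[off_b:]
            fusion_seqs[fid] = seq
            used_pairs.add(pair)
            truth.append(
                TruthRecord(
                    fusion_id=fid,
                    gene_a=ta.gene_id,
                    gene_b=tb.gene_id,
                    transcript_a=ta_id,
                    transcript_b=tb_id,
                    chrom_a=ta.chrom,
                    pos_a=pos_a,
                    chrom_b=tb.chrom,
                    pos_b=pos_b,
                    coverage=cov,
                    sequence=seq,
                )
            )
            break
        else:
            raise RuntimeError("could not place fusion under the constraints")
    return fusion_seqs, truth


def _gene_distance(index, gene_a, gene_b):
    ca, sa, ea, _ = index.gene_span[gene_a]
    cb, sb, eb, _ = index.gene_span[gene_b]
    if ca != cb:
        return None
    return max(sb - ea, sa - eb, 0)


def _pairs_from_transcript(
    name: str,
    seq: str,
    n_pairs: int,
    config: SimConfig,
    rng: np.random.Generator,
    start_index: int = 0,
) -> list[tuple[Read, Read]]:
    """Draw ``n_pairs`` error-bearing read pairs from one transcript."""
    L = len(seq)
    rl = config.read_length
    out = []
    if L < rl or n_pairs <= 0:
        return out
    frags = np.clip(
        np.rint(rng.normal(config.fragment_mean, config.fragment_sd, n_pairs)).astype(int),
        rl,
        L,
    )
    starts = rng.integers(0, L - frags + 1)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    for j in range(n_pairs):
        s, f = int(starts[j]), int(frags[j])
        r1 = _with_errors(arr[s : s + rl], config.error_rate, rng)
        r2_fwd = _with_errors(arr[s + f - rl : s + f], config.error_rate, rng)
        r2 = revcomp(r2_fwd)
        i = start_index + j
        out.append((Read(f"{name}_{i}/1", r1), Read(f"{name}_{i}/2", r2)))
    return out


def _with_errors(arr: np.ndarray, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return arr.tobytes().decode("ascii")
    mask = rng.random(len(arr)) < rate
    if not mask.any():
        return arr.tobytes().decode("ascii")
    arr = arr.copy()
    idx = np.nonzero(mask)[0]
    # substitute with a uniformly chosen *different* base
    shifts = rng.integers(1, 4, len(idx))
    code = {65: 0, 67: 1, 71: 2, 84: 3}
    lut = np.zeros(256, dtype=np.uint8)
    for b, c in code.items():
        lut[b] = c
    newc = (lut[arr[idx]] + shifts) % 4
    arr[idx] = _BASES[newc]
    return arr.tobytes().decode("ascii")


def pairs_for_coverage(length: int, coverage: float, read_length: int) -> int:
    """Pairs needed for an average coverage over a transcript."""
    return int(round(coverage * length / (2 * read_length)))


def simulate_reads(
    transcripts: dict[str, str],
    coverage: dict[str, float],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[tuple[Read, Read]]:
    """Paired reads at per-transcript coverage (deterministic pair counts)."""
    rng = rng if rng is not None else config.rng()
    out = []
    for name in transcripts:
        seq = transcripts[name]
        if len(seq) < config.read_length:
            import logging

            logging.getLogger(__name__).warning(
                "%s shorter than read length; skipped", name
            )
            continue
        n = pairs_for_coverage(len(seq), coverage[name], config.read_length)
        out.extend(_pairs_from_transcript(name, seq, n, config, rng))
    return out


def simulate_background(
    index: TranscriptomeIndex,
    tx_seqs: dict[str, str],
    n_pairs: int,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[tuple[Read, Read]]:
    """Background pairs from non-fusion transcripts.

    Per-gene expression is a log-normal(0, 1) draw; pairs are allocated
    multinomially across usable transcripts.  Fragments never straddle two
    genes, so the background contains no chimeric evidence by
    construction.
    """
    rng = rng if rng is not None else config.rng()
    tids = [
        tid for tid in index.transcripts if len(tx_seqs[tid]) >= config.read_length
    ]
    if not tids or n_pairs <= 0:
        return []
    weights = rng.lognormal(0.0, 1.0, len(tids))
    counts = rng.multinomial(n_pairs, weights / weights.sum())
    out = []
    for tid, n in zip(tids, counts):
        out.extend(
            _pairs_from_transcript(f"bg_{tid}", tx_seqs[tid], int(n), config, rng)
        )
    return out


def write_truth_tsv(truth: Sequence[TruthRecord], path) -> None:
    cols = [
        "fusion_id",
        "gene_a",
        "gene_b",
        "transcript_a",
        "transcript_b",
        "chrom_a",
        "pos_a",
        "chrom_b",
        "pos_b",
        "coverage",
        "sequence",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for t in truth:
            fh.write(
                "\t".join(
                    str(getattr(t, c)) for c in cols
                )
                + "\n"
            )


def write_annotation_tabular(index: TranscriptomeIndex, path) -> None:
    """Tabular annotation twin: geneID txID chrom strand starts ends cds."""
    with open(path, "w") as fh:
        for t in index.transcripts.values():
            exs = sorted(t.exons, key=lambda e: e.start)
            starts = ",".join(str(e.start) for e in exs)
            ends = ",".join(str(e.end) for e in exs)
            if t.is_coding:
                lo, hi = _cds_genomic(t)
                cds = f"\t{lo}\t{hi}"
            else:
                cds = "\t-\t-"
            fh.write(
                f"{t.gene_id}\t{t.transcript_id}\t{t.chrom}\t{t.strand}\t{starts}\t{ends}{cds}\n"
            )


def write_annotation_gtf(index: TranscriptomeIndex, path) -> None:
    with open(path, "w") as fh:
        for t in index.transcripts.values():
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'gene_name "{t.gene_name}";'
            )
            for e in sorted(t.exons, key=lambda x: x.start):
                fh.write(
                    f"{t.chrom}\tsim\texon\t{e.start + 1}\t{e.end}\t.\t{t.strand}\t.\t{attrs}\n"
                )
            if t.is_coding:
                lo, hi = _cds_genomic(t)
                fh.write(
                    f"{t.chrom}\tsim\tCDS\t{lo + 1}\t{hi}\t.\t{t.strand}\t.\t{attrs}\n"
                )


def _cds_genomic(t: TranscriptModel) -> tuple[int, int]:
    """Genomic (start, end) half-open span of the CDS (may include introns)."""
    positions = []
    for off in (t.cds_start_offset, t.cds_end_offset):
        cum = 0
        for e in t.exons:
            if cum <= off <= cum + len(e):
                within = off - cum
                g = e.start + within if t.strand == "+" else e.end - within
                positions.append(g)
                break
            cum += len(e)
    lo, hi = min(positions), max(positions)
    return lo, hi
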