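"""Shared fixtures and fixture builders.

Threshold-sweep tests need references where nothing accidental can match
across genes, so ``two_gene_reference`` draws gene A's exons from the
{A,C} alphabet and gene B's from {G,T}: cross-gene seed hits and junction
microhomology are impossible by construction, making every boundary sweep
exact.
"""

from __future__ import annotations

import numpy as np
import pytest

from fusiondart.refmodel import (
    ExonInterval,
    TranscriptModel,
    TranscriptomeIndex,
    extract_transcript_sequences,
)
from fusiondart.seqio import Read, revcomp


def _alph_seq(rng: np.random.Generator, n: int, alphabet: str) -> str:
    return "".join(rng.choice(list(alphabet), n))


def build_reference(genes, chrom_lengths, seed=0, intergenic_alphabet="ACGT"):
    """Assemble a genome + index from gene descriptions.

    ``genes``: list of dicts with keys gene_id, chrom, strand, exons
    (genomic (start, end) pairs), alphabet (bases used for exonic
    sequence), and optional cds (spliced start, end offsets).
    """
    rng = np.random.default_rng(seed)
    genome = {
        chrom: list(_alph_seq(rng, n, intergenic_alphabet))
        for chrom, n in chrom_lengths.items()
    }
    transcripts = []
    for g in genes:
        chrom = genome[g["chrom"]]
        for s, e in g["exons"]:
            chrom[s:e] = list(_alph_seq(rng, e - s, g.get("alphabet", "ACGT")))
        exs = sorted(g["exons"], reverse=g["strand"] == "-")
        transcripts.append(
            TranscriptModel(
                transcript_id=g.get("transcript_id", g["gene_id"] + ".t1"),
                gene_id=g["gene_id"],
                gene_name=g.get("gene_name", g["gene_id"]),
                chrom=g["chrom"],
                strand=g["strand"],
                exons=tuple(
                    ExonInterval(g["chrom"], s, e, g["strand"]) for s, e in exs
                ),
                cds_start_offset=g.get("cds", (None, None))[0],
                cds_end_offset=g.get("cds", (None, None))[1],
            )
        )
    genome = {c: "".join(s) for c, s in genome.items()}
    index = TranscriptomeIndex(transcripts)
    tx_seqs = extract_transcript_sequences(index, genome)
    return genome, index, tx_seqs


def two_gene_reference(
    distance=50_000,
    strand_a="+",
    strand_b="+",
    same_chrom=True,
    exon_len=200,
    n_exons=3,
    intron=400,
    seed=0,
):
    """Two multi-exon coding genes with disjoint base alphabets.

    Gene A's exons use {A,C}, gene B's {G,T}; the genomic distance between
    the gene spans is exactly ``distance`` when they share a chromosome.
    """
    def exon_coords(start):
        out = []
        pos = start
        for _ in range(n_exons):
            out.append((pos, pos + exon_len))
            pos += exon_len + intron
        return out, pos - intron

    a_exons, a_end = exon_coords(1000)
    b_start = a_end + distance if same_chrom else 1000
    b_exons, b_end = exon_coords(b_start)
    chrom_b = "chr1" if same_chrom else "chr2"
    chroms = {"chr1": a_end + (distance if same_chrom else 0) + n_exons * (exon_len + intron) + 2000}
    if not same_chrom:
        chroms["chr2"] = b_end + 1000
    genes = [
        dict(gene_id="GA", chrom="chr1", strand=strand_a, exons=a_exons,
             alphabet="AC", cds=(0, 3 * (n_exons * exon_len // 3))),
        dict(gene_id="GB", chrom=chrom_b, strand=strand_b, exons=b_exons,
             alphabet="GT", cds=(0, 3 * (n_exons * exon_len // 3))),
    ]
    return build_reference(genes, chroms, seed=seed)


def fusion_read(tx_seqs, tx_a, tx_b, cut_a, cut_b, prefix, suffix, rid="fread"):
    """A read spanning the junction tx_a[:cut_a] + tx_b[cut_b:] with the
    given flank lengths."""
    seq = tx_seqs[tx_a][cut_a - prefix : cut_a] + tx_seqs[tx_b][cut_b : cut_b + suffix]
    return Read(rid, seq)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def two_genes():
    """Default two-gene reference: 50 kb apart, both plus strand."""
    return two_gene_reference()
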