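"""Lightweight sequence I/O helpers shared across the pipeline.

FASTA/FASTQ parsing is delegated to Biopython; reads are carried around as
plain ``(id, sequence)`` named tuples because the pipeline never needs
qualities or rich annotation.
"""

from __future__ import annotations

import itertools
from collections import namedtuple
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

Read = namedtuple("Read", ["rid", "seq"])

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path) -> dict[str, str]:
    """Load a (multi-record, wrapped or unwrapped) FASTA into an ordered dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path) -> Iterator[Read]:
    """Iterate reads from a 4-line FASTQ; Phred qualities are ignored."""
    with open(path) as fh:
        for title, seq, _qual in FastqGeneralIterator(fh):
            yield Read(title.split()[0], seq.upper())


def read_sequences(path) -> Iterator[Read]:
    """Iterate reads from FASTA or FASTQ, sniffing the format."""
    with open(path) as fh:
        first = fh.read(1)
    if first == "@":
        yield from read_fastq(path)
    else:
        for rec in SeqIO.parse(str(path), "fasta"):
            yield Read(rec.id, str(rec.seq).upper())


def read_pairs(path1, path2=None) -> list[tuple[Read, Read | None]]:
    """Load read pairs from _1/_2 files, an interleaved file, or single-end.

    With two paths, records are paired positionally.  With one path the file
    is treated as single-end (mate ``None`` for every read); use
    :func:`interleave_pairs` for interleaved input.
    """
    if path2 is not None:
        r1 = list(read_sequences(path1))
        r2 = list(read_sequences(path2))
        if len(r1) != len(r2):
            raise ValueError(
                f"paired files differ in length: {len(r1)} vs {len(r2)} records"
            )
        return list(zip(r1, r2))
    return [(r, None) for r in read_sequences(path1)]


def interleave_pairs(path) -> list[tuple[Read, Read]]:
    it = read_sequences(path)
    return list(itertools.zip_longest(*[iter(it)] * 2))


def write_fastq(reads: Iterable[Read], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
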