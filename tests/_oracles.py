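"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the implementation: the alignment
oracle is an exhaustive per-diagonal dynamic programme, the breakpoint
homology oracle enumerates every breakpoint shift explicitly.
"""

from __future__ import annotations

import numpy as np

from fusiondart.seqio import revcomp


def ungapped_local_score(query: str, subject: str) -> int:
    """Exact best ungapped local alignment score (match +1, mismatch -1),
    both query orientations, by enumerating every diagonal."""
    best = 0
    sarr = np.frombuffer(subject.encode(), dtype=np.uint8)
    for q in (query, revcomp(query)):
        qarr = np.frombuffer(q.encode(), dtype=np.uint8)
        n, m = len(qarr), len(sarr)
        for diag in range(-(n - 1), m):
            lo, hi = max(0, -diag), min(n, m - diag)
            if hi <= lo:
                continue
            sc = np.where(qarr[lo:hi] == sarr[lo + diag : hi + diag], 1, -1)
            prefix = np.concatenate(([0], np.cumsum(sc)))
            gains = prefix[1:] - np.minimum.accumulate(prefix)[:-1]
            best = max(best, int(gains.max()))
    return best


def exact_ungapped_matches(query: str, subject: str) -> int:
    """Longest exact (mismatch-free) ungapped match, both orientations."""
    best = 0
    sarr = np.frombuffer(subject.encode(), dtype=np.uint8)
    for q in (query, revcomp(query)):
        qarr = np.frombuffer(q.encode(), dtype=np.uint8)
        n, m = len(qarr), len(sarr)
        for diag in range(-(n - 1), m):
            lo, hi = max(0, -diag), min(n, m - diag)
            if hi <= lo:
                continue
            eq = qarr[lo:hi] == sarr[lo + diag : hi + diag]
            run = best_run = 0
            for e in eq:
                run = run + 1 if e else 0
                best_run = max(best_run, run)
            best = max(best, best_run)
    return best


def breakpoint_shift_homology(tx_a: str, tx_b: str, cut_a: int, cut_b: int) -> int:
    """Number of alternative breakpoints producing the identical fusion
    sequence, found by exhaustive shift enumeration.

    For every shift d, the fusion tx_a[:cut_a+d] + tx_b[cut_b+d:] is
    compared with the nominal one; the count of non-zero shifts with an
    identical product is the junction homology length.
    """
    nominal = tx_a[:cut_a] + tx_b[cut_b:]
    count = 0
    for d in range(-min(cut_a, cut_b), min(len(tx_a) - cut_a, len(tx_b) - cut_b) + 1):
        if d == 0:
            continue
        if tx_a[: cut_a + d] + tx_b[cut_b + d :] == nominal:
            count += 1
    return count


def modal_phase(phases: list[int]) -> int:
    """Modal value, ties to the smallest, by brute-force enumeration."""
    return min(
        (p for p in set(phases)),
        key=lambda p: (-phases.count(p), p),
    )
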