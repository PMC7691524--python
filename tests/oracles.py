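"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: matches are counted
by expanding the CIGAR column-by-column against the two sequences, and
N50/N90 by an explicit sorted cumulative scan.
"""

from __future__ import annotations

import numpy as np

_CIGAR_OPS = "MIDNSH=X"


def parse_cigar_simple(cigar: str) -> list[tuple[int, str]]:
    ops, num = [], ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((int(num), ch))
            num = ""
    return ops


def count_matches_columnwise(query: str, target: str, cigar: str) -> int:
    """Matches counted by walking the expanded alignment columns."""
    qi = ti = m = 0
    for n, op in parse_cigar_simple(cigar):
        if op in "M=X":
            for k in range(n):
                if query[qi + k] == target[ti + k]:
                    m += 1
            qi += n
            ti += n
        elif op in "IS":
            qi += n
        elif op in "DN":
            ti += n
        # H consumes neither stored sequence
    return m


def coverage_bruteforce(cigar: str) -> float:
    """Aligned query fraction: non-clip query-consuming bases over all."""
    aligned = total = 0
    for n, op in parse_cigar_simple(cigar):
        if op in "MI=X":
            aligned += n
            total += n
        elif op in "SH":
            total += n
    return aligned / total


def nxx_bruteforce(lengths, frac: float) -> int:
    """Smallest L such that sequences >= L cover ``frac`` of the total."""
    s = sorted(lengths, reverse=True)
    total = sum(s)
    run = 0
    for length in s:
        run += length
        if run >= frac * total:
            return length
    raise AssertionError("unreachable for non-empty input")


def random_toy_alignment(rng: np.random.Generator):
    """A random gapped toy alignment with known sequences.

    Returns ``(query, target, cigar, nm)`` where the query was derived
    from the target through the CIGAR with planted substitutions, and
    ``nm`` is the SAM edit distance (mismatches + inserted + deleted
    bases; intron N bases excluded).
    """
    bases = "ACGT"
    target_parts, query_parts, ops = [], [], []
    lead_clip = int(rng.integers(0, 8))
    if lead_clip:
        query_parts.append("".join(rng.choice(list(bases), lead_clip)))
        ops.append(f"{lead_clip}S")
    n_exons = int(rng.integers(1, 4))
    mismatches = ins_bases = del_bases = 0
    for e in range(n_exons):
        if e:
            intron = int(rng.integers(60, 300))
            target_parts.append("".join(rng.choice(list(bases), intron)))
            ops.append(f"{intron}N")
        n_blocks = int(rng.integers(1, 3))
        for b in range(n_blocks):
            mlen = int(rng.integers(5, 40))
            tseq = "".join(rng.choice(list(bases), mlen))
            qseq = list(tseq)
            for i in range(mlen):
                if rng.random() < 0.1:
                    alt = [c for c in bases if c != qseq[i]]
                    qseq[i] = alt[int(rng.integers(3))]
                    mismatches += 1
            target_parts.append(tseq)
            query_parts.append("".join(qseq))
            ops.append(f"{mlen}M")
            if b < n_blocks - 1:
                if rng.random() < 0.5:
                    ilen = int(rng.integers(1, 5))
                    query_parts.append("".join(rng.choice(list(bases), ilen)))
                    ops.append(f"{ilen}I")
                    ins_bases += ilen
                else:
                    dlen = int(rng.integers(1, 5))
                    target_parts.append("".join(rng.choice(list(bases), dlen)))
                    ops.append(f"{dlen}D")
                    del_bases += dlen
    tail_clip = int(rng.integers(0, 8))
    if tail_clip:
        query_parts.append("".join(rng.choice(list(bases), tail_clip)))
        ops.append(f"{tail_clip}S")
    return (
        "".join(query_parts),
        "".join(target_parts),
        "".join(ops),
        mismatches + ins_bases + del_bases,
    )
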