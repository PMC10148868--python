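"""Independent oracles shared by the unit and acceptance tests.

Everything here is deliberately brute-force and written without reference to
the package's internal algorithms, so that agreement is a real check.
"""

from __future__ import annotations

import math

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def oracle_context(sequence: str, pos: int, strand: str) -> str:
    """Context by explicit strand-sequence extraction (CG needs 1 downstream
    base, CHG/CHH need 2; missing bases or N -> undefined)."""
    if strand == "+":
        downstream = sequence[pos + 1 : pos + 3]
    else:
        start = max(pos - 2, 0)
        downstream = rc(sequence[start:pos])
    b1 = downstream[0] if len(downstream) >= 1 else None
    b2 = downstream[1] if len(downstream) >= 2 else None
    if b1 == "G":
        return "CG"
    if b1 in (None, "N"):
        return "undefined"
    if b2 == "G":
        return "CHG"
    if b2 in (None, "N"):
        return "undefined"
    return "CHH"


def oracle_mismatches(ref: str, read: str, frame: str) -> int:
    """Bisulfite-aware mismatch count by per-base inspection."""
    mm = 0
    for r, q in zip(ref, read):
        if r == q:
            continue
        if frame == "OT" and r == "C" and q == "T":
            continue
        if frame == "OB" and r == "G" and q == "A":
            continue
        mm += 1
    return mm


def oracle_map(sequence: str, read_bases: str, max_mismatch: int):
    """Exhaustive position x frame scan.

    Returns (status, pos, frame, mismatches) with status in
    {unique, ambiguous, unmapped}; pos/frame are None unless unique.
    """
    L = len(read_bases)
    best = None
    hits = []
    for frame in ("OT", "OB"):
        oriented = read_bases if frame == "OT" else rc(read_bases)
        for p in range(len(sequence) - L + 1):
            mm = oracle_mismatches(sequence[p : p + L], oriented, frame)
            if best is None or mm < best:
                best = mm
                hits = [(p, frame)]
            elif mm == best:
                hits.append((p, frame))
    if best is None or best > max_mismatch:
        return ("unmapped", None, None, None)
    if len(hits) > 1:
        return ("ambiguous", None, None, best)
    return ("unique", hits[0][0], hits[0][1], best)


def oracle_binom_tail(n: int, m: int, eps: float) -> float:
    """P(X >= m) for X ~ Binomial(n, eps) by direct summation."""
    return sum(
        math.comb(n, k) * eps**k * (1 - eps) ** (n - k) for k in range(m, n + 1)
    )


def intervals_disjoint_with_gaps(intervals, min_gap: int) -> bool:
    """Pairwise interval scan: sorted, non-overlapping, gaps >= min_gap."""
    ivs = sorted(intervals)
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 - e1 < min_gap:
            return False
    return all(s < e for s, e in ivs)
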