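"""Reduced-alphabet bisulfite read mapping.

Reads are aligned ungapped against two converted frames of the reference:
the C->T frame (OT, original top strand) and the G->A frame (OB, original
bottom strand, handled in top-strand coordinates via the reverse-complemented
read). Candidate positions come from exact k-mer seeds at both read ends;
candidates are rescored with bisulfite-aware mismatch counting, in which
reference-C/read-T (OT) and reference-G/read-A (OB) are free but the reverse
substitutions are not.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional

import numpy as np

from .core import A, C, G, T, Alignment, Genome, ReadRecord, kmer_codes, revcomp, seq_to_array

__all__ = ["BisulfiteIndex", "map_read", "map_reads", "default_max_mismatch"]


def default_max_mismatch(read_length: int) -> int:
    """2 mismatches per 100 bp, scaled by read length."""
    return round(2 * read_length / 100)


class BisulfiteIndex:
    """Sorted k-mer position index over both converted reference frames."""

    def __init__(self, genome: Genome, k: int = 16) -> None:
        if not 4 <= k <= 32:
            raise ValueError(f"seed length k must be in [4, 32], got {k}")
        if k > len(genome):
            raise ValueError("seed length exceeds genome length")
        self.genome = genome
        self.k = k
        self._frames: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for frame, converted in (
            ("OT", genome.sequence.replace("C", "T")),
            ("OB", genome.sequence.replace("G", "A")),
        ):
            codes = kmer_codes(converted, k)
            order = np.argsort(codes, kind="stable").astype(np.int64)
            self._frames[frame] = (codes[order], order)

    def lookup(self, frame: str, code: int) -> np.ndarray:
        """Genome positions whose converted-frame k-mer equals ``code``."""
        sorted_codes, positions = self._frames[frame]
        code_u = np.uint64(code)
        lo = int(np.searchsorted(sorted_codes, code_u, side="left"))
        hi = int(np.searchsorted(sorted_codes, code_u, side="right"))
        return positions[lo:hi]


def _mismatches(ref: np.ndarray, read: np.ndarray, frame: str) -> int:
    if frame == "OT":
        free = (ref == C) & (read == T)
    else:
        free = (ref == G) & (read == A)
    return int(np.count_nonzero((ref != read) & ~free))


def map_read(
    index: BisulfiteIndex,
    read: ReadRecord,
    max_mismatch: Optional[int] = None,
) -> Alignment:
    """Map one read; ties across distinct (position, frame) are ambiguous."""
    L = len(read.bases)
    k = index.k
    if L < k:
        return Alignment(
            read_id=read.read_id,
            chrom=None,
            pos=None,
            bisulfite_strand=None,
            mismatches=None,
            status="unmapped",
            read_length=L,
            reason="read shorter than seed",
        )
    if max_mismatch is None:
        max_mismatch = default_max_mismatch(L)
    g = index.genome.arr
    Lg = len(index.genome)
    best = math.inf
    best_hits: list[tuple[int, str]] = []
    for frame in ("OT", "OB"):
        if frame == "OT":
            oriented = read.bases
            query = oriented.replace("C", "T")
        else:
            oriented = revcomp(read.bases)
            query = oriented.replace("G", "A")
        oriented_arr = seq_to_array(oriented)
        seen: set[int] = set()
        qcodes = kmer_codes(query, k)
        for off in (0, L - k):
            for hit in index.lookup(frame, int(qcodes[off])):
                p = int(hit) - off
                if p < 0 or p + L > Lg or p in seen:
                    continue
                seen.add(p)
                mm = _mismatches(g[p : p + L], oriented_arr, frame)
                if mm < best:
                    best = mm
                    best_hits = [(p, frame)]
                elif mm == best:
                    best_hits.append((p, frame))
    if not best_hits or best > max_mismatch:
        return Alignment(
            read_id=read.read_id,
            chrom=None,
            pos=None,
            bisulfite_strand=None,
            mismatches=None,
            status="unmapped",
            read_length=L,
            reason="no candidate within mismatch budget",
        )
    if len(best_hits) > 1:
        return Alignment(
            read_id=read.read_id,
            chrom=None,
            pos=None,
            bisulfite_strand=None,
            mismatches=int(best),
            status="ambiguous",
            read_length=L,
            reason=f"{len(best_hits)} equally good positions",
        )
    pos, frame = best_hits[0]
    return Alignment(
        read_id=read.read_id,
        chrom=index.genome.name,
        pos=pos,
        bisulfite_strand=frame,
        mismatches=int(best),
        status="unique",
        read_length=L,
    )


def map_reads(
    index: BisulfiteIndex,
    reads: Iterable[ReadRecord],
    max_mismatch: Optional[int] = None,
) -> list[Alignment]:
    return [map_read(index, r, max_mismatch) for r in reads]
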