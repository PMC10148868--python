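"""Per-cytosine pileup, context classification and binomial methylation calling.

Evidence model: on the strand interrogated by a read's bisulfite frame
(OT -> top-strand cytosines, OB -> bottom-strand cytosines), an unconverted
base (C, appearing as G in top-strand coordinates for OB) is methylation
evidence and a converted base (T / A) is non-methylation evidence; any other
base is a sequencing error and ignored. Sites are tested with an exact
binomial upper tail against the non-conversion rate epsilon and corrected
with Benjamini-Hochberg across all sites meeting the coverage floor.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .core import A, C, G, N, T, Alignment, Genome, ReadRecord, revcomp, seq_to_array

__all__ = [
    "classify_context",
    "classify_contexts",
    "pileup",
    "call_methylation",
    "estimate_epsilon",
    "context_summary",
    "CALL_COLUMNS",
]

COUNT_COLUMNS = ("chrom", "pos", "strand", "n_meth", "n_total")
CALL_COLUMNS = COUNT_COLUMNS + ("context", "beta", "p", "q", "called")

_COMPL_CODE = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMPL_CODE[_a] = _b


def classify_context(genome: Genome, pos: int, strand: str) -> str:
    """CG/CHG/CHH context of the cytosine at (pos, strand).

    The two bases 3' of the C on its own strand decide the context (H is
    A, T or C); for the '-' strand these are the complements of pos-1 and
    pos-2. CG needs one downstream base, CHG/CHH need two; fewer bases, or
    an N among the needed ones, gives 'undefined'.
    """
    if strand not in ("+", "-"):
        raise ValueError(f"invalid strand {strand!r}")
    if genome.base_at(pos, strand) != "C":
        raise ValueError(
            f"reference base at {pos}{strand} is {genome.base_at(pos, strand)!r}, "
            "expected C"
        )
    return str(
        classify_contexts(
            genome, np.array([pos]), np.array([strand], dtype=object), _validate=False
        )[0]
    )


def classify_contexts(
    genome: Genome,
    positions: np.ndarray,
    strands: np.ndarray,
    _validate: bool = True,
) -> np.ndarray:
    """Vectorised context classification; see :func:`classify_context`."""
    g = genome.arr
    L = len(g)
    positions = np.asarray(positions, dtype=np.int64)
    is_top = np.asarray(strands) == "+"
    if _validate:
        want = np.where(is_top, C, G)
        if np.any(g[positions] != want):
            bad = positions[g[positions] != want][0]
            raise ValueError(f"reference base at {bad} is not C on its strand")

    # downstream base 1 and 2 on the site's own strand
    step = np.where(is_top, 1, -1)
    p1 = positions + step
    p2 = positions + 2 * step
    ok1 = (p1 >= 0) & (p1 < L)
    ok2 = (p2 >= 0) & (p2 < L)
    b1 = np.where(ok1, g[np.clip(p1, 0, L - 1)], 0).astype(np.uint8)
    b2 = np.where(ok2, g[np.clip(p2, 0, L - 1)], 0).astype(np.uint8)
    b1 = np.where(is_top, b1, _COMPL_CODE[b1])
    b2 = np.where(is_top, b2, _COMPL_CODE[b2])

    out = np.full(len(positions), "undefined", dtype=object)
    cg = ok1 & (b1 == G)
    chg = ok1 & (b1 != G) & (b1 != N) & ok2 & (b2 == G)
    chh = ok1 & (b1 != G) & (b1 != N) & ok2 & (b2 != G) & (b2 != N)
    out[cg] = "CG"
    out[chg] = "CHG"
    out[chh] = "CHH"
    return out


def pileup(
    alignments: Iterable[Alignment],
    reads: Union[Mapping[str, ReadRecord], Sequence[ReadRecord]],
    genome: Genome,
) -> pd.DataFrame:
    """Accumulate per-cytosine converted/unconverted evidence.

    Only status=unique alignments contribute. Returns a table with columns
    ``chrom, pos, strand, n_meth, n_total`` (0-based positions), restricted
    to sites with n_total > 0 and sorted by position then strand.
    """
    if not isinstance(reads, Mapping):
        reads = {r.read_id: r for r in reads}
    g = genome.arr
    L = len(genome)
    meth_top = np.zeros(L, dtype=np.int32)
    tot_top = np.zeros(L, dtype=np.int32)
    meth_bot = np.zeros(L, dtype=np.int32)
    tot_bot = np.zeros(L, dtype=np.int32)
    for aln in alignments:
        if aln.status != "unique":
            continue
        read = reads[aln.read_id]
        n = len(read.bases)
        if aln.pos < 0 or aln.pos + n > L:
            raise ValueError(
                f"alignment of {aln.read_id} at {aln.pos} (+{n} bp) is out of bounds"
            )
        ref = g[aln.pos : aln.pos + n]
        if aln.bisulfite_strand == "OT":
            q = seq_to_array(read.bases)
            mask = ref == C
            idx = aln.pos + np.flatnonzero(mask)
            qb = q[mask]
            is_meth = qb == C
            is_conv = qb == T
        else:
            q = seq_to_array(revcomp(read.bases))
            mask = ref == G
            idx = aln.pos + np.flatnonzero(mask)
            qb = q[mask]
            is_meth = qb == G
            is_conv = qb == A
        meth, tot = (meth_top, tot_top) if aln.bisulfite_strand == "OT" else (
            meth_bot,
            tot_bot,
        )
        meth[idx[is_meth]] += 1
        tot[idx[is_meth | is_conv]] += 1

    frames = []
    for strand, meth, tot in (("+", meth_top, tot_top), ("-", meth_bot, tot_bot)):
        pos = np.flatnonzero(tot)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": genome.name,
                    "pos": pos.astype(np.int64),
                    "strand": strand,
                    "n_meth": meth[pos].astype(np.int64),
                    "n_total": tot[pos].astype(np.int64),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["pos", "strand"], kind="stable").reset_index(drop=True)


def estimate_epsilon(counts: pd.DataFrame, min_cov: int = 5) -> float:
    """Median unconverted fraction over near-unmethylated sites (beta < 0.1)."""
    covered = counts[counts["n_total"] >= min_cov]
    beta = covered["n_meth"] / covered["n_total"]
    low = beta[beta < 0.1]
    if low.empty:
        raise ValueError("no near-unmethylated sites to estimate epsilon from")
    return float(low.median())


def call_methylation(
    counts: pd.DataFrame,
    genome: Genome,
    epsilon: float = 0.005,
    alpha: float = 0.05,
    min_cov: int = 5,
    min_level: float = 0.5,
) -> pd.DataFrame:
    """Exact binomial methylation calls with BH correction.

    Per site the upper tail p = P(X >= n_meth | n_total, epsilon) is
    computed; q-values are BH-adjusted across sites with
    n_total >= min_cov, and a site is called iff q <= alpha and
    beta = n_meth/n_total >= min_level. Context labels come from
    :func:`classify_contexts`.
    """
    if not 0.0 < epsilon < 1.0:
        raise ValueError(f"epsilon must be in (0, 1), got {epsilon}")
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    out = counts.copy().reset_index(drop=True)
    if out.empty:
        return pd.DataFrame(columns=list(CALL_COLUMNS))
    n_meth = out["n_meth"].to_numpy(dtype=np.int64)
    n_total = out["n_total"].to_numpy(dtype=np.int64)
    out["context"] = classify_contexts(
        genome, out["pos"].to_numpy(), out["strand"].to_numpy()
    )
    out["beta"] = n_meth / n_total
    out["p"] = binom.sf(n_meth - 1, n_total, epsilon)
    tested = n_total >= min_cov
    q = np.full(len(out), np.nan)
    if tested.any():
        q[tested] = multipletests(out["p"].to_numpy()[tested], method="fdr_bh")[1]
    out["q"] = q
    out["called"] = tested & (q <= alpha) & (out["beta"].to_numpy() >= min_level)
    return out


def context_summary(calls: pd.DataFrame) -> dict[str, int]:
    """Counts of called sites per CG/CHG/CHH context (undefined separate)."""
    summary = {"CG": 0, "CHG": 0, "CHH": 0, "undefined": 0}
    if calls.empty:
        return summary
    called = calls[calls["called"]]
    for ctx, n in called["context"].value_counts().items():
        summary[str(ctx)] = int(n)
    return summary
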