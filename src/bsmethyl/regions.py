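"""Upstream-region extraction, gene-level methylation reports and anchored
consensus-motif discovery.

The region of a gene is the strand-aware window from ``up`` bp before to
``down`` bp after its translation start (the start-codon base counts as the
first downstream base). Motif discovery counts exact k-mers anchored on each
called methylated cytosine, taken in the site's own 5'->3' frame, and scores
them against the genome-wide anchored k-mer frequency among all cytosines
with an exact binomial upper tail and BH correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .core import C, G, GeneAnnotation, Genome, kmer_codes, revcomp

__all__ = [
    "UpstreamRegion",
    "MotifResult",
    "upstream_interval",
    "upstream_region",
    "genes_with_methylated_upstream",
    "anchored_motif_discovery",
]


@dataclass(frozen=True)
class UpstreamRegion:
    gene_id: str
    start: int  # 0-based inclusive, forward coordinates
    end: int  # exclusive
    strand: str
    clipped: bool


@dataclass(frozen=True)
class MotifResult:
    """An anchored consensus k-mer; ``anchor`` (1-based) marks the methylated C."""

    consensus: str
    anchor: int
    support: int
    expected: float
    enrichment: float
    p_value: float
    q_value: float


def upstream_interval(
    translation_start: int,
    strand: str,
    up: int,
    down: int,
    genome_length: int,
) -> tuple[int, int, bool]:
    """Forward-coordinate half-open window around a translation start.

    '+' strand: [p - up, p + down); '-' strand: [p - down + 1, p + up + 1).
    The window is clipped to [0, genome_length); the flag reports clipping.
    """
    p = translation_start
    if strand == "+":
        start, end = p - up, p + down
    elif strand == "-":
        start, end = p - down + 1, p + up + 1
    else:
        raise ValueError(f"invalid strand {strand!r}")
    cstart, cend = max(start, 0), min(end, genome_length)
    return cstart, cend, (cstart, cend) != (start, end)


def upstream_region(
    gene: GeneAnnotation,
    genome_length: int,
    up: int = 500,
    down: int = 100,
) -> UpstreamRegion:
    if gene.end > genome_length:
        raise ValueError(f"gene {gene.gene_id} extends past the genome")
    start, end, clipped = upstream_interval(
        gene.translation_start, gene.strand, up, down, genome_length
    )
    return UpstreamRegion(
        gene_id=gene.gene_id, start=start, end=end, strand=gene.strand, clipped=clipped
    )


def genes_with_methylated_upstream(
    calls: pd.DataFrame,
    regions: Sequence[UpstreamRegion],
) -> pd.DataFrame:
    """Genes whose upstream region holds >= 1 called site (either strand).

    Sites inside overlapping regions are credited to every containing gene.
    Returns columns ``gene_id, n_sites, sites`` where ``sites`` is a list of
    (pos, strand) tuples; pass the called subset of the call table.
    """
    rows = []
    if not calls.empty:
        pos = calls["pos"].to_numpy(dtype=np.int64)
        strand = calls["strand"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos, strand = pos[order], strand[order]
        for region in regions:
            lo = np.searchsorted(pos, region.start, side="left")
            hi = np.searchsorted(pos, region.end, side="left")
            if hi > lo:
                rows.append(
                    {
                        "gene_id": region.gene_id,
                        "n_sites": int(hi - lo),
                        "sites": [
                            (int(p), str(s))
                            for p, s in zip(pos[lo:hi], strand[lo:hi])
                        ],
                    }
                )
    return pd.DataFrame(rows, columns=["gene_id", "n_sites", "sites"])


def _anchored_background(genome: Genome, k: int, anchor: int) -> tuple[dict, int]:
    """Genome-wide anchored k-mer machinery for one (k, anchor) pair.

    Returns the k-mer occurrence counter of the top strand (2-bit codes ->
    counts) and the number of cytosines on both strands whose full anchored
    window fits inside the genome.
    """
    codes = kmer_codes(genome.sequence, k)
    uniq, cnt = np.unique(codes, return_counts=True)
    counter = dict(zip(uniq.tolist(), cnt.tolist()))
    g = genome.arr
    L = len(g)
    left, right = anchor - 1, k - anchor
    n_top = int(np.count_nonzero(g[left : max(L - right, left)] == C))
    n_bot = int(np.count_nonzero(g[right : max(L - left, right)] == G))
    return counter, n_top + n_bot


def _site_kmers(
    genome: Genome,
    calls: pd.DataFrame,
    k_values: Sequence[int],
    flank: int,
) -> dict[tuple[str, int], set[int]]:
    """Anchored k-mers observed at called sites -> supporting site indices."""
    seq = genome.sequence
    L = len(seq)
    observed: dict[tuple[str, int], set[int]] = {}
    pos = calls["pos"].to_numpy(dtype=np.int64)
    strand = calls["strand"].to_numpy()
    for i in range(len(calls)):
        p = int(pos[i])
        if p - flank < 0 or p + flank + 1 > L:
            continue
        window = seq[p - flank : p + flank + 1]
        if strand[i] == "-":
            window = revcomp(window)
        for k in k_values:
            for a in range(1, k + 1):
                start = flank - (a - 1)
                if start < 0 or start + k > 2 * flank + 1:
                    continue
                observed.setdefault((window[start : start + k], a), set()).add(i)
    return observed


def _contains_at_anchor(longer: MotifResult, shorter: MotifResult) -> bool:
    d = longer.anchor - shorter.anchor
    if d < 0 or d + len(shorter.consensus) > len(longer.consensus):
        return False
    return longer.consensus[d : d + len(shorter.consensus)] == shorter.consensus


def anchored_motif_discovery(
    calls: pd.DataFrame,
    genome: Genome,
    k_values: Sequence[int] = (5, 6),
    flank: int = 10,
    min_support: int = 5,
    q_threshold: float = 0.05,
    redundancy_overlap: float = 0.9,
) -> list[MotifResult]:
    """Discover anchored consensus motifs around called methylated cytosines.

    For every called site the surrounding sequence is taken on the site's
    strand (anchor centred); each k-mer/anchor combination covering the
    anchor is counted. Expected counts come from the genome-wide frequency
    of the anchored k-mer among all cytosine positions (both strands);
    significance is an exact binomial upper tail, BH-corrected across all
    observed (k-mer, anchor) pairs. Reported motifs pass q <= q_threshold
    and support >= min_support, are pruned to a non-redundant set (a longer
    motif absorbs a nested shorter one when it explains
    >= ``redundancy_overlap`` of its background-excess support; a longer
    motif retaining less than half the nested shorter motif's excess is
    dropped as a spurious extension), and are ranked by significance
    (p-value, then enrichment).
    """
    if calls.empty:
        return []
    observed = _site_kmers(genome, calls, k_values, flank)
    if not observed:
        return []
    n_sites = len(calls)
    from .core import encode_kmer

    background: dict[tuple[int, int], tuple[dict, int]] = {}
    records = []
    for (kmer, a), sites in observed.items():
        k = len(kmer)
        if (k, a) not in background:
            background[(k, a)] = _anchored_background(genome, k, a)
        counter, denom = background[(k, a)]
        if denom == 0:
            continue
        hits = counter.get(encode_kmer(kmer), 0) + counter.get(
            encode_kmer(revcomp(kmer)), 0
        )
        freq = min(hits / denom, 1.0)
        support = len(sites)
        expected = n_sites * freq
        p = float(binom.sf(support - 1, n_sites, freq)) if freq > 0 else 0.0
        records.append((kmer, a, support, expected, freq, p, sites))

    if not records:
        return []
    pvals = np.array([r[5] for r in records])
    qvals = multipletests(pvals, method="fdr_bh")[1]

    results = []
    site_sets = {}
    for (kmer, a, support, expected, freq, p, sites), q in zip(records, qvals):
        if q > q_threshold or support < min_support:
            continue
        enrichment = support / expected if expected > 0 else np.inf
        res = MotifResult(
            consensus=kmer,
            anchor=a,
            support=support,
            expected=expected,
            enrichment=enrichment,
            p_value=p,
            q_value=float(q),
        )
        results.append(res)
        site_sets[(kmer, a)] = sites

    # non-redundancy over nested pairs (anchors consistent, so the longer
    # motif's sites are a subset of the shorter's): the longer motif
    # suppresses the shorter when it explains >= redundancy_overlap of its
    # support; a longer motif retaining < extension_retention of the
    # shorter's support is a spurious single-base extension and is dropped
    extension_retention = 0.5
    suppressed: set[tuple[str, int]] = set()

    def _excess(r: MotifResult) -> float:
        return max(r.support - r.expected, 1e-9)

    for ti in results:
        for si in results:
            if ti is si or len(ti.consensus) <= len(si.consensus):
                continue
            if not _contains_at_anchor(ti, si):
                continue
            t_sites = site_sets[(ti.consensus, ti.anchor)]
            s_sites = site_sets[(si.consensus, si.anchor)]
            shared = len(t_sites & s_sites)
            if shared >= redundancy_overlap * _excess(si):
                suppressed.add((si.consensus, si.anchor))
            elif _excess(ti) < extension_retention * _excess(si):
                suppressed.add((ti.consensus, ti.anchor))

    kept = [r for r in results if (r.consensus, r.anchor) not in suppressed]
    kept.sort(key=lambda r: (r.p_value, -r.enrichment, r.consensus))
    return kept
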