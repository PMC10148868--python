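"""Synthetic genome, annotation, methylome and bisulfite-read generation.

The simulator emulates a GC-rich linear bacterial chromosome carrying
motif-anchored methylated cytosines in gene upstream regions plus
configurable per-context background methylation, then produces directional
bisulfite-converted reads (OT/OB) with known truth for every stage of the
downstream pipeline to recover.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import (
    A,
    C,
    G,
    T,
    _BASES_U8,
    _CODE_LUT,
    GeneAnnotation,
    Genome,
    MethylationTruth,
    MotifSpec,
    ReadRecord,
    revcomp,
)
from .mcall import classify_contexts
from .regions import upstream_interval

__all__ = [
    "generate_genome",
    "generate_annotation",
    "plant_methylome",
    "simulate_reads",
    "DEFAULT_MOTIFS",
]

DEFAULT_MOTIFS = (
    MotifSpec("GGCCGG", anchor=4),
    MotifSpec("GCCCG", anchor=4),
)


def generate_genome(
    length: int,
    gc_fraction: float = 0.70,
    seed: int = 0,
    name: str = "chr",
) -> Genome:
    """Generate a random linear chromosome with i.i.d. bases.

    Parameters
    ----------
    length
        Chromosome length in bp (>= 1).
    gc_fraction
        P(G) + P(C); G and C (and A and T) are equiprobable.
    seed
        Seed for the PRNG; identical inputs give byte-identical sequences.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError(f"gc_fraction must be in [0, 1], got {gc_fraction}")
    rng = np.random.default_rng(seed)
    half_gc = gc_fraction / 2.0
    half_at = (1.0 - gc_fraction) / 2.0
    # order A, C, G, T
    bases = rng.choice(_BASES_U8, size=length, p=[half_at, half_gc, half_gc, half_at])
    return Genome(name=name, sequence=bases.tobytes().decode("ascii"))


def generate_annotation(
    genome: Genome,
    n_genes: int,
    gene_length: tuple[int, int] = (900, 1500),
    min_gap: int = 200,
    seed: int = 0,
) -> list[GeneAnnotation]:
    """Place ``n_genes`` non-overlapping genes with gaps >= ``min_gap``.

    Gene lengths are uniform over ``gene_length`` (inclusive), strands are
    assigned uniformly at random, and leftover space is spread randomly
    between the genes. Infeasible packings raise ``ValueError`` rather than
    silently truncating.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    if n_genes == 0:
        return []
    lo, hi = gene_length
    if not 1 <= lo <= hi:
        raise ValueError(f"invalid gene_length range {gene_length}")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(lo, hi + 1, size=n_genes)
    slack = len(genome) - int(lengths.sum()) - min_gap * (n_genes - 1)
    if slack < 0:
        raise ValueError(
            f"cannot place {n_genes} genes of {gene_length} bp with "
            f"min_gap={min_gap} in a {len(genome)} bp genome"
        )
    # random composition of the slack into n_genes + 1 inter-gene gaps
    extra = rng.multinomial(slack, np.full(n_genes + 1, 1.0 / (n_genes + 1)))
    strands = rng.choice(np.array(["+", "-"]), size=n_genes)
    genes = []
    cursor = 0
    width = len(str(n_genes))
    for i in range(n_genes):
        cursor += int(extra[i])
        if i > 0:
            cursor += min_gap
        start = cursor
        end = start + int(lengths[i])
        genes.append(
            GeneAnnotation(
                gene_id=f"gene_{i + 1:0{width}d}",
                start=start,
                end=end,
                strand=str(strands[i]),
            )
        )
        cursor = end
    return genes


def _place_motif(
    seq: list[str],
    gene: GeneAnnotation,
    motif: MotifSpec,
    genome_length: int,
    rng: np.random.Generator,
    occupied: list[tuple[int, int]],
    up: int,
    down: int,
    max_tries: int = 50,
) -> tuple[int, list[tuple[int, str]]]:
    """Write one motif instance into ``gene``'s upstream region.

    Returns the placement start (top-strand coordinates) and the anchor
    site(s) as (pos, strand) tuples.
    """
    region_start, region_end, _clipped = upstream_interval(
        gene.translation_start, gene.strand, up, down, genome_length
    )
    k = len(motif.sequence)
    if region_end - region_start < k:
        raise ValueError(
            f"motif {motif.sequence} ({k} bp) does not fit the "
            f"[{region_start}, {region_end}) upstream region of {gene.gene_id}"
        )
    for _ in range(max_tries):
        s = int(rng.integers(region_start, region_end - k + 1))
        if all(s + k <= a or s >= b for a, b in occupied):
            break
    else:
        raise ValueError(f"could not place motif for {gene.gene_id} without overlap")
    occupied.append((s, s + k))
    written = motif.sequence if gene.strand == "+" else revcomp(motif.sequence)
    seq[s : s + k] = list(written)
    if gene.strand == "+":
        anchors = [(s + motif.anchor - 1, "+")]
    else:
        anchors = [(s + k - motif.anchor, "-")]
    if motif.is_palindromic:
        flip = {"+": "-", "-": "+"}
        pos = s + k - motif.anchor if gene.strand == "+" else s + motif.anchor - 1
        anchors.append((pos, flip[gene.strand]))
    return s, anchors


def plant_methylome(
    genome: Genome,
    annotation: Sequence[GeneAnnotation],
    motifs: Sequence[MotifSpec] = DEFAULT_MOTIFS,
    genes_with_motif_fraction: float = 0.5,
    background_rates: Optional[Mapping[str, float]] = None,
    background_site_fraction: float = 1.0,
    seed: int = 0,
    up: int = 500,
    down: int = 100,
    methylate_palindrome_partner: bool = True,
) -> tuple[Genome, MethylationTruth]:
    """Edit motif instances into gene upstream regions and build the truth.

    A random subset of genes (``genes_with_motif_fraction`` of them) each
    receives one motif instance, written strand-aware into the gene's
    -``up``/+``down`` window around its translation start; the instance's
    anchor C (plus the opposite-strand anchor when the motif is its own
    reverse complement and ``methylate_palindrome_partner`` is set) enters
    the truth at the motif's methylation fraction. Background methylation
    then marks a Bernoulli(``background_rates[context]``) subset of the
    remaining cytosines per context at ``background_site_fraction``.

    Returns the edited genome and the complete ground truth.
    """
    if not 0.0 <= genes_with_motif_fraction <= 1.0:
        raise ValueError("genes_with_motif_fraction must be in [0, 1]")
    background_rates = dict(background_rates or {})
    for ctx, rate in background_rates.items():
        if ctx not in ("CG", "CHG", "CHH"):
            raise ValueError(f"unknown context {ctx!r} in background_rates")
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"background rate for {ctx} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_sel = int(round(genes_with_motif_fraction * len(annotation)))
    selected = sorted(rng.choice(len(annotation), size=n_sel, replace=False).tolist())

    seq = list(genome.sequence)
    occupied: list[tuple[int, int]] = []
    sites: list[tuple[int, str, float, str]] = []
    for rank, gi in enumerate(selected):
        motif = motifs[rank % len(motifs)]
        _, anchors = _place_motif(
            seq, annotation[gi], motif, len(genome), rng, occupied, up, down
        )
        if not methylate_palindrome_partner:
            anchors = anchors[:1]
        for pos, strand in anchors:
            sites.append((pos, strand, motif.methylation_fraction, "motif-planted"))

    edited = Genome(name=genome.name, sequence="".join(seq), topology=genome.topology)

    if any(rate > 0 for rate in background_rates.values()):
        taken = {(p, s) for p, s, _, _ in sites}
        positions, strands, contexts = _all_cytosine_contexts(edited)
        for ctx, rate in background_rates.items():
            if rate <= 0:
                continue
            mask = contexts == ctx
            picks = mask & (rng.random(len(positions)) < rate)
            for pos, strand in zip(positions[picks], strands[picks]):
                key = (int(pos), str(strand))
                if key in taken:
                    continue
                sites.append(
                    (key[0], key[1], background_site_fraction, "background")
                )

    truth = MethylationTruth.from_sites(sites)
    truth.validate_against(edited)
    return edited, truth


def _all_cytosine_contexts(genome: Genome):
    """Positions, strands and CG/CHG/CHH context of every cytosine, both strands."""
    arr = genome.arr
    top = np.flatnonzero(arr == C)
    bot = np.flatnonzero(arr == G)
    positions = np.concatenate([top, bot])
    strands = np.concatenate(
        [np.full(len(top), "+", dtype=object), np.full(len(bot), "-", dtype=object)]
    )
    contexts = classify_contexts(genome, positions, strands)
    return positions, strands, contexts


def simulate_reads(
    genome: Genome,
    truth: MethylationTruth,
    coverage: float = 30.0,
    read_length: int = 100,
    conversion_rate: float = 0.995,
    error_rate: float = 0.001,
    seed: int = 0,
    quality_char: str = "?",  # Phred 30
    chunk_size: int = 50_000,
) -> list[ReadRecord]:
    """Simulate directional bisulfite reads (OT/OB with equal probability).

    Fragments are drawn uniformly over the linear genome (no wraparound).
    Methylation is Bernoulli per molecule at each truth site's fraction;
    protected cytosines never convert, unprotected ones convert with
    probability ``conversion_rate``. I.i.d. substitution errors at
    ``error_rate`` are applied after conversion. The read count is
    ``ceil(coverage * genome_length / read_length)``.
    """
    L = len(genome)
    if read_length > L:
        raise ValueError(f"read_length {read_length} exceeds genome length {L}")
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if not 0.0 <= conversion_rate <= 1.0 or not 0.0 <= error_rate <= 1.0:
        raise ValueError("rates must be in [0, 1]")

    n_reads = math.ceil(coverage * L / read_length)
    rng = np.random.default_rng(seed)
    frac_top, frac_bot = truth.fraction_arrays(L)
    g = genome.arr
    offs = np.arange(read_length)
    qual = quality_char * read_length
    reads: list[ReadRecord] = []
    emitted = 0
    while emitted < n_reads:
        m = min(chunk_size, n_reads - emitted)
        starts = rng.integers(0, L - read_length + 1, size=m)
        is_ob = rng.random(m) < 0.5
        posmat = starts[:, None] + offs
        mat = g[posmat].copy()
        u_prot = rng.random((m, read_length))
        u_conv = rng.random((m, read_length))
        protected_top = u_prot < frac_top[posmat]
        protected_bot = u_prot < frac_bot[posmat]
        conv = u_conv < conversion_rate
        conv_ot = (~is_ob[:, None]) & (mat == C) & ~protected_top & conv
        conv_ob = is_ob[:, None] & (mat == G) & ~protected_bot & conv
        mat[conv_ot] = T
        mat[conv_ob] = A
        if error_rate > 0:
            err = rng.random((m, read_length)) < error_rate
            shifts = rng.integers(1, 4, size=(m, read_length))
            codes = _CODE_LUT[mat].astype(np.int64)
            mat[err] = _BASES_U8[(codes[err] + shifts[err]) % 4]
        for i in range(m):
            idx = emitted + i
            frame = "OB" if is_ob[i] else "OT"
            bases = mat[i].tobytes().decode("ascii")
            if frame == "OB":
                bases = revcomp(bases)
            reads.append(
                ReadRecord(
                    read_id=f"r{idx:08d}",
                    bases=bases,
                    qualities=qual,
                    origin_pos=int(starts[i]),
                    origin_strand=frame,
                )
            )
        emitted += m
    return reads
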