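"""Shared domain types and low-level sequence utilities.

Coordinates are 0-based half-open everywhere inside the package; 1-based
conventions appear only at the GFF3/SAM/report boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "Genome",
    "GeneAnnotation",
    "MethylationTruth",
    "MotifSpec",
    "ReadRecord",
    "Alignment",
    "revcomp",
    "kmer_codes",
    "encode_kmer",
]

_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")

# ASCII byte values used for vectorised base comparisons.
A, C, G, T, N = (ord(x) for x in "ACGTN")

_ALLOWED = frozenset("ACGTN")

# 2-bit codes (A=0, C=1, G=2, T=3); other bytes map to 0.
_CODE_LUT = np.zeros(256, dtype=np.uint64)
_CODE_LUT[C] = 1
_CODE_LUT[G] = 2
_CODE_LUT[T] = 3

_BASES_U8 = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_array(seq: str) -> np.ndarray:
    """View a DNA string as a uint8 array of ASCII codes."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def kmer_codes(seq: str, k: int) -> np.ndarray:
    """2-bit packed codes of every k-mer of ``seq`` (k <= 32)."""
    if not 1 <= k <= 32:
        raise ValueError(f"k must be in [1, 32], got {k}")
    b = _CODE_LUT[seq_to_array(seq)]
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        codes = (codes << np.uint64(2)) | b[j : j + n]
    return codes


def encode_kmer(kmer: str) -> int:
    code = 0
    for ch in kmer:
        code = (code << 2) | int(_CODE_LUT[ord(ch)])
    return code


@dataclass(frozen=True)
class Genome:
    """A single linear chromosome.

    Parameters
    ----------
    name
        Sequence identifier (FASTA record name).
    sequence
        Uppercase DNA over {A,C,G,T}; parsed genomes may contain N.
    """

    name: str
    sequence: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("genome sequence must be non-empty")
        if self.topology != "linear":
            raise ValueError("only linear chromosomes are supported")
        bad = set(self.sequence) - _ALLOWED
        if bad:
            raise ValueError(f"genome contains invalid characters: {sorted(bad)!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @cached_property
    def arr(self) -> np.ndarray:
        """ASCII byte view of the sequence (shared, do not mutate)."""
        return seq_to_array(self.sequence)

    def base_at(self, pos: int, strand: str) -> str:
        """Base at ``pos`` read on ``strand`` (complemented for '-')."""
        b = self.sequence[pos]
        return b if strand == "+" else revcomp(b)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval; ``translation_start`` is the first base of the start codon."""

    gene_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid gene interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def translation_start(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


class MethylationTruth:
    """Ground-truth methylated sites planted by the simulator.

    Stored as a table with columns ``pos`` (0-based), ``strand`` (+/-),
    ``fraction`` (per-molecule methylation probability in (0, 1]) and
    ``provenance`` ({'motif-planted', 'background'}).
    """

    COLUMNS = ("pos", "strand", "fraction", "provenance")

    def __init__(self, table: Optional[pd.DataFrame] = None) -> None:
        if table is None:
            table = pd.DataFrame(
                {
                    "pos": pd.Series(dtype=np.int64),
                    "strand": pd.Series(dtype=object),
                    "fraction": pd.Series(dtype=float),
                    "provenance": pd.Series(dtype=object),
                }
            )
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"truth table missing columns: {sorted(missing)}")
        frac = table["fraction"].to_numpy()
        if len(frac) and (np.any(frac <= 0) or np.any(frac > 1)):
            raise ValueError("truth fractions must lie in (0, 1]")
        self.table = table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MethylationTruth):
            return NotImplemented
        return self.table.equals(other.table)

    @classmethod
    def from_sites(
        cls, sites: Iterable[tuple[int, str, float, str]]
    ) -> "MethylationTruth":
        rows = list(sites)
        if not rows:
            return cls()
        df = pd.DataFrame(rows, columns=list(cls.COLUMNS))
        df = df.sort_values(["pos", "strand"], kind="stable").reset_index(drop=True)
        return cls(df)

    def site_set(self) -> set[tuple[int, str]]:
        return set(zip(self.table["pos"].tolist(), self.table["strand"].tolist()))

    def fraction_arrays(self, genome_length: int) -> tuple[np.ndarray, np.ndarray]:
        """Per-position methylation fractions for the top and bottom strands."""
        top = np.zeros(genome_length, dtype=np.float64)
        bot = np.zeros(genome_length, dtype=np.float64)
        pos = self.table["pos"].to_numpy(dtype=np.int64)
        frac = self.table["fraction"].to_numpy(dtype=np.float64)
        is_top = (self.table["strand"] == "+").to_numpy()
        top[pos[is_top]] = frac[is_top]
        bot[pos[~is_top]] = frac[~is_top]
        return top, bot

    def validate_against(self, genome: Genome) -> None:
        """Assert that every site's base on its own strand is a cytosine."""
        for pos, strand in self.site_set():
            base = genome.base_at(pos, strand)
            if base != "C":
                raise ValueError(
                    f"truth site {pos}{strand} is {base}, expected C on its strand"
                )


@dataclass(frozen=True)
class MotifSpec:
    """An anchored methylation motif: ``anchor`` (1-based) marks the methylated C."""

    sequence: str
    anchor: int
    methylation_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 1 <= self.anchor <= len(self.sequence):
            raise ValueError("anchor outside motif")
        if self.sequence[self.anchor - 1] != "C":
            raise ValueError(
                f"motif base at anchor {self.anchor} is "
                f"{self.sequence[self.anchor - 1]!r}, expected 'C'"
            )
        if not 0 < self.methylation_fraction <= 1:
            raise ValueError("methylation_fraction must be in (0, 1]")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(f"motif contains invalid characters: {sorted(bad)!r}")

    @property
    def is_palindromic(self) -> bool:
        return revcomp(self.sequence) == self.sequence


@dataclass(frozen=True)
class ReadRecord:
    """A simulated (or parsed) sequencing read with optional truth of origin."""

    read_id: str
    bases: str
    qualities: str
    origin_pos: Optional[int] = None
    origin_strand: Optional[str] = None  # OT / OB

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError("bases and qualities differ in length")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class Alignment:
    """An ungapped bisulfite alignment in top-strand coordinates."""

    read_id: str
    chrom: Optional[str]
    pos: Optional[int]  # 0-based leftmost; None unless unique
    bisulfite_strand: Optional[str]  # OT / OB
    mismatches: Optional[int]
    status: str  # unique / ambiguous / unmapped
    read_length: int = 0
    reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status not in ("unique", "ambiguous", "unmapped"):
            raise ValueError(f"invalid status {self.status!r}")
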