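"""Readers and writers for the pipeline's file formats.

FASTA via Biopython, GFF3 via gffutils, SAM via pysam, tables via pandas.
All on-disk coordinates follow the format's native convention (GFF3 and the
cytosine report are 1-based; BED/bedGraph and the truth TSV are 0-based).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence, Union

import gffutils
import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .core import Alignment, GeneAnnotation, Genome, MethylationTruth, ReadRecord, revcomp
from .landscape import WindowProfile
from .regions import MotifResult, UpstreamRegion

PathLike = Union[str, Path]

TRUTH_COLUMNS = ["chrom", "pos0", "strand", "fraction", "provenance"]


# ---------------------------------------------------------------------------
# FASTA / GFF3 / FASTQ

def write_fasta(genome: Genome, path: PathLike) -> None:
    record = SeqRecord(Seq(genome.sequence), id=genome.name, description="")
    SeqIO.write([record], str(path), "fasta")


def read_fasta(path: PathLike) -> Genome:
    record = next(SeqIO.parse(str(path), "fasta"))
    return Genome(name=record.id, sequence=str(record.seq).upper())


def write_gff3(genes: Sequence[GeneAnnotation], chrom: str, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            fh.write(
                f"{chrom}\tbsmethyl\tgene\t{gene.start + 1}\t{gene.end}\t.\t"
                f"{gene.strand}\t.\tID={gene.gene_id}\n"
            )


def read_gff3(path: PathLike) -> list[GeneAnnotation]:
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    genes = []
    for feat in db.features_of_type("gene", order_by="start"):
        genes.append(
            GeneAnnotation(
                gene_id=feat.id,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
            )
        )
    return genes


def write_fastq(reads: Iterable[ReadRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        for read in reads:
            desc = ""
            if read.origin_pos is not None:
                desc = f" pos={read.origin_pos} frame={read.origin_strand}"
            fh.write(f"@{read.read_id}{desc}\n{read.bases}\n+\n{read.qualities}\n")


def read_fastq(path: PathLike) -> list[ReadRecord]:
    reads = []
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            reads.append(
                ReadRecord(read_id=title.split()[0], bases=seq.upper(), qualities=qual)
            )
    return reads


# ---------------------------------------------------------------------------
# Truth sidecar

def write_truth(truth: MethylationTruth, chrom: str, path: PathLike) -> None:
    df = truth.table.rename(columns={"pos": "pos0"}).copy()
    df.insert(0, "chrom", chrom)
    df[TRUTH_COLUMNS].to_csv(path, sep="\t", index=False)


def read_truth(path: PathLike) -> MethylationTruth:
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={"pos0": "pos"}).drop(columns=["chrom"])
    return MethylationTruth(df)


# ---------------------------------------------------------------------------
# SAM

_FLAG_REVERSE = 16
_FLAG_UNMAPPED = 4


def write_sam(
    alignments: Sequence[Alignment],
    reads: Union[dict, Sequence[ReadRecord]],
    genome: Genome,
    path: PathLike,
) -> None:
    """Minimal SAM: unique alignments only, XG tag carries the bisulfite frame.

    OB alignments are stored reverse-complemented (flag 16) so SEQ matches
    the forward reference, as a conventional aligner would.
    """
    if not isinstance(reads, dict):
        reads = {r.read_id: r for r in reads}
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": genome.name, "LN": len(genome)}],
        }
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            if aln.status != "unique":
                continue
            read = reads[aln.read_id]
            seg = pysam.AlignedSegment(header)
            seg.query_name = aln.read_id
            is_ob = aln.bisulfite_strand == "OB"
            seg.flag = _FLAG_REVERSE if is_ob else 0
            seg.reference_id = 0
            seg.reference_start = aln.pos
            seg.mapping_quality = 255
            seg.cigarstring = f"{len(read.bases)}M"
            seq = revcomp(read.bases) if is_ob else read.bases
            qual = read.qualities[::-1] if is_ob else read.qualities
            seg.query_sequence = seq
            seg.query_qualities = pysam.qualitystring_to_array(qual)
            seg.set_tag("XG", aln.bisulfite_strand, value_type="Z")
            seg.set_tag("NM", aln.mismatches, value_type="i")
            out.write(seg)


def read_sam(path: PathLike) -> tuple[list[Alignment], dict[str, ReadRecord]]:
    """Parse a SAM back into unique alignments plus original-orientation reads."""
    alignments = []
    reads: dict[str, ReadRecord] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            frame = seg.get_tag("XG") if seg.has_tag("XG") else (
                "OB" if seg.is_reverse else "OT"
            )
            seq = seg.query_sequence
            qual = pysam.qualities_to_qualitystring(seg.query_qualities)
            if seg.is_reverse:
                seq, qual = revcomp(seq), qual[::-1]
            reads[seg.query_name] = ReadRecord(
                read_id=seg.query_name, bases=seq, qualities=qual
            )
            alignments.append(
                Alignment(
                    read_id=seg.query_name,
                    chrom=seg.reference_name,
                    pos=seg.reference_start,
                    bisulfite_strand=str(frame),
                    mismatches=int(seg.get_tag("NM")) if seg.has_tag("NM") else None,
                    status="unique",
                    read_length=seg.query_length,
                )
            )
    return alignments, reads


# ---------------------------------------------------------------------------
# Call tables / BED / bedGraph

def write_calls(calls: pd.DataFrame, path: PathLike) -> None:
    """Bismark-style cytosine report (1-based positions)."""
    df = calls.copy()
    df["pos1"] = df["pos"] + 1
    df["n_unmeth"] = df["n_total"] - df["n_meth"]
    cols = ["chrom", "pos1", "strand", "n_meth", "n_unmeth", "context", "p", "q", "called"]
    with open(path, "w") as fh:
        fh.write("# positions are 1-based\n")
        df[cols].to_csv(fh, sep="\t", index=False)


def read_calls(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    df["pos"] = df["pos1"] - 1
    df["n_total"] = df["n_meth"] + df["n_unmeth"]
    df["beta"] = df["n_meth"] / df["n_total"]
    df["called"] = df["called"].astype(bool)
    return df[
        ["chrom", "pos", "strand", "n_meth", "n_total", "context", "beta", "p", "q", "called"]
    ]


def write_bedgraph(calls: pd.DataFrame, path: PathLike) -> None:
    """bedGraph of 100*beta, called sites only (0-based half-open)."""
    called = calls[calls["called"]]
    with open(path, "w") as fh:
        for row in called.itertuples():
            fh.write(f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{100 * row.beta:.2f}\n")


def write_bed(bed: pd.DataFrame, path: PathLike) -> None:
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )


def write_regions_bed(regions: Sequence[UpstreamRegion], chrom: str, path: PathLike) -> None:
    rows = [
        (chrom, r.start, r.end, r.gene_id, 0, r.strand) for r in regions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_windows(profile: WindowProfile, path: PathLike) -> None:
    profile.table.to_csv(path, sep="\t", index=False)


def read_windows(path: PathLike, window_size: int, genome_length: int) -> WindowProfile:
    return WindowProfile(
        window_size=window_size,
        genome_length=genome_length,
        table=pd.read_csv(path, sep="\t"),
    )


def write_motifs(motifs: Sequence[MotifResult], path: PathLike) -> None:
    rows = [
        (m.consensus, m.anchor, m.support, m.expected, m.enrichment, m.p_value, m.q_value)
        for m in motifs
    ]
    pd.DataFrame(
        rows,
        columns=["consensus", "anchor", "support", "expected", "enrichment", "p", "q"],
    ).to_csv(path, sep="\t", index=False)
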