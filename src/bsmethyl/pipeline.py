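"""End-to-end orchestration: simulate -> map -> call -> landscape -> regions.

A single :class:`PipelineConfig` carries every stage parameter; one global
seed expands deterministically into per-stage seeds, so a fixed config and
seed reproduce byte-identical artifacts (and manifest checksums).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import bsmap, io, landscape, mcall, regions as regions_mod, synthdata
from .core import Genome, MethylationTruth, MotifSpec

logger = logging.getLogger("bsmethyl")

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    # genome
    genome_length: int = 1_000_000
    gc_fraction: float = 0.70
    chrom_name: str = "chr"
    # annotation
    n_genes: int = 200
    gene_length: tuple[int, int] = (900, 1500)
    min_gap: int = 200
    # methylome
    motifs: tuple[tuple[str, int, float], ...] = (
        ("GGCCGG", 4, 1.0),
        ("GCCCG", 4, 1.0),
    )
    genes_with_motif_fraction: float = 0.5
    background_rates: dict = field(default_factory=lambda: {"CG": 0.001})
    background_site_fraction: float = 1.0
    methylate_palindrome_partner: bool = True
    # upstream window
    up: int = 500
    down: int = 100
    # sequencing
    coverage: float = 30.0
    read_length: int = 100
    conversion_rate: float = 0.995
    error_rate: float = 0.001
    # mapping
    k: int = 16
    max_mismatch: Optional[int] = None
    # calling
    epsilon: float = 0.005
    alpha: float = 0.05
    min_cov: int = 5
    min_level: float = 0.5
    # landscape
    window: int = 250_000
    # motif discovery
    k_values: tuple[int, ...] = (5, 6)
    flank: int = 10
    min_support: int = 5
    motif_q: float = 0.05
    # global seed
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise ValueError("genome_length must be >= 1")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")
        if self.read_length > self.genome_length:
            raise ValueError("read_length exceeds genome_length")
        for seq, anchor, frac in self.motifs:
            MotifSpec(seq, anchor, frac)  # validates

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        if "gene_length" in data:
            data["gene_length"] = tuple(data["gene_length"])
        if "motifs" in data:
            data["motifs"] = tuple(tuple(m) for m in data["motifs"])
        if "k_values" in data:
            data["k_values"] = tuple(data["k_values"])
        return cls(**data)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gene_length"] = list(self.gene_length)
        d["motifs"] = [list(m) for m in self.motifs]
        d["k_values"] = list(self.k_values)
        return d

    def motif_specs(self) -> list[MotifSpec]:
        return [MotifSpec(s, a, f) for s, a, f in self.motifs]

    def stage_seeds(self) -> dict[str, int]:
        ss = np.random.SeedSequence(self.seed)
        names = ("genome", "annotation", "methylome", "reads")
        return {
            name: int(child.generate_state(1)[0])
            for name, child in zip(names, ss.spawn(len(names)))
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _recovery_metrics(
    calls, truth: MethylationTruth, gene_table, region_list
) -> dict:
    called = calls[calls["called"]]
    called_set = set(zip(called["pos"].tolist(), called["strand"].tolist()))
    truth_set = truth.site_set()
    tp = len(called_set & truth_set)
    sensitivity = tp / len(truth_set) if truth_set else float("nan")
    precision = tp / len(called_set) if called_set else float("nan")

    truth_genes = set()
    if len(truth):
        pos = np.sort(truth.table["pos"].to_numpy(dtype=np.int64))
        for region in region_list:
            lo = np.searchsorted(pos, region.start, side="left")
            hi = np.searchsorted(pos, region.end, side="left")
            if hi > lo:
                truth_genes.add(region.gene_id)
    reported_genes = set(gene_table["gene_id"].tolist())
    union = truth_genes | reported_genes
    jaccard = len(truth_genes & reported_genes) / len(union) if union else float("nan")
    return {
        "n_truth_sites": len(truth_set),
        "n_called_sites": len(called_set),
        "site_sensitivity": sensitivity,
        "site_precision": precision,
        "n_truth_genes": len(truth_genes),
        "n_reported_genes": len(reported_genes),
        "gene_jaccard": jaccard,
    }


def run_all(config: PipelineConfig, outdir) -> dict:
    """Run every stage on synthetic data; returns the manifest dict.

    Writes all artifacts plus ``manifest.json`` (file checksums, effective
    config) and ``summary.json`` (context counts, totals, top motifs,
    truth-recovery metrics) into ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    stage = "simulate"
    try:
        logger.info("simulate: genome %d bp, %d genes", config.genome_length, config.n_genes)
        genome = synthdata.generate_genome(
            config.genome_length, config.gc_fraction, seed=seeds["genome"],
            name=config.chrom_name,
        )
        genes = synthdata.generate_annotation(
            genome, config.n_genes, config.gene_length, config.min_gap,
            seed=seeds["annotation"],
        )
        genome, truth = synthdata.plant_methylome(
            genome,
            genes,
            motifs=config.motif_specs(),
            genes_with_motif_fraction=config.genes_with_motif_fraction,
            background_rates=config.background_rates,
            background_site_fraction=config.background_site_fraction,
            seed=seeds["methylome"],
            up=config.up,
            down=config.down,
            methylate_palindrome_partner=config.methylate_palindrome_partner,
        )
        reads = synthdata.simulate_reads(
            genome,
            truth,
            coverage=config.coverage,
            read_length=config.read_length,
            conversion_rate=config.conversion_rate,
            error_rate=config.error_rate,
            seed=seeds["reads"],
        )
        io.write_fasta(genome, outdir / "genome.fa")
        io.write_gff3(genes, genome.name, outdir / "genes.gff3")
        io.write_truth(truth, genome.name, outdir / "truth.tsv")
        io.write_fastq(reads, outdir / "reads.fastq")

        stage = "map"
        logger.info("map: %d reads, k=%d", len(reads), config.k)
        index = bsmap.BisulfiteIndex(genome, k=config.k)
        alignments = bsmap.map_reads(index, reads, max_mismatch=config.max_mismatch)
        io.write_sam(alignments, reads, genome, outdir / "alignments.sam")
        n_unique = sum(a.status == "unique" for a in alignments)

        stage = "call"
        counts = mcall.pileup(alignments, reads, genome)
        calls = mcall.call_methylation(
            counts,
            genome,
            epsilon=config.epsilon,
            alpha=config.alpha,
            min_cov=config.min_cov,
            min_level=config.min_level,
        )
        io.write_calls(calls, outdir / "calls.tsv")
        io.write_bedgraph(calls, outdir / "calls.bedgraph")
        called = calls[calls["called"]]

        stage = "landscape"
        profile = landscape.window_profile(called, len(genome), config.window)
        io.write_windows(profile, outdir / "windows.tsv")
        bed = landscape.site_track(called)
        io.write_bed(bed, outdir / "sites.bed")
        landscape.plot_profiles([profile], ["sample"], outdir / "landscape.png")
        landscape.plot_site_track(bed, outdir / "sites.png")

        stage = "regions"
        region_list = [
            regions_mod.upstream_region(g, len(genome), config.up, config.down)
            for g in genes
        ]
        io.write_regions_bed(region_list, genome.name, outdir / "regions.bed")
        gene_table = regions_mod.genes_with_methylated_upstream(called, region_list)
        gene_table.assign(
            sites=gene_table["sites"].map(
                lambda xs: ";".join(f"{p}{s}" for p, s in xs)
            )
        ).to_csv(outdir / "genes_methylated.tsv", sep="\t", index=False)
        motif_results = regions_mod.anchored_motif_discovery(
            called,
            genome,
            k_values=config.k_values,
            flank=config.flank,
            min_support=config.min_support,
            q_threshold=config.motif_q,
        )
        io.write_motifs(motif_results, outdir / "motifs.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary = {
        "n_reads": len(reads),
        "n_unique_alignments": n_unique,
        "mapping_rate": n_unique / len(reads) if reads else float("nan"),
        "n_sites_with_coverage": len(counts),
        "n_called": int(called.shape[0]),
        "context_counts": mcall.context_summary(calls),
        "n_genes_reported": int(gene_table.shape[0]),
        "top_motifs": [
            {
                "consensus": m.consensus,
                "anchor": m.anchor,
                "support": m.support,
                "enrichment": m.enrichment,
                "q": m.q_value,
            }
            for m in motif_results[:10]
        ],
        "recovery": _recovery_metrics(calls, truth, gene_table, region_list),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    artifact_names = sorted(
        p.name for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "files": {name: _sha256(outdir / name) for name in artifact_names},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
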