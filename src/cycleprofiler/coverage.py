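"""Gene and genome coverage, RPKM, and step relative abundance.

Community-mode runs weight each genome's functional repertoire by its
abundance in the sample.  Abundance is measured as read coverage: mean
per-base depth of each gene (from a sorted BAM of reads mapped to the gene
collection, or from a pre-computed depth table), aggregated to a per-genome
coverage C_g.  For metatranscriptomes the same machinery runs on RPKM
(reads per kilobase of transcript per million mapped reads) instead of DNA
depth.  The relative abundance of a biogeochemical cycling step is the
summed coverage of the genes responsible for that step, normalized by the
summed coverage of all genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError


@dataclass(frozen=True)
class GeneCoverage:
    """Mean per-base read depth over one gene."""

    genome_id: str
    gene_id: str
    length_bp: int
    mean_depth: float
    mapped_reads: int | None = None


@dataclass(frozen=True)
class GenomeCoverage:
    """Genome abundance C_g: aggregate of its genes' depths."""

    genome_id: str
    coverage: float


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    rpkm: float


def gene_coverage(depths: Sequence[float] | np.ndarray, genome_id: str,
                  gene_id: str, mapped_reads: int | None = None) -> GeneCoverage:
    """Mean depth of a per-base depth series spanning exactly the gene."""
    depths = np.asarray(depths, dtype=float)
    if depths.size == 0:
        raise ConfigError(f"gene {gene_id}: zero-length interval")
    if np.any(depths < 0):
        raise ConfigError(f"gene {gene_id}: negative depth")
    return GeneCoverage(genome_id=genome_id, gene_id=gene_id,
                        length_bp=int(depths.size),
                        mean_depth=float(depths.mean()),
                        mapped_reads=mapped_reads)


def genome_coverage(genes: Sequence[GeneCoverage], weighted: bool = True) -> GenomeCoverage:
    """Aggregate gene depths to genome coverage C_g.

    Default is the length-weighted mean of gene mean depths (equivalent to
    total bases over total gene length); ``weighted=False`` gives the simple
    mean.
    """
    if not genes:
        raise ConfigError("cannot compute genome coverage from an empty gene list")
    gid = genes[0].genome_id
    if weighted:
        total_len = sum(g.length_bp for g in genes)
        cov = sum(g.mean_depth * g.length_bp for g in genes) / total_len
    else:
        cov = sum(g.mean_depth for g in genes) / len(genes)
    return GenomeCoverage(genome_id=gid, coverage=float(cov))


def rpkm(mapped_reads: int, length_bp: int, total_mapped: int, gene_id: str = "") -> ExpressionRecord:
    """Reads per kilobase of transcript per million mapped reads."""
    if total_mapped < 1:
        raise ConfigError("total mapped reads must be >= 1")
    if length_bp < 1:
        raise ConfigError("gene length must be >= 1")
    value = mapped_reads / ((length_bp / 1_000) * (total_mapped / 1_000_000))
    return ExpressionRecord(gene_id=gene_id, rpkm=float(value))


def depth_from_bam(bam_path: str | Path,
                   gene_intervals: Mapping[str, tuple[str, int, int]],
                   genome_of: Mapping[str, str] | None = None) -> list[GeneCoverage]:
    """Per-gene mean depth from a sorted, indexed BAM.

    ``gene_intervals`` maps gene_id -> (contig, start, end) in 1-based
    inclusive coordinates.  Only primary alignments count: secondary,
    supplementary and unmapped records are excluded, so a multi-mapping read
    contributes once.
    """
    import pysam

    def _primary(read) -> bool:
        return not (read.is_unmapped or read.is_secondary or read.is_supplementary)

    out: list[GeneCoverage] = []
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        lengths = dict(zip(bam.references, bam.lengths))
        for gene_id, (contig, start, end) in gene_intervals.items():
            if contig not in lengths:
                raise ConfigError(f"gene {gene_id}: contig {contig!r} absent from BAM header")
            if not (1 <= start <= end <= lengths[contig]):
                raise ConfigError(f"gene {gene_id}: interval {start}-{end} outside contig")
            cov = bam.count_coverage(contig, start - 1, end,
                                     quality_threshold=0, read_callback=_primary)
            depths = np.asarray(cov).sum(axis=0)
            gid = genome_of[gene_id] if genome_of else ""
            out.append(gene_coverage(depths, genome_id=gid, gene_id=gene_id))
    return out


def read_depth_table(path: str | Path) -> list[GeneCoverage]:
    """Read a depth TSV with columns (genome_id, gene_id, length_bp, mean_depth)."""
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str, "gene_id": str},
                     keep_default_na=False)
    required = {"genome_id", "gene_id", "length_bp", "mean_depth"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"depth table missing columns: {sorted(missing)}")
    return [
        GeneCoverage(genome_id=str(r.genome_id), gene_id=str(r.gene_id),
                     length_bp=int(r.length_bp), mean_depth=float(r.mean_depth))
        for r in df.itertuples()
    ]


def write_depth_table(genes: Iterable[GeneCoverage], path: str | Path) -> None:
    pd.DataFrame(
        [(g.genome_id, g.gene_id, g.length_bp, g.mean_depth) for g in genes],
        columns=["genome_id", "gene_id", "length_bp", "mean_depth"],
    ).to_csv(path, sep="\t", index=False)


def step_relative_abundance(
    step_id: str,
    annotations: pd.DataFrame,
    genes: Sequence[GeneCoverage],
    step_map: Mapping[str, frozenset[str] | set[str]],
) -> float:
    """Relative abundance (%) of one cycling step from gene coverages.

    Coverage of genes winning annotation to any of the step's profiles,
    summed and normalized by the summed coverage of all genes.
    """
    if step_id not in step_map:
        raise ConfigError(f"unknown step id {step_id!r}")
    total = sum(g.mean_depth for g in genes)
    if total <= 0:
        raise ConfigError("zero total gene coverage")
    profiles = set(step_map[step_id])
    winners = annotations.loc[annotations["winning"] & annotations["profile_id"].isin(profiles)]
    step_genes = set(zip(winners["genome_id"], winners["protein_id"]))
    step_cov = sum(g.mean_depth for g in genes if (g.genome_id, g.gene_id) in step_genes)
    return 100.0 * step_cov / total
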