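"""Per-contig depth tables and per-genome breadth/abundance from alignments.

Alignments (SAM/BAM via pysam, or a plain TSV of intervals) are reduced to
0-based half-open aligned spans.  From those spans the module computes

* the MetaBAT2-style contig depth table — per contig and sample, the mean
  and population variance of per-base coverage, keeping only contigs of at
  least ``min_contig_len`` (1500 nt by default, the binning floor);
* per-genome horizontal coverage (breadth: the fraction of positions
  covered at least once), mean depth and the fraction of a sample's reads
  recruited by the genome;
* the prevalence-abundance summary: a genome counts as detected in a
  sample when its breadth is at least ``breadth_min`` (0.3 by default),
  prevalence is the number of samples detecting it, and cumulative
  abundance is the summed mapped-read percentage normalized by genome
  length.

Each aligned interval contributes once per base of its span; soft clips
and insertions fall outside the span.  Duplicate query ids within a sample
count once toward read recruitment but every alignment adds depth.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pysam

from .io_formats import ContigDepthTable, _open_text

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignmentInterval:
    """One aligned span on a contig or genome, 0-based half-open."""

    query_id: str
    target_id: str
    start: int
    end: int
    sample_id: str
    is_primary: bool = True
    mapq: int = 255

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"interval [{self.start}, {self.end}) on {self.target_id!r} is invalid"
            )


@dataclass(frozen=True)
class GenomeCoverage:
    """Breadth, mean depth and read recruitment of one genome in one sample."""

    genome_id: str
    sample_id: str
    breadth: float
    mean_depth: float
    mapped_read_fraction: float


@dataclass(frozen=True)
class PrevalenceAbundance:
    """Across-sample detection count and length-normalized abundance."""

    genome_id: str
    prevalence: int
    cumulative_abundance: float


def load_alignments(
    path,
    source_format: str = "auto",
    sample_id: str = "",
    mapq_min: int = 0,
    primary_only: bool = True,
) -> Iterator[AlignmentInterval]:
    """Stream filtered alignment intervals from SAM/BAM or a TSV.

    SAM/BAM coordinates are converted to 0-based half-open aligned spans
    (reference_start to reference_end); secondary and supplementary records
    are dropped when ``primary_only`` and records below ``mapq_min`` are
    skipped.  TSV input needs columns query_id, target_id, start, end.
    """
    path = Path(path)
    if source_format == "auto":
        ext = path.suffix.lower()
        source_format = {"": "tsv", ".tsv": "tsv", ".sam": "sam", ".bam": "bam"}.get(ext)
        if source_format is None:
            raise ValueError(f"cannot infer alignment format from {path}")
    if source_format in ("sam", "bam"):
        yield from _load_sam(path, source_format, sample_id, mapq_min, primary_only)
    elif source_format == "tsv":
        yield from _load_tsv(path, sample_id, mapq_min)
    else:
        raise ValueError(f"unknown alignment format {source_format!r}")


def _load_sam(path: Path, fmt: str, sample_id: str, mapq_min: int,
              primary_only: bool) -> Iterator[AlignmentInterval]:
    mode = "rb" if fmt == "bam" else "r"
    with pysam.AlignmentFile(str(path), mode) as af:
        lengths = dict(zip(af.references, af.lengths))
        for rec in af:
            if rec.is_unmapped:
                continue
            if primary_only and (rec.is_secondary or rec.is_supplementary):
                continue
            if rec.mapping_quality < mapq_min:
                continue
            target = rec.reference_name
            end = rec.reference_end
            tlen = lengths.get(target)
            if tlen is not None and end > tlen:
                raise ValueError(
                    f"{path}: alignment of {rec.query_name!r} ends at {end}, "
                    f"beyond length {tlen} of target {target!r}"
                )
            yield AlignmentInterval(
                query_id=rec.query_name,
                target_id=target,
                start=rec.reference_start,
                end=end,
                sample_id=sample_id,
                is_primary=True,
                mapq=rec.mapping_quality,
            )


def _load_tsv(path: Path, sample_id: str, mapq_min: int) -> Iterator[AlignmentInterval]:
    with _open_text(path) as handle:
        reader = csv.reader(handle, delimiter="\t")
        for row_no, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#") or row[0] == "query_id":
                continue
            if len(row) < 4:
                raise ValueError(f"{path}:{row_no}: expected >= 4 columns")
            mapq = int(row[4]) if len(row) > 4 else 255
            if mapq < mapq_min:
                continue
            yield AlignmentInterval(
                query_id=row[0], target_id=row[1],
                start=int(row[2]), end=int(row[3]),
                sample_id=sample_id, mapq=mapq,
            )


def write_alignment_tsv(intervals: Iterable[AlignmentInterval], path) -> None:
    with _open_text(path, "wt") as out:
        out.write("query_id\ttarget_id\tstart\tend\tmapq\n")
        for iv in intervals:
            out.write(f"{iv.query_id}\t{iv.target_id}\t{iv.start}\t{iv.end}\t{iv.mapq}\n")


class _CoverageAccumulator:
    """Difference-array per-base coverage for one target across samples."""

    def __init__(self, length: int, n_samples: int) -> None:
        self.length = length
        self.diff = np.zeros((n_samples, length + 1), dtype=np.int64)

    def add(self, sample_idx: int, start: int, end: int) -> None:
        if end > self.length:
            raise ValueError(f"interval end {end} beyond target length {self.length}")
        self.diff[sample_idx, start] += 1
        self.diff[sample_idx, end] -= 1

    def coverage(self) -> np.ndarray:
        return np.cumsum(self.diff[:, :-1], axis=1)


def contig_depth_table(
    alignments: Iterable[AlignmentInterval],
    contig_lengths: Mapping[str, int],
    sample_ids: Sequence[str],
    min_contig_len: int = 1500,
) -> ContigDepthTable:
    """Mean and population variance of per-base coverage per contig/sample.

    Contigs shorter than ``min_contig_len`` are excluded from the table
    (they are below the binning floor); contigs with no alignments keep
    zero rows.
    """
    sample_idx = {sid: i for i, sid in enumerate(sample_ids)}
    accs: dict[str, _CoverageAccumulator] = {}
    for iv in alignments:
        if iv.target_id not in contig_lengths:
            raise ValueError(f"alignment target {iv.target_id!r} not in contig_lengths")
        if iv.sample_id not in sample_idx:
            raise ValueError(f"alignment sample {iv.sample_id!r} not in sample_ids")
        acc = accs.get(iv.target_id)
        if acc is None:
            acc = accs[iv.target_id] = _CoverageAccumulator(
                contig_lengths[iv.target_id], len(sample_ids))
        acc.add(sample_idx[iv.sample_id], iv.start, iv.end)

    kept = [(c, L) for c, L in contig_lengths.items() if L >= min_contig_len]
    mean = np.zeros((len(kept), len(sample_ids)))
    var = np.zeros((len(kept), len(sample_ids)))
    for i, (contig, _L) in enumerate(kept):
        acc = accs.get(contig)
        if acc is None:
            continue
        cov = acc.coverage()
        mean[i] = cov.mean(axis=1)
        var[i] = cov.var(axis=1)  # population variance
    return ContigDepthTable(contigs=kept, sample_ids=list(sample_ids),
                            mean_depth=mean, depth_variance=var)


def genome_coverage(
    alignments: Iterable[AlignmentInterval],
    genome_lengths: Mapping[str, int],
    reads_per_sample: Mapping[str, int],
) -> list[GenomeCoverage]:
    """Breadth, mean depth and recruited-read fraction per (genome, sample).

    Genome coordinates are the concatenation of its contigs' positions;
    overlapping reads cover a position once for breadth.  Every (genome,
    sample) combination is reported, including undetected zeros.
    """
    for gid, L in genome_lengths.items():
        if L <= 0:
            raise ValueError(f"genome {gid!r} has non-positive length")
    for sid, n in reads_per_sample.items():
        if n <= 0:
            raise ValueError(f"sample {sid!r} has non-positive read count")
    samples = list(reads_per_sample)
    sample_idx = {sid: i for i, sid in enumerate(samples)}
    accs: dict[str, _CoverageAccumulator] = {}
    queries: dict[tuple[str, str], set[str]] = {}
    for iv in alignments:
        if iv.target_id not in genome_lengths:
            raise ValueError(f"alignment target {iv.target_id!r} not in genome_lengths")
        acc = accs.get(iv.target_id)
        if acc is None:
            acc = accs[iv.target_id] = _CoverageAccumulator(
                genome_lengths[iv.target_id], len(samples))
        acc.add(sample_idx[iv.sample_id], iv.start, iv.end)
        queries.setdefault((iv.target_id, iv.sample_id), set()).add(iv.query_id)

    out: list[GenomeCoverage] = []
    for gid, L in genome_lengths.items():
        acc = accs.get(gid)
        cov = acc.coverage() if acc is not None else None
        for sid in samples:
            if cov is None:
                breadth = depth = 0.0
            else:
                row = cov[sample_idx[sid]]
                breadth = float((row > 0).sum() / L)
                depth = float(row.sum() / L)
            n_reads = len(queries.get((gid, sid), ()))
            out.append(GenomeCoverage(
                genome_id=gid, sample_id=sid, breadth=breadth, mean_depth=depth,
                mapped_read_fraction=n_reads / reads_per_sample[sid],
            ))
    return out


def detect_genome(cov: GenomeCoverage, breadth_min: float = 0.3) -> bool:
    """A genome is detected in a sample when breadth >= breadth_min."""
    return cov.breadth >= breadth_min


def prevalence_abundance(
    covs: Iterable[GenomeCoverage],
    genome_lengths: Mapping[str, int],
    breadth_min: float = 0.3,
) -> list[PrevalenceAbundance]:
    """Detection count and summed length-normalized abundance per genome.

    cumulative_abundance = Σ over samples of (100 × mapped_read_fraction)
    divided by the genome length, i.e. percentage of mapped reads per base.
    """
    prev: dict[str, int] = {g: 0 for g in genome_lengths}
    abund: dict[str, float] = {g: 0.0 for g in genome_lengths}
    for cov in covs:
        if cov.genome_id not in genome_lengths:
            raise ValueError(f"coverage for unknown genome {cov.genome_id!r}")
        if detect_genome(cov, breadth_min):
            prev[cov.genome_id] += 1
        abund[cov.genome_id] += 100.0 * cov.mapped_read_fraction / genome_lengths[cov.genome_id]
    return [
        PrevalenceAbundance(genome_id=g, prevalence=prev[g], cumulative_abundance=abund[g])
        for g in genome_lengths
    ]


def write_genome_coverage_tsv(covs: Iterable[GenomeCoverage], path) -> None:
    with _open_text(path, "wt") as out:
        out.write("genome_id\tsample_id\tbreadth\tmean_depth\tmapped_read_fraction\n")
        for c in covs:
            out.write(f"{c.genome_id}\t{c.sample_id}\t{c.breadth:.10g}\t"
                      f"{c.mean_depth:.10g}\t{c.mapped_read_fraction:.10g}\n")


def write_prevalence_abundance_tsv(rows: Iterable[PrevalenceAbundance], path) -> None:
    with _open_text(path, "wt") as out:
        out.write("genome_id\tprevalence\tcumulative_abundance\n")
        for r in rows:
            out.write(f"{r.genome_id}\t{r.prevalence}\t{r.cumulative_abundance:.10g}\n")
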