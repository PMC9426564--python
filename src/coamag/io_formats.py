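"""Readers and writers for the on-disk formats the toolkit touches.

Formats covered: FASTA/FASTQ (plain or gzipped), sample manifests, square
distance-matrix TSVs, MetaBAT2-dialect contig depth tables, CheckM-style
quality TSVs and coassembly group manifests.  The depth-table layout copies
the ``jgi_summarize_bam_contig_depths`` column order so the file can be fed
to MetaBAT2 unchanged.
"""

from __future__ import annotations

import gzip
import logging
import os
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")

_FASTA_EXTS = (".fa", ".fasta", ".fna")
_FASTQ_EXTS = (".fq", ".fastq")


class FormatError(ValueError):
    """A file violates the syntactic contract of its format."""


class ConsistencyError(ValueError):
    """An in-memory object violates a cross-record consistency rule."""


@dataclass(frozen=True)
class SequenceRecord:
    """One sequence with optional per-base quality.

    Sequences are stored upper-case over the alphabet {A, C, G, T, N}.
    """

    seq_id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise FormatError(f"record {self.seq_id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise FormatError(
                f"record {self.seq_id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SampleRecord:
    """One metagenomic sample: a label plus its read file(s)."""

    sample_id: str
    read_paths: tuple[str, ...]
    read_count: int | None = None

    def __post_init__(self) -> None:
        sid = self.sample_id
        if not sid or any(c.isspace() for c in sid) or "/" in sid or "\\" in sid:
            raise ValueError(
                f"sample_id {sid!r} must be non-empty with no whitespace or path separators"
            )
        if not 1 <= len(self.read_paths) <= 2:
            raise ValueError(f"sample {sid!r}: expected 1 (single-end) or 2 (paired) read paths")
        if self.read_count is not None and self.read_count < 0:
            raise ValueError(f"sample {sid!r}: negative read_count")


@dataclass
class ContigDepthTable:
    """Per-contig mean depth and depth variance across samples (binning input)."""

    contigs: list[tuple[str, int]]
    sample_ids: list[str]
    mean_depth: np.ndarray       # shape (n_contigs, n_samples)
    depth_variance: np.ndarray   # shape (n_contigs, n_samples)

    def __post_init__(self) -> None:
        shape = (len(self.contigs), len(self.sample_ids))
        self.mean_depth = np.asarray(self.mean_depth, dtype=float).reshape(shape)
        self.depth_variance = np.asarray(self.depth_variance, dtype=float).reshape(shape)
        names = [c for c, _ in self.contigs]
        if len(set(names)) != len(names):
            raise ConsistencyError("duplicate contig names in depth table")

    @property
    def total_avg_depth(self) -> np.ndarray:
        return self.mean_depth.sum(axis=1)

    def equals(self, other: "ContigDepthTable", tol: float = 1e-9) -> bool:
        return (
            self.contigs == other.contigs
            and self.sample_ids == other.sample_ids
            and np.allclose(self.mean_depth, other.mean_depth, atol=tol)
            and np.allclose(self.depth_variance, other.depth_variance, atol=tol)
        )


def _open_text(path: str | os.PathLike, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if "r" in mode and not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    if path.suffix == ".gz":
        if "w" in mode:
            # fixed mtime/filename keep outputs byte-reproducible
            return gzip.open(path, mode, mtime=0)  # type: ignore[return-value]
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def _infer_format(path: Path) -> str:
    suffixes = path.suffixes
    if suffixes and suffixes[-1] == ".gz":
        suffixes = suffixes[:-1]
    ext = suffixes[-1].lower() if suffixes else ""
    if ext in _FASTA_EXTS:
        return "fasta"
    if ext in _FASTQ_EXTS:
        return "fastq"
    raise FormatError(f"cannot infer sequence format from extension of {path}")


def _check_alphabet(seq: str, line_no: int, path: Path) -> str:
    seq = seq.upper()
    if not _VALID_BASES.issuperset(seq):
        bad = sorted(set(seq) - _VALID_BASES)
        raise FormatError(f"{path}:{line_no}: invalid sequence characters {bad}")
    return seq


def read_sequences(path: str | os.PathLike, format: str = "auto") -> Iterator[SequenceRecord]:
    """Stream SequenceRecords from a FASTA or FASTQ file (gzip transparent).

    Records are yielded in file order with sequences upper-cased; characters
    outside {A, C, G, T, N} are rejected.  Malformed records raise
    :class:`FormatError` naming the offending line.
    """
    path = Path(path)
    if format == "auto":
        format = _infer_format(path)
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown sequence format {format!r}")
    with _open_text(path) as handle:
        if format == "fasta":
            yield from _parse_fasta(handle, path)
        else:
            yield from _parse_fastq(handle, path)


def _parse_fasta(handle: IO[str], path: Path) -> Iterator[SequenceRecord]:
    header: str | None = None
    header_line = 0
    chunks: list[str] = []
    line_no = 0
    for line_no, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                yield SequenceRecord(header, "".join(chunks))
            header = line[1:].split()[0] if line[1:].split() else ""
            if not header:
                raise FormatError(f"{path}:{line_no}: empty FASTA header")
            header_line = line_no
            chunks = []
        else:
            if header is None:
                raise FormatError(f"{path}:{line_no}: sequence data before first FASTA header")
            chunks.append(_check_alphabet(line, line_no, path))
    if header is not None:
        if not chunks:
            raise FormatError(f"{path}:{header_line}: FASTA record {header!r} has no sequence")
        yield SequenceRecord(header, "".join(chunks))


def _parse_fastq(handle: IO[str], path: Path) -> Iterator[SequenceRecord]:
    line_no = 0
    while True:
        lines = []
        for _ in range(4):
            raw = handle.readline()
            line_no += 1
            if raw == "":
                if not lines or (len(lines) == 1 and lines[0] == ""):
                    return
                raise FormatError(f"{path}:{line_no}: truncated FASTQ record")
            lines.append(raw.rstrip("\n"))
        head, seq, plus, qual = lines
        if not head.startswith("@"):
            raise FormatError(f"{path}:{line_no - 3}: FASTQ header must start with '@'")
        if not plus.startswith("+"):
            raise FormatError(f"{path}:{line_no - 1}: FASTQ separator line must start with '+'")
        seq_id = head[1:].split()[0] if head[1:].split() else ""
        if not seq_id:
            raise FormatError(f"{path}:{line_no - 3}: empty FASTQ header")
        seq = _check_alphabet(seq, line_no - 2, path)
        if len(qual) != len(seq):
            raise FormatError(
                f"{path}:{line_no}: quality length {len(qual)} != sequence length {len(seq)}"
            )
        yield SequenceRecord(seq_id, seq, qual)


def write_sequences(records: Iterable[SequenceRecord], path: str | os.PathLike,
                    format: str = "auto") -> None:
    """Write records as FASTA or FASTQ (gzip transparent, reproducible bytes)."""
    path = Path(path)
    if format == "auto":
        format = _infer_format(path)
    with _open_text(path, "wt") as out:
        for rec in records:
            if format == "fasta":
                out.write(f">{rec.seq_id}\n{rec.sequence}\n")
            else:
                qual = rec.quality if rec.quality is not None else "I" * len(rec)
                out.write(f"@{rec.seq_id}\n{rec.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# sample manifest


def read_sample_manifest(path: str | os.PathLike) -> list[SampleRecord]:
    """Read a TSV manifest: sample_id, path_r1 and optionally path_r2."""
    samples: list[SampleRecord] = []
    with _open_text(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "sample_id":  # optional header
                continue
            if len(parts) not in (2, 3):
                raise FormatError(
                    f"{path}:{line_no}: expected 2 or 3 tab-separated columns, got {len(parts)}"
                )
            samples.append(SampleRecord(parts[0], tuple(parts[1:])))
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ConsistencyError(f"duplicate sample_id in manifest {path}")
    return samples


def write_sample_manifest(samples: Iterable[SampleRecord], path: str | os.PathLike) -> None:
    with _open_text(path, "wt") as out:
        for s in samples:
            out.write("\t".join((s.sample_id, *s.read_paths)) + "\n")


# ---------------------------------------------------------------------------
# distance matrix


def write_distance_matrix(matrix, path: str | os.PathLike) -> None:
    """Write a square TSV with a header row and an index column of sample ids."""
    df = pd.DataFrame(matrix.values, index=matrix.sample_ids, columns=matrix.sample_ids)
    df.to_csv(path, sep="\t", float_format="%.10g", index_label="sample_id")


def read_distance_matrix(path: str | os.PathLike, metric_name: str = "ab_jaccard"):
    from .kmer_distance import DistanceMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: distance matrix row and column labels differ")
    return DistanceMatrix(
        sample_ids=[str(s) for s in df.index],
        values=df.to_numpy(dtype=float),
        metric_name=metric_name,
    )


# ---------------------------------------------------------------------------
# MetaBAT2-dialect depth table


def write_depth_table(table: ContigDepthTable, path: str | os.PathLike) -> None:
    """Write the depth table in the jgi_summarize_bam_contig_depths dialect.

    Columns: contigName, contigLen, totalAvgDepth, then per sample
    ``<sample_id>.bam`` and ``<sample_id>.bam-var``.  totalAvgDepth is the
    row sum of per-sample mean depths.
    """
    if not table.contigs:
        raise ConsistencyError("refusing to write an empty depth table")
    header = ["contigName", "contigLen", "totalAvgDepth"]
    for sid in table.sample_ids:
        header += [f"{sid}.bam", f"{sid}.bam-var"]
    totals = table.total_avg_depth
    with _open_text(path, "wt") as out:
        out.write("\t".join(header) + "\n")
        for i, (name, length) in enumerate(table.contigs):
            row = [name, str(length), _fmt(totals[i])]
            for j in range(len(table.sample_ids)):
                row += [_fmt(table.mean_depth[i, j]), _fmt(table.depth_variance[i, j])]
            out.write("\t".join(row) + "\n")


def _fmt(x: float) -> str:
    return format(float(x), ".10g")


def read_depth_table(path: str | os.PathLike) -> ContigDepthTable:
    df = pd.read_csv(path, sep="\t")
    expected = {"contigName", "contigLen", "totalAvgDepth"}
    if not expected.issubset(df.columns):
        raise FormatError(f"{path}: missing depth-table columns {expected - set(df.columns)}")
    sample_cols = [c for c in df.columns[3:] if not c.endswith("-var")]
    sample_ids = [c.removesuffix(".bam") for c in sample_cols]
    n = len(df)
    mean = np.zeros((n, len(sample_ids)))
    var = np.zeros((n, len(sample_ids)))
    for j, col in enumerate(sample_cols):
        mean[:, j] = df[col].to_numpy(dtype=float)
        var[:, j] = df[f"{col}-var"].to_numpy(dtype=float)
    contigs = list(zip(df["contigName"].astype(str), df["contigLen"].astype(int)))
    return ContigDepthTable(contigs=contigs, sample_ids=sample_ids,
                            mean_depth=mean, depth_variance=var)


# ---------------------------------------------------------------------------
# CheckM-style quality table


_QUALITY_COL_ALIASES = {
    "bin_id": {"bin_id", "bin id", "name", "genome"},
    "completeness": {"completeness"},
    "contamination": {"contamination"},
}


def read_quality_table(path: str | os.PathLike):
    """Read a CheckM-style TSV into a mapping bin_id -> GenomeQuality.

    Any TSV carrying bin-identifier, completeness and contamination columns
    (percent scale) is accepted; extra columns are ignored.  Out-of-range
    percentages are kept with a warning (CheckM contamination can exceed 100).
    """
    from .mag_quality_derep import GenomeQuality

    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        return {}
    cols: dict[str, str] = {}
    lowered = {c.lower().strip(): c for c in df.columns}
    for canon, aliases in _QUALITY_COL_ALIASES.items():
        for alias in aliases:
            if alias in lowered:
                cols[canon] = lowered[alias]
                break
        else:
            raise FormatError(f"{path}: missing required column {canon!r}")
    out = {}
    for _, row in df.iterrows():
        bin_id = str(row[cols["bin_id"]])
        comp = float(row[cols["completeness"]])
        cont = float(row[cols["contamination"]])
        if not 0 <= comp <= 100 or cont < 0:
            warnings.warn(
                f"{path}: bin {bin_id!r} has out-of-range quality "
                f"(completeness={comp}, contamination={cont}); row kept"
            )
            comp = min(max(comp, 0.0), 100.0)
            cont = max(cont, 0.0)
        elif cont > 100:
            warnings.warn(f"{path}: bin {bin_id!r} contamination {cont} > 100%; row kept")
        out[bin_id] = GenomeQuality(bin_id=bin_id, completeness=comp, contamination=cont)
    return out


# ---------------------------------------------------------------------------
# coassembly manifest


def write_coassembly_manifest(plan, path: str | os.PathLike) -> None:
    """Write `sample_id<TAB>group_id` rows sorted by group then sample."""
    rows = []
    for gid, members in plan.groups.items():
        rows += [(sid, gid) for sid in members]
    rows.sort(key=lambda r: (r[1], r[0]))
    with _open_text(path, "wt") as out:
        out.write("sample_id\tgroup_id\n")
        for sid, gid in rows:
            out.write(f"{sid}\t{gid}\n")


def read_coassembly_manifest(path: str | os.PathLike):
    from .coassembly_clustering import CoassemblyPlan

    groups: dict[int, list[str]] = {}
    with _open_text(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line == "sample_id\tgroup_id":
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{line_no}: expected 2 columns")
            groups.setdefault(int(parts[1]), []).append(parts[0])
    return CoassemblyPlan(groups=dict(sorted(groups.items())), source_k=len(groups))
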