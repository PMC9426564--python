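"""Bin quality classes and ANI-based dereplication of MAGs.

Quality classes follow the community-standard strict thresholds:
high quality (HQ) needs completeness > 90% and contamination < 5%;
medium quality (MQ) needs completeness > 50% and contamination < 10%;
everything else is low quality (LQ).  Only HQ and MQ bins count as MAGs
and only MAGs enter dereplication.

Dereplication links two MAGs when their estimated average nucleotide
identity (ANI) reaches a threshold t (0.95 ≈ species, 0.99 ≈ strain) over
more than ``af_min`` (default 60%) of the smaller genome's bases; clusters
are the connected components of that graph and each cluster's
representative maximizes completeness − 5 × contamination.

The ANI estimator is alignment-free: the smaller genome is tiled into
non-overlapping windows, each window's canonical k-mer containment j in
the other genome is converted to a per-window identity j**(1/k) (under an
i.i.d. substitution model a k-mer survives with probability (1−d)^k, so
the containment of a window at divergence d concentrates on (1−d)^k),
and ANI is the mean identity over mapped windows (containment at least
a small floor, so lone chance k-mer hits do not count as alignment).  The
aligned fraction is the mapped share of windows, measured on the smaller
genome.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io_formats import SequenceRecord
from .kmer_distance import count_kmers

logger = logging.getLogger(__name__)

QUALITY_CLASSES = ("HQ", "MQ", "LQ")


def classify_quality(completeness: float, contamination: float) -> str:
    """HQ / MQ / LQ from CheckM-style percentages (strict inequalities)."""
    if not 0 <= completeness <= 100:
        raise ValueError(f"completeness {completeness} outside [0, 100]")
    if contamination < 0:
        raise ValueError(f"negative contamination {contamination}")
    if completeness > 90 and contamination < 5:
        return "HQ"
    if completeness > 50 and contamination < 10:
        return "MQ"
    return "LQ"


@dataclass(frozen=True)
class GenomeQuality:
    """Completeness/contamination of one bin plus its derived class."""

    bin_id: str
    completeness: float
    contamination: float
    quality_class: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "quality_class", classify_quality(self.completeness, self.contamination)
        )

    @property
    def is_mag(self) -> bool:
        return self.quality_class in ("HQ", "MQ")


def score_genome(q: GenomeQuality) -> float:
    """Representative-selection score: completeness − 5 × contamination."""
    return q.completeness - 5.0 * q.contamination


@dataclass(frozen=True)
class AniEstimate:
    """Windowed-containment ANI between two genomes.

    ``aligned_fraction`` is the share of the smaller genome's windows with
    any k-mer evidence in the larger genome.
    """

    genome_a: str
    genome_b: str
    ani: float
    aligned_fraction: float


@dataclass
class DereplicationResult:
    """ANI-linked clusters of MAGs with one representative each."""

    threshold_t: float
    clusters: dict[int, list[str]]
    representatives: dict[int, str]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


Genome = Sequence[SequenceRecord]


def _genome_length(genome: Genome) -> int:
    return sum(len(rec) for rec in genome)


def _genome_kmer_set(genome: Genome, k: int) -> np.ndarray:
    profile = count_kmers(genome, k=k)
    return profile.codes  # sorted unique canonical codes


def _window_views(genome: Genome, window: int) -> list[str]:
    """Non-overlapping full tiles per contig; contigs shorter than one
    window contribute themselves as a single (shorter) window."""
    tiles: list[str] = []
    for rec in genome:
        seq = rec.sequence
        n_full = len(seq) // window
        for i in range(n_full):
            tiles.append(seq[i * window : (i + 1) * window])
        if n_full == 0:
            tiles.append(seq)
    return tiles


def _tile_code_sets(genome: Genome, window: int, k: int) -> list[np.ndarray]:
    return [count_kmers([tile], k=k).codes for tile in _window_views(genome, window)]


def _ani_from_codes(
    tile_codes: list[np.ndarray],
    ref_codes: np.ndarray,
    k: int,
    min_containment: float,
) -> tuple[float, float]:
    identities: list[float] = []
    mapped = 0
    for codes in tile_codes:
        if codes.size == 0:
            continue
        if ref_codes.size == 0:
            j = 0.0
        else:
            # ref_codes is sorted unique, so membership via binary search
            pos = np.minimum(np.searchsorted(ref_codes, codes), ref_codes.size - 1)
            j = float((ref_codes[pos] == codes).sum()) / codes.size
        if j >= min_containment and j > 0:
            mapped += 1
            identities.append(float(j ** (1.0 / k)))
    total = len(tile_codes)
    ani = float(np.mean(identities)) if identities else 0.0
    af = mapped / total if total else 0.0
    return ani, af


def estimate_ani(
    genome_a: Genome,
    genome_b: Genome,
    window: int = 1000,
    k: int = 16,
    min_containment: float = 0.01,
    ids: tuple[str, str] = ("a", "b"),
) -> AniEstimate:
    """Estimate ANI and aligned fraction between two genomes.

    The smaller genome is tiled into non-overlapping ``window``-bp windows;
    each window's canonical k-mer containment j in the other genome maps to
    identity j**(1/k).  Windows with j below ``min_containment`` are
    unmapped: a lone chance 16-mer hit (expected a few percent of windows
    against an unrelated 100-kb genome) is not alignment evidence, while
    genuine homology keeps j well above the floor for any divergence the
    substitution model allows (j >= 0.028 at 20%).  ANI is the mean
    identity over mapped windows (0 if none map).
    """
    if window < 2 * k:
        raise ValueError(f"window ({window}) must be at least 2k ({2 * k})")
    if not genome_a or not genome_b:
        raise ValueError("both genomes must be non-empty")
    la, lb = _genome_length(genome_a), _genome_length(genome_b)
    if la <= lb:
        query, ref = genome_a, genome_b
    else:
        query, ref = genome_b, genome_a
    ani, af = _ani_from_codes(
        _tile_code_sets(query, window, k), _genome_kmer_set(ref, k), k, min_containment
    )
    return AniEstimate(genome_a=ids[0], genome_b=ids[1], ani=ani, aligned_fraction=af)


def pairwise_ani(
    genomes: dict[str, Genome],
    window: int = 1000,
    k: int = 16,
    min_containment: float = 0.01,
) -> dict[tuple[str, str], AniEstimate]:
    """All-vs-all ANI with per-genome k-mer sets and window codes cached."""
    ids = list(genomes)
    lengths = {g: _genome_length(genomes[g]) for g in ids}
    ref_sets = {g: _genome_kmer_set(genomes[g], k) for g in ids}
    tile_sets = {g: _tile_code_sets(genomes[g], window, k) for g in ids}
    out: dict[tuple[str, str], AniEstimate] = {}
    for a, b in itertools.combinations(ids, 2):
        query, ref = (a, b) if lengths[a] <= lengths[b] else (b, a)
        ani, af = _ani_from_codes(tile_sets[query], ref_sets[ref], k, min_containment)
        out[(a, b)] = AniEstimate(genome_a=a, genome_b=b, ani=ani, aligned_fraction=af)
    return out


def dereplicate(
    mags: Iterable[tuple[str, Genome, GenomeQuality]],
    t: float,
    af_min: float = 0.6,
    window: int = 1000,
    k: int = 16,
    ani_estimates: dict[tuple[str, str], AniEstimate] | None = None,
) -> DereplicationResult:
    """Collapse near-identical MAGs at identity threshold t.

    An edge joins two MAGs when ani >= t and aligned_fraction > af_min;
    clusters are connected components.  Each cluster's representative is
    the member maximizing completeness − 5 × contamination (ties: larger
    total length, then lexicographically smaller bin id).  Pass
    ``ani_estimates`` (from :func:`pairwise_ani`) to dereplicate the same
    panel at several thresholds without re-estimating.
    """
    if not 0 < t < 1:
        raise ValueError(f"identity threshold t={t} outside (0, 1)")
    mags = list(mags)
    for bin_id, _genome, quality in mags:
        if not quality.is_mag:
            raise ValueError(
                f"bin {bin_id!r} is {quality.quality_class}; only HQ/MQ MAGs are dereplicated"
            )
    n = len(mags)
    ids = [m[0] for m in mags]
    if ani_estimates is None:
        ani_estimates = pairwise_ani({bid: genome for bid, genome, _q in mags},
                                     window=window, k=k)
    rows, cols = [], []
    for i, j in itertools.combinations(range(n), 2):
        est = ani_estimates.get((ids[i], ids[j])) or ani_estimates.get((ids[j], ids[i]))
        if est is None:
            raise ValueError(f"missing ANI estimate for pair ({ids[i]}, {ids[j]})")
        if est.ani >= t and est.aligned_fraction > af_min:
            rows += [i, j]
            cols += [j, i]
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)

    clusters: dict[int, list[str]] = {}
    members_by_comp: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        members_by_comp.setdefault(int(lab), []).append(idx)
    representatives: dict[int, str] = {}
    # number clusters 1..n_comp in order of first member appearance
    for cid, comp in enumerate(sorted(members_by_comp.values(), key=lambda m: m[0]), start=1):
        clusters[cid] = [ids[i] for i in comp]
        # highest score, then largest genome, then lexicographically smallest id
        best = min(
            comp,
            key=lambda i: (-score_genome(mags[i][2]), -_genome_length(mags[i][1]), ids[i]),
        )
        representatives[cid] = ids[best]
    return DereplicationResult(threshold_t=t, clusters=clusters,
                               representatives=representatives)
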