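"""Canonical k-mer counting and abundance-weighted metagenomic distances.

Samples are compared through their canonical k-mer abundance spectra, the
way Simka compares metagenomes: every length-k window of every read (over
{A, C, G, T}; windows containing N are skipped) increments the count of its
canonical form, the lexicographic minimum of the k-mer and its reverse
complement.  Two dissimilarities are provided on those spectra:

* ``ab_jaccard`` — abundance-weighted Jaccard (Ruzicka) dissimilarity,
  ``1 − Σ min(p_w, q_w) / Σ max(p_w, q_w)``.  This is a true metric
  (triangle inequality holds), which is why it is preferred for feeding a
  hierarchical clustering.
* ``bray_curtis`` — ``1 − 2 Σ min(p_w, q_w) / (Σ p + Σ q)``.  Bounded and
  symmetric but not a metric.

Counting is exact: k-mers are packed 2 bits per base into uint64 words
(k ≤ 31) and tallied with a single vectorized pass per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io_formats import SampleRecord, SequenceRecord, read_sequences

logger = logging.getLogger(__name__)

_METRICS = ("ab_jaccard", "bray_curtis")

# base -> 2-bit code; everything else (incl. N) -> 255, which poisons any
# window it falls in via the validity pass
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode_sequence(seq: str) -> np.ndarray:
    """Map a sequence string to uint8 codes (A,C,G,T -> 0..3, other -> 255)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_kmer(code: int, k: int) -> str:
    """Unpack a 2-bit-packed k-mer code back to its string."""
    bases = [(int(code) >> (2 * (k - 1 - i))) & 3 for i in range(k)]
    return "".join("ACGT"[b] for b in bases)


def encode_kmer(kmer: str) -> int:
    code = 0
    for b in kmer:
        code = (code << 2) | int(_CODE[ord(b)])
    return code


@dataclass
class KmerProfile:
    """Canonical k-mer abundance spectrum of one sample.

    ``codes`` holds the 2-bit-packed canonical k-mers, sorted ascending and
    unique; ``counts`` the matching abundances.  ``total`` is the count sum.
    """

    sample_id: str
    k: int
    codes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.uint64))
    counts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.codes.shape != self.counts.shape:
            raise ValueError("codes and counts must be congruent")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __len__(self) -> int:
        return len(self.codes)

    def as_dict(self) -> dict[str, int]:
        """Spectrum as {k-mer string: count} (for inspection and small tests)."""
        return {decode_kmer(c, self.k): int(n) for c, n in zip(self.codes, self.counts)}

    @classmethod
    def from_dict(cls, sample_id: str, k: int, counts: dict[str, int]) -> "KmerProfile":
        codes = np.array([encode_kmer(w) for w in counts], dtype=np.uint64)
        vals = np.array(list(counts.values()), dtype=np.int64)
        order = np.argsort(codes)
        return cls(sample_id=sample_id, k=k, codes=codes[order], counts=vals[order])


@dataclass
class DistanceMatrix:
    """Labelled symmetric pairwise metagenomic dissimilarities in [0, 1]."""

    sample_ids: list[str]
    values: np.ndarray
    metric_name: str = "ab_jaccard"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")

    def validate(self, atol: float = 1e-9) -> None:
        v = self.values
        if np.isnan(v).any():
            raise ValueError("distance matrix contains NaN")
        if not np.allclose(v, v.T, atol=atol):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=atol):
            raise ValueError("distance matrix diagonal is not zero")
        if v.min() < -atol or v.max() > 1 + atol:
            raise ValueError("distance values outside [0, 1]")

    @property
    def n(self) -> int:
        return len(self.sample_ids)


def _count_codes(encoded: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical k-mer codes + counts from a uint8 code array.

    ``encoded`` may contain 255 sentinels (N bases or read separators);
    windows touching one are dropped.  Horner accumulation over k shifted
    views packs forward and reverse-complement codes without materializing
    an (n_windows, k) matrix.
    """
    n_win = len(encoded) - k + 1
    if n_win <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    enc = encoded.astype(np.uint64)
    fwd = np.zeros(n_win, dtype=np.uint64)
    rev = np.zeros(n_win, dtype=np.uint64)
    valid = np.ones(n_win, dtype=bool)
    comp = np.uint64(3) - enc  # wraps on sentinels; masked below
    for j in range(k):
        window = enc[j : j + n_win]
        fwd = (fwd << np.uint64(2)) | (window & np.uint64(3))
        valid &= window <= np.uint64(3)
    for j in range(k - 1, -1, -1):
        rev = (rev << np.uint64(2)) | (comp[j : j + n_win] & np.uint64(3))
    canonical = np.minimum(fwd, rev)[valid]
    return np.unique(canonical, return_counts=True)


def count_kmers(
    records: Iterable[SequenceRecord | str],
    k: int,
    min_abundance: int = 1,
    sample_id: str = "",
) -> KmerProfile:
    """Count canonical k-mers over a read stream.

    Every length-k window over {A,C,G,T} contributes 1 to its canonical
    form; windows containing N are skipped; k-mers whose final count falls
    below ``min_abundance`` are removed before totalling.
    """
    if not 1 <= k <= 31:
        raise ValueError(f"k must be in [1, 31], got {k}")
    if min_abundance < 1:
        raise ValueError("min_abundance must be >= 1")
    # join reads on an N separator: the sentinel masks cross-read windows,
    # and one encoding pass beats per-read array juggling
    seqs = [rec.sequence if isinstance(rec, SequenceRecord) else rec for rec in records]
    n_reads = len(seqs)
    if not seqs:
        return KmerProfile(sample_id=sample_id, k=k)
    big = encode_sequence("N".join(seqs))
    codes, counts = _count_codes(big, k)
    if codes.size == 0 and n_reads:
        logger.warning("sample %r: no k-mers counted (k=%d exceeds every read length?)",
                       sample_id, k)
    if min_abundance > 1:
        keep = counts >= min_abundance
        codes, counts = codes[keep], counts[keep]
    return KmerProfile(sample_id=sample_id, k=k, codes=codes, counts=counts)


def _shared_min_sum(p: KmerProfile, q: KmerProfile) -> int:
    """Σ over shared k-mers of min(count_p, count_q)."""
    common, ip, iq = np.intersect1d(p.codes, q.codes, assume_unique=True,
                                    return_indices=True)
    if common.size == 0:
        return 0
    return int(np.minimum(p.counts[ip], q.counts[iq]).sum())


def _check_compatible(p: KmerProfile, q: KmerProfile) -> None:
    if p.k != q.k:
        raise ValueError(f"profiles have different k: {p.k} vs {q.k}")


def ab_jaccard_distance(p: KmerProfile, q: KmerProfile) -> float:
    """Abundance-weighted Jaccard dissimilarity 1 − Σmin / Σmax.

    Sums run over the union of k-mers (absent counts as 0); two empty
    profiles are at distance 0.  Unlike Bray-Curtis this dissimilarity
    satisfies the triangle inequality.
    """
    _check_compatible(p, q)
    smin = _shared_min_sum(p, q)
    smax = p.total + q.total - smin  # Σmax = Σp + Σq − Σmin over the union
    if smax == 0:
        return 0.0
    return 1.0 - smin / smax


def bray_curtis_distance(p: KmerProfile, q: KmerProfile) -> float:
    """Bray-Curtis dissimilarity 1 − 2 Σmin / (Σp + Σq); empty pair -> 0."""
    _check_compatible(p, q)
    denom = p.total + q.total
    if denom == 0:
        return 0.0
    return 1.0 - 2.0 * _shared_min_sum(p, q) / denom


_METRIC_FUNCS = {"ab_jaccard": ab_jaccard_distance, "bray_curtis": bray_curtis_distance}


def profile_sample(sample: SampleRecord, k: int, min_abundance: int = 1) -> KmerProfile:
    """Count one sample's k-mers, pooling both mates of a paired sample."""

    def stream():
        for path in sample.read_paths:
            yield from read_sequences(path)

    try:
        return count_kmers(stream(), k=k, min_abundance=min_abundance,
                           sample_id=sample.sample_id)
    except (OSError, ValueError) as exc:
        raise type(exc)(f"sample {sample.sample_id!r}: {exc}") from exc


def distances_from_profiles(profiles: Sequence[KmerProfile],
                            metric: str = "ab_jaccard") -> DistanceMatrix:
    """Pairwise dissimilarity matrix over already-counted profiles."""
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {_METRICS}")
    if len(profiles) < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    func = _METRIC_FUNCS[metric]
    n = len(profiles)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = func(profiles[i], profiles[j])
            values[i, j] = values[j, i] = d
    matrix = DistanceMatrix(sample_ids=[p.sample_id for p in profiles],
                            values=values, metric_name=metric)
    matrix.validate()
    return matrix


def pairwise_distances(
    samples: Sequence[SampleRecord],
    k: int = 21,
    metric: str = "ab_jaccard",
    min_abundance: int = 1,
) -> DistanceMatrix:
    """Count k-mers for every sample and return the pairwise distance matrix.

    Sample order is preserved from the input manifest.  Any unreadable
    sample aborts the whole computation with an error naming it.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    profiles = [profile_sample(s, k=k, min_abundance=min_abundance) for s in samples]
    return distances_from_profiles(profiles, metric=metric)
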