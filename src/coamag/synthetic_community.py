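"""Synthetic multi-sample communities with planted ground truth.

The generator emulates what a CAMISIM-style community simulation provides
at desk scale: i.i.d. random genomes, per-sample genome abundances drawn
from a log-normal distribution (location μ = 1, scale σ = 2 on the natural
log, the conventional defaults), uniformly positioned substitution-error
reads with recorded origins, planted sample-group structure (disjoint
genome pools per group so within-group k-mer distances are small and
between-group distances large), and mutated genome copies at controlled
divergence for ANI/dereplication tests.

Everything is a pure function of its seed: the same spec and seed yield
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .io_formats import SampleRecord, SequenceRecord, write_sequences

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G on 2-bit codes


@dataclass(frozen=True)
class CommunitySpec:
    """Study conditions for one synthetic clustered dataset.

    Defaults are the desk-scale conditions: 12 samples in 3 groups,
    2 × 10⁴ reads of 150 bp per sample (≈ 3 Mb), 100-kb genomes, and the
    log-normal abundance parameters μ = 1, σ = 2.  ``sample_sigma`` is the
    per-sample log-scale jitter around a group's base abundance profile:
    samples of the same group are correlated resamplings of one community,
    the way related metagenomes (a time series, one habitat) are.
    """

    n_genomes: int = 12
    genome_length: int = 100_000
    mu: float = 1.0
    sigma: float = 2.0
    n_samples: int = 12
    n_groups: int = 3
    reads_per_sample: int = 20_000
    read_length: int = 150
    error_rate: float = 0.001
    sample_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups > self.n_samples:
            raise ValueError("n_groups cannot exceed n_samples")
        if self.n_groups > self.n_genomes:
            raise ValueError("need at least one genome per group")
        for name in ("n_genomes", "genome_length", "n_samples", "n_groups",
                     "reads_per_sample", "read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.error_rate < 0.25:
            raise ValueError("error_rate must be in [0, 0.25)")
        if self.sample_sigma < 0:
            raise ValueError("sample_sigma must be non-negative")
        if self.read_length > self.genome_length:
            raise ValueError("read_length cannot exceed genome_length")


@dataclass
class PlantedTruth:
    """Ground truth of a generated dataset, sufficient to score recovery."""

    sample_group: dict[str, int]
    genome_abundances: dict[tuple[str, str], float]  # (sample_id, genome_id) -> rel. abundance
    read_origin: dict[str, str] = field(default_factory=dict)  # read_id -> genome_id

    def group_labels(self, sample_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.sample_group[s] for s in sample_ids])


class MutationResult(NamedTuple):
    record: SequenceRecord
    n_substitutions: int


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def generate_genome(length: int, gc: float = 0.5, seed: int = 0,
                    seq_id: str | None = None) -> SequenceRecord:
    """I.i.d. random genome with P(G) + P(C) = gc; deterministic per seed."""
    if length < 1000:
        raise ValueError("genome length must be at least 1000")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    if seq_id is None:
        seq_id = f"genome_seed{seed}"
    return SequenceRecord(seq_id=seq_id, sequence=_codes_to_str(codes))


def mutate_genome(genome: SequenceRecord, divergence: float, seed: int = 0,
                  seq_id: str | None = None) -> MutationResult:
    """Substitute each base with probability ``divergence`` (uniform over
    the three other bases); returns the mutant and the realized count."""
    if not 0 <= divergence <= 0.2:
        raise ValueError("divergence must be in [0, 0.2]")
    rng = np.random.default_rng(seed)
    codes = np.frombuffer(genome.sequence.encode("ascii"), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    codes = lut[codes]
    hit = rng.random(len(codes)) < divergence
    # shift by 1..3 mod 4 -> always a different base
    shifts = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
    codes = codes.copy()
    codes[hit] = (codes[hit] + shifts) % 4
    if seq_id is None:
        seq_id = f"{genome.seq_id}_mut{divergence:g}_s{seed}"
    return MutationResult(
        record=SequenceRecord(seq_id=seq_id, sequence=_codes_to_str(codes)),
        n_substitutions=int(hit.sum()),
    )


def draw_lognormal_abundances(n_genomes: int, mu: float = 1.0, sigma: float = 2.0,
                              rng: np.random.Generator | None = None,
                              seed: int | None = None) -> np.ndarray:
    """Raw (un-normalized) log-normal abundance draws."""
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    return rng.lognormal(mean=mu, sigma=sigma, size=n_genomes)


def sample_abundances(n_genomes: int, mu: float = 1.0, sigma: float = 2.0,
                      seed: int | None = None,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Normalized log-normal relative abundances (sum to 1)."""
    raw = draw_lognormal_abundances(n_genomes, mu=mu, sigma=sigma, rng=rng, seed=seed)
    return raw / raw.sum()


def simulate_reads(
    genomes: Sequence[SequenceRecord],
    abundances: Sequence[float],
    n_reads: int,
    read_length: int,
    error_rate: float = 0.0,
    seed: int = 0,
    read_prefix: str = "read",
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Simulate substitution-error reads; returns (records, read_origin).

    Source genomes are drawn with probability proportional to
    abundance × genome length (longer genomes shed more reads at equal
    cellular abundance); positions and strands are uniform; substitution
    errors hit each base independently at ``error_rate``.  Quality strings
    are a fixed 'I' per base.
    """
    abundances = np.asarray(abundances, dtype=float)
    if len(genomes) != len(abundances):
        raise ValueError("genomes and abundances must be congruent")
    lengths = np.array([len(g) for g in genomes])
    if (lengths < read_length).any():
        raise ValueError("read_length exceeds a genome length")
    rng = np.random.default_rng(seed)
    weights = abundances * lengths
    weights = weights / weights.sum()

    origin_idx = rng.choice(len(genomes), size=n_reads, p=weights)
    starts = (rng.random(n_reads) * (lengths[origin_idx] - read_length + 1)).astype(np.int64)
    strands = rng.integers(0, 2, size=n_reads)

    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    genome_codes = [lut[np.frombuffer(g.sequence.encode("ascii"), dtype=np.uint8)]
                    for g in genomes]

    mat = np.empty((n_reads, read_length), dtype=np.uint8)
    offsets = np.arange(read_length)
    for gi, codes in enumerate(genome_codes):
        mask = origin_idx == gi
        if not mask.any():
            continue
        mat[mask] = codes[starts[mask, None] + offsets[None, :]]
    rev = strands == 1
    mat[rev] = _COMPLEMENT[mat[rev][:, ::-1]]
    if error_rate > 0:
        hit = rng.random(mat.shape) < error_rate
        shifts = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
        mat[hit] = (mat[hit] + shifts) % 4

    qual = "I" * read_length
    records: list[SequenceRecord] = []
    read_origin: dict[str, str] = {}
    seqs = _BASES[mat].tobytes().decode("ascii")
    for i in range(n_reads):
        rid = f"{read_prefix}_{i}"
        seq = seqs[i * read_length : (i + 1) * read_length]
        records.append(SequenceRecord(seq_id=rid, sequence=seq, quality=qual))
        read_origin[rid] = genomes[origin_idx[i]].seq_id
    return records, read_origin


def generate_clustered_dataset(
    spec: CommunitySpec,
    out_dir: str | Path | None = None,
) -> tuple[list[SampleRecord] | dict[str, list[SequenceRecord]], PlantedTruth]:
    """Multi-sample dataset with planted group structure.

    Genomes are split into ``n_groups`` disjoint pools.  Each group draws
    one base log-normal(μ, σ) abundance profile over its pool; each sample
    of the group resamples that profile with log-normal(0, sample_sigma)
    jitter.  Within-group k-mer distances are therefore small while
    between-group distances sit near 1 (disjoint pools share no genomes).
    When ``out_dir`` is given, per-sample FASTQ files are written and
    SampleRecords returned; otherwise the reads stay in memory as
    {sample_id: records}.
    """
    root = np.random.default_rng(spec.seed)
    # independent child seeds (kept below 2**31 for portability)
    genome_seeds = root.integers(0, 2**31 - 1, size=spec.n_genomes)
    genomes = [
        generate_genome(spec.genome_length, gc=0.5, seed=int(genome_seeds[i]),
                        seq_id=f"genome_{i:03d}")
        for i in range(spec.n_genomes)
    ]
    pools = [list(range(g, spec.n_genomes, spec.n_groups)) for g in range(spec.n_groups)]
    group_of_sample = [s % spec.n_groups for s in range(spec.n_samples)]
    base_profiles = [
        draw_lognormal_abundances(
            len(pools[g]), mu=spec.mu, sigma=spec.sigma,
            rng=np.random.default_rng(np.random.SeedSequence([spec.seed, 104729, g])))
        for g in range(spec.n_groups)
    ]

    truth = PlantedTruth(sample_group={}, genome_abundances={})
    per_sample: dict[str, list[SequenceRecord]] = {}
    sample_ids = [f"sample_{s:03d}" for s in range(spec.n_samples)]
    for s, sid in enumerate(sample_ids):
        group = group_of_sample[s]
        pool = pools[group]
        srng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, 7919, s])
        )
        raw = base_profiles[group] * srng.lognormal(0.0, spec.sample_sigma, len(pool))
        ab = raw / raw.sum()
        reads, origin = simulate_reads(
            [genomes[i] for i in pool], ab,
            n_reads=spec.reads_per_sample, read_length=spec.read_length,
            error_rate=spec.error_rate,
            seed=int(srng.integers(0, 2**31 - 1)),
            read_prefix=sid,
        )
        truth.sample_group[sid] = group
        for gi, a in zip(pool, ab):
            truth.genome_abundances[(sid, genomes[gi].seq_id)] = float(a)
        truth.read_origin.update(origin)
        per_sample[sid] = reads

    if out_dir is None:
        return per_sample, truth

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples: list[SampleRecord] = []
    for sid in sample_ids:
        path = out_dir / f"{sid}.fastq"
        write_sequences(per_sample[sid], path, format="fastq")
        samples.append(SampleRecord(sample_id=sid, read_paths=(str(path),),
                                    read_count=spec.reads_per_sample))
    write_sequences(genomes, out_dir / "genomes.fasta", format="fasta")
    _write_truth(truth, out_dir)
    return samples, truth


def _write_truth(truth: PlantedTruth, out_dir: Path) -> None:
    with open(out_dir / "truth_groups.tsv", "w") as out:
        out.write("sample_id\tgroup\n")
        for sid, g in sorted(truth.sample_group.items()):
            out.write(f"{sid}\t{g}\n")
    with open(out_dir / "truth_abundances.tsv", "w") as out:
        out.write("sample_id\tgenome_id\tabundance\n")
        for (sid, gid), a in sorted(truth.genome_abundances.items()):
            out.write(f"{sid}\t{gid}\t{a:.10g}\n")
    with open(out_dir / "truth_origin.tsv", "w") as out:
        out.write("read_id\tgenome_id\n")
        for rid, gid in truth.read_origin.items():
            out.write(f"{rid}\t{gid}\n")


def strain_panel(
    n_species: int = 5,
    n_strains: int = 3,
    genome_length: int = 100_000,
    intra_pair_divergence: tuple[float, float] = (0.01, 0.03),
    seed: int = 0,
) -> list[tuple[str, list[SequenceRecord]]]:
    """Panel of species × strains at controlled divergence for ANI tests.

    Each species is an independent random genome (inter-species identity is
    chance level, divergence far above 10%); its strains are mutated copies
    at per-strain rates drawn so that any two strains of the same species
    differ by a pairwise divergence inside ``intra_pair_divergence``.
    """
    rng = np.random.default_rng(seed)
    lo, hi = intra_pair_divergence
    panel: list[tuple[str, list[SequenceRecord]]] = []
    for sp in range(n_species):
        ancestor = generate_genome(genome_length, seed=int(rng.integers(0, 2**31 - 1)),
                                   seq_id=f"sp{sp}")
        # each strain diverges from the ancestor at rate in [lo/2, hi/2],
        # so strain-strain divergence is approximately in [lo, hi]
        for st in range(n_strains):
            rate = float(rng.uniform(lo / 2, hi / 2))
            mutant, _ = mutate_genome(ancestor, rate,
                                      seed=int(rng.integers(0, 2**31 - 1)),
                                      seq_id=f"sp{sp}_st{st}")
            panel.append((mutant.seq_id, [mutant]))
    return panel
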