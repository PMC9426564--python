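import numpy as np
import pytest

from coamag.kmer_distance import KmerProfile


def random_profile(rng: np.random.Generator, k: int = 5, max_kmers: int = 12,
                   sample_id: str = "s") -> KmerProfile:
    """Random small k-mer profile built through the public constructor."""
    n = int(rng.integers(1, max_kmers + 1))
    kmers = set()
    while len(kmers) < n:
        kmers.add("".join(rng.choice(list("ACGT"), size=k)))
    # canonicalize by hand so the dict keys obey the profile invariant
    canon = {}
    comp = str.maketrans("ACGT", "TGCA")
    for w in kmers:
        rc = w.translate(comp)[::-1]
        key = min(w, rc)
        canon[key] = canon.get(key, 0) + int(rng.integers(1, 20))
    return KmerProfile.from_dict(sample_id, k, canon)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tmp_fasta(tmp_path):
    def _write(text: str, name: str = "seqs.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write
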