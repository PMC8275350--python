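import numpy as np
import pytest
from hypothesis import settings

from cdbg.synthetic import inject_n_runs, insert_palindromes, random_genome

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

#: The small two-reference collection used as the worked example
#: throughout: it exercises sentinels, a crossing loop (the palindromic
#: 4-mer CATG), orientation flips and cross-reference sharing at k=3.
TOY_INPUT = ["CGACATGTCTTAG", "GCTCTTAG"]
TOY_K = 3
TOY_UNITIGS = {"CGA", "ATGTC", "CTAAGA", "GAGC"}


@pytest.fixture
def toy():
    return list(TOY_INPUT)


def random_collection(seed: int, k: int, total_length: int = 2000):
    """A seeded multi-sequence fixture with N runs and crossing loops."""
    rng = np.random.default_rng(seed)
    n_seqs = int(rng.integers(1, 6))
    seqs = []
    remaining = total_length
    for i in range(n_seqs):
        length = int(rng.integers(k, max(k + 1, remaining // (n_seqs - i) + 1)))
        g = random_genome(length, rng)
        g = insert_palindromes(g, k, int(rng.integers(0, 4)), rng)
        if rng.random() < 0.5:
            g = inject_n_runs(g, 0.02, rng)
        seqs.append(g)
        remaining -= length
    return seqs
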