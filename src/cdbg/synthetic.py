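"""Deterministic synthetic genomes emulating the tool's input regimes.

Two regimes are modelled: a single random genome, and a "colored"
collection — one base genome plus closely related variants derived by
point substitutions, short (1–3 bp) indels, and optional runs of N that
break sequences into valid runs. Base composition is uniform; the
algorithm is composition-agnostic, so GC skew is deliberately not
modelled. All output is fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

_BASES = np.array(list("ACGT"))
_OTHER = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic reference collection.

    Defaults model a small collection of genomes of related strains:
    ~1% substitution divergence, an order of magnitude fewer indels, and
    sparse assembly-gap N runs.
    """

    base_length: int = 5000
    n_references: int = 5
    snp_rate: float = 0.01
    indel_rate: float = 0.001
    n_run_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("snp_rate", "indel_rate", "n_run_rate"):
            rate = getattr(self, name)
            if not 0 <= rate < 1:
                raise ValueError(f"{name} must be in [0, 1), got {rate}")
        if self.base_length < 1 or self.n_references < 1:
            raise ValueError("base_length and n_references must be positive")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def random_genome(length: int, seed) -> str:
    """Uniform i.i.d. ACGT string of the given length."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = _rng(seed)
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def mutate(reference: str, snp_rate: float, indel_rate: float, seed) -> str:
    """Derived haplotype: per-position substitutions and short indels.

    Each position independently substitutes to a different base with
    probability ``snp_rate``; with probability ``indel_rate`` a 1–3 bp
    insertion or deletion (equally likely) is applied at the position.
    """
    rng = _rng(seed)
    out: list[str] = []
    i = 0
    while i < len(reference):
        if indel_rate > 0 and rng.random() < indel_rate:
            size = int(rng.integers(1, 4))
            if rng.random() < 0.5:
                out.append("".join(_BASES[rng.integers(0, 4, size=size)]))
                # insertion: the current base is still consumed below
            else:
                i += size  # deletion
                continue
        base = reference[i]
        if snp_rate > 0 and rng.random() < snp_rate:
            base = _OTHER[base][int(rng.integers(0, 3))]
        out.append(base)
        i += 1
    return "".join(out)


def inject_n_runs(sequence: str, rate: float, seed) -> str:
    """Replace random stretches (1–10 bp) with N at the given per-base rate."""
    if rate == 0:
        return sequence
    rng = _rng(seed)
    chars = list(sequence)
    i = 0
    while i < len(chars):
        if rng.random() < rate:
            size = int(rng.integers(1, 11))
            for j in range(i, min(i + size, len(chars))):
                chars[j] = "N"
            i += size
        else:
            i += 1
    return "".join(chars)


def insert_palindromes(sequence: str, k: int, count: int, seed) -> str:
    """Splice ``count`` palindromic (k+1)-mers into the sequence.

    A palindromic (k+1)-mer (w followed by its reverse complement, with
    |w| = (k+1)/2) induces a crossing loop — an edge incident twice to
    one side of a vertex — exercising the hardest orientation case.
    """
    rng = _rng(seed)
    rc = str.maketrans("ACGT", "TGCA")
    chars = sequence
    for _ in range(count):
        w = "".join(_BASES[rng.integers(0, 4, size=(k + 1) // 2)])
        pal = w + w.translate(rc)[::-1]
        pos = int(rng.integers(0, len(chars) + 1))
        chars = chars[:pos] + pal + chars[pos:]
    return chars


def make_collection(spec: FixtureSpec) -> list[tuple[str, str]]:
    """Generate a reference collection as ``(id, sequence)`` pairs."""
    rng = np.random.default_rng(spec.seed)
    base = random_genome(spec.base_length, rng)
    records = [("ref_0", inject_n_runs(base, spec.n_run_rate, rng))]
    for i in range(1, spec.n_references):
        mut = mutate(base, spec.snp_rate, spec.indel_rate, rng)
        records.append((f"ref_{i}", inject_n_runs(mut, spec.n_run_rate, rng)))
    return records


def write_collection(spec: FixtureSpec, path: str | Path) -> Path:
    """Write the collection as a multi-record FASTA file."""
    path = Path(path)
    with open(path, "wt") as fh:
        for rid, seq in make_collection(spec):
            fh.write(f">{rid} synthetic\n{seq}\n")
    return path
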