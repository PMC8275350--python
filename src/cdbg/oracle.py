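"""Ground truth: an explicit-adjacency compactor, and the output validator.

The naive compactor builds the bidirected graph's full adjacency
explicitly from every (k+1)-mer instance — the formulation the automaton
pipeline deliberately avoids — and enumerates maximal unitigs by path
walking. It is written independently of the automaton code path (its own
orientation and classification logic throughout) so that agreement with
the main pipeline on random inputs is meaningful evidence of correctness.

The validator checks the two defining properties of a correct compaction:
(i) node decomposition — every distinct canonical k-mer of the input
occurs in exactly one output unitig, exactly once — and (ii) every input
run is reconstructible as a tiling of complete oriented unitigs with
(k-1)-overlaps.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .walker import split_valid_runs

_RC = str.maketrans("ACGT", "TGCA")


def _rc(s: str) -> str:
    return s.translate(_RC)[::-1]


def _canon(s: str) -> str:
    r = _rc(s)
    return s if s <= r else r


_FRONT, _BACK = 0, 1


class _SideInfo:
    """Incidence summary of one vertex side."""

    __slots__ = ("chars", "eps", "double")

    def __init__(self) -> None:
        self.chars: set[str] = set()   # distinct incident edge characters
        self.eps = False               # boundary sentinel incident
        self.double = False            # a crossing loop incident twice here

    @property
    def unique(self) -> bool:
        return not self.eps and not self.double and len(self.chars) == 1


def _build_adjacency(runs, k) -> dict[str, tuple[_SideInfo, _SideInfo]]:
    adj: dict[str, tuple[_SideInfo, _SideInfo]] = {}

    def info(v: str) -> tuple[_SideInfo, _SideInfo]:
        if v not in adj:
            adj[v] = (_SideInfo(), _SideInfo())
        return adj[v]

    def record(v: str, side: int, char: str) -> None:
        info(v)[side].chars.add(char)

    for run in runs:
        t = run.text
        # register every vertex, then the sentinel sides of the run ends
        for i in range(len(t) - k + 1):
            info(_canon(t[i:i + k]))
        first, last = t[:k], t[len(t) - k:]
        # side with no entering edge: front if the instance is canonical
        info(_canon(first))[_FRONT if first <= _rc(first) else _BACK].eps = True
        # side with no exiting edge: back if the instance is canonical
        info(_canon(last))[_BACK if last <= _rc(last) else _FRONT].eps = True
        for i in range(len(t) - k):
            e = t[i:i + k + 1]
            pre, suf = e[:-1], e[1:]
            if e == _rc(e):
                # crossing loop: both endpoints are the same (vertex, side)
                v = _canon(suf)
                side = _FRONT if suf <= _rc(suf) else _BACK
                s = info(v)[side]
                s.double = True
                oriented = e if side == _FRONT else _rc(e)
                s.chars.add(oriented[0] if side == _FRONT else oriented[-1])
                continue
            # endpoint at the k-prefix: back side iff the prefix is canonical
            u = _canon(pre)
            if pre <= _rc(pre):
                record(u, _BACK, e[-1])          # edge reads label + d
            else:
                record(u, _FRONT, _rc(e)[0])     # edge reads c + label
            # endpoint at the k-suffix: front side iff the suffix is canonical
            v = _canon(suf)
            if suf <= _rc(suf):
                record(v, _FRONT, e[0])
            else:
                record(v, _BACK, _rc(e)[-1])
    return adj


def _neighbor(v: str, exit_side: int, char: str, k: int) -> tuple[str, int]:
    """Other endpoint of the unique edge leaving (v, exit_side)."""
    if exit_side == _BACK:
        e = v + char
        nxt = e[1:]
        side = _FRONT if nxt <= _rc(nxt) else _BACK
    else:
        e = char + v
        nxt = e[:-1]
        side = _BACK if nxt <= _rc(nxt) else _FRONT
    return _canon(nxt), side


def naive_compact(sequences: Iterable[str], k: int) -> set[str]:
    """Canonical spellings of all maximal unitigs, by explicit adjacency."""
    runs = [r for s in sequences for r in split_valid_runs(s, k)]
    adj = _build_adjacency(runs, k)
    if not adj:
        return set()

    unitigs: set[str] = set()
    covered: set[str] = set()

    for v in sorted(adj):
        for free_side in (_FRONT, _BACK):
            side = adj[v][free_side]
            if side.unique:
                u, su = _neighbor(v, free_side, next(iter(side.chars)), k)
                if adj[u][su].unique:
                    continue  # extendable through the free side: not a start
            spelling = _walk(adj, v, free_side, k)
            unitigs.add(_canon(spelling))
            for i in range(len(spelling) - k + 1):
                covered.add(_canon(spelling[i:i + k]))

    if covered != set(adj):
        raise RuntimeError(
            "vertices left uncovered by flanking-anchored walks "
            "(a cycle with no boundary, impossible for linear input)"
        )
    return unitigs


def _walk(adj, v0: str, free_side: int, k: int) -> str:
    exit_side = _BACK if free_side == _FRONT else _FRONT
    spelling = v0 if exit_side == _BACK else _rc(v0)
    v, t = v0, exit_side
    in_path = {v0}
    while True:
        side = adj[v][t]
        if not side.unique:
            return spelling
        u, su = _neighbor(v, t, next(iter(side.chars)), k)
        if not adj[u][su].unique:
            return spelling
        if u in in_path:
            raise RuntimeError("unitig walk revisited a vertex")
        in_path.add(u)
        seen = u if su == _FRONT else _rc(u)
        assert spelling[-(k - 1):] == seen[:k - 1]
        spelling = spelling + seen[k - 1:]
        v, t = u, (_BACK if su == _FRONT else _FRONT)


@dataclass
class ValidationReport:
    """Outcome of the two compaction checks, with human-readable notes."""

    node_decomposition: bool
    reconstructible: bool
    diagnostics: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.node_decomposition and self.reconstructible


def validate(sequences: Iterable[str], unitigs: Iterable[str], k: int) -> ValidationReport:
    """Check a claimed unitig set against the input it was built from."""
    sequences = list(sequences)
    unitigs = list(unitigs)
    runs = [r for s in sequences for r in split_valid_runs(s, k)]
    input_kmers = {
        _canon(r.text[i:i + k]) for r in runs for i in range(len(r.text) - k + 1)
    }

    diagnostics: list[str] = []

    counts: Counter[str] = Counter()
    for u in unitigs:
        for i in range(len(u) - k + 1):
            counts[_canon(u[i:i + k])] += 1
    missing = input_kmers - set(counts)
    extra = set(counts) - input_kmers
    repeated = {x for x, c in counts.items() if c > 1}
    node_decomposition = not (missing or extra or repeated)
    if missing:
        diagnostics.append(f"{len(missing)} input k-mer(s) absent from the unitigs")
    if extra:
        diagnostics.append(f"{len(extra)} unitig k-mer(s) absent from the input")
    if repeated:
        diagnostics.append(f"{len(repeated)} k-mer(s) occur more than once in the unitigs")

    by_prefix: dict[str, list[str]] = {}
    for u in unitigs:
        for o in {u, _rc(u)}:
            by_prefix.setdefault(o[:k], []).append(o)
    reconstructible = True
    for r in runs:
        if not _tilable(r.text, by_prefix, k):
            reconstructible = False
            diagnostics.append(f"run {r.seq_id}:{r.start}-{r.end} is not a tiling of the unitigs")

    return ValidationReport(node_decomposition, reconstructible, diagnostics)


def _tilable(text: str, by_prefix: dict[str, list[str]], k: int) -> bool:
    """Can ``text`` be covered by oriented unitigs with (k-1)-overlaps?

    ``ok[p]`` — the suffix starting at p is coverable by tiles whose
    first one starts exactly at p; successive tiles overlap by k-1, so a
    tile ending at ``end`` hands over at position ``end - (k-1)``.
    Computed right-to-left (tile length >= k > k-1 makes this acyclic).
    """
    n = len(text)
    ok = [False] * (n + 1)
    for p in range(n - k, -1, -1):
        for o in by_prefix.get(text[p:p + k], []):
            if text.startswith(o, p):
                end = p + len(o)
                if end == n or ok[end - (k - 1)]:
                    ok[p] = True
                    break
    return ok[0]
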