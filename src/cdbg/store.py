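"""Associative state storage over the static canonical k-mer set.

The vertex set of the graph is static once the input has been scanned, so
states live in a keyless table addressed through a minimal perfect index:
a bijection from the n canonical k-mers onto [0, n). Here the index is a
sorted array with binary search — minimal and perfect by construction;
callers must never query k-mers outside the set (the static-key
contract), and doing so raises.

Per vertex the table holds a fixed-width 5-bit state code (26 states need
ceil(log2 26) = 5 bits) in a bit-packed array, plus a separate 1-bit
"already emitted" flag used by the unitig extractor — 6 bits per vertex,
independent of k and n.
"""

from __future__ import annotations

import struct
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .automaton import SIDE_STATUSES, UNVISITED, VertexState, transition
from .kmers import SideSymbol, canonical, validate_k
from .walker import split_valid_runs

#: Bits per state code: ceil(log2(26)).
STATE_CODE_WIDTH = 5

#: Extra per-vertex bit for the extractor's emission flag.
EMISSION_FLAG_WIDTH = 1

_STATUS_INDEX = {s: i for i, s in enumerate(SIDE_STATUSES)}
_UNVISITED_CODE = 0


class StoreCorruptionError(RuntimeError):
    """A state code outside the assigned range was decoded."""


class AlienKeyError(KeyError):
    """A k-mer outside the static key set was queried."""


def encode_state(state: VertexState) -> int:
    """Bijective 5-bit code for one of the 26 automaton states."""
    if not state.visited:
        return _UNVISITED_CODE
    return 1 + 5 * _STATUS_INDEX[state.front] + _STATUS_INDEX[state.back]


def decode_state(code: int) -> VertexState:
    if code == _UNVISITED_CODE:
        return UNVISITED
    if not 0 < code <= 25:
        raise StoreCorruptionError(f"state code {code} is not assigned")
    f, b = divmod(code - 1, 5)
    return VertexState(SIDE_STATUSES[f], SIDE_STATUSES[b])


class PackedArray:
    """Fixed-width unsigned integers bit-packed into a byte buffer."""

    def __init__(self, n: int, width: int, buffer: np.ndarray | None = None):
        if not 1 <= width <= 8:
            raise ValueError("width must be in [1, 8]")
        self.n = n
        self.width = width
        nbytes = (n * width + 7) // 8 + 1  # +1 spare byte simplifies spills
        if buffer is None:
            buffer = np.zeros(nbytes, dtype=np.uint8)
        elif len(buffer) != nbytes:
            raise ValueError("buffer size mismatch")
        self._buf = buffer

    def __len__(self) -> int:
        return self.n

    def __getitem__(self, i: int) -> int:
        byte, off = divmod(i * self.width, 8)
        val = int(self._buf[byte]) >> off
        if off + self.width > 8:
            val |= int(self._buf[byte + 1]) << (8 - off)
        return val & ((1 << self.width) - 1)

    def __setitem__(self, i: int, value: int) -> None:
        mask = (1 << self.width) - 1
        if value & ~mask:
            raise ValueError(f"value {value} exceeds {self.width} bits")
        byte, off = divmod(i * self.width, 8)
        self._buf[byte] = (int(self._buf[byte]) & ~((mask << off) & 0xFF)) | ((value << off) & 0xFF)
        if off + self.width > 8:
            hi_bits = self.width - (8 - off)
            hi_mask = (1 << hi_bits) - 1
            self._buf[byte + 1] = (int(self._buf[byte + 1]) & ~hi_mask) | (value >> (8 - off))

    @property
    def buffer(self) -> np.ndarray:
        return self._buf


@dataclass(frozen=True)
class KmerSet:
    """The distinct canonical k-mers of an input collection."""

    k: int
    members: frozenset[str] = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.members)


class EmptyInputError(ValueError):
    """No input sequence contained a single valid k-mer."""


def enumerate_kmers(sequences: Iterable[str], k: int) -> KmerSet:
    """Distinct canonical k-mers over all valid ACGT runs of the input.

    Lowercase is folded and non-ACGT characters split sequences into
    independent runs; runs shorter than k contribute nothing.
    """
    validate_k(k)
    members: set[str] = set()
    for seq in sequences:
        for run in split_valid_runs(seq, k):
            t = run.text
            for i in range(len(t) - k + 1):
                members.add(canonical(t[i:i + k]))
    if not members:
        raise EmptyInputError(f"no sequence contains a valid k-mer for k={k}")
    return KmerSet(k=k, members=frozenset(members))


class StateStore:
    """State table over a static canonical k-mer set.

    ``index`` is a minimal perfect map (sorted keys + binary search);
    ``codes`` holds one 5-bit automaton state per vertex and ``emitted``
    one flag bit. All vertices start unvisited and un-emitted.
    """

    def __init__(self, kmers: KmerSet, _keys: list[str] | None = None,
                 _codes: PackedArray | None = None, _emitted: PackedArray | None = None):
        self.k = kmers.k
        self._keys = sorted(kmers.members) if _keys is None else _keys
        self.n = len(self._keys)
        self._codes = PackedArray(self.n, STATE_CODE_WIDTH) if _codes is None else _codes
        self._emitted = PackedArray(self.n, EMISSION_FLAG_WIDTH) if _emitted is None else _emitted

    # -- minimal perfect index -------------------------------------------------

    def index(self, kmer: str) -> int:
        """Slot of a canonical k-mer in [0, n); raises on alien keys."""
        i = bisect_left(self._keys, kmer)
        if i == self.n or self._keys[i] != kmer:
            raise AlienKeyError(f"k-mer {kmer!r} is not in the store's key set")
        return i

    def __contains__(self, kmer: str) -> bool:
        i = bisect_left(self._keys, kmer)
        return i < self.n and self._keys[i] == kmer

    def keys(self) -> Iterable[str]:
        return iter(self._keys)

    # -- state access ----------------------------------------------------------

    def get_state(self, kmer: str) -> VertexState:
        return decode_state(self._codes[self.index(kmer)])

    def update_state(self, kmer: str, symbol: SideSymbol) -> None:
        """Fold one observed instance symbol into the vertex's automaton."""
        i = self.index(kmer)
        self._codes[i] = encode_state(transition(decode_state(self._codes[i]), symbol))

    # -- emission flags --------------------------------------------------------

    def is_emitted(self, kmer: str) -> bool:
        return bool(self._emitted[self.index(kmer)])

    def mark_emitted(self, kmer: str) -> None:
        self._emitted[self.index(kmer)] = 1

    def reset_emitted(self) -> None:
        self._emitted = PackedArray(self.n, EMISSION_FLAG_WIDTH)

    @property
    def bits_per_vertex(self) -> int:
        """Constant per-vertex table width: 5 state bits + 1 flag bit."""
        return STATE_CODE_WIDTH + EMISSION_FLAG_WIDTH

    # -- serialization ---------------------------------------------------------

    _MAGIC = b"CDBGST01"

    def save(self, path: str | Path) -> None:
        """Write index + codes with a versioned binary header."""
        payload = "".join(self._keys).encode("ascii")
        with open(path, "wb") as fh:
            fh.write(self._MAGIC)
            fh.write(struct.pack("<QQB", self.k, self.n, STATE_CODE_WIDTH))
            fh.write(payload)
            fh.write(self._codes.buffer.tobytes())
            fh.write(self._emitted.buffer.tobytes())

    @classmethod
    def load(cls, path: str | Path) -> "StateStore":
        with open(path, "rb") as fh:
            magic = fh.read(8)
            if magic != cls._MAGIC:
                raise StoreCorruptionError(f"bad magic {magic!r}")
            k, n, width = struct.unpack("<QQB", fh.read(17))
            if width != STATE_CODE_WIDTH:
                raise StoreCorruptionError(f"unsupported code width {width}")
            keys_blob = fh.read(k * n).decode("ascii")
            keys = [keys_blob[i * k:(i + 1) * k] for i in range(n)]
            codes_bytes = (n * STATE_CODE_WIDTH + 7) // 8 + 1
            codes = PackedArray(n, STATE_CODE_WIDTH,
                                np.frombuffer(fh.read(codes_bytes), dtype=np.uint8).copy())
            emitted_bytes = (n * EMISSION_FLAG_WIDTH + 7) // 8 + 1
            emitted = PackedArray(n, EMISSION_FLAG_WIDTH,
                                  np.frombuffer(fh.read(emitted_bytes), dtype=np.uint8).copy())
        kmers = KmerSet(k=k, members=frozenset(keys))
        return cls(kmers, _keys=keys, _codes=codes, _emitted=emitted)


def build_store(kmers: KmerSet) -> StateStore:
    """Fresh store: every vertex unvisited, every emission flag clear."""
    if kmers.n == 0:
        raise EmptyInputError("cannot build a store over an empty k-mer set")
    return StateStore(kmers)
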