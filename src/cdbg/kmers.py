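"""DNA-string primitives and bidirected de Bruijn graph semantics.

The graph is edge-centric and bidirected: vertices are *canonical* k-mers
(lexicographic minimum of a k-mer and its reverse complement), and every
(k+1)-mer occurring in the input induces one edge. Each vertex has two
*sides* (front and back); an edge attaches to a specific side of each of
its endpoints, determined by the orientation in which the endpoint k-mer
occurs inside the (k+1)-mer. This module implements those rules plus the
derivation of per-vertex automaton input symbols from sequence context.

k must be odd so that no k-mer equals its own reverse complement, which
makes vertex orientation well defined everywhere.
"""

from __future__ import annotations

import enum
from typing import NamedTuple

ALPHABET = "ACGT"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Empty symbol marking the absence of a flanking character at the
#: boundary of an input string (or of a valid ACGT run inside it).
EPS = ""

#: Side-symbol value meaning "more than one distinct incident edge, or an
#: edge that cannot be summarised by a single character" (boundary or
#: crossing loop). Once a side observes this, it is permanently branching.
AMBIGUOUS = "*"


class Side(enum.Enum):
    """One of the two sides of a bidirected vertex."""

    FRONT = "front"
    BACK = "back"

    def opposite(self) -> "Side":
        return Side.BACK if self is Side.FRONT else Side.FRONT


class SideSymbol(NamedTuple):
    """Automaton input derived from one k-mer instance.

    ``front`` / ``back`` are each a single base (the unique character
    encoding the incident edge on that side) or :data:`AMBIGUOUS`.
    """

    front: str
    back: str


class InvalidAlphabetError(ValueError):
    """A sequence contained a character outside {A, C, G, T}."""


def _check_acgt(s: str) -> None:
    if not set(s) <= set(ALPHABET):
        bad = sorted(set(s) - set(ALPHABET))
        raise InvalidAlphabetError(f"non-ACGT character(s): {bad!r}")


def validate_k(k: int) -> None:
    """Reject k values the bidirected model cannot support.

    k must be odd so a k-mer is never its own reverse complement; even k
    would need a tie-break for palindromic vertices and is refused.
    """
    if not isinstance(k, int) or k < 3 or k % 2 == 0:
        raise ValueError(f"k must be an odd integer >= 3, got {k!r}")


def reverse_complement(s: str) -> str:
    """Reverse-complement of an ACGT string (an involution)."""
    _check_acgt(s)
    return s.translate(_COMPLEMENT)[::-1]


def complement(c: str) -> str:
    """Complement of a single base; the empty symbol maps to itself."""
    if c == EPS:
        return EPS
    _check_acgt(c)
    return c.translate(_COMPLEMENT)


def canonical(x: str) -> str:
    """Canonical form: min(x, reverse_complement(x)) lexicographically."""
    return min(x, reverse_complement(x))


def is_canonical(x: str) -> bool:
    return x <= reverse_complement(x)


def is_palindromic(e: str) -> bool:
    """True iff e equals its own reverse complement.

    Only even-length strings can be palindromic in this sense; for a
    (k+1)-mer with odd k this identifies *crossing loops*: edges incident
    twice to the same side of one vertex.
    """
    return e == reverse_complement(e)


def edge_endpoints(e: str) -> tuple[tuple[str, Side], tuple[str, Side]]:
    """Endpoints of the edge induced by a (k+1)-mer.

    Returns ``((u, side_u), (v, side_v))`` where ``u`` is the canonical
    form of the k-prefix of ``e`` and ``v`` of its k-suffix. The edge is
    incident to the back of ``u`` iff the k-prefix is itself canonical
    (front otherwise), and to the front of ``v`` iff the k-suffix is
    canonical (back otherwise). Loops (``u == v``) are permitted.
    """
    if len(e) < 4 or len(e) % 2:
        raise ValueError(f"edge must be a (k+1)-mer with odd k >= 3, got length {len(e)}")
    _check_acgt(e)
    pre, suf = e[:-1], e[1:]
    u_side = Side.BACK if is_canonical(pre) else Side.FRONT
    v_side = Side.FRONT if is_canonical(suf) else Side.BACK
    return (canonical(pre), u_side), (canonical(suf), v_side)


def glue(x: str, y: str, overlap: int) -> str:
    """Concatenate x and y, merging a shared overlap.

    Requires the length-``overlap`` suffix of ``x`` to equal the prefix of
    ``y``; returns ``x`` followed by the remainder of ``y``.
    """
    if overlap > min(len(x), len(y)) or overlap < 0:
        raise ValueError(f"overlap {overlap} out of range for |x|={len(x)}, |y|={len(y)}")
    if x[len(x) - overlap:] != y[:overlap]:
        raise GlueError(f"suffix/prefix mismatch gluing {x!r} and {y!r} with overlap {overlap}")
    return x + y[overlap:]


class GlueError(ValueError):
    """Overlap mismatch during spelling; indicates a walker bug upstream."""


def derive_input_symbol(instance: str, prev: str, nxt: str) -> SideSymbol:
    """Automaton input for one k-mer instance with its flanking characters.

    ``instance`` is the k-mer exactly as it appears in the sequence
    (possibly non-canonical); ``prev``/``nxt`` are the characters
    immediately before/after it, or :data:`EPS` at a run boundary.

    The edge on the vertex's front side is encoded by the character c such
    that the edge reads ``c + label`` with the label as suffix; the back
    side by d such that the edge reads ``label + d``. Hence for a
    canonical instance ``(front, back) = (prev, nxt)`` and for a
    non-canonical one ``(front, back) = (complement(nxt), complement(prev))``.
    An empty symbol makes that side ambiguous outright.

    Crossing loops: if ``prev + instance`` (resp. ``instance + nxt``) is a
    palindromic (k+1)-mer, that edge is incident to one side of the vertex
    twice, so the side it encodes is forced ambiguous.
    """
    canon = is_canonical(instance)
    if canon:
        front, back = prev, nxt
    else:
        front, back = complement(nxt), complement(prev)

    front = AMBIGUOUS if front == EPS else front
    back = AMBIGUOUS if back == EPS else back

    if prev != EPS and is_palindromic(prev + instance):
        # prev encodes the front of a canonical instance, the back otherwise
        if canon:
            front = AMBIGUOUS
        else:
            back = AMBIGUOUS
    if nxt != EPS and is_palindromic(instance + nxt):
        if canon:
            back = AMBIGUOUS
        else:
            front = AMBIGUOUS
    return SideSymbol(front, back)
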