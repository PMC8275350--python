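"""DNA primitives and bidirected-incidence semantics."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cdbg.kmers import (
    AMBIGUOUS,
    EPS,
    GlueError,
    InvalidAlphabetError,
    Side,
    SideSymbol,
    canonical,
    complement,
    derive_input_symbol,
    edge_endpoints,
    glue,
    is_canonical,
    reverse_complement,
    validate_k,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=40)
kmer3 = st.text(alphabet="ACGT", min_size=3, max_size=3)
base_or_eps = st.sampled_from(["A", "C", "G", "T", EPS])


@pytest.mark.parametrize(
    "s,expected",
    [("ATG", "CAT"), ("CATG", "CATG"), ("A", "T"), ("GAC", "GTC")],
)
def test_reverse_complement_examples(s, expected):
    assert reverse_complement(s) == expected


@given(dna)
def test_reverse_complement_is_an_involution(s):
    assert reverse_complement(reverse_complement(s)) == s
    assert len(reverse_complement(s)) == len(s)


def test_reverse_complement_rejects_non_acgt():
    with pytest.raises(InvalidAlphabetError):
        reverse_complement("ACGN")


@pytest.mark.parametrize(
    "x,expected", [("CAT", "ATG"), ("GAC", "GAC"), ("ACA", "ACA")]
)
def test_canonical_examples(x, expected):
    assert canonical(x) == expected


@given(dna)
def test_canonical_is_idempotent_and_orientation_free(x):
    assert canonical(canonical(x)) == canonical(x)
    assert canonical(reverse_complement(x)) == canonical(x)


@pytest.mark.parametrize("k", [2, 4, 1, 0, -3])
def test_even_or_tiny_k_rejected(k):
    with pytest.raises(ValueError):
        validate_k(k)


@pytest.mark.parametrize(
    "e,expected",
    [
        ("CGAC", (("CGA", Side.BACK), ("GAC", Side.FRONT))),
        ("CATG", (("ATG", Side.FRONT), ("ATG", Side.FRONT))),
        ("GCTC", (("AGC", Side.FRONT), ("CTC", Side.FRONT))),
    ],
)
def test_edge_endpoints_examples(e, expected):
    assert edge_endpoints(e) == expected


def test_edge_endpoints_rejects_wrong_length():
    with pytest.raises(ValueError):
        edge_endpoints("ACGTA")  # length 5 -> even k


def test_edge_endpoints_orientation_consistency_exhaustive_k3():
    """An edge and its reverse complement are the same incidence pair."""
    for e in map("".join, itertools.product("ACGT", repeat=4)):
        fwd = frozenset(edge_endpoints(e))
        rev = frozenset(edge_endpoints(reverse_complement(e)))
        assert fwd == rev


@pytest.mark.parametrize(
    "x,y,l,expected",
    [("GAC", "ACA", 2, "GACA"), ("ATGT", "GTC", 2, "ATGTC"), ("TAG", "TAG", 3, "TAG")],
)
def test_glue_examples(x, y, l, expected):
    assert glue(x, y, l) == expected


def test_glue_mismatch_raises():
    with pytest.raises(GlueError):
        glue("GAC", "CCA", 2)


@pytest.mark.parametrize(
    "x,p,n,expected",
    [
        ("GAC", "C", "A", SideSymbol("C", "A")),
        ("CAT", "A", "G", SideSymbol(AMBIGUOUS, "T")),  # CATG is a crossing loop
        ("CGA", EPS, "C", SideSymbol(AMBIGUOUS, "C")),  # sentinel on the entry side
    ],
)
def test_derive_input_symbol_examples(x, p, n, expected):
    assert derive_input_symbol(x, p, n) == expected


@given(kmer3, base_or_eps, base_or_eps)
def test_input_symbol_invariant_under_reverse_complement_context(x, p, n):
    """The same instance read on the other strand yields the same symbol."""
    sym = derive_input_symbol(x, p, n)
    sym_rc = derive_input_symbol(reverse_complement(x), complement(n), complement(p))
    assert sym == sym_rc


def _observed_side_chars(sequence, k=3):
    """Map (vertex, side) -> set of non-ambiguous edge characters seen."""
    out = {}
    for i in range(len(sequence) - k + 1):
        x = sequence[i:i + k]
        p = sequence[i - 1] if i > 0 else EPS
        n = sequence[i + k] if i + k < len(sequence) else EPS
        sym = derive_input_symbol(x, p, n)
        v = canonical(x)
        for side, c in ((Side.FRONT, sym.front), (Side.BACK, sym.back)):
            if c != AMBIGUOUS:
                out.setdefault((v, side), set()).add(c)
    return out


def test_edge_character_encoding_is_context_independent_exhaustive_k3():
    """Both strand readings of every edge agree on its per-side character."""
    for e in map("".join, itertools.product("ACGT", repeat=4)):
        merged = {}
        for s in (e, reverse_complement(e)):
            for key, chars in _observed_side_chars(s).items():
                merged.setdefault(key, set()).update(chars)
        for (v, side), chars in merged.items():
            assert len(chars) == 1, (e, v, side, chars)


def test_at_most_four_distinct_edge_characters_per_side():
    """Brute force over all single-character extensions of every vertex."""
    for v in map("".join, itertools.product("ACGT", repeat=3)):
        if not is_canonical(v):
            continue
        per_side = {Side.FRONT: set(), Side.BACK: set()}
        for c in "ACGT":
            for seq in (c + v, v + c):
                for key, chars in _observed_side_chars(seq).items():
                    if key[0] == v:
                        per_side[key[1]].update(chars)
        assert all(len(chars) <= 4 for chars in per_side.values())
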