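"""Unitig initiation/termination rules, spelling, and extraction."""

from collections import Counter

import pytest

from cdbg.automaton import StateClass
from cdbg.kmers import Side, canonical, glue, reverse_complement
from cdbg.extract import (
    canonical_spelling,
    entry_side,
    extract_maximal_unitigs,
    initiates,
    spell_walk,
    terminates,
)
from cdbg.pipeline import compact_sequences
from cdbg.walker import walk_contexts
from conftest import TOY_INPUT, TOY_K, TOY_UNITIGS, random_collection


@pytest.mark.parametrize(
    "instance,expected",
    [("ATG", Side.FRONT), ("CAT", Side.BACK), ("GAC", Side.FRONT), ("GTC", Side.BACK)],
)
def test_entry_side_follows_instance_orientation(instance, expected):
    assert entry_side(instance) == expected


@pytest.mark.parametrize("entry", [Side.FRONT, Side.BACK])
def test_fully_branching_class_both_initiates_and_terminates(entry):
    assert initiates(StateClass.MULTI_IN_MULTI_OUT, entry)
    assert terminates(StateClass.MULTI_IN_MULTI_OUT, entry)


def test_initiation_termination_truth_table():
    F, B = Side.FRONT, Side.BACK
    assert initiates(StateClass.MULTI_IN_SINGLE_OUT, F)
    assert not initiates(StateClass.MULTI_IN_SINGLE_OUT, B)
    assert initiates(StateClass.SINGLE_IN_MULTI_OUT, B)
    assert not initiates(StateClass.SINGLE_IN_MULTI_OUT, F)
    assert terminates(StateClass.SINGLE_IN_MULTI_OUT, F)
    assert terminates(StateClass.MULTI_IN_SINGLE_OUT, B)
    for entry in (F, B):
        assert not initiates(StateClass.SINGLE_IN_SINGLE_OUT, entry)
        assert not terminates(StateClass.SINGLE_IN_SINGLE_OUT, entry)


@pytest.mark.parametrize(
    "walk,expected",
    [
        (["GAC", "ACA", "ATG"], "GACAT"),
        (["GAC", "ACA", "ATG", "ATG"], "GACATG"),
        (["TAG"], "TAG"),
    ],
)
def test_spell_walk_printed_examples(walk, expected):
    assert spell_walk(walk) == expected


@pytest.mark.parametrize("seed", [5, 6])
def test_spelling_a_run_reproduces_its_text(seed):
    from cdbg.walker import split_valid_runs

    for seq in random_collection(seed, 5):
        for run in split_valid_runs(seq, 5, "s"):
            assert spell_walk(list(walk_contexts(run, 5)), 5) == run.text


@pytest.mark.parametrize(
    "s,expected", [("GACAT", "ATGTC"), ("CGA", "CGA"), ("TCTTAG", "CTAAGA")]
)
def test_canonical_spelling_examples(s, expected):
    assert canonical_spelling(s) == expected
    assert canonical_spelling(reverse_complement(s)) == expected


def test_worked_example_extraction():
    res = compact_sequences(TOY_INPUT, TOY_K)
    assert res.spellings == TOY_UNITIGS
    assert len(res.unitigs) == 4
    for rec in res.unitigs:
        assert rec.spelling == canonical_spelling(rec.spelling)
        assert rec.length == len(rec.spelling)
        assert rec.first_vertex == canonical(rec.spelling[:TOY_K])
        assert rec.last_vertex == canonical(rec.spelling[-TOY_K:])


def test_unitig_ids_follow_sorted_spelling_order():
    res = compact_sequences(TOY_INPUT, TOY_K)
    spellings = [u.spelling for u in sorted(res.unitigs, key=lambda u: u.id)]
    assert spellings == sorted(spellings)


def test_each_unitig_emitted_exactly_once_even_when_revisited():
    # the toy input traverses ATGTC twice (forward then reverse) and
    # CTAAGA appears in both references
    res = compact_sequences(TOY_INPUT, TOY_K)
    counts = Counter(u.spelling for u in res.unitigs)
    assert all(c == 1 for c in counts.values())


@pytest.mark.parametrize("seed", [21, 22, 23])
def test_node_decomposition_on_random_fixtures(seed):
    """Every canonical k-mer of the input lands in exactly one unitig."""
    k = 5
    seqs = random_collection(seed, k)
    res = compact_sequences(seqs, k)
    counts = Counter()
    for u in res.unitigs:
        for i in range(len(u.spelling) - k + 1):
            counts[canonical(u.spelling[i:i + k])] += 1
    assert set(counts) == set(res.store.keys())
    assert all(c == 1 for c in counts.values())


def test_tilings_reconstruct_every_run():
    res = compact_sequences(TOY_INPUT, TOY_K)
    by_id = {u.id: u.spelling for u in res.unitigs}
    for run in res.runs:
        steps = res.tilings[(run.seq_id, run.start)]
        out = None
        for s in steps:
            oriented = by_id[s.unitig_id]
            if s.orientation == "-":
                oriented = reverse_complement(oriented)
            out = oriented if out is None else glue(out, oriented, TOY_K - 1)
        assert out == run.text
        assert steps[0].start == run.start


def test_unitigs_never_span_two_runs():
    # identical flanks joined by N: each side compacts independently
    res = compact_sequences(["ACGTAC" + "N" + "ACGTAC"], 3)
    rep_res = compact_sequences(["ACGTAC"], 3)
    assert res.spellings == rep_res.spellings
    assert len(res.tilings) == 2


def test_branch_free_runs_give_one_unitig_per_run():
    # no shared k-mers, no repeated vertices, no palindromic 4-mers
    seqs = ["ACGGA", "TTGAG"]
    res = compact_sequences(seqs, 3)
    assert len(res.unitigs) == 2
    assert res.spellings == {canonical_spelling(s) for s in seqs}
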