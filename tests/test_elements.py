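"""Loop / dinucleotide-step / single-strand decomposition and element curves."""

import networkx as nx
import numpy as np
import pytest

from rnatangle.elements import (
    all_elements,
    find_dinucleotide_steps,
    find_loops,
    find_single_strands,
)
from rnatangle.structure_io import annotate_base_pairs, parse_dotbracket

from conftest import straight_chain_model


def decomposed(db):
    model = straight_chain_model(len(db))
    ss = annotate_base_pairs(model, "dotbracket", db)
    chain = model.chains[0]
    return model, ss, chain


# --- loops -----------------------------------------------------------------

def test_hairpin_single_loop():
    _, ss, chain = decomposed("((((....))))")
    loops = find_loops(ss, chain)
    assert len(loops) == 1
    (loop,) = loops
    assert loop.closed
    assert {r.index for r in loop.residues} == set(range(3, 9))
    assert loop.segment_provenance.count("hydrogen_bond") == 1


def test_internal_loop_plus_hairpin():
    _, ss, chain = decomposed("((..((...))..))")
    loops = find_loops(ss, chain)
    assert len(loops) == 2
    residue_sets = sorted(({r.index for r in lp.residues} for lp in loops), key=min)
    # internal loop: closing pair (1,13) with child (4,10)
    assert residue_sets[0] == {1, 2, 3, 4, 10, 11, 12, 13}
    # hairpin of pair (5,9)
    assert residue_sets[1] == {5, 6, 7, 8, 9}


def test_loop_cycles_match_cycle_space_oracle():
    """Loops + steps form exactly the independent cycles of the SS graph."""
    db = "((..((...))..((....))..))"
    _, ss, chain = decomposed(db)
    loops = find_loops(ss, chain)
    steps = find_dinucleotide_steps(ss, chain)
    g = nx.Graph()
    n = len(db)
    g.add_edges_from((k, k + 1) for k in range(n - 1))
    g.add_edges_from((i, j) for i, j, _ in parse_dotbracket(db))
    cycle_count = g.number_of_edges() - g.number_of_nodes() + nx.number_connected_components(g)
    assert len(loops) + len(steps) == cycle_count
    # cross-check residue sets against the minimum cycle basis
    basis = sorted((sorted(c) for c in nx.minimum_cycle_basis(g)), key=lambda c: (len(c), c))
    ours = sorted(
        (sorted({r.index for r in el.residues}) for el in loops + steps),
        key=lambda c: (len(c), c),
    )
    assert ours == basis


def test_empty_pair_set_no_loops():
    _, ss, chain = decomposed("........")
    assert find_loops(ss, chain) == []


def test_pseudoknot_pair_closes_loop_in_its_layer():
    # hairpin closed by a pseudoknotted (layer-1) pair
    db = "((..[[..))..]]"
    _, ss, chain = decomposed(db)
    loops = find_loops(ss, chain)
    sets = sorted(({r.index for r in lp.residues} for lp in loops), key=min)
    assert {4, 5, 12, 13} <= sets[1] or any({5, 6, 7, 8, 9, 10, 11, 12} == s for s in sets)
    assert len(loops) == 2  # one per layer's innermost pair


# --- dinucleotide steps ----------------------------------------------------

def test_hairpin_steps():
    _, ss, chain = decomposed("((((....))))")
    steps = find_dinucleotide_steps(ss, chain)
    assert len(steps) == 3
    quads = sorted(tuple(sorted(r.index for r in s.residues)) for s in steps)
    assert quads == [(0, 1, 10, 11), (1, 2, 9, 10), (2, 3, 8, 9)]
    for s in steps:
        assert s.closed
        assert s.segment_provenance.count("hydrogen_bond") == 2


def test_isolated_pair_no_steps():
    _, ss, chain = decomposed("..(....)..")
    assert find_dinucleotide_steps(ss, chain) == []


def test_two_helices_step_count():
    _, ss, chain = decomposed("((((...))))..(((...)))")
    steps = find_dinucleotide_steps(ss, chain)
    assert len(steps) == 3 + 2


# --- single strands --------------------------------------------------------

def test_hairpin_interior_not_a_strand():
    _, ss, chain = decomposed("((((....))))")
    assert find_single_strands(ss, chain) == []


def test_dangling_end_strand_with_anchor():
    _, ss, chain = decomposed("....((((....))))")
    strands = find_single_strands(ss, chain)
    assert len(strands) == 1
    assert [r.index for r in strands[0].residues] == [0, 1, 2, 3, 4]
    assert not strands[0].closed
    assert strands[0].segment_provenance.count("hydrogen_bond") == 0


def test_fully_unpaired_chain_one_strand():
    _, ss, chain = decomposed("." * 20)
    strands = find_single_strands(ss, chain)
    assert len(strands) == 1
    assert len(strands[0].residues) == 20


# --- invariants ------------------------------------------------------------

@pytest.mark.parametrize("db", ["((((....))))", "..((..((...))..))..", "((..[[..))..]]"])
def test_every_residue_covered(db):
    _, ss, chain = decomposed(db)
    elements = all_elements(ss, chain)
    covered = {r.index for el in elements for r in el.residues}
    assert covered == set(range(len(db)))
    paired = ss.paired_indices("A")
    closed_cov = {r.index for el in elements if el.closed for r in el.residues}
    assert paired <= closed_cov


def test_decomposition_invariant_to_pair_order():
    db = "((..((...))..))"
    model = straight_chain_model(len(db))
    ss = annotate_base_pairs(model, "dotbracket", db)
    chain = model.chains[0]
    ref = sorted(tuple(sorted(r.index for r in el.residues)) for el in all_elements(ss, chain))
    ss.pairs = list(reversed(ss.pairs))
    got = sorted(tuple(sorted(r.index for r in el.residues)) for el in all_elements(ss, chain))
    assert got == ref


@pytest.mark.parametrize("db", ["((((....))))", "((..((...))..))"])
def test_closed_curves_have_zero_gap(db):
    _, ss, chain = decomposed(db)
    for el in all_elements(ss, chain):
        if el.closed:
            assert np.linalg.norm(el.curve[0] - el.curve[-1]) < 1e-9
        else:
            assert np.linalg.norm(el.curve[0] - el.curve[-1]) > 1e-9
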