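"""Spanning surfaces, punctures, linking, subclass taxonomy, and lasso depth."""

import numpy as np
import pytest

from rnatangle.entangle import (
    Entanglement,
    IntersectionPoint,
    classify_pair,
    detect_all,
    find_punctures,
    lasso_depth,
    linking_number,
    linking_number_gauss,
    span_surface,
)
from rnatangle.structure_io import ResRef, annotate_base_pairs
from rnatangle.synthetic import (
    make_dinucleotide_pierce,
    make_hairpin_lasso,
    make_hopf_loops,
)

from conftest import polyline_element


def circle(center, radius, plane="xy", n=40):
    th = np.linspace(0, 2 * np.pi, n + 1)
    c = np.asarray(center, float)
    if plane == "xy":
        pts = np.column_stack([np.cos(th), np.sin(th), np.zeros_like(th)])
    else:  # xz
        pts = np.column_stack([np.cos(th), np.zeros_like(th), np.sin(th)])
    return c + radius * pts


# --- spanning surface ------------------------------------------------------

def test_square_surface_area_and_planarity():
    sq = polyline_element("loop", True, [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0], [0, 0, 0]])
    surf = span_surface(sq)
    assert abs(surf.area - 1.0) < 0.01
    assert np.abs(surf.vertices[:, 2]).max() < 1e-12


def test_planar_12gon_relaxation_stays_in_plane():
    el = polyline_element("loop", True, circle([0, 0, 0], 5.0, n=12))
    surf = span_surface(el, subdivision_rounds=3)
    assert np.abs(surf.vertices[:, 2]).max() < 1e-12


def test_quadrilateral_fan_before_subdivision():
    sq = polyline_element(
        "dinucleotide_step", True, [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0], [0, 0, 0]]
    )
    surf = span_surface(sq, subdivision_rounds=0)
    assert len(surf.triangles) == 4


def test_open_element_rejected():
    el = polyline_element("single_strand", False, [[0, 0, 0], [1, 0, 0]])
    with pytest.raises(ValueError):
        span_surface(el)


# --- punctures -------------------------------------------------------------

def test_single_puncture_through_square_center():
    sq = polyline_element("loop", True, [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0], [0, 0, 0]])
    surf = span_surface(sq)
    seg = polyline_element("single_strand", False, [[0.5, 0.5, -1], [0.5, 0.5, 1]], chain_id="B")
    punct = find_punctures(surf, seg)
    assert len(punct) == 1
    assert np.allclose(punct[0].position, [0.5, 0.5, 0.0], atol=1e-9)


def test_no_puncture_outside_boundary():
    sq = polyline_element("loop", True, [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0], [0, 0, 0]])
    surf = span_surface(sq)
    seg = polyline_element("single_strand", False, [[2.5, 0.5, -1], [2.5, 0.5, 1]], chain_id="B")
    assert find_punctures(surf, seg) == []


def test_in_and_out_threading_has_opposite_signs():
    sq = polyline_element(
        "loop", True, [[0, 0, 0], [2, 0, 0], [2, 2, 0], [0, 2, 0], [0, 0, 0]]
    )
    surf = span_surface(sq)
    thread = polyline_element(
        "loop",
        True,
        [
            [0.5, 1.0, -1], [0.5, 1.0, 1], [1.5, 1.0, 1], [1.5, 1.0, -1], [0.5, 1.0, -1],
        ],
        chain_id="B",
    )
    punct = find_punctures(surf, thread)
    assert len(punct) == 2
    assert sorted(p.crossing_sign for p in punct) == [-1, 1]


# --- linking number --------------------------------------------------------

def test_disjoint_circles_unlinked():
    a = circle([0, 0, 0], 1.0)
    b = circle([5, 0, 0], 1.0)
    assert linking_number(a, b) == 0
    assert abs(linking_number_gauss(a, b)) < 1e-6


def test_hopf_circles_linked_once():
    a = circle([0, 0, 0], 1.0, "xy")
    b = circle([1, 0, 0], 1.0, "xz")
    lk = linking_number(a, b)
    assert abs(lk) == 1
    assert abs(linking_number_gauss(a, b) - lk) < 1e-6


def test_doubly_wound_link():
    a = circle([0, 0, 0], 1.0, "xy", n=60)
    t = np.linspace(0, 2 * np.pi, 121)
    b = np.column_stack(
        [1 + 0.4 * np.cos(2 * t), 0.05 * np.sin(t), 0.4 * np.sin(2 * t)]
    )
    b[-1] = b[0]
    lk = linking_number(a, b)
    assert abs(lk) == 2
    assert abs(linking_number_gauss(a, b) - lk) < 1e-6


def test_puncture_parity_matches_linking():
    """Signed punctures of one loop's surface by the other equal +-lk; summing
    over both orderings gives magnitude 2*lk."""
    a_el = polyline_element("loop", True, circle([0, 0, 0], 1.0, "xy"))
    b_el = polyline_element("loop", True, circle([1, 0, 0], 1.0, "xz"), chain_id="B")
    lk = linking_number(a_el.curve, b_el.curve)
    signed_ab = sum(p.crossing_sign for p in find_punctures(span_surface(a_el), b_el))
    signed_ba = sum(p.crossing_sign for p in find_punctures(span_surface(b_el), a_el))
    assert abs(signed_ab) == abs(lk)
    assert abs(signed_ba) == abs(lk)
    assert abs(signed_ab) + abs(signed_ba) == 2 * abs(lk)


# --- classification --------------------------------------------------------

def _fake_puncture(res_a, res_b, sign=1, chain="B"):
    return IntersectionPoint(
        position=np.zeros(3),
        piercing_residues=(ResRef(chain, res_a), ResRef(chain, res_b)),
        piercing_provenance="backbone",
        pierced_element="A:L0",
        crossing_sign=sign,
    )


def test_classify_taxonomy():
    loop = polyline_element("loop", True, circle([0, 0, 0], 1.0))
    loop2 = polyline_element("loop", True, circle([1, 0, 0], 1.0, "xz"), chain_id="B")
    step = polyline_element(
        "dinucleotide_step", True, [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0], [0, 0, 0]]
    )
    strand = polyline_element("single_strand", False, [[0, 0, -1], [0, 0, 1]], chain_id="B")

    ls = classify_pair(loop, strand, [_fake_puncture(3, 4)])
    assert ls.subclass == "L(S)"
    ll_interlace = classify_pair(loop, loop2, [_fake_puncture(3, 4)], lk=1)
    assert ll_interlace.subclass == "L&L"
    assert ll_interlace.artifact
    dl = classify_pair(step, loop2, [_fake_puncture(3, 4), _fake_puncture(8, 9, -1)], lk=0)
    assert dl.subclass == "D(L)"
    assert dl.artifact  # all D(*) lassos are artifacts
    ld_interlace = classify_pair(loop, step, [], lk=-1)
    assert ld_interlace.subclass == "D&L"  # alphabetical, D before L
    assert classify_pair(loop, strand, []) is None
    assert classify_pair(loop, loop2, [], lk=0) is None


def test_double_puncture_loop_lasso():
    ent = classify_pair(
        polyline_element("loop", True, circle([0, 0, 0], 1.0)),
        polyline_element("loop", True, circle([1, 0, 0], 1.0, "xz"), chain_id="B"),
        [_fake_puncture(3, 4, 1), _fake_puncture(12, 13, -1)],
        lk=0,
    )
    assert ent.subclass == "L(L)"
    assert len(ent.intersections) == 2
    assert ent.depth == 13 - 4 + 1 - 1  # residues 4..12 strictly between segments


# --- depth -----------------------------------------------------------------

def _strand_entanglement(first, last, cross_a, cross_b, chain="B"):
    n = last - first + 1
    pts = np.column_stack([np.arange(n, dtype=float), np.zeros(n), np.zeros(n)])
    el = polyline_element("single_strand", False, pts, chain_id=chain, first_index=first)
    loop = polyline_element("loop", True, circle([0, 0, 0], 1.0))
    return Entanglement(
        subclass="L(S)",
        element_x=loop,
        element_y=el,
        intersections=[_fake_puncture(cross_a, cross_b, chain=chain)],
    )


def test_depth_single_puncture_worked_example():
    """Strand residues 36-69 (36 a paired anchor), one crossing between
    residues 62 and 63: six nucleotides (64..69) remain on the 3' side."""
    ent = _strand_entanglement(36, 69, 62, 63)
    from rnatangle.structure_io import BasePair, SecondaryStructure

    ss = SecondaryStructure(pairs=[BasePair(ResRef("B", 6), ResRef("B", 36), "WC-GC")])
    depth = lasso_depth(ent, ss)
    assert depth == 6


def test_depth_minimum_of_two_sides():
    ent = _strand_entanglement(0, 20, 3, 4)
    assert lasso_depth(ent) == min(3, 16)


def test_depth_double_puncture_between_rule():
    # crossings between (5,6) and (13,14): residues 6..13 lie between the
    # two intersection points -> depth 8
    ent = _strand_entanglement(0, 30, 5, 6)
    ent.intersections.append(_fake_puncture(13, 14))
    assert lasso_depth(ent) == 8


def test_depth_not_applicable_for_three_punctures():
    ent = _strand_entanglement(0, 30, 5, 6)
    ent.intersections.extend([_fake_puncture(14, 15), _fake_puncture(20, 21)])
    assert lasso_depth(ent) is None


@pytest.mark.parametrize("depth,expected_class", [(5, "shallow"), (6, "deep")])
def test_shallow_deep_boundary(depth, expected_class):
    model, db, truth = make_hairpin_lasso(loop_size=6, depth=depth)
    ss = annotate_base_pairs(model, "dotbracket", db)
    ents = detect_all(model, ss)
    assert len(ents) == 1
    assert ents[0].depth == depth
    assert ents[0].depth_class == expected_class
    assert ents[0].artifact == (expected_class == "deep")


@pytest.mark.parametrize("depth", [1, 3, 8])
def test_programmed_depth_recovered(depth):
    model, db, truth = make_hairpin_lasso(loop_size=6, depth=depth)
    ss = annotate_base_pairs(model, "dotbracket", db)
    ents = detect_all(model, ss)
    assert [e.subclass for e in ents] == ["L(S)"]
    assert ents[0].depth == depth


# --- full detection --------------------------------------------------------

def test_detect_all_fixture_truths():
    model, db, _ = make_hopf_loops()
    ss = annotate_base_pairs(model, "dotbracket", db)
    ents = detect_all(model, ss)
    assert [e.subclass for e in ents] == ["L&L"]
    assert abs(ents[0].linking) == 1

    model, db, _ = make_dinucleotide_pierce()
    ss = annotate_base_pairs(model, "dotbracket", db)
    ents = detect_all(model, ss)
    assert [e.subclass for e in ents] == ["D(S)"]
    assert ents[0].artifact

    for make, kwargs in [
        (make_hopf_loops, {"linked": False}),
        (make_dinucleotide_pierce, {"threaded": False}),
        (make_hairpin_lasso, {"depth": 7, "threaded": False}),
    ]:
        model, db, _ = make(**kwargs)
        ss = annotate_base_pairs(model, "dotbracket", db)
        assert detect_all(model, ss) == []


def test_labels_independent_of_subdivision_rounds():
    for make in (make_hairpin_lasso, make_hopf_loops, make_dinucleotide_pierce):
        model, db, _ = make()
        ss = annotate_base_pairs(model, "dotbracket", db)
        one = [(e.subclass, e.depth) for e in detect_all(model, ss, subdivision_rounds=1)]
        three = [(e.subclass, e.depth) for e in detect_all(model, ss, subdivision_rounds=3)]
        assert one == three
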