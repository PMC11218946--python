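"""KMT reduction, stochastic closures, and the full knot assessment."""

import numpy as np
import pytest

from rnatangle.knots import (
    InvalidCoordinatesError,
    assess_knot,
    classify_closed_curve,
    direct_closure,
    kmt_reduce,
    random_two_point_closure,
)
from rnatangle.synthetic import make_dense_walk, make_knot_curve

from conftest import torus_curve


# --- KMT reduction ---------------------------------------------------------

def test_convex_polygon_reduces_to_triangle():
    th = np.linspace(0, 2 * np.pi, 21)
    poly = np.column_stack([np.cos(th), np.sin(th), np.zeros_like(th)])
    red = kmt_reduce(poly)
    assert len(red) - 1 == 3  # closed: first vertex repeated


def test_three_point_chain_unchanged():
    pts = np.array([[0.0, 0, 0], [1, 1, 0], [2, 0, 0]])
    assert np.array_equal(kmt_reduce(pts), pts)


def test_open_chain_endpoints_fixed():
    rng = np.random.default_rng(4)
    pts = np.cumsum(rng.normal(size=(60, 3)), axis=0)
    red = kmt_reduce(pts, fixed_endpoints=True)
    assert np.allclose(red[0], pts[0])
    assert np.allclose(red[-1], pts[-1])
    assert len(red) <= len(pts)


def test_kmt_preserves_trefoil(rng):
    curve = torus_curve(2, 3)
    red = kmt_reduce(curve)
    assert len(red) < len(curve)
    assert classify_closed_curve(curve, rng) == "3_1"
    assert classify_closed_curve(red, rng) == "3_1"


# --- closures --------------------------------------------------------------

def test_straight_chain_closure_is_unknot(rng):
    pts = np.column_stack([np.linspace(0, 30, 10), np.zeros(10), np.zeros(10)])
    for _ in range(5):
        closed = random_two_point_closure(pts, rng)
        assert np.allclose(closed[0], closed[-1])
        assert classify_closed_curve(closed, rng) == "unknot"


def test_closure_stays_outside_chain():
    rng = np.random.default_rng(9)
    pts = np.cumsum(rng.normal(size=(50, 3)), axis=0)
    center = pts.mean(axis=0)
    extent = np.linalg.norm(pts - center, axis=1).max()
    closed = random_two_point_closure(pts, rng)
    closure_part = closed[len(pts):-1]
    assert (np.linalg.norm(closure_part - center, axis=1) > 5 * extent).all()


def test_direct_closure():
    u_shape = np.array([[0.0, 0, 0], [0, 1, 0], [1, 1, 0], [1, 0, 0]])
    closed = direct_closure(u_shape)
    assert np.allclose(closed[0], closed[-1])
    assert np.array_equal(direct_closure(closed), closed)  # already closed
    open_tre, _ = make_knot_curve("torus", (2, 3), open_fraction=0.05)
    rng = np.random.default_rng(2)
    assert classify_closed_curve(direct_closure(open_tre), rng) == "3_1"


# --- assessment ------------------------------------------------------------

def test_open_trefoil_assessment():
    pts, label = make_knot_curve("torus", (2, 3), open_fraction=0.05)
    a = assess_knot(pts, n_closures=200, seed=7)
    assert a.knotted
    assert a.dominant_label == "3_1"
    assert a.closure_histogram.get("3_1", 0) / 200 >= 0.9
    assert a.direct_closure_label == "3_1"
    assert not a.ambiguous
    assert not a.ttc


def test_unknotted_chain_assessment():
    pts = np.column_stack([np.linspace(0, 60, 20), np.sin(np.linspace(0, 3, 20)), np.zeros(20)])
    a = assess_knot(pts, n_closures=50, seed=7)
    assert not a.knotted
    assert a.dominant_label == "unknot"
    assert a.unknot_fraction == 1.0


def test_histogram_bitwise_reproducible():
    pts, _ = make_knot_curve("torus", (2, 5), n_points=260, open_fraction=0.05)
    a = assess_knot(pts, n_closures=40, seed=13)
    b = assess_knot(pts, n_closures=40, seed=13)
    assert a.closure_histogram == b.closure_histogram
    assert a.direct_closure_label == b.direct_closure_label


def test_histogram_stable_across_seeds():
    pts, _ = make_knot_curve("torus", (2, 3), open_fraction=0.05)
    a = assess_knot(pts, n_closures=100, seed=1)
    b = assess_knot(pts, n_closures=100, seed=2)
    fa = a.closure_histogram.get("3_1", 0) / 100
    fb = b.closure_histogram.get("3_1", 0) / 100
    assert abs(fa - fb) < 0.10


def test_dense_walk_is_ttc():
    walk = make_dense_walk(n_steps=1200, box=15.0, seed=3)
    a = assess_knot(walk, n_closures=15, seed=5)
    assert a.ttc


def test_dilute_walk_not_ttc():
    rng = np.random.default_rng(0)
    pts = np.cumsum(rng.normal(size=(100, 3)) * 10, axis=0)
    a = assess_knot(pts, n_closures=15, seed=5)
    assert not a.ttc


def test_duplicate_coordinates_rejected():
    pts = np.column_stack([np.linspace(0, 30, 12), np.zeros(12), np.zeros(12)])
    pts[7] = pts[2]
    with pytest.raises(InvalidCoordinatesError):
        assess_knot(pts, n_closures=5, seed=0)
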