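"""Knot diagrams and the Alexander polynomial.

A closed 3D polyline is projected along a generic direction to obtain a knot
diagram (crossings with over/under information and orientation signs).  From
the diagram the Alexander matrix is assembled via the arc relations of the
Wirtinger presentation; one row and one column are deleted and the determinant
taken over Z[t].  The polynomial, normalized to its symmetric representative
with positive constant term, is the invariant used to label knots through
seven crossings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sympy as sp

from .geometry import (
    GeneralPositionError,
    orthonormal_frame,
    polyline_crossings_2d,
    random_unit_vector,
)

__all__ = [
    "Crossing",
    "KnotDiagram",
    "project_to_diagram",
    "alexander_polynomial",
    "alexander_determinant",
    "classify_knot",
    "ALEXANDER_TABLE",
]

_T = sp.Symbol("t")


@dataclass(frozen=True)
class Crossing:
    over_arc: int
    under_in: int
    under_out: int
    sign: int  # +1 / -1 from projected orientation handedness


@dataclass
class KnotDiagram:
    """Planar diagram of a single closed curve."""

    crossings: list[Crossing] = field(default_factory=list)

    @property
    def n_arcs(self) -> int:
        return max(len(self.crossings), 1)


class TooManyCrossingsError(RuntimeError):
    """Projection produced more crossings than the caller's budget."""


def project_to_diagram(
    curve: np.ndarray,
    rng: np.random.Generator,
    max_tries: int = 100,
    max_crossings: int | None = None,
    direction: np.ndarray | None = None,
) -> KnotDiagram:
    """Project a closed curve along random directions until generic.

    The curve must be closed (first vertex repeated at the end).  Directions
    producing tangencies, vertex hits or near-parallel overlaps are rejected
    and redrawn, up to ``max_tries``; persistent failure raises
    :class:`GeneralPositionError` (callers route this to the
    too-tangled-to-check pathway).  When ``direction`` is given it is tried
    first, before any random redraw.
    """
    pts = np.asarray(curve, dtype=float)
    if np.linalg.norm(pts[0] - pts[-1]) > 1e-9:
        raise ValueError("project_to_diagram requires a closed curve")
    pts = pts[:-1]
    n = len(pts)
    if n < 3:
        return KnotDiagram([])
    last_err: Exception | None = None
    for trial in range(max_tries):
        if trial == 0 and direction is not None:
            trial_dir = np.asarray(direction, dtype=float)
        else:
            trial_dir = random_unit_vector(rng)
        e1, e2, d = orthonormal_frame(trial_dir)
        xy = np.column_stack([pts @ e1, pts @ e2])
        depth = pts @ d
        try:
            raw = polyline_crossings_2d(xy, cyclic=True, vertex_margin=1e-9)
        except GeneralPositionError as err:
            last_err = err
            continue
        if max_crossings is not None and len(raw) > max_crossings:
            raise TooManyCrossingsError(
                f"{len(raw)} crossings exceed budget {max_crossings}"
            )
        try:
            return _build_diagram(xy, depth, raw, n)
        except GeneralPositionError as err:
            last_err = err
            continue
    raise GeneralPositionError(f"no generic projection found: {last_err}")


def _build_diagram(xy, depth, raw_crossings, n) -> KnotDiagram:
    if not raw_crossings:
        return KnotDiagram([])
    d2 = np.roll(xy, -1, axis=0) - xy
    dz = np.roll(depth, -1) - depth
    events = []  # (under position, crossing index)
    over_pos = []
    signs = []
    for k, (i, s, j, t) in enumerate(raw_crossings):
        zi = depth[i] + s * dz[i]
        zj = depth[j] + t * dz[j]
        if abs(zi - zj) < 1e-9:
            raise GeneralPositionError("coincident depths at crossing")
        if zi > zj:
            over_seg, over_par, under_seg, under_par = i, s, j, t
            d_over, d_under = d2[i], d2[j]
        else:
            over_seg, over_par, under_seg, under_par = j, t, i, s
            d_over, d_under = d2[j], d2[i]
        cross = d_over[0] * d_under[1] - d_over[1] * d_under[0]
        sign = 1 if cross > 0 else -1
        events.append((under_seg + under_par, k))
        over_pos.append(over_seg + over_par)
        signs.append(sign)
    events.sort()
    positions = [p for p, _ in events]
    m = len(events)
    # arc a starts at under event a and runs to under event a+1 (cyclically)
    arc_of_event = {k: a for a, (_, k) in enumerate(events)}
    crossings = []
    for k in range(m):
        a_end = arc_of_event[k]  # event k terminates arc a_end-1, starts arc a_end
        under_in = (a_end - 1) % m
        under_out = a_end
        over = _locate_arc(over_pos[k], positions)
        crossings.append(Crossing(over, under_in, under_out, signs[k]))
    return KnotDiagram(crossings)


def _locate_arc(pos: float, sorted_positions: list[float]) -> int:
    """Arc index whose open interval (pos_a, pos_{a+1}) contains ``pos``."""
    import bisect

    m = len(sorted_positions)
    idx = bisect.bisect_left(sorted_positions, pos)
    return (idx - 1) % m


def alexander_polynomial(diagram: KnotDiagram) -> tuple[int, ...]:
    """Normalized Alexander polynomial coefficients of a connected diagram.

    Returns the symmetric representative as an integer tuple, constant term
    positive, e.g. ``(1, -1, 1)`` for the trefoil and ``(1,)`` for the unknot.
    """
    m = len(diagram.crossings)
    if m == 0:
        return (1,)
    M = sp.zeros(m, m)
    for r, c in enumerate(diagram.crossings):
        if c.sign > 0:
            M[r, c.over_arc] += 1 - _T
            M[r, c.under_in] += -1
            M[r, c.under_out] += _T
        else:
            M[r, c.over_arc] += 1 - _T
            M[r, c.under_in] += _T
            M[r, c.under_out] += -1
    minor = M[: m - 1, : m - 1]
    if m == 1:
        det = sp.Integer(1)
    else:
        det = minor.det(method="bareiss")
    poly = sp.Poly(sp.expand(det), _T)
    coeffs = [int(c) for c in poly.all_coeffs()]  # descending powers
    return _normalize(coeffs)


def _normalize(coeffs: list[int]) -> tuple[int, ...]:
    # strip unit factors +-t^k
    while coeffs and coeffs[-1] == 0:
        coeffs.pop()
    while coeffs and coeffs[0] == 0:
        coeffs.pop(0)
    if not coeffs:
        raise ValueError("zero Alexander determinant: disconnected diagram")
    if coeffs[-1] < 0:
        coeffs = [-c for c in coeffs]
    # canonical orientation: a palindrome is its own reverse; otherwise pick
    # the lexicographically larger reading so the result is well defined
    rev = list(reversed(coeffs))
    if rev > coeffs:
        coeffs = rev
    return tuple(coeffs)


def alexander_determinant(coeffs: tuple[int, ...]) -> int:
    """|Delta(-1)|: odd for every knot, 1 for the unknot."""
    val = 0
    for k, c in enumerate(reversed(coeffs)):
        val += c * ((-1) ** k)
    return abs(val)


# Alexander polynomials of prime knots through seven crossings (symmetric
# representatives, descending powers).  Within this range the polynomial
# separates all knot types, so every entry maps to a single label; if a future
# extension introduces a collision the lookup joins the labels with '|'.
ALEXANDER_TABLE: dict[tuple[int, ...], str] = {
    (1,): "unknot",
    (1, -1, 1): "3_1",
    (1, -3, 1): "4_1",
    (1, -1, 1, -1, 1): "5_1",
    (2, -3, 2): "5_2",
    (2, -5, 2): "6_1",
    (1, -3, 3, -3, 1): "6_2",
    (1, -3, 5, -3, 1): "6_3",
    (1, -1, 1, -1, 1, -1, 1): "7_1",
    (3, -5, 3): "7_2",
    (2, -3, 3, -3, 2): "7_3",
    (4, -7, 4): "7_4",
    (2, -4, 5, -4, 2): "7_5",
    (1, -5, 7, -5, 1): "7_6",
    (1, -5, 9, -5, 1): "7_7",
}


def classify_knot(coeffs: tuple[int, ...]) -> str:
    """Label a normalized Alexander polynomial; unrecognized -> 'unknown'."""
    labels = [lab for key, lab in ALEXANDER_TABLE.items() if key == tuple(coeffs)]
    if not labels:
        return "unknown"
    return "|".join(labels)
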