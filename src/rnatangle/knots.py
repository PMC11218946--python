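"""Backbone knot detection for open chains.

The protocol: reduce the open backbone polyline with the KMT algorithm
(endpoints fixed), then close it many times by projecting both endpoints onto
a large sphere around the molecule and joining them through a random point on
that sphere; each closure is classified via the Alexander polynomial.  A chain
is called knotted when fewer than half of the closures are unknots.  A single
direct closure (straight segment between the endpoints) is computed as a
cross-check; chains that are probabilistically knotted but trivially closed
are flagged ambiguous.  Closures whose diagrams stay above the crossing budget
after reduction feed the "too tangled to check" (TTC) category.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .alexander import (
    GeneralPositionError,
    TooManyCrossingsError,
    alexander_polynomial,
    classify_knot,
    project_to_diagram,
)
from .geometry import drop_duplicate_vertices, is_closed, random_unit_vector, triangle_blocked

__all__ = [
    "KnotAssessment",
    "InvalidCoordinatesError",
    "kmt_reduce",
    "random_two_point_closure",
    "direct_closure",
    "classify_closed_curve",
    "assess_knot",
    "TOO_COMPLEX",
]

TOO_COMPLEX = "too_complex"

# closed curves longer than this skip the per-closure KMT pass: the shared
# open-chain reduction already ran, and chains this long head to TTC anyway
_PER_CLOSURE_KMT_CAP = 600


class InvalidCoordinatesError(ValueError):
    """The chain contains (near-)duplicate atom coordinates."""


@dataclass
class KnotAssessment:
    """Per-chain verdict of the stochastic-closure knot analysis."""

    chain_id: str
    closure_histogram: dict[str, int]
    dominant_label: str
    knotted: bool
    ttc: bool
    direct_closure_label: str
    ambiguous: bool
    seed: int
    n_closures: int
    unknot_fraction: float = field(default=0.0)

    def to_dict(self) -> dict:
        return {
            "chain_id": self.chain_id,
            "closure_histogram": dict(sorted(self.closure_histogram.items())),
            "dominant_label": self.dominant_label,
            "knotted": self.knotted,
            "ttc": self.ttc,
            "direct_closure_label": self.direct_closure_label,
            "ambiguous": self.ambiguous,
            "seed": self.seed,
            "n_closures": self.n_closures,
            "unknot_fraction": self.unknot_fraction,
        }


# ---------------------------------------------------------------------------
# KMT chain reduction
# ---------------------------------------------------------------------------

def kmt_reduce(
    points: np.ndarray,
    fixed_endpoints: bool = True,
    eps: float = 1e-9,
    max_passes: int = 10_000,
) -> np.ndarray:
    """Topology-preserving vertex deletion (Koniaris-Muthukumar-Taylor).

    A vertex ``v`` is deleted when the triangle ``(prev, v, next)`` is crossed
    by no other segment of the chain; the process iterates to a fixed point.
    Open chains keep their endpoints.  A closed input (first vertex repeated
    at the end) is treated cyclically and returned closed.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        return pts.copy()
    closed = is_closed(pts)
    if closed:
        pts = drop_duplicate_vertices(pts)
        if is_closed(pts):
            pts = pts[:-1]
    else:
        pts = drop_duplicate_vertices(pts)

    pts = [p for p in pts]
    for _ in range(max_passes):
        removed = False
        n = len(pts)
        if n <= (3 if closed else 3):
            break
        arr = np.asarray(pts)
        i = 1 if (not closed and fixed_endpoints) else 0
        while i < len(pts):
            n = len(pts)
            if n <= 3:
                break
            if not closed and fixed_endpoints and (i == 0 or i == n - 1):
                i += 1
                continue
            arr = np.asarray(pts)
            a = arr[(i - 1) % n]
            v = arr[i]
            b = arr[(i + 1) % n]
            if _triangle_clear(arr, i, a, v, b, closed, eps):
                del pts[i]
                removed = True
                # stay at same index: new vertex moved into place
            else:
                i += 1
        if not removed:
            break
    out = np.asarray(pts)
    if closed:
        out = np.vstack([out, out[:1]])
    return out


def _triangle_clear(arr, i, a, v, b, closed, eps) -> bool:
    n = len(arr)
    area2 = np.linalg.norm(np.cross(v - a, b - a))
    edge = max(np.linalg.norm(v - a), np.linalg.norm(b - a), 1e-12)
    if area2 < eps * edge:
        return True  # collinear: removing v is a no-op geometrically
    # segments sharing a vertex with the removal triangle cannot transversally
    # obstruct it (they meet it at a corner); excluding them is the standard
    # KMT bookkeeping for a simple (non-self-touching) chain
    if closed:
        seg_idx = np.arange(n)
        starts = arr
        ends = arr[(seg_idx + 1) % n]
        skip = {(i - 2) % n, (i - 1) % n, i, (i + 1) % n}
    else:
        starts = arr[:-1]
        ends = arr[1:]
        skip = {i - 2, i - 1, i, i + 1} & set(range(n - 1))
        seg_idx = np.arange(n - 1)
    keep = np.array([s not in skip for s in seg_idx])
    return not triangle_blocked((a, v, b), starts[keep], ends[keep], eps=eps)


# ---------------------------------------------------------------------------
# chain closures
# ---------------------------------------------------------------------------

def _slerp_arc(p: np.ndarray, q: np.ndarray, center: np.ndarray, radius: float,
               max_step_deg: float = 20.0) -> np.ndarray:
    """Points along the great-circle arc from p to q on the sphere (excl. ends)."""
    u = (p - center) / np.linalg.norm(p - center)
    v = (q - center) / np.linalg.norm(q - center)
    dot = float(np.clip(u @ v, -1.0, 1.0))
    ang = np.arccos(dot)
    if ang < 1e-9:
        return np.empty((0, 3))
    nsub = max(1, int(np.ceil(np.degrees(ang) / max_step_deg)))
    ts = np.linspace(0, 1, nsub + 1)[1:-1]
    sin_ang = np.sin(ang)
    pts = []
    for t in ts:
        w = (np.sin((1 - t) * ang) * u + np.sin(t * ang) * v) / sin_ang
        pts.append(center + radius * w)
    return np.asarray(pts).reshape(-1, 3)


def random_two_point_closure(
    points: np.ndarray,
    rng: np.random.Generator,
    radius_factor: float = 10.0,
) -> np.ndarray:
    """Close an open chain far outside its convex hull.

    Both endpoints are pushed radially from the chain centroid onto a sphere
    of radius ``radius_factor`` times the maximal centroid distance; the two
    sphere points are then joined by two great-circle arcs through a random
    point of the sphere, each approximated by short straight segments.  All
    closure vertices sit on the sphere, so every closure segment stays well
    outside the chain.  Returns a closed polyline (first point repeated).
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points to close")
    center = pts.mean(axis=0)
    extent = np.linalg.norm(pts - center, axis=1).max()
    radius = radius_factor * max(extent, 1e-6)

    def to_sphere(e):
        d = e - center
        nd = np.linalg.norm(d)
        if nd < 1e-9:
            d = np.array([1.0, 0.0, 0.0])
            nd = 1.0
        return center + radius * d / nd

    p_end = to_sphere(pts[-1])
    p_start = to_sphere(pts[0])
    for _ in range(100):
        q = center + radius * random_unit_vector(rng)
        cos_e = (q - center) @ (p_end - center) / radius**2
        cos_s = (q - center) @ (p_start - center) / radius**2
        if cos_e < 1 - 1e-6 and cos_s < 1 - 1e-6:
            break
    closure = [p_end]
    closure.extend(_slerp_arc(p_end, q, center, radius))
    closure.append(q)
    closure.extend(_slerp_arc(q, p_start, center, radius))
    closure.append(p_start)
    closed = np.vstack([pts, np.asarray(closure), pts[:1]])
    return drop_duplicate_vertices(closed)


def direct_closure(points: np.ndarray) -> np.ndarray:
    """Close a chain with one straight segment; closed input returned as-is."""
    pts = np.asarray(points, dtype=float)
    if is_closed(pts):
        return pts.copy()
    return np.vstack([pts, pts[:1]])


# ---------------------------------------------------------------------------
# classification of one closed curve
# ---------------------------------------------------------------------------

def classify_closed_curve(
    curve: np.ndarray,
    rng: np.random.Generator,
    crossing_budget: int | None = None,
    reduce_first: bool = True,
) -> str:
    """KMT-reduce a closed curve, project, and label its knot type.

    Returns a knot label, ``'unknown'`` for polynomials outside the lookup
    table, or ``'too_complex'`` when the diagram exceeds ``crossing_budget``
    or no generic projection is found.
    """
    pts = np.asarray(curve, dtype=float)
    if reduce_first and len(pts) <= _PER_CLOSURE_KMT_CAP:
        pts = kmt_reduce(pts)
    if len(pts) <= 4:  # closed triangle: trivially unknotted
        return "unknot"
    try:
        diagram = project_to_diagram(pts, rng, max_crossings=crossing_budget)
    except TooManyCrossingsError:
        return TOO_COMPLEX
    except GeneralPositionError:
        return TOO_COMPLEX
    try:
        coeffs = alexander_polynomial(diagram)
    except ValueError:
        return TOO_COMPLEX
    return classify_knot(coeffs)


# ---------------------------------------------------------------------------
# full assessment
# ---------------------------------------------------------------------------

def _check_unique(points: np.ndarray, tol: float = 1e-6) -> None:
    rounded = np.round(points / max(tol, 1e-12)).astype(np.int64)
    _, counts = np.unique(rounded, axis=0, return_counts=True)
    if (counts > 1).any():
        raise InvalidCoordinatesError("chain contains duplicate atom coordinates")


def assess_knot(
    chain,
    n_closures: int = 200,
    unknot_threshold: float = 0.5,
    crossing_budget: int = 50,
    seed: int = 0,
) -> KnotAssessment:
    """Run the full stochastic-closure protocol on one backbone chain.

    ``chain`` is a :class:`~rnatangle.structure_io.BackboneChain` or a bare
    ``(n, 3)`` polyline.  The closure histogram is bit-for-bit reproducible
    for a given ``(input, seed, n_closures)``: each closure draws from its own
    deterministic stream derived from the master seed and the closure index.
    """
    chain_id = getattr(chain, "chain_id", "chain")
    pts = np.asarray(getattr(chain, "points", chain), dtype=float)
    if len(pts) < 3:
        raise ValueError("chain too short for knot assessment")
    _check_unique(pts)

    reduced = kmt_reduce(pts, fixed_endpoints=True)

    direct_rng = np.random.default_rng([seed & 0x7FFFFFFF, 999_983])
    direct_label = classify_closed_curve(
        direct_closure(reduced), direct_rng, crossing_budget=crossing_budget
    )

    hist: Counter[str] = Counter()
    for i in range(n_closures):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, i])
        closed = random_two_point_closure(reduced, rng)
        label = classify_closed_curve(closed, rng, crossing_budget=crossing_budget)
        hist[label] += 1

    total = sum(hist.values())
    unknot_fraction = hist.get("unknot", 0) / total if total else 1.0
    knotted = unknot_fraction < unknot_threshold
    nontrivial = [(c, lab) for lab, c in hist.items() if lab != "unknot"]
    dominant = max(nontrivial)[1] if nontrivial else "unknot"
    ttc = (hist.get(TOO_COMPLEX, 0) / total if total else 0.0) > 0.2
    ambiguous = bool(knotted and direct_label == "unknot")
    return KnotAssessment(
        chain_id=chain_id,
        closure_histogram=dict(hist),
        dominant_label=dominant,
        knotted=knotted,
        ttc=ttc,
        direct_closure_label=direct_label,
        ambiguous=ambiguous,
        seed=seed,
        n_closures=n_closures,
        unknot_fraction=unknot_fraction,
    )
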