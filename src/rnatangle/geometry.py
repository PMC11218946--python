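"""Low-level 3D/2D geometry kernels shared by the knot and entanglement code.

Everything here operates on plain ``numpy`` arrays: polylines are ``(n, 3)``
float arrays, triangles are triples of vertices.  All tolerances are absolute
and in the length unit of the input (angstroms throughout the package).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "is_closed",
    "drop_duplicate_vertices",
    "random_unit_vector",
    "orthonormal_frame",
    "triangle_blocked",
    "segment_triangle_hits",
    "polyline_crossings_2d",
    "GeneralPositionError",
]


class GeneralPositionError(RuntimeError):
    """A projection direction produced a degenerate (non-generic) diagram."""


def is_closed(points: np.ndarray, tol: float = 1e-9) -> bool:
    """True when the first and last vertex of a polyline coincide."""
    points = np.asarray(points, dtype=float)
    return bool(np.linalg.norm(points[0] - points[-1]) <= tol)


def drop_duplicate_vertices(points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Remove consecutive vertices closer than ``tol`` (keeps the first)."""
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        return points
    keep = [0]
    for i in range(1, len(points)):
        if np.linalg.norm(points[i] - points[keep[-1]]) > tol:
            keep.append(i)
    return points[keep]


def random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def orthonormal_frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Right-handed frame ``(e1, e2, d)`` with ``d`` the normalized direction."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(d @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(helper, d)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2, d


# ---------------------------------------------------------------------------
# segment / triangle intersection (vectorized Moller-Trumbore)
# ---------------------------------------------------------------------------

def segment_triangle_hits(
    tri: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
    eps: float = 1e-9,
    interior_margin: float = 0.0,
):
    """Intersect a batch of segments with one triangle.

    Returns ``(mask, t, u, v)`` where ``mask`` selects segments that cross the
    triangle, ``t`` is the parameter along each segment and ``(u, v)`` the
    barycentric coordinates of the hit.  ``interior_margin`` shrinks the
    accepted barycentric region (used to demand strictly interior hits).
    Near-parallel segments are reported as misses; callers that need a
    conservative *blocked* answer should use :func:`triangle_blocked`.
    """
    a, b, c = (np.asarray(x, dtype=float) for x in tri)
    starts = np.asarray(starts, dtype=float)
    ends = np.asarray(ends, dtype=float)
    d = ends - starts
    e1 = b - a
    e2 = c - a
    h = np.cross(d, e2)
    det = h @ e1
    ok = np.abs(det) > eps
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    s = starts - a
    u = inv * np.einsum("ij,ij->i", s, h)
    q = np.cross(s, e1)
    v = inv * np.einsum("ij,ij->i", d, q)
    t = inv * (q @ e2)
    m = interior_margin
    mask = (
        ok
        & (u >= -eps + m)
        & (v >= -eps + m)
        & (u + v <= 1.0 + eps - m)
        & (t >= -eps)
        & (t <= 1.0 + eps)
    )
    return mask, t, u, v


def triangle_blocked(
    tri: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
    eps: float = 1e-9,
) -> bool:
    """Conservative test: does any segment touch the triangle?

    Used by the chain-reduction step, which must only delete a vertex when the
    removal triangle is provably clear.  Segments lying (near-)parallel to the
    triangle plane are treated as blocking whenever they come within ``eps`` of
    the plane while overlapping the triangle's bounding box, which errs on the
    side of keeping vertices.
    """
    a, b, c = (np.asarray(x, dtype=float) for x in tri)
    starts = np.asarray(starts, dtype=float)
    ends = np.asarray(ends, dtype=float)
    if len(starts) == 0:
        return False

    # quick AABB rejection
    tlo = np.minimum(np.minimum(a, b), c) - eps
    thi = np.maximum(np.maximum(a, b), c) + eps
    slo = np.minimum(starts, ends)
    shi = np.maximum(starts, ends)
    cand = np.all(shi >= tlo, axis=1) & np.all(slo <= thi, axis=1)
    if not cand.any():
        return False
    starts = starts[cand]
    ends = ends[cand]

    normal = np.cross(b - a, c - a)
    nn = np.linalg.norm(normal)
    if nn < 1e-14:
        # degenerate (collinear) triangle blocks nothing
        return False
    normal = normal / nn

    d = ends - starts
    e2 = c - a
    h = np.cross(d, e2)
    det = np.einsum("ij,j->i", h, b - a)
    parallel = np.abs(det) <= eps * np.maximum(1.0, np.linalg.norm(d, axis=1))
    if parallel.any():
        # a parallel segment blocks if it runs within eps of the plane
        ds = np.einsum("ij,j->i", starts[parallel] - a, normal)
        de = np.einsum("ij,j->i", ends[parallel] - a, normal)
        if np.any((np.abs(ds) <= 10 * eps) | (np.abs(de) <= 10 * eps)):
            return True
    nonpar = ~parallel
    if not nonpar.any():
        return False
    inv = 1.0 / det[nonpar]
    s = starts[nonpar] - a
    u = inv * np.einsum("ij,ij->i", s, h[nonpar])
    q = np.cross(s, b - a)
    v = inv * np.einsum("ij,ij->i", d[nonpar], q)
    t = inv * np.einsum("ij,j->i", q, e2)
    hit = (
        (u >= -eps)
        & (v >= -eps)
        & (u + v <= 1.0 + eps)
        & (t >= -eps)
        & (t <= 1.0 + eps)
    )
    return bool(hit.any())


# ---------------------------------------------------------------------------
# planar crossings of projected polylines
# ---------------------------------------------------------------------------

def _segment_pairs_intersect(p, d_p, q, d_q, eps):
    """Solve p + s*d_p = q + t*d_q for all broadcast pairs."""
    denom = d_p[:, None, 0] * d_q[None, :, 1] - d_p[:, None, 1] * d_q[None, :, 0]
    diff = q[None, :, :] - p[:, None, :]
    s_num = diff[..., 0] * d_q[None, :, 1] - diff[..., 1] * d_q[None, :, 0]
    t_num = diff[..., 0] * d_p[:, None, 1] - diff[..., 1] * d_p[:, None, 0]
    ok = np.abs(denom) > eps
    denom_safe = np.where(ok, denom, 1.0)
    s = s_num / denom_safe
    t = t_num / denom_safe
    return ok, s, t, denom


def polyline_crossings_2d(
    pts2d: np.ndarray,
    cyclic: bool,
    eps: float = 1e-9,
    vertex_margin: float = 1e-4,
):
    """All transversal self-crossings of a projected polyline.

    ``pts2d`` must not repeat the first vertex at the end; ``cyclic`` adds the
    wrap-around segment.  Returns a list of ``(i, s, j, t)`` with ``i < j``
    segment indices and parameters in ``(0, 1)``.  Raises
    :class:`GeneralPositionError` when a crossing falls within
    ``vertex_margin`` of a vertex or two segments are near-parallel while
    intersecting (the caller should re-project along a new direction).
    """
    pts2d = np.asarray(pts2d, dtype=float)
    if cyclic:
        starts = pts2d
        ends = np.roll(pts2d, -1, axis=0)
    else:
        starts = pts2d[:-1]
        ends = pts2d[1:]
    nseg = len(starts)
    d = ends - starts
    crossings = []
    # chunk rows to bound memory on long chains
    chunk = max(1, int(4_000_000 // max(nseg, 1)))
    for lo in range(0, nseg, chunk):
        hi = min(nseg, lo + chunk)
        ok, s, t, denom = _segment_pairs_intersect(starts[lo:hi], d[lo:hi], starts, d, eps)
        row = np.arange(lo, hi)[:, None]
        col = np.arange(nseg)[None, :]
        valid = col > row + 1
        if cyclic:
            valid &= ~((row == 0) & (col == nseg - 1))
        touching = (
            ok & valid
            & (s > -vertex_margin) & (s < 1 + vertex_margin)
            & (t > -vertex_margin) & (t < 1 + vertex_margin)
        )
        interior = (
            touching
            & (s > vertex_margin) & (s < 1 - vertex_margin)
            & (t > vertex_margin) & (t < 1 - vertex_margin)
        )
        if (touching & ~interior).any():
            raise GeneralPositionError("crossing too close to a vertex")
        ii, jj = np.nonzero(interior)
        for a_, b_ in zip(ii, jj):
            crossings.append((int(a_ + lo), float(s[a_, b_]), int(b_), float(t[a_, b_])))
        # near-parallel segment pairs: degenerate only if they nearly overlap
        bad = (~ok) & valid
        if bad.any():
            for a_, b_ in zip(*np.nonzero(bad)):
                i, j = a_ + lo, b_
                p0 = starts[i]
                q0, q1 = starts[j], ends[j]
                dp = d[i]
                L = np.linalg.norm(dp)
                if L < eps:
                    continue
                nvec = np.array([-dp[1], dp[0]]) / L
                off0 = abs((q0 - p0) @ nvec)
                off1 = abs((q1 - p0) @ nvec)
                if min(off0, off1) < vertex_margin:
                    ta = ((q0 - p0) @ dp) / (L * L)
                    tb = ((q1 - p0) @ dp) / (L * L)
                    if max(min(ta, tb), 0.0) <= min(max(ta, tb), 1.0):
                        raise GeneralPositionError("near-parallel overlapping segments")
    return crossings
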