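"""Detection and classification of entanglements of structure elements.

A closed element (loop or dinucleotide step) is spanned by a triangulated
surface; another element entangles it when its curve punctures that surface.
Two closed elements with non-zero Gauss linking number form an **interlace**
(X&Y); a punctured closed element with zero linking forms a **lasso** X(Y).
The nine subclasses combine loops (L), dinucleotide steps (D) and single
strands (S): L&L, L&D, D&D, L(S), L(D), L(L), D(S), D(D), D(L).

For lassos around a loop, L(*), the threading depth in nucleotides is
computed: with a single puncture the minimum residue count from the crossing
segment toward either strand end, with two punctures the residue count
between the crossing segments.  Depth <= 5 nt is *shallow*, > 5 nt *deep*.
Interlaces, D(*) lassos and deep L(*) lassos are flagged as modeling
artifacts; shallow L(*) lassos can plausibly disentangle during folding and
are not flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elements import StructuralElement, all_elements
from .geometry import GeneralPositionError, orthonormal_frame, random_unit_vector, segment_triangle_hits
from .structure_io import ResRef, RnaModel, SecondaryStructure

__all__ = [
    "SpanningSurface",
    "IntersectionPoint",
    "Entanglement",
    "span_surface",
    "find_punctures",
    "linking_number",
    "linking_number_gauss",
    "classify_pair",
    "lasso_depth",
    "detect_all",
    "SHALLOW_DEPTH_MAX",
]

SHALLOW_DEPTH_MAX = 5  # shallow: depth <= 5 nt; deep: depth > 5 nt
_MERGE_ALONG = 0.1  # punctures closer than this along the piercing curve merge (A)
_GEOM_EPS = 1e-6


@dataclass
class SpanningSurface:
    vertices: np.ndarray  # (m, 3)
    triangles: np.ndarray  # (k, 3) int indices, consistent winding
    boundary: np.ndarray  # closed polyline of the spanned element

    @property
    def area(self) -> float:
        a = self.vertices[self.triangles[:, 0]]
        b = self.vertices[self.triangles[:, 1]]
        c = self.vertices[self.triangles[:, 2]]
        return float(0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1).sum())


@dataclass
class IntersectionPoint:
    position: np.ndarray
    piercing_residues: tuple[ResRef, ResRef]
    piercing_provenance: str  # backbone | hydrogen_bond
    pierced_element: str  # element id
    crossing_sign: int
    along: float = 0.0  # arc-length position along the piercing curve


@dataclass
class Entanglement:
    subclass: str  # L&L, L&D, D&D, L(S), L(D), L(L), D(S), D(D), D(L)
    element_x: StructuralElement
    element_y: StructuralElement
    intersections: list[IntersectionPoint] = field(default_factory=list)
    linking: int = 0
    depth: int | None = None
    depth_class: str = "not_applicable"  # shallow | deep | not_applicable
    artifact: bool = False

    @property
    def is_interlace(self) -> bool:
        return "&" in self.subclass

    def to_dict(self) -> dict:
        return {
            "subclass": self.subclass,
            "element_x": self.element_x.describe(),
            "element_y": self.element_y.describe(),
            "n_intersections": len(self.intersections),
            "linking": self.linking,
            "depth": self.depth,
            "depth_class": self.depth_class,
            "artifact": self.artifact,
        }


# ---------------------------------------------------------------------------
# spanning surface
# ---------------------------------------------------------------------------

def span_surface(element: StructuralElement, subdivision_rounds: int = 3,
                 relax_iterations: int = 20) -> SpanningSurface:
    """Triangulated surface over a closed element.

    A triangle fan from the boundary centroid, followed by rounds of midpoint
    subdivision with Laplacian relaxation of the interior vertices (boundary
    vertices stay fixed, so the triangle edges on the boundary always cover
    the boundary polyline exactly).  Deterministic for a given boundary.
    """
    if not element.closed:
        raise ValueError("span_surface requires a closed element")
    boundary = np.asarray(element.curve, dtype=float)
    ring = boundary[:-1] if np.linalg.norm(boundary[0] - boundary[-1]) < 1e-9 else boundary
    n = len(ring)
    centroid = ring.mean(axis=0)
    verts = [np.asarray(p) for p in ring] + [centroid]
    tris = [(i, (i + 1) % n, n) for i in range(n)]
    fixed = set(range(n))

    verts = [np.asarray(v, dtype=float) for v in verts]
    for _ in range(subdivision_rounds):
        verts, tris, fixed = _subdivide(verts, tris, fixed)
        _relax(verts, tris, fixed, relax_iterations)
    return SpanningSurface(
        vertices=np.asarray(verts),
        triangles=np.asarray(tris, dtype=int),
        boundary=boundary,
    )


def _subdivide(verts, tris, fixed):
    mid_cache: dict[tuple[int, int], int] = {}

    def midpoint(a, b):
        key = (a, b) if a < b else (b, a)
        if key not in mid_cache:
            verts.append(0.5 * (verts[a] + verts[b]))
            idx = len(verts) - 1
            # an edge between two fixed vertices is always a boundary
            # subsegment in this fan construction (every interior edge has the
            # centroid or a later interior vertex as an endpoint), so its
            # midpoint lies on the boundary polyline and stays fixed
            if a in fixed and b in fixed:
                fixed.add(idx)
            mid_cache[key] = idx
        return mid_cache[key]

    new_tris = []
    for (a, b, c) in tris:
        ab = midpoint(a, b)
        bc = midpoint(b, c)
        ca = midpoint(c, a)
        new_tris.extend([(a, ab, ca), (ab, b, bc), (ca, bc, c), (ab, bc, ca)])
    return verts, new_tris, fixed


def _relax(verts, tris, fixed, iterations):
    n = len(verts)
    neighbors: list[set[int]] = [set() for _ in range(n)]
    for (a, b, c) in tris:
        neighbors[a].update((b, c))
        neighbors[b].update((a, c))
        neighbors[c].update((a, b))
    movable = [i for i in range(n) if i not in fixed]
    for _ in range(iterations):
        snapshot = [v.copy() for v in verts]
        for i in movable:
            nb = neighbors[i]
            if nb:
                verts[i] = np.mean([snapshot[k] for k in nb], axis=0)


# ---------------------------------------------------------------------------
# punctures
# ---------------------------------------------------------------------------

def find_punctures(surface: SpanningSurface, other: StructuralElement) -> list[IntersectionPoint]:
    """All points where ``other``'s curve pierces the surface.

    Crossing signs follow the surface orientation (the winding of the
    triangulation); hits within 0.1 A of each other along the piercing curve,
    or geometrically coincident (shared triangle edges), are merged.
    """
    curve = np.asarray(other.curve, dtype=float)
    starts = curve[:-1]
    ends = curve[1:]
    seg_len = np.linalg.norm(ends - starts, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    tri_v = surface.vertices
    A = tri_v[surface.triangles[:, 0]]
    B = tri_v[surface.triangles[:, 1]]
    C = tri_v[surface.triangles[:, 2]]
    hits = []
    d = ends - starts
    e1 = B - A
    e2 = C - A
    normals = np.cross(e1, e2)
    nn = np.linalg.norm(normals, axis=1)
    good = nn > 1e-12
    # batched Moller-Trumbore: segments x triangles, chunked over triangles
    chunk = max(1, int(2_000_000 // max(len(starts), 1)))
    for lo in range(0, len(A), chunk):
        sl = slice(lo, min(lo + chunk, len(A)))
        e2c = e2[sl]
        h = np.cross(d[:, None, :], e2c[None, :, :])  # (S, T, 3)
        det = np.einsum("stk,tk->st", h, e1[sl])
        ok = np.abs(det) > _GEOM_EPS
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        s_vec = starts[:, None, :] - A[None, sl, :]
        u = inv * np.einsum("stk,stk->st", s_vec, h)
        q = np.cross(s_vec, e1[None, sl, :])
        v = inv * np.einsum("sk,stk->st", d, q)
        t = inv * np.einsum("stk,tk->st", q, e2c)
        mask = (
            ok
            & good[None, sl]
            & (u >= -_GEOM_EPS)
            & (v >= -_GEOM_EPS)
            & (u + v <= 1.0 + _GEOM_EPS)
            & (t >= -_GEOM_EPS)
            & (t <= 1.0 + _GEOM_EPS)
        )
        for k, ti in zip(*np.nonzero(mask)):
            tg = lo + ti
            normal = normals[tg] / nn[tg]
            sign = 1 if d[k] @ normal > 0 else -1
            pos = starts[k] + t[k, ti] * d[k]
            along = cum[k] + t[k, ti] * seg_len[k]
            hits.append((along, pos, k, sign))
    hits.sort(key=lambda h: h[0])
    merged = []
    for along, pos, k, sign in hits:
        if merged:
            pa, pp = merged[-1][0], merged[-1][1]
            if abs(along - pa) < _MERGE_ALONG or np.linalg.norm(pos - pp) < 1e-4:
                continue
        merged.append((along, pos, k, sign))
    out = []
    for along, pos, k, sign in merged:
        ra, rb = other.segment_residues[k]
        out.append(
            IntersectionPoint(
                position=pos,
                piercing_residues=(ra, rb),
                piercing_provenance=other.segment_provenance[k],
                pierced_element=getattr(surface, "element_id", ""),
                crossing_sign=sign,
                along=along,
            )
        )
    return out


# ---------------------------------------------------------------------------
# linking number
# ---------------------------------------------------------------------------

def linking_number(a: np.ndarray, b: np.ndarray, seed: int = 0, max_tries: int = 50) -> int:
    """Gauss linking number of two closed polylines.

    Computed as half the sum of signed crossings between the two curves in a
    general-position projection; retried along fresh random directions when a
    projection is degenerate.
    """
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 77])
    pa = np.asarray(a, dtype=float)
    pb = np.asarray(b, dtype=float)
    if np.linalg.norm(pa[0] - pa[-1]) > 1e-9 or np.linalg.norm(pb[0] - pb[-1]) > 1e-9:
        raise ValueError("linking_number requires closed curves")
    pa = pa[:-1]
    pb = pb[:-1]
    for _ in range(max_tries):
        direction = random_unit_vector(rng)
        e1, e2, d = orthonormal_frame(direction)
        try:
            total = _signed_inter_crossings(pa, pb, e1, e2, d)
        except GeneralPositionError:
            continue
        half = total / 2.0
        return int(round(half))
    raise GeneralPositionError("no generic projection for linking number")


def _signed_inter_crossings(pa, pb, e1, e2, d):
    xa = np.column_stack([pa @ e1, pa @ e2])
    xb = np.column_stack([pb @ e1, pb @ e2])
    za = pa @ d
    zb = pb @ d
    sa = xa
    ea = np.roll(xa, -1, axis=0)
    sb = xb
    eb = np.roll(xb, -1, axis=0)
    da = ea - sa
    db = eb - sb
    dza = np.roll(za, -1) - za
    dzb = np.roll(zb, -1) - zb
    denom = da[:, None, 0] * db[None, :, 1] - da[:, None, 1] * db[None, :, 0]
    diff = sb[None, :, :] - sa[:, None, :]
    s_num = diff[..., 0] * db[None, :, 1] - diff[..., 1] * db[None, :, 0]
    t_num = diff[..., 0] * da[:, None, 1] - diff[..., 1] * da[:, None, 0]
    ok = np.abs(denom) > 1e-12
    denom_safe = np.where(ok, denom, 1.0)
    s = s_num / denom_safe
    t = t_num / denom_safe
    margin = 1e-7
    crossing = ok & (s > margin) & (s < 1 - margin) & (t > margin) & (t < 1 - margin)
    near = ok & (s > -margin) & (s < 1 + margin) & (t > -margin) & (t < 1 + margin) & ~crossing
    if near.any():
        raise GeneralPositionError("crossing at a vertex")
    total = 0
    ii, jj = np.nonzero(crossing)
    for i, j in zip(ii, jj):
        zi = za[i] + s[i, j] * dza[i]
        zj = zb[j] + t[i, j] * dzb[j]
        if abs(zi - zj) < 1e-9:
            raise GeneralPositionError("coincident depths")
        over_dir, under_dir = (da[i], db[j]) if zi > zj else (db[j], da[i])
        cr = over_dir[0] * under_dir[1] - over_dir[1] * under_dir[0]
        total += 1 if cr > 0 else -1
    return total


def linking_number_gauss(a: np.ndarray, b: np.ndarray) -> float:
    """Gauss linking integral evaluated exactly per segment pair.

    Independent of any projection; used as a cross-check of
    :func:`linking_number`.  Returns the (near-integer) real value.
    """
    pa = np.asarray(a, dtype=float)
    pb = np.asarray(b, dtype=float)
    if np.linalg.norm(pa[0] - pa[-1]) < 1e-9:
        pa = pa[:-1]
    if np.linalg.norm(pb[0] - pb[-1]) < 1e-9:
        pb = pb[:-1]
    total = 0.0
    nb = len(pb)
    for i in range(len(pa)):
        a1 = pa[i]
        a2 = pa[(i + 1) % len(pa)]
        for j in range(nb):
            total += _segment_pair_solid_angle(a1, a2, pb[j], pb[(j + 1) % nb])
    return total / (4.0 * np.pi)


def _segment_pair_solid_angle(p1, p2, p3, p4):
    r13, r14 = p3 - p1, p4 - p1
    r23, r24 = p3 - p2, p4 - p2
    r34 = p4 - p3
    r12 = p2 - p1
    n1 = np.cross(r13, r14)
    n2 = np.cross(r14, r24)
    n3 = np.cross(r24, r23)
    n4 = np.cross(r23, r13)
    for n in (n1, n2, n3, n4):
        norm = np.linalg.norm(n)
        if norm < 1e-14:
            return 0.0
    n1, n2, n3, n4 = (n / np.linalg.norm(n) for n in (n1, n2, n3, n4))
    s = (
        np.arcsin(np.clip(n1 @ n2, -1, 1))
        + np.arcsin(np.clip(n2 @ n3, -1, 1))
        + np.arcsin(np.clip(n3 @ n4, -1, 1))
        + np.arcsin(np.clip(n4 @ n1, -1, 1))
    )
    sign = np.sign(np.cross(r34, r12) @ r13)
    return s * sign


# ---------------------------------------------------------------------------
# classification and depth
# ---------------------------------------------------------------------------

def classify_pair(
    x: StructuralElement,
    y: StructuralElement,
    punctures: list[IntersectionPoint],
    lk: int | None = None,
) -> Entanglement | None:
    """Assign the entanglement subclass for a closed element ``x`` vs ``y``.

    Non-zero linking of two closed elements -> interlace (kinds joined with
    '&', D before L); zero linking with punctures -> lasso X(Y); an open
    strand with punctures -> lasso X(S); otherwise no entanglement.
    """
    if not x.closed:
        raise ValueError("element_x must be closed")
    if y.closed and lk is not None and lk != 0:
        kinds = sorted([x.letter, y.letter])  # D before L alphabetically
        ent = Entanglement(
            subclass=f"{kinds[0]}&{kinds[1]}",
            element_x=x,
            element_y=y,
            intersections=punctures,
            linking=lk,
            artifact=True,
        )
        return ent
    if punctures:
        ent = Entanglement(
            subclass=f"{x.letter}({y.letter})",
            element_x=x,
            element_y=y,
            intersections=punctures,
            linking=lk or 0,
        )
        if x.letter == "L":
            _annotate_depth(ent)
            ent.artifact = ent.depth_class == "deep"
        else:
            ent.artifact = True  # D(*) lassos are always artifacts
        return ent
    return None


def lasso_depth(ent: Entanglement, ss: SecondaryStructure | None = None) -> int | None:
    """Threading depth in nucleotides of an L(*) lasso.

    One puncture (strand through a loop): for each chain direction count the
    residues strictly beyond the crossing-adjacent residue on that side,
    through the strand's terminal unpaired residue; depth is the minimum of
    the two counts.  Two punctures: residues strictly between the two
    crossing segments.  Any other puncture count -> no depth.
    """
    y = ent.element_y
    paired: set[int] = set()
    if ss is not None:
        paired = ss.paired_indices(y.residues[0].chain_id)
    n_punct = len(ent.intersections)
    indices = [r.index for r in y.residues]
    if n_punct == 1:
        ra, rb = ent.intersections[0].piercing_residues
        lo = min(ra.index, rb.index)
        hi = max(ra.index, rb.index)
        before = [k for k in indices if k < lo and k not in paired]
        after = [k for k in indices if k > hi and k not in paired]
        return min(len(before), len(after))
    if n_punct == 2:
        segs = sorted(
            (min(p.piercing_residues[0].index, p.piercing_residues[1].index),
             max(p.piercing_residues[0].index, p.piercing_residues[1].index))
            for p in ent.intersections
        )
        (lo1, hi1), (lo2, hi2) = segs
        if hi1 > lo2:
            return 0
        return len([k for k in indices if hi1 <= k <= lo2])
    return None


def _annotate_depth(ent: Entanglement, ss: SecondaryStructure | None = None) -> None:
    depth = lasso_depth(ent, ss)
    ent.depth = depth
    if depth is None:
        ent.depth_class = "not_applicable"
    else:
        ent.depth_class = "shallow" if depth <= SHALLOW_DEPTH_MAX else "deep"


# ---------------------------------------------------------------------------
# full scan
# ---------------------------------------------------------------------------

def detect_all(
    model: RnaModel,
    ss: SecondaryStructure,
    subdivision_rounds: int = 3,
) -> list[Entanglement]:
    """All entanglements between structure elements of a model.

    Elements of all chains are pooled (inter-chain entanglements allowed);
    elements sharing a residue are never tested against each other.  Each
    interlace is reported once per unordered pair; every L(*) lasso carries
    its depth and shallow/deep class.
    """
    elements: list[StructuralElement] = []
    for chain in model.chains:
        elements.extend(all_elements(ss, chain))
    closed = [e for e in elements if e.closed]
    surfaces = {id(e): span_surface(e, subdivision_rounds) for e in closed}

    results: list[Entanglement] = []
    seen_interlace: set[frozenset[int]] = set()
    for x in closed:
        surf = surfaces[id(x)]
        setattr(surf, "element_id", x.element_id)
        for y in elements:
            if y is x or x.shares_residue(y):
                continue
            lk = None
            if y.closed:
                key = frozenset((id(x), id(y)))
                lk = linking_number(x.curve, y.curve)
                if lk != 0 and key in seen_interlace:
                    continue
            punct = find_punctures(surf, y)
            ent = classify_pair(x, y, punct, lk)
            if ent is None:
                continue
            if ent.is_interlace:
                seen_interlace.add(frozenset((id(x), id(y))))
            if ent.subclass.startswith("L(") and ent.depth is not None:
                # recompute depth with pairing information for anchor exclusion
                paired_aware = lasso_depth(ent, ss)
                ent.depth = paired_aware
                ent.depth_class = (
                    "shallow" if paired_aware <= SHALLOW_DEPTH_MAX else "deep"
                ) if paired_aware is not None else "not_applicable"
                if ent.subclass.startswith("L("):
                    ent.artifact = ent.depth_class == "deep"
            results.append(ent)
    return results
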