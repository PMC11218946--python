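"""Ground-truth fixture generators.

Every generator returns coordinates with a known topological truth — knot
type, entanglement subclass, lasso depth — fully determined by its
parameters, so detectors can be tested without downloading any real model.
RNA-like fixtures carry six backbone atoms per residue (P, O5', C5', C4',
C3', O3') at an idealized ~6 A per-residue spacing plus a C1' proxy atom, and
are written as plain PDB files with a layered dot-bracket sidecar encoding
the designed pairing.

The geometries emulate the entanglement archetypes seen in predicted RNA
models: a hairpin whose apical loop is threaded by the chain's free end
(L(S) lasso of programmable depth), two hairpin loops forming a Hopf-linked
L&L interlace in place of kissing loops, a strand pushed through a helix
dinucleotide step (D(S)), plus open knotted backbones (torus and twist
knots) and densely packed random walks that defeat knot classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .structure_io import BACKBONE_ATOMS, ChainRecord, Residue, RnaModel

__all__ = [
    "FixtureSpec",
    "ParameterError",
    "make_knot_curve",
    "make_hairpin_lasso",
    "make_hopf_loops",
    "make_dinucleotide_pierce",
    "make_dense_walk",
    "make_helix_model",
    "model_from_polyline",
    "write_fixture",
    "TWIST_TEMPLATES",
]


class ParameterError(ValueError):
    pass


@dataclass
class FixtureSpec:
    """Declarative description of a fixture and its expected labels."""

    kind: str
    parameters: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# knotted space curves
# ---------------------------------------------------------------------------

# 4-plat braid words (generator index, sign) whose plat closures realize the
# twist knots; validated against the closed-form twist-knot Alexander
# polynomials (k half-twists: middle coefficient -(k+1) resp. -k pattern)
TWIST_TEMPLATES: dict[str, list[tuple[int, int]]] = {
    "3_1": [(2, 1), (1, -1), (2, 1)],
    "4_1": [(2, 1), (1, -1), (2, 1), (2, 1)],
    "5_2": [(2, 1), (1, -1), (1, -1), (2, 1), (2, 1)],
    "6_1": [(2, 1), (1, -1), (1, -1), (1, -1), (2, 1), (2, 1)],
    "7_2": [(2, 1), (2, 1), (2, 1), (2, 1), (2, 1), (1, -1), (2, 1)],
}


def _plat_closure(word: list[tuple[int, int]], spread: float = 3.0, zo: float = 1.2) -> np.ndarray:
    """Closed polygonal curve realizing the plat closure of a 4-strand braid."""
    nslots = 4
    slot_of = list(range(nslots))
    paths: dict[int, list[np.ndarray]] = {
        k: [np.array([0.0, spread * k, 0.0])] for k in range(nslots)
    }
    x = 0.0
    for gen, sign in word:
        g = gen - 1
        x += 1.0
        sa, sb = slot_of[g], slot_of[g + 1]
        mid_y = spread * (g + 0.5)
        paths[sa].append(np.array([x - 0.5, mid_y, zo if sign > 0 else -zo]))
        paths[sb].append(np.array([x - 0.5, mid_y, -zo if sign > 0 else zo]))
        slot_of[g], slot_of[g + 1] = sb, sa
        for k in range(nslots):
            paths[slot_of[k]].append(np.array([x, spread * k, 0.0]))
    conn: dict = {}

    def cap(p1, p2, dx):
        return [(p1 + p2) / 2 + np.array([dx, 0.0, 0.0])]

    for (s1, s2) in [(0, 1), (2, 3)]:
        c = cap(paths[s1][0], paths[s2][0], -2.0)
        conn[(s1, "start")] = ((s2, "start"), c)
        conn[(s2, "start")] = ((s1, "start"), list(reversed(c)))
    for (k1, k2) in [(0, 1), (2, 3)]:
        s1, s2 = slot_of[k1], slot_of[k2]
        c = cap(paths[s1][-1], paths[s2][-1], +2.0)
        conn[(s1, "end")] = ((s2, "end"), c)
        conn[(s2, "end")] = ((s1, "end"), list(reversed(c)))
    pts: list[np.ndarray] = []
    cur, endpt = 0, "start"
    visited: set[int] = set()
    while cur not in visited:
        visited.add(cur)
        path = paths[cur] if endpt == "start" else list(reversed(paths[cur]))
        pts.extend(path)
        other_end = "end" if endpt == "start" else "start"
        (nxt, nend), c = conn[(cur, other_end)]
        pts.extend(c)
        cur, endpt = nxt, nend
    if len(visited) != nslots:
        raise ParameterError("braid word closes into a link, not a knot")
    pts.append(pts[0])
    return np.asarray(pts)


def _resample(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a polyline at (approximately) uniform arc-length spacing."""
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    n = max(int(round(total / spacing)), 4)
    targets = np.linspace(0.0, total, n + 1)
    out = np.empty((n + 1, 3))
    for d in range(3):
        out[:, d] = np.interp(targets, cum, pts[:, d])
    return out


def make_knot_curve(
    kind: str,
    params=None,
    n_points: int = 200,
    open_fraction: float = 0.0,
    scale: float = 10.0,
):
    """Parametric or template space curve of a known knot type.

    ``kind='torus'`` with ``params=(p, q)`` (coprime) gives the torus knot
    T(p, q) — T(2,3)=3_1, T(2,5)=5_1, T(2,7)=7_1; ``kind='twist'`` with
    ``params`` one of the labels in :data:`TWIST_TEMPLATES` gives a polygonal
    twist-knot template; ``kind='unknot'`` gives a circle.  ``open_fraction``
    removes a terminal arc (the knot core stays intact for small fractions).
    Returns ``(points, truth_label)``.
    """
    if kind == "torus":
        p, q = params if params is not None else (2, 3)
        if math.gcd(p, q) != 1:
            raise ParameterError(f"torus knot requires coprime (p, q), got {(p, q)}")
        if n_points < 50:
            raise ParameterError("n_points must be >= 50 for a faithful torus knot")
        th = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
        R, r = 2.0, 1.0
        pts = np.column_stack(
            [
                (R + r * np.cos(q * th)) * np.cos(p * th),
                (R + r * np.cos(q * th)) * np.sin(p * th),
                -r * np.sin(q * th),
            ]
        ) * (scale / 2.0)
        label = _torus_label(p, q)
        curve = np.vstack([pts, pts[:1]])
    elif kind == "twist":
        label = str(params)
        if label not in TWIST_TEMPLATES:
            raise ParameterError(f"no twist template for {label!r}")
        raw = _plat_closure(TWIST_TEMPLATES[label]) * scale
        curve = _resample(raw, spacing=6.0)
    elif kind == "unknot":
        th = np.linspace(0, 2 * np.pi, max(n_points, 12), endpoint=False)
        pts = np.column_stack([np.cos(th), np.sin(th), np.zeros_like(th)]) * scale
        curve = np.vstack([pts, pts[:1]])
        label = "unknot"
    else:
        raise ParameterError(f"unknown curve kind {kind!r}")
    if open_fraction > 0:
        open_pts = curve[:-1]
        keep = int(round(len(open_pts) * (1.0 - open_fraction)))
        if keep < 4:
            raise ParameterError("open_fraction removes too much of the curve")
        return open_pts[:keep], label
    return curve, label


def _torus_label(p: int, q: int) -> str:
    p, q = sorted((abs(p), abs(q)))
    if p <= 1:
        return "unknot"
    if p == 2:
        return f"{q}_1"
    raise ParameterError(f"no standard label wired for torus knot T({p},{q})")


def make_dense_walk(n_steps: int = 1200, box: float = 15.0, seed: int = 0,
                    step: float = 3.0) -> np.ndarray:
    """Random walk confined to a small box: far too tangled to classify.

    Emulates the non-physically dense predicted models that defeat knot-type
    assignment.  Deterministic for a fixed seed.
    """
    if n_steps < 1000:
        raise ParameterError("dense walk needs n_steps >= 1000")
    rng = np.random.default_rng(seed)
    pts = np.empty((n_steps, 3))
    pos = np.full(3, box / 2.0)
    for i in range(n_steps):
        d = rng.normal(size=3)
        d *= step / np.linalg.norm(d)
        pos = pos + d
        # reflecting walls keep the chain inside without stacking points
        # exactly on the box faces
        for k in range(3):
            if pos[k] < 0.0:
                pos[k] = -pos[k]
            elif pos[k] > box:
                pos[k] = 2.0 * box - pos[k]
        pts[i] = pos
    return pts


# ---------------------------------------------------------------------------
# RNA-like model construction
# ---------------------------------------------------------------------------

def _leg(a, b, spacing=6.0):
    """Anchor points from just after ``a`` to exactly ``b``."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n = max(1, int(round(np.linalg.norm(b - a) / spacing)))
    return [a + (b - a) * k / n for k in range(1, n + 1)]


def _route(waypoints, spacing=6.0):
    out = [np.asarray(waypoints[0], float)]
    for w in waypoints[1:]:
        out.extend(_leg(out[-1], w, spacing))
    return out


def _model_from_anchors(
    anchors,
    pairs,
    model_id: str,
    chain_id: str = "A",
    bases: list[str] | None = None,
) -> RnaModel:
    """Residues with 6 idealized backbone atoms + C1' along an anchor path.

    ``pairs`` are (i, j) chain-index pairs; paired residues get G/C bases and
    their C1' pushed toward the partner so hydrogen-bond proxy geometry is
    sensible.  Unpaired residues default to A.
    """
    anchors = [np.asarray(a, float) for a in anchors]
    n = len(anchors)
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
    if bases is None:
        bases = []
        for k in range(n):
            if k in partner:
                bases.append("G" if k < partner[k] else "C")
            else:
                bases.append("A")
    residues = []
    for k in range(n):
        if k + 1 < n:
            d = anchors[k + 1] - anchors[k]
        else:
            d = anchors[k] - anchors[k - 1]
        atoms = {}
        for j, name in enumerate(BACKBONE_ATOMS):
            atoms[name] = anchors[k] + d * (j / 6.0)
        if k in partner:
            v = anchors[partner[k]] - anchors[k]
        else:
            v = np.cross(d, [0.0, 0.0, 1.0])
            if np.linalg.norm(v) < 1e-6:
                v = np.cross(d, [0.0, 1.0, 0.0])
        v = v - (v @ d) * d / max(d @ d, 1e-12)
        nv = np.linalg.norm(v)
        v = v / nv if nv > 1e-9 else np.zeros(3)
        atoms["C1'"] = anchors[k] + d * 0.4 + v * 1.5
        residues.append(Residue(number=k + 1, icode="", base=bases[k], atoms=atoms))
    chain = ChainRecord(chain_id=chain_id, residues=residues)
    return RnaModel(model_id=model_id, chains=[chain])


def _dotbracket(n: int, pairs) -> str:
    out = ["."] * n
    for i, j in pairs:
        out[i] = "("
        out[j] = ")"
    return "".join(out)


def _hairpin_layout(loop_size: int, stem_len: int):
    """Anchor positions and pairs for a planar hairpin in the z=0 plane.

    The apical loop sits on a circle centred at the origin (closing-pair
    residues at 240 and -60 degrees); the stem extends towards -y.  Returns
    ``(anchors, pairs, loop_radius)`` with chain order 5' stem strand, loop
    arc, 3' stem strand.
    """
    if loop_size < 4:
        raise ParameterError("loop_size must be >= 4")
    arc_span = math.radians(300.0)
    rl = 6.0 * (loop_size + 1) / arc_span
    a0 = math.radians(240.0)
    angles = [a0 - arc_span * k / (loop_size + 1) for k in range(loop_size + 2)]
    ring = [rl * np.array([math.cos(t), math.sin(t), 0.0]) for t in angles]
    p_start, p_end = ring[0], ring[-1]
    strand_a = [p_start + np.array([0.0, -6.0 * k, 0.0]) for k in range(stem_len, 0, -1)]
    strand_b = [p_end + np.array([0.0, -6.0 * k, 0.0]) for k in range(1, stem_len + 1)]
    anchors = strand_a + ring + strand_b
    pairs = [(stem_len, stem_len + loop_size + 1)]  # closing pair
    nb0 = stem_len + loop_size + 2
    for k in range(stem_len):
        pairs.append((k, nb0 + (stem_len - 1 - k)))
    return anchors, sorted(pairs), rl


def make_hairpin_lasso(
    loop_size: int = 6,
    depth: int = 7,
    seed: int = 0,
    stem_len: int = 4,
    threaded: bool = True,
):
    """Stem-loop whose apical loop is threaded once by the chain's 3' tail.

    The tail crosses the loop plane exactly once, between two consecutive
    residues, leaving exactly ``depth`` unpaired residues beyond the crossing
    towards the free 3' end (the 5'-side count is longer, so the depth
    convention returns ``depth`` exactly).  With ``threaded=False`` the tail
    rises outside the loop: a negative control with no entanglement.
    Returns ``(model, dotbracket, truth_dict)``.
    """
    if depth < 1:
        raise ParameterError("depth must be >= 1")
    anchors, pairs, rl = _hairpin_layout(loop_size, stem_len)
    sb = anchors[-1]  # 3' stem bottom
    rise_x = 0.0 if threaded else rl + 22.0
    pre = _route(
        [
            sb,
            np.array([rl + 14.0, sb[1], -5.0]),
            np.array([rl + 14.0, 20.0, -11.5]),
            np.array([rise_x, 6.0, -11.5]),
            np.array([rise_x, 0.0, -11.5]),
        ]
    )[1:]
    n_pre_unpaired = len(pre) + 1  # + the crossing residue itself
    if n_pre_unpaired <= depth:
        raise ParameterError(
            f"depth {depth} infeasible: only {n_pre_unpaired} residues before the crossing"
        )
    crossing = [np.array([rise_x, 0.0, -5.5]), np.array([rise_x, 0.0, 0.5])]
    post = [np.array([rise_x, 0.0, 6.5])]
    direction = np.array([1.2, -0.8, 5.8])
    direction *= 6.0 / np.linalg.norm(direction)
    for k in range(1, depth):
        post.append(post[-1] + direction)
    tail = pre + crossing + post
    all_anchors = anchors + tail
    model = _model_from_anchors(all_anchors, pairs, model_id=f"hairpin_lasso_d{depth}")
    db = _dotbracket(len(all_anchors), pairs)
    r_cross = len(anchors) + len(pre)  # crossing between r_cross and r_cross+1
    truth = {
        "subclass": "L(S)" if threaded else None,
        "depth": depth if threaded else None,
        "depth_class": (
            ("shallow" if depth <= 5 else "deep") if threaded else None
        ),
        "crossing_residues": (r_cross, r_cross + 1) if threaded else None,
        "n_entanglements": 1 if threaded else 0,
    }
    return model, db, truth


def make_hopf_loops(seed: int = 0, linked: bool = True, loop_size: int = 6,
                    stem_len: int = 3):
    """Two hairpin loops in one chain forming a Hopf-linked L&L interlace.

    Loop A lies in the z=0 plane centred at the origin; loop B is rotated
    into the y=0 plane and centred on loop A's circle, so the two loop cycles
    have linking number +-1 (misfolded 'kissing loops').  With
    ``linked=False`` loop B is translated away: no entanglement.
    Returns ``(model, dotbracket, truth_dict)``.
    """
    anchors_a, pairs_a, rl = _hairpin_layout(loop_size, stem_len)
    anchors_b_local, pairs_b_local, _ = _hairpin_layout(loop_size, stem_len)
    shift = rl if linked else rl + 30.0

    def xform(p):
        return np.array([p[0] + shift, p[2], p[1]])

    anchors_b = [xform(p) for p in anchors_b_local]
    sb_a = anchors_a[-1]
    b_first = anchors_b[0]
    linker = _route(
        [
            sb_a,
            np.array([rl + 6.0, sb_a[1] - 5.0, -8.0]),
            np.array([rl + 6.0, sb_a[1] - 5.0, -32.0]),
            np.array([b_first[0], -8.0, -32.0]),
            b_first - np.array([0.0, 6.0, 6.0]),
        ]
    )[1:]
    all_anchors = anchors_a + linker + anchors_b
    off = len(anchors_a) + len(linker)
    pairs = list(pairs_a) + [(i + off, j + off) for i, j in pairs_b_local]
    model = _model_from_anchors(all_anchors, pairs, model_id="hopf_loops" if linked else "hopf_unlinked")
    db = _dotbracket(len(all_anchors), pairs)
    truth = {
        "subclass": "L&L" if linked else None,
        "n_entanglements": 1 if linked else 0,
        "abs_linking": 1 if linked else 0,
    }
    return model, db, truth


def make_dinucleotide_pierce(seed: int = 0, threaded: bool = True,
                             stem_len: int = 4, loop_size: int = 4):
    """A 3' tail pushed through a middle dinucleotide step of a hairpin stem.

    The tail pierces the quadrilateral of the stacked pairs (1, 2) (counted
    from the stem base) exactly once: a D(S) lasso.  With ``threaded=False``
    the tail rises far from the stem: no entanglement.
    Returns ``(model, dotbracket, truth_dict)``.
    """
    anchors, pairs, rl = _hairpin_layout(loop_size, stem_len)
    sb = anchors[-1]
    # pierce between the stem pairs at heights of strand-A indices 1 and 2
    y_quad = float(anchors[1][1] + anchors[2][1]) / 2.0
    rise_x = 0.0 if threaded else rl + 25.0
    pre = _route(
        [
            sb,
            np.array([rl + 10.0, sb[1] - 4.0, -5.0]),
            np.array([rl + 10.0, y_quad, -11.5]),
            np.array([rise_x, y_quad, -11.5]),
        ]
    )[1:]
    crossing = [np.array([rise_x, y_quad, -5.5]), np.array([rise_x, y_quad, 0.5])]
    post = [np.array([rise_x, y_quad, 6.5]), np.array([rise_x - 4.0, y_quad - 6.0, 10.5])]
    all_anchors = anchors + pre + crossing + post
    model = _model_from_anchors(all_anchors, pairs, model_id="step_pierce" if threaded else "step_clear")
    db = _dotbracket(len(all_anchors), pairs)
    truth = {
        "subclass": "D(S)" if threaded else None,
        "n_entanglements": 1 if threaded else 0,
    }
    return model, db, truth


def make_helix_model(n_bp: int = 6, loop_size: int = 4) -> tuple[RnaModel, list[tuple[int, int]]]:
    """Idealized G-C hairpin helix with explicit donor/acceptor base atoms.

    Built to satisfy the geometric canonical-pair criteria exactly
    (C1'-C1' ~10.4 A, hydrogen-bond atom distances ~2.9 A), for testing the
    detect mode of base-pair annotation.  Returns ``(model, designed_pairs)``.
    """
    twist = math.radians(32.7)
    rise = 3.3
    r_bb, r_c1, r_hb = 9.2, 5.2, 1.45
    anchors = []
    n = n_bp
    for k in range(n):  # 5' strand ascending
        t = twist * k
        anchors.append(np.array([r_bb * math.cos(t), r_bb * math.sin(t), rise * k]))
    top = rise * n + 6.0
    for k in range(loop_size):  # unpaired connector over the top
        t = twist * (n - 1) + (math.pi) * (k + 1) / (loop_size + 1)
        anchors.append(np.array([r_bb * math.cos(t), r_bb * math.sin(t), top]))
    for k in range(n - 1, -1, -1):  # 3' strand descending
        t = twist * k + math.pi
        anchors.append(np.array([r_bb * math.cos(t), r_bb * math.sin(t), rise * k]))
    pairs = [(k, 2 * n + loop_size - 1 - k) for k in range(n)]
    bases = ["G"] * n + ["A"] * loop_size + ["C"] * n
    model = _model_from_anchors(anchors, pairs, model_id="ideal_helix", bases=bases)
    chain = model.chains[0]
    # overwrite C1' and add canonical G-C hydrogen-bond atoms at exact geometry
    for (i, j) in pairs:
        t = twist * i
        u = np.array([math.cos(t), math.sin(t), 0.0])
        perp = np.array([-math.sin(t), math.cos(t), 0.0])
        mid = np.array([0.0, 0.0, rise * i])
        gi, cj = chain.residues[i], chain.residues[j]
        gi.atoms["C1'"] = mid + u * r_c1
        cj.atoms["C1'"] = mid - u * r_c1
        for off, (ga, ca) in zip((-1.1, 0.0, 1.1), (("N2", "O2"), ("N1", "N3"), ("O6", "N4"))):
            gi.atoms[ga] = mid + u * r_hb + perp * off
            cj.atoms[ca] = mid - u * r_hb + perp * off
    return model, pairs


def model_from_polyline(points: np.ndarray, model_id: str, spacing: float = 6.0) -> RnaModel:
    """Wrap a bare space curve as a poly-U backbone trace."""
    anchors = _resample(np.asarray(points, float), spacing)
    bases = ["U"] * len(anchors)
    return _model_from_anchors(anchors, [], model_id=model_id, bases=bases)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_fixture(model_or_points, out_path, dotbracket: str | None = None) -> Path:
    """Write a fixture as a PDB file (+ optional dot-bracket sidecar).

    Bare polylines are converted to poly-U backbone traces first.  The
    sidecar (``<stem>.dbn``) holds one sequence line and one structure line.
    """
    out_path = Path(out_path)
    if isinstance(model_or_points, RnaModel):
        model = model_or_points
    else:
        model = model_from_polyline(np.asarray(model_or_points, float), out_path.stem)
    structure = gemmi.Structure()
    structure.name = model.model_id
    gmodel = gemmi.Model("1")
    for chain in model.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.base if res.base in "ACGU" else "N"
            gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
            for name, xyz in res.atoms.items():
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(name[0])
                atom.pos = gemmi.Position(*map(float, xyz))
                gres.add_atom(atom)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    structure.add_model(gmodel)
    structure.setup_entities()
    structure.write_pdb(str(out_path))
    if dotbracket is not None:
        seq = "".join(
            res.base if res.base in "ACGU" else "N"
            for chain in model.chains
            for res in chain.residues
        )
        out_path.with_suffix(".dbn").write_text(f"{seq}\n{dotbracket}\n")
    return out_path
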