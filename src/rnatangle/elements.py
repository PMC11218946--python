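"""Decomposition of a secondary structure into spatial structure elements.

Three element kinds are built on top of the canonical pair set of a chain:

* **loops (L)** — closed cycles alternating backbone arcs with hydrogen-bond
  edges: a closing pair plus the maximal set of directly enclosed pairs
  (hairpin, internal, and multibranch loop cycles alike);
* **dinucleotide steps (D)** — closed quadrilaterals formed by two
  consecutive stacked pairs (i, j), (i+1, j-1);
* **single strands (S)** — maximal unpaired runs, extended by their flanking
  paired anchor residues, as open polylines.

Each element carries an ordered 3D curve: backbone segments traverse the six
backbone atoms of every residue, hydrogen-bond edges are single straight
segments between per-residue pairing proxy points (mean of the canonical
donor/acceptor atoms when present, else C1').  Pseudoknotted pairs take part
in loop decomposition within their own crossing-free layer, so a hairpin
closed by a pseudoknotted pair yields a loop exactly like a nested pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .structure_io import (
    BACKBONE_ATOMS,
    ChainRecord,
    ResRef,
    SecondaryStructure,
    _pattern_for,
)

logger = logging.getLogger(__name__)

__all__ = ["StructuralElement", "find_loops", "find_dinucleotide_steps",
           "find_single_strands", "build_curve", "all_elements", "KIND_LETTER"]

KIND_LETTER = {"loop": "L", "dinucleotide_step": "D", "single_strand": "S"}


@dataclass
class StructuralElement:
    kind: str  # loop | dinucleotide_step | single_strand
    closed: bool
    residues: list[ResRef]
    curve: np.ndarray  # (n, 3)
    segment_provenance: list[str]  # per curve segment: backbone | hydrogen_bond
    segment_residues: list[tuple[ResRef, ResRef]]  # residues bounding each segment
    element_id: str = ""

    @property
    def letter(self) -> str:
        return KIND_LETTER[self.kind]

    def shares_residue(self, other: "StructuralElement") -> bool:
        return bool(set(self.residues) & set(other.residues))

    def describe(self) -> str:
        rs = self.residues
        return f"{self.letter}[{rs[0].chain_id}:{rs[0].index}-{rs[-1].index}]"


# ---------------------------------------------------------------------------
# decomposition on the pair list
# ---------------------------------------------------------------------------

def _chain_pairs_by_layer(ss: SecondaryStructure, chain_id: str):
    by_layer: dict[int, list[tuple[int, int]]] = {}
    for p in ss.pairs_of_chain(chain_id):
        lvl = ss.layers.get(p, 0)
        by_layer.setdefault(lvl, []).append((p.i.index, p.j.index))
    for v in by_layer.values():
        v.sort()
    return by_layer


def _direct_children(pair, pairs_sorted):
    """Directly enclosed pairs of (i, j) within one crossing-free layer."""
    i, j = pair
    children = []
    k = i + 1
    inside = {a: b for a, b in pairs_sorted}
    while k < j:
        if k in inside and inside[k] < j:
            children.append((k, inside[k]))
            k = inside[k] + 1
        else:
            k += 1
    return children


def find_loops(ss: SecondaryStructure, chain: ChainRecord) -> list[StructuralElement]:
    """One loop element per cycle of the standard loop decomposition.

    Helix-interior cycles of two stacked pairs are dinucleotide steps, not
    loops, and are skipped here.
    """
    out = []
    for _layer, pairs in sorted(_chain_pairs_by_layer(ss, chain.chain_id).items()):
        for (i, j) in pairs:
            children = _direct_children((i, j), pairs)
            if children == [(i + 1, j - 1)]:
                continue  # helix interior: a dinucleotide step
            element = _build_loop_element(chain, (i, j), children)
            if element is not None:
                out.append(element)
    for n, el in enumerate(out):
        el.element_id = f"{chain.chain_id}:L{n}"
    return out


def find_dinucleotide_steps(ss: SecondaryStructure, chain: ChainRecord) -> list[StructuralElement]:
    """One closed quadrilateral per pair of consecutive stacked pairs."""
    pair_set = set()
    for p in ss.pairs_of_chain(chain.chain_id):
        pair_set.add((p.i.index, p.j.index))
    out = []
    for (i, j) in sorted(pair_set):
        if (i + 1, j - 1) in pair_set:
            el = _build_step_element(chain, (i, j), (i + 1, j - 1))
            if el is not None:
                out.append(el)
    for n, el in enumerate(out):
        el.element_id = f"{chain.chain_id}:D{n}"
    return out


def find_single_strands(ss: SecondaryStructure, chain: ChainRecord) -> list[StructuralElement]:
    """Maximal unpaired runs extended by flanking paired anchors.

    A hairpin-interior run (whose two anchors pair with each other) is wholly
    contained in its loop element and is not emitted as a separate strand.
    """
    paired = ss.paired_indices(chain.chain_id)
    partner_of = {}
    for p in ss.pairs_of_chain(chain.chain_id):
        partner_of[p.i.index] = p.j.index
        partner_of[p.j.index] = p.i.index
    n = len(chain.residues)
    out = []
    i = 0
    while i < n:
        if i in paired:
            i += 1
            continue
        j = i
        while j + 1 < n and (j + 1) not in paired:
            j += 1
        lo = i - 1 if i - 1 >= 0 else None
        hi = j + 1 if j + 1 < n else None
        if lo is not None and hi is not None and partner_of.get(lo) == hi:
            i = j + 1
            continue  # hairpin interior
        indices = list(range(lo if lo is not None else i, (hi if hi is not None else j) + 1))
        el = _build_strand_element(chain, indices)
        if el is not None:
            out.append(el)
        i = j + 1
    for n_, el in enumerate(out):
        el.element_id = f"{chain.chain_id}:S{n_}"
    return out


def all_elements(ss: SecondaryStructure, chain: ChainRecord) -> list[StructuralElement]:
    return (
        find_loops(ss, chain)
        + find_dinucleotide_steps(ss, chain)
        + find_single_strands(ss, chain)
    )


# ---------------------------------------------------------------------------
# curves
# ---------------------------------------------------------------------------

def _proxy_point(chain: ChainRecord, idx: int, partner_idx: int | None) -> np.ndarray | None:
    """Hydrogen-bond edge endpoint for a residue: mean of its canonical
    donor/acceptor atoms toward the partner when present, else C1'."""
    res = chain.residues[idx]
    if partner_idx is not None:
        other = chain.residues[partner_idx]
        pattern, _ = _pattern_for(res.base, other.base)
        if pattern:
            pts = [res.atom(a) for a, _b in pattern]
            pts = [p for p in pts if p is not None]
            if pts:
                return np.mean(pts, axis=0)
    for name in ("C1'", "C4'", "P"):
        p = res.atom(name)
        if p is not None:
            return p
    if res.atoms:
        return next(iter(res.atoms.values()))
    return None


def _backbone_atoms(chain: ChainRecord, idx: int) -> list[np.ndarray]:
    res = chain.residues[idx]
    return [res.atoms[n] for n in BACKBONE_ATOMS if n in res.atoms]


def _dedupe(points, provenance, seg_res):
    """Remove zero-length segments (consecutive duplicate vertices)."""
    out_p = [points[0]]
    out_prov, out_sr = [], []
    for k in range(1, len(points)):
        if np.linalg.norm(points[k] - out_p[-1]) > 1e-9:
            out_p.append(points[k])
            out_prov.append(provenance[k - 1])
            out_sr.append(seg_res[k - 1])
    return np.asarray(out_p), out_prov, out_sr


def build_curve(chain: ChainRecord, arcs, closed: bool):
    """Assemble an element polyline from a list of arcs.

    ``arcs`` is a sequence of ``('backbone', i, j)`` (traverse backbone atoms
    of residues i..j inclusive) and ``('hbond', i, j)`` (straight segment
    between the proxy points of paired residues i and j) entries.  Returns
    ``(points, provenance, segment_residues)`` or ``None`` when backbone atoms
    are missing.
    """
    cid = chain.chain_id
    points: list[np.ndarray] = []
    provenance: list[str] = []
    seg_res: list[tuple[ResRef, ResRef]] = []

    def append(p, prov, ra, rb):
        if points:
            provenance.append(prov)
            seg_res.append((ResRef(cid, ra), ResRef(cid, rb)))
        points.append(np.asarray(p, dtype=float))

    for kind, i, j in arcs:
        if kind == "backbone":
            step = 1 if j >= i else -1
            prev = i
            for idx in range(i, j + step, step):
                atoms = _backbone_atoms(chain, idx)
                if not atoms:
                    logger.warning(
                        "chain %s residue %d has no backbone atoms; element dropped", cid, idx
                    )
                    return None
                if step < 0:
                    atoms = list(reversed(atoms))
                for a in atoms:
                    append(a, "backbone", prev, idx)
                    prev = idx
        elif kind == "hbond":
            pa = _proxy_point(chain, i, j)
            pb = _proxy_point(chain, j, i)
            if pa is None or pb is None:
                return None
            append(pa, "backbone", i, i)
            append(pb, "hydrogen_bond", i, j)
        else:  # pragma: no cover
            raise ValueError(kind)
    if closed:
        append(points[0].copy(), provenance[0] if provenance else "backbone",
               seg_res[0][0].index if seg_res else 0, seg_res[0][0].index if seg_res else 0)
    return _dedupe(points, provenance, seg_res)


def _build_loop_element(chain, closing, children):
    i, j = closing
    arcs = []
    cursor = i
    for (k, l) in children:
        arcs.append(("backbone", cursor, k))
        arcs.append(("hbond", k, l))
        cursor = l
    arcs.append(("backbone", cursor, j))
    arcs.append(("hbond", j, i))
    built = _build_closed(chain, arcs)
    if built is None:
        return None
    pts, prov, sr = built
    resset = sorted({r.index for pair in sr for r in pair})
    refs = [ResRef(chain.chain_id, k) for k in resset]
    return StructuralElement("loop", True, refs, pts, prov, sr)


def _build_step_element(chain, outer, inner):
    i, j = outer
    arcs = [
        ("backbone", i, i + 1),
        ("hbond", i + 1, j - 1),
        ("backbone", j - 1, j),
        ("hbond", j, i),
    ]
    built = _build_closed(chain, arcs)
    if built is None:
        return None
    pts, prov, sr = built
    refs = [ResRef(chain.chain_id, k) for k in (i, i + 1, j - 1, j)]
    return StructuralElement("dinucleotide_step", True, refs, pts, prov, sr)


def _build_closed(chain, arcs):
    built = build_curve(chain, arcs, closed=True)
    if built is None:
        return None
    pts, prov, sr = built
    if len(pts) < 4:
        return None
    # enforce exact closure
    if np.linalg.norm(pts[0] - pts[-1]) > 1e-9:
        pts = np.vstack([pts, pts[:1]])
        prov.append("backbone")
        sr.append((sr[-1][1], sr[0][0]))
    return pts, prov, sr


def _build_strand_element(chain, indices):
    built = build_curve(chain, [("backbone", indices[0], indices[-1])], closed=False)
    if built is None:
        return None
    pts, prov, sr = built
    if len(pts) < 2:
        return None
    refs = [ResRef(chain.chain_id, k) for k in indices]
    return StructuralElement("single_strand", False, refs, pts, prov, sr)
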