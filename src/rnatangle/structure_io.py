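"""Reading and sanitizing 3D RNA models.

Models arrive as PDB or mmCIF files (including CASP submission files whose
non-standard ``PFRMAT``/``TARGET`` header lines are stripped before parsing).
Only RNA residues are retained; the sugar-phosphate backbone is extracted as
an ordered polyline over the atoms P, O5', C5', C4', C3', O3', and canonical
base pairs (Watson-Crick A-U / G-C and wobble G-U) are obtained either
geometrically or from a layered dot-bracket string.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "RnaModel",
    "ChainRecord",
    "Residue",
    "BackboneChain",
    "ResRef",
    "BasePair",
    "SecondaryStructure",
    "BACKBONE_ATOMS",
    "FormatError",
    "EmptyModelError",
    "TooShortError",
    "DotBracketError",
    "read_model",
    "detect_duplicate_coordinates",
    "extract_backbone",
    "annotate_base_pairs",
    "parse_dotbracket",
    "to_dotbracket",
]

BACKBONE_ATOMS = ("P", "O5'", "C5'", "C4'", "C3'", "O3'")

_RNA_NAMES = {
    "A": "A", "C": "C", "G": "G", "U": "U", "I": "other",
    "RA": "A", "RC": "C", "RG": "G", "RU": "U",
    "ADE": "A", "CYT": "C", "GUA": "G", "URA": "U", "URI": "U",
    "A23": "A", "1MA": "A", "5MC": "C", "OMC": "C", "OMG": "G",
    "2MG": "G", "7MG": "G", "PSU": "U", "5MU": "U", "4SU": "U",
}

# canonical hydrogen-bond donor/acceptor atom pairs, keyed by sorted bases
_HBOND_PATTERNS: dict[tuple[str, str], list[tuple[str, str]]] = {
    ("A", "U"): [("N1", "N3"), ("N6", "O4")],
    ("C", "G"): [("N3", "N1"), ("O2", "N2"), ("N4", "O6")],
    ("G", "U"): [("O6", "N3"), ("N1", "O2")],
}
_PAIR_CLASS = {("A", "U"): "WC-AU", ("C", "G"): "WC-GC", ("G", "U"): "wobble-GU"}

_BRACKETS = ["()", "[]", "{}", "<>"]


class FormatError(ValueError):
    pass


class EmptyModelError(ValueError):
    pass


class TooShortError(ValueError):
    pass


class DotBracketError(ValueError):
    pass


def _normalize_atom_name(name: str) -> str:
    return name.strip().replace("*", "'").replace("′", "'")


@dataclass
class Residue:
    number: int
    icode: str
    base: str  # A/C/G/U/other
    atoms: dict[str, np.ndarray]

    def atom(self, name: str) -> np.ndarray | None:
        return self.atoms.get(_normalize_atom_name(name))

    @property
    def label(self) -> str:
        return f"{self.base}{self.number}{self.icode.strip()}"


@dataclass
class ChainRecord:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class RnaModel:
    model_id: str
    chains: list[ChainRecord]
    source_path: str = ""

    def chain(self, chain_id: str) -> ChainRecord:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(f"no chain {chain_id!r} in model {self.model_id}")

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)


@dataclass
class BackboneChain:
    chain_id: str
    points: np.ndarray  # (n, 3)
    residue_index_of_point: np.ndarray  # (n,) int, index into chain residues


@dataclass(frozen=True, order=True)
class ResRef:
    """Reference to a residue by chain id and position within the chain."""

    chain_id: str
    index: int


@dataclass(frozen=True)
class BasePair:
    i: ResRef
    j: ResRef
    pair_class: str

    def __post_init__(self):
        if self.i.chain_id == self.j.chain_id and self.i.index >= self.j.index:
            raise ValueError("base pair must be ordered i before j")


@dataclass
class SecondaryStructure:
    pairs: list[BasePair] = field(default_factory=list)
    layers: dict[BasePair, int] = field(default_factory=dict)

    def pairs_of_chain(self, chain_id: str) -> list[BasePair]:
        return [p for p in self.pairs if p.i.chain_id == chain_id and p.j.chain_id == chain_id]

    def partner(self, ref: ResRef) -> ResRef | None:
        for p in self.pairs:
            if p.i == ref:
                return p.j
            if p.j == ref:
                return p.i
        return None

    def paired_indices(self, chain_id: str) -> set[int]:
        out = set()
        for p in self.pairs:
            if p.i.chain_id == chain_id:
                out.add(p.i.index)
            if p.j.chain_id == chain_id:
                out.add(p.j.index)
        return out


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

_PDB_RECORDS = ("ATOM", "HETATM", "MODEL", "ENDMDL", "TER", "END", "HEADER", "CRYST1")


def _clean_casp_text(text: str) -> str:
    """Drop CASP TS-file metadata lines, keeping standard PDB records."""
    kept = [ln for ln in text.splitlines() if ln[:6].strip() in _PDB_RECORDS or ln.startswith("ATOM")]
    return "\n".join(kept) + "\n"


def read_model(path, format: str = "auto", model_index: int = 0) -> RnaModel:
    """Read a PDB/mmCIF file into an :class:`RnaModel`.

    Heteroatoms, waters and non-RNA residues are dropped.  Multi-model files
    yield the model at ``model_index`` (first by default).  Raises
    :class:`FormatError` when the file cannot be parsed and
    :class:`EmptyModelError` when no RNA residues remain.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    try:
        if fmt == "pdb":
            text = path.read_text(errors="replace")
            structure = gemmi.read_pdb_string(_clean_casp_text(text))
        elif fmt == "mmcif":
            structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise FormatError(f"unknown format {format!r}")
    except FormatError:
        raise
    except Exception as err:  # gemmi raises RuntimeError/ValueError on bad input
        raise FormatError(f"cannot parse {path}: {err}") from err

    if len(structure) == 0:
        raise EmptyModelError(f"{path}: file contains no models")
    if model_index >= len(structure):
        raise FormatError(f"{path}: model index {model_index} out of range")
    gmodel = structure[model_index]

    chains: list[ChainRecord] = []
    for gchain in gmodel:
        residues: list[Residue] = []
        for gres in gchain:
            name = gres.name.strip().upper()
            if name in ("HOH", "WAT"):
                continue
            base = _RNA_NAMES.get(name)
            atoms = {}
            for atom in gres:
                atoms[_normalize_atom_name(atom.name)] = np.array(
                    [atom.pos.x, atom.pos.y, atom.pos.z]
                )
            if base is None:
                # accept unnamed ribonucleotides by their ribose signature
                if "O2'" in atoms and "C1'" in atoms and "C4'" in atoms:
                    base = "other"
                else:
                    continue
            residues.append(
                Residue(
                    number=gres.seqid.num,
                    icode=(gres.seqid.icode or "").strip(),
                    base=base,
                    atoms=atoms,
                )
            )
        if residues:
            residues.sort(key=lambda r: (r.number, r.icode))
            chains.append(ChainRecord(chain_id=gchain.name, residues=residues))
    if not chains:
        raise EmptyModelError(f"{path}: no RNA residues found")
    seen = set()
    for ch in chains:
        if ch.chain_id in seen:
            raise FormatError(f"{path}: duplicate chain id {ch.chain_id!r}")
        seen.add(ch.chain_id)
    return RnaModel(model_id=path.stem, chains=chains, source_path=str(path))


# ---------------------------------------------------------------------------
# sanitation
# ---------------------------------------------------------------------------

def detect_duplicate_coordinates(model: RnaModel, tolerance: float = 0.01):
    """All atom pairs across distinct residues closer than ``tolerance`` (A).

    A non-empty result marks the model as having non-unique coordinates,
    which excludes its chains from knot analysis.
    """
    coords = []
    keys = []
    for ch in model.chains:
        for ri, res in enumerate(ch.residues):
            for name, xyz in res.atoms.items():
                coords.append(xyz)
                keys.append((ch.chain_id, ri, name))
    if not coords:
        return []
    arr = np.asarray(coords)
    tree = cKDTree(arr)
    pairs = tree.query_pairs(r=max(tolerance, 0.0), output_type="ndarray")
    out = []
    for a, b in pairs:
        ka, kb = keys[a], keys[b]
        if ka[:2] == kb[:2]:
            continue  # same residue
        out.append((ka, kb))
    return out


def extract_backbone(model: RnaModel, chain_id: str) -> BackboneChain:
    """Ordered backbone polyline of one chain.

    Atoms are appended per residue in the fixed order P, O5', C5', C4', C3',
    O3'.  A missing phosphate on the first residue is tolerated; a residue
    missing any other backbone atom is skipped with a warning.  Raises
    :class:`TooShortError` when fewer than 3 residues remain usable.
    """
    chain = model.chain(chain_id)
    points: list[np.ndarray] = []
    idx: list[int] = []
    usable = 0
    for ri, res in enumerate(chain.residues):
        names = [n for n in BACKBONE_ATOMS if n in res.atoms]
        missing = [n for n in BACKBONE_ATOMS if n not in res.atoms]
        if missing == ["P"] and ri == 0:
            pass  # 5' terminus commonly lacks the phosphate
        elif missing:
            logger.warning(
                "model %s chain %s residue %s: missing backbone atoms %s; residue skipped",
                model.model_id, chain_id, res.label, ",".join(missing),
            )
            continue
        usable += 1
        for n in names:
            points.append(res.atoms[n])
            idx.append(ri)
    if usable < 3:
        raise TooShortError(
            f"chain {chain_id} of {model.model_id}: only {usable} usable residues"
        )
    pts = np.asarray(points, dtype=float)
    return BackboneChain(chain_id=chain_id, points=pts, residue_index_of_point=np.asarray(idx))


# ---------------------------------------------------------------------------
# dot-bracket
# ---------------------------------------------------------------------------

def parse_dotbracket(db: str) -> list[tuple[int, int, int]]:
    """Parse a layered dot-bracket string into (i, j, layer) index triples.

    Supported bracket alphabets: ``()``, ``[]``, ``{}``, ``<>`` (layers 0-3).
    Raises :class:`DotBracketError` on unbalanced strings.
    """
    stacks: list[list[int]] = [[] for _ in _BRACKETS]
    pairs = []
    for pos, ch in enumerate(db):
        if ch == ".":
            continue
        for layer, (op, cl) in enumerate(_BRACKETS):
            if ch == op:
                stacks[layer].append(pos)
                break
            if ch == cl:
                if not stacks[layer]:
                    raise DotBracketError(f"unbalanced {cl!r} at position {pos}")
                pairs.append((stacks[layer].pop(), pos, layer))
                break
        else:
            raise DotBracketError(f"unsupported character {ch!r} at position {pos}")
    for layer, st in enumerate(stacks):
        if st:
            raise DotBracketError(f"unbalanced {_BRACKETS[layer][0]!r} at position {st[-1]}")
    return sorted(pairs)


def to_dotbracket(ss: SecondaryStructure, chain_id: str, length: int) -> str:
    """Serialize the pairs of one chain back into a layered dot-bracket string."""
    out = ["."] * length
    for p in ss.pairs_of_chain(chain_id):
        layer = ss.layers.get(p, 0)
        if layer >= len(_BRACKETS):
            raise DotBracketError("more pseudoknot layers than bracket alphabets")
        op, cl = _BRACKETS[layer]
        out[p.i.index] = op
        out[p.j.index] = cl
    return "".join(out)


def _assign_layers(pairs: list[tuple[int, int]]) -> dict[tuple[int, int], int]:
    """Greedy first-fit pseudoknot layering: each layer is crossing-free."""
    layers: list[list[tuple[int, int]]] = []
    out = {}
    for i, j in sorted(pairs):
        placed = False
        for lvl, members in enumerate(layers):
            if all(not (a < i < b < j or i < a < j < b) for a, b in members):
                members.append((i, j))
                out[(i, j)] = lvl
                placed = True
                break
        if not placed:
            layers.append([(i, j)])
            out[(i, j)] = len(layers) - 1
    return out


# ---------------------------------------------------------------------------
# base-pair annotation
# ---------------------------------------------------------------------------

def _pattern_for(base_a: str, base_b: str):
    key = tuple(sorted((base_a, base_b)))
    pat = _HBOND_PATTERNS.get(key)
    if pat is None:
        return None, None
    if (base_a, base_b) == key:
        return pat, _PAIR_CLASS[key]
    return [(b, a) for a, b in pat], _PAIR_CLASS[key]


def _detect_pairs_geometric(
    chain: ChainRecord,
    hb_range: tuple[float, float] = (2.4, 3.5),
    c1_range: tuple[float, float] = (10.0, 11.0),
):
    """Canonical pairs from geometry: every donor-acceptor distance of the
    canonical pattern within ``hb_range`` and C1'-C1' within ``c1_range``."""
    c1 = []
    keep = []
    for ri, res in enumerate(chain.residues):
        p = res.atom("C1'")
        if p is not None and res.base in "ACGU":
            c1.append(p)
            keep.append(ri)
    if len(c1) < 2:
        return []
    arr = np.asarray(c1)
    tree = cKDTree(arr)
    cand = tree.query_pairs(r=c1_range[1], output_type="ndarray")
    scored = []
    for a, b in cand:
        ri, rj = keep[a], keep[b]
        if abs(ri - rj) < 2:
            continue
        d_c1 = float(np.linalg.norm(arr[a] - arr[b]))
        if d_c1 < c1_range[0]:
            continue
        res_i, res_j = chain.residues[ri], chain.residues[rj]
        pattern, pair_class = _pattern_for(res_i.base, res_j.base)
        if pattern is None:
            continue
        dists = []
        ok = True
        for an, bn in pattern:
            pa, pb = res_i.atom(an), res_j.atom(bn)
            if pa is None or pb is None:
                ok = False
                break
            d = float(np.linalg.norm(pa - pb))
            if not (hb_range[0] <= d <= hb_range[1]):
                ok = False
                break
            dists.append(d)
        if not ok:
            continue
        score = -sum(abs(d - 2.9) for d in dists) / len(dists)
        scored.append((score, min(ri, rj), max(ri, rj), pair_class))
    scored.sort(reverse=True)
    taken: set[int] = set()
    pairs = []
    for score, ri, rj, pair_class in scored:
        if ri in taken or rj in taken:
            continue
        taken.update((ri, rj))
        pairs.append((ri, rj, pair_class))
    return sorted(pairs)


def annotate_base_pairs(
    model: RnaModel,
    source: str = "detect",
    dotbracket: str | dict[str, str] | None = None,
) -> SecondaryStructure:
    """Canonical base pairs for a model.

    ``source='detect'`` applies the geometric criteria; ``source='dotbracket'``
    maps a layered dot-bracket string (one string for a single-chain model or
    a ``{chain_id: string}`` mapping) onto the residues.  Each residue keeps at
    most one partner (best-scoring in detect mode).
    """
    all_pairs: list[BasePair] = []
    index_pairs_per_chain: dict[str, list[tuple[int, int]]] = {}
    if source == "detect":
        for chain in model.chains:
            trip = _detect_pairs_geometric(chain)
            index_pairs_per_chain[chain.chain_id] = [(i, j) for i, j, _ in trip]
            for i, j, pair_class in trip:
                all_pairs.append(
                    BasePair(ResRef(chain.chain_id, i), ResRef(chain.chain_id, j), pair_class)
                )
    elif source == "dotbracket":
        if dotbracket is None:
            raise DotBracketError("source='dotbracket' requires a dot-bracket string")
        if isinstance(dotbracket, str):
            if len(model.chains) != 1:
                raise DotBracketError("plain string dot-bracket needs a single-chain model")
            mapping = {model.chains[0].chain_id: dotbracket}
        else:
            mapping = dict(dotbracket)
        for chain_id, db in mapping.items():
            chain = model.chain(chain_id)
            if len(db) != len(chain.residues):
                raise DotBracketError(
                    f"dot-bracket length {len(db)} != {len(chain.residues)} residues "
                    f"of chain {chain_id}"
                )
            trip = parse_dotbracket(db)
            index_pairs_per_chain[chain_id] = [(i, j) for i, j, _ in trip]
            for i, j, _layer in trip:
                bi, bj = chain.residues[i].base, chain.residues[j].base
                _, pair_class = _pattern_for(bi, bj)
                all_pairs.append(
                    BasePair(ResRef(chain_id, i), ResRef(chain_id, j), pair_class or "WC-AU")
                )
    else:
        raise ValueError(f"unknown source {source!r}")

    ss = SecondaryStructure(pairs=all_pairs)
    for chain_id, idx_pairs in index_pairs_per_chain.items():
        lay = _assign_layers(idx_pairs)
        for p in all_pairs:
            if p.i.chain_id == chain_id and p.j.chain_id == chain_id:
                key = (p.i.index, p.j.index)
                if key in lay:
                    ss.layers[p] = lay[key]
    return ss
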