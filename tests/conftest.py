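import numpy as np
import pytest

from rnatangle.elements import StructuralElement
from rnatangle.structure_io import ResRef
from rnatangle.synthetic import _model_from_anchors


def torus_curve(p, q, n=200, scale=10.0):
    """Closed parametric torus knot T(p, q); T(2,3) is the trefoil."""
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    R, r = 2.0, 1.0
    pts = np.column_stack(
        [
            (R + r * np.cos(q * th)) * np.cos(p * th),
            (R + r * np.cos(q * th)) * np.sin(p * th),
            -r * np.sin(q * th),
        ]
    ) * (scale / 2.0)
    return np.vstack([pts, pts[:1]])


def figure_eight_curve(n=300, scale=5.0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack(
        [(2 + np.cos(2 * t)) * np.cos(3 * t), (2 + np.cos(2 * t)) * np.sin(3 * t), np.sin(4 * t)]
    ) * scale
    return np.vstack([pts, pts[:1]])


def polyline_element(kind, closed, pts, chain_id="A", first_index=0):
    """Wrap bare coordinates as a StructuralElement (one residue per vertex)."""
    pts = np.asarray(pts, dtype=float)
    n = len(pts)
    refs = [ResRef(chain_id, first_index + k) for k in range(n)]
    prov = ["backbone"] * (n - 1)
    segres = [
        (ResRef(chain_id, first_index + k), ResRef(chain_id, first_index + k + 1))
        for k in range(n - 1)
    ]
    return StructuralElement(kind, closed, refs, pts, prov, segres,
                             element_id=f"{chain_id}:{kind}:{first_index}")


def straight_chain_model(n, model_id="straight", chain_id="A", pairs=()):
    """RNA-like model whose residues lie on a straight line (for decomposition
    tests where 3D geometry is irrelevant)."""
    anchors = [np.array([6.0 * k, 0.0, 0.0]) for k in range(n)]
    return _model_from_anchors(anchors, list(pairs), model_id=model_id, chain_id=chain_id)


def pdb_atom_line(serial, name, resname, chain, resseq, x, y, z):
    """One fixed-column PDB ATOM record."""
    return (
        f"ATOM  {serial:5d} {name:<4s} {resname:>3s} {chain}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {name[0]:>2s}"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
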