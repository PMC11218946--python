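"""Reading, sanitizing, and annotating RNA models."""

import numpy as np
import pytest

from rnatangle.structure_io import (
    DotBracketError,
    EmptyModelError,
    TooShortError,
    annotate_base_pairs,
    detect_duplicate_coordinates,
    extract_backbone,
    parse_dotbracket,
    read_model,
    to_dotbracket,
)
from rnatangle.synthetic import make_hairpin_lasso, make_helix_model, write_fixture

from conftest import straight_chain_model


# --- reading ---------------------------------------------------------------

def test_round_trip_counts_and_coordinates(tmp_path):
    model, db, _ = make_hairpin_lasso(loop_size=6, depth=7)
    path = write_fixture(model, tmp_path / "fix.pdb", dotbracket=db)
    back = read_model(path)
    assert len(back.chains) == 1
    assert back.n_residues == model.n_residues
    for r0, r1 in zip(model.chains[0].residues, back.chains[0].residues):
        assert r0.base == r1.base
        for name, xyz in r0.atoms.items():
            assert np.allclose(xyz, r1.atoms[name], atol=1e-3)


def test_two_chains_in_file_order(tmp_path):
    from conftest import pdb_atom_line

    text = []
    serial = 1
    for cid, x0 in (("A", 0.0), ("B", 50.0)):
        for ri in range(1, 4):
            for j, name in enumerate(["P", "O5'", "C5'", "C4'", "C3'", "O3'"]):
                text.append(pdb_atom_line(serial, name, "A", cid, ri, x0 + 6 * ri + j, 0.0, 0.0))
                serial += 1
    p = tmp_path / "two.pdb"
    p.write_text("\n".join(text) + "\nEND\n")
    model = read_model(p)
    assert [c.chain_id for c in model.chains] == ["A", "B"]
    assert all(len(c) == 3 for c in model.chains)


def test_protein_only_file_raises_empty(tmp_path):
    from conftest import pdb_atom_line

    lines = []
    serial = 1
    for ri, aa in enumerate(["ALA", "GLY", "SER"], start=1):
        for j, name in enumerate(["N", "CA", "C", "O"]):
            lines.append(pdb_atom_line(serial, name, aa, "A", ri, ri * 3.0 + j, 0.0, 0.0))
            serial += 1
    p = tmp_path / "prot.pdb"
    p.write_text("\n".join(lines) + "\nEND\n")
    with pytest.raises(EmptyModelError):
        read_model(p)


def test_casp_ts_headers_are_stripped(tmp_path):
    model, db, _ = make_hairpin_lasso(loop_size=6, depth=3)
    path = write_fixture(model, tmp_path / "R1107TS001_1.pdb")
    body = path.read_text()
    path.write_text("PFRMAT TS\nTARGET R1107\nMODEL  1\n" + body)
    back = read_model(path)
    assert back.n_residues == model.n_residues


# --- duplicate coordinates -------------------------------------------------

def test_duplicate_coordinates_detection():
    model = straight_chain_model(8)
    assert detect_duplicate_coordinates(model) == []
    # copy P of residue 3 onto residue 7
    model.chains[0].residues[6].atoms["P"] = model.chains[0].residues[2].atoms["P"].copy()
    dup = detect_duplicate_coordinates(model)
    assert len(dup) == 1
    (ka, kb) = dup[0]
    assert {ka[1], kb[1]} == {2, 6}


def test_duplicate_tolerance_boundary():
    model = straight_chain_model(8)
    base = model.chains[0].residues[2].atoms["P"]
    model.chains[0].residues[6].atoms["P"] = base + np.array([0.005, 0.0, 0.0])
    assert detect_duplicate_coordinates(model, tolerance=0.0) == []
    assert len(detect_duplicate_coordinates(model, tolerance=0.01)) == 1


# --- backbone extraction ---------------------------------------------------

def test_backbone_point_counts():
    model = straight_chain_model(10)
    bb = extract_backbone(model, "A")
    assert len(bb.points) == 60
    del model.chains[0].residues[0].atoms["P"]
    bb = extract_backbone(model, "A")
    assert len(bb.points) == 59  # leading 5' phosphate tolerated


def test_backbone_missing_atom_skips_residue(caplog):
    model = straight_chain_model(10)
    del model.chains[0].residues[4].atoms["C4'"]
    bb = extract_backbone(model, "A")
    assert len(bb.points) == 54
    assert 4 not in set(bb.residue_index_of_point)


def test_backbone_errors():
    model = straight_chain_model(10)
    with pytest.raises(KeyError):
        extract_backbone(model, "Z")
    short = straight_chain_model(4)
    for k in (1, 2):
        del short.chains[0].residues[k].atoms["O3'"]
    with pytest.raises(TooShortError):
        extract_backbone(short, "A")


# --- dot-bracket -----------------------------------------------------------

def _oracle_bracket_match(db):
    """Independent stack matcher over each bracket alphabet separately."""
    out = set()
    for op, cl in ("()", "[]", "{}", "<>"):
        stack = []
        for k, ch in enumerate(db):
            if ch == op:
                stack.append(k)
            elif ch == cl:
                out.add((stack.pop(), k))
    return out


@pytest.mark.parametrize(
    "db",
    [
        "((((....))))",
        "((..[[..))..]]",
        "..((..[[..{{..))..]]..}}..",
        "....",
        "(((...)))..(((...)))",
    ],
)
def test_dotbracket_parse_matches_oracle(db):
    got = {(i, j) for i, j, _ in parse_dotbracket(db)}
    assert got == _oracle_bracket_match(db)


def test_dotbracket_layered_example():
    pairs = parse_dotbracket("((..[[..))..]]")
    assert {(i, j) for i, j, _ in pairs} == {(0, 9), (1, 8), (4, 13), (5, 12)}
    layers = {(i, j): l for i, j, l in pairs}
    assert layers[(0, 9)] == layers[(1, 8)]
    assert layers[(4, 13)] == layers[(5, 12)]
    assert layers[(0, 9)] != layers[(4, 13)]


@pytest.mark.parametrize("bad", ["((", "))", "(]", "((..)"])
def test_dotbracket_unbalanced(bad):
    with pytest.raises(DotBracketError):
        parse_dotbracket(bad)


def test_dotbracket_length_mismatch():
    model = straight_chain_model(10)
    with pytest.raises(DotBracketError):
        annotate_base_pairs(model, "dotbracket", "((..))")


@pytest.mark.parametrize("db", ["((((....))))", "((..[[..))..]]", "....(((...)))"])
def test_dotbracket_round_trip_identity(db):
    model = straight_chain_model(len(db))
    ss = annotate_base_pairs(model, "dotbracket", db)
    assert to_dotbracket(ss, "A", len(db)) == db


def test_annotate_hairpin_pairs():
    db = "((((....))))"
    model = straight_chain_model(12)
    ss = annotate_base_pairs(model, "dotbracket", db)
    got = sorted((p.i.index, p.j.index) for p in ss.pairs)
    assert got == [(0, 11), (1, 10), (2, 9), (3, 8)]


# --- geometric detection ---------------------------------------------------

def test_detect_mode_recovers_designed_helix_pairs():
    model, designed = make_helix_model(n_bp=6)
    ss = annotate_base_pairs(model, "detect")
    got = sorted((p.i.index, p.j.index) for p in ss.pairs)
    assert got == sorted(designed)
    assert all(p.pair_class == "WC-GC" for p in ss.pairs)
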