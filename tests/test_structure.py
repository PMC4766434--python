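import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epistate import (
    DomainAnnotation,
    ParseError,
    SymOp,
    UnitCell,
    apply_symop,
    convert_coordinates,
    generate_symmetry_mates,
    parse_structure,
    write_pdb,
)
from epistate.errors import GeometryError
from epistate.structure import Atom3D

MINIMAL_PDB = (
    "CRYST1   10.000   10.000   10.000  90.00  90.00  90.00 P 1\n"
    "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C\n"
    "END\n"
)

CUBIC = UnitCell(10, 10, 10, 90, 90, 90)
TRICLINIC = UnitCell(10.3, 12.7, 9.2, 75.0, 100.0, 83.0)


class TestParsing:
    def test_minimal_p1(self):
        model = parse_structure(MINIMAL_PDB)
        assert len(model.atoms()) == 1
        assert model.cell_defined and model.spacegroup == "P 1"
        assert len(model.symops) == 1 and model.symops[0].is_identity
        assert model.atoms()[0].coords == (1.0, 2.0, 3.0)

    def test_missing_cryst1_degrades_to_identity(self):
        text = "\n".join(l for l in MINIMAL_PDB.splitlines() if not l.startswith("CRYST1"))
        model = parse_structure(text)
        assert not model.cell_defined
        assert [op.is_identity for op in model.symops] == [True]

    def test_write_read_roundtrip_within_pdb_precision(self, toy_crystal, toy_model):
        rewritten = write_pdb(toy_model.residues(), cell=toy_model.cell,
                              spacegroup=toy_model.spacegroup)
        reread = parse_structure(rewritten)
        a1, a2 = toy_model.atoms(), reread.atoms()
        assert len(a1) == len(a2)
        for x, y in zip(a1, a2):
            assert np.allclose(x.coords, y.coords, atol=1e-3)

    def test_malformed_atom_record_names_line(self):
        bad = MINIMAL_PDB.replace("   1.000", "   abcde")
        with pytest.raises(ParseError, match="line 2"):
            parse_structure(bad)

    def test_unknown_spacegroup_lists_supported_symbols(self):
        bad = MINIMAL_PDB.replace(" P 1\n", " Q 9\n")
        with pytest.raises(ParseError, match="P 1"):
            parse_structure(bad)

    def test_highest_occupancy_altloc_kept(self):
        text = (
            "ATOM      1  CA AALA A   1       1.000   2.000   3.000  0.30  0.00           C\n"
            "ATOM      2  CA BALA A   1       4.000   5.000   6.000  0.70  0.00           C\n"
            "END\n"
        )
        model = parse_structure(text)
        (atom,) = model.atoms()
        assert atom.coords == (4.0, 5.0, 6.0)


@pytest.mark.parametrize(
    "symbol, n_ops",
    [("P 1", 1), ("P 21", 2), ("P 21 21 21", 4), ("C 2", 4), ("P 21 21 2", 4), ("P 43 21 2", 8)],
)
def test_spacegroup_operator_table(symbol, n_ops):
    text = MINIMAL_PDB.replace(" P 1\n", f" {symbol}\n")
    model = parse_structure(text)
    assert len(model.symops) == n_ops
    assert any(op.is_identity for op in model.symops)
    for op in model.symops:
        assert abs(abs(np.linalg.det(op.rot_matrix)) - 1.0) < 1e-9


class TestCoordinateConversion:
    def test_orth_to_frac_cubic(self):
        assert np.allclose(convert_coordinates((5, 0, 0), CUBIC, "orth_to_frac"), [0.5, 0, 0])

    def test_frac_to_orth_cubic(self):
        assert np.allclose(convert_coordinates((1, 1, 1), CUBIC, "frac_to_orth"), [10, 10, 10])

    def test_undefined_cell_errors(self):
        with pytest.raises(GeometryError):
            convert_coordinates((1, 1, 1), None, "orth_to_frac")

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=3))
    def test_roundtrip_identity_triclinic(self, v):
        frac = convert_coordinates(v, TRICLINIC, "orth_to_frac")
        back = convert_coordinates(frac, TRICLINIC, "frac_to_orth")
        assert np.allclose(back, v, atol=1e-9)


def _atoms(coords):
    return [
        Atom3D(serial=i + 1, name="CA", element="C", coords=tuple(c))
        for i, c in enumerate(coords)
    ]


class TestSymOp:
    def test_identity_leaves_coordinates(self):
        atoms = _atoms([(1, 2, 3), (4, 5, 6)])
        out = apply_symop(atoms, SymOp.identity(), CUBIC)
        assert [a.coords for a in out] == [a.coords for a in atoms]

    def test_unit_translation_shifts_by_cell_edge(self):
        atoms = _atoms([(1, 2, 3), (4, 5, 6)])
        out = apply_symop(atoms, SymOp.from_triplet("x+1,y,z"), CUBIC)
        for before, after in zip(atoms, out):
            assert np.allclose(after.xyz - before.xyz, [10, 0, 0], atol=1e-9)

    def test_non_identity_requires_cell(self):
        with pytest.raises(GeometryError):
            apply_symop(_atoms([(0, 0, 0)]), SymOp.from_triplet("-x,-y,z"), None)

    @settings(max_examples=25, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-20, 20), st.floats(-20, 20), st.floats(-20, 20)),
                    min_size=2, max_size=8))
    def test_twofold_is_isometry(self, coords):
        # 2-fold along c requires a cell with alpha = beta = 90 (monoclinic, unique c)
        cell = UnitCell(10.3, 12.7, 9.2, 90.0, 90.0, 83.0)
        atoms = _atoms(coords)
        out = apply_symop(atoms, SymOp.from_triplet("-x,-y,z"), cell)
        before = np.array([a.coords for a in atoms])
        after = np.array([a.coords for a in out])
        d_before = np.linalg.norm(before[:, None] - before[None, :], axis=-1)
        d_after = np.linalg.norm(after[:, None] - after[None, :], axis=-1)
        assert np.max(np.abs(d_before - d_after)) <= 1e-6


class TestSymmetryMates:
    def test_planted_mate_found_with_provenance(self, toy_model, toy_domains, toy_crystal):
        reg, par = toy_domains
        mates = generate_symmetry_mates(toy_model, par, reg, shell=4.5)
        assert len(mates) == 1
        assert mates[0].shift == (-1, 0, 0)
        assert mates[0].op.label == toy_crystal[1]["operator_triplet"]
        assert "(-1,0,0)" in mates[0].label

    def test_tiny_shell_returns_nothing(self, toy_model, toy_domains):
        reg, par = toy_domains
        assert generate_symmetry_mates(toy_model, par, reg, shell=0.1) == []

    def test_monotone_in_shell_and_identity_excluded(self, toy_model, toy_domains):
        reg, par = toy_domains
        counts = []
        for shell in (0.5, 3.0, 5.0, 12.0, 25.0):
            mates = generate_symmetry_mates(toy_model, par, reg, shell=shell)
            counts.append(len(mates))
            for m in mates:
                assert not (m.op.is_identity and m.shift == (0, 0, 0))
        assert counts == sorted(counts)

    def test_empty_domain_errors(self, toy_model, toy_domains):
        reg, _ = toy_domains
        ghost = DomainAnnotation("ghost", "B", 500, 600)
        with pytest.raises(GeometryError):
            generate_symmetry_mates(toy_model, ghost, reg, shell=4.5)
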