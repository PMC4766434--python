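import math

import numpy as np
import pytest

from epistate import EpistateError, residue_contacts, sasa_per_atom
from epistate.errors import GeometryError
from epistate.interface import VDW_RADII, compute_sasa, unit_sphere_points
from epistate.structure import Atom3D, ResidueRecord


def _res(chain, num, name, atoms):
    return ResidueRecord(chain, num, " ", name, tuple(atoms))


def _carbon(serial, xyz):
    return Atom3D(serial=serial, name="CA", element="C", coords=xyz)


def brute_force_sasa(coords, radii, probe, n_points):
    """Independent per-point oracle: pure-python loops over the same lattice."""
    sphere = unit_sphere_points(n_points)
    out = []
    for i in range(len(coords)):
        r_i = radii[i] + probe
        exposed = 0
        for pt in sphere:
            p = coords[i] + r_i * pt
            ok = True
            for j in range(len(coords)):
                if j == i:
                    continue
                r_j = radii[j] + probe
                if np.dot(p - coords[j], p - coords[j]) < r_j * r_j:
                    ok = False
                    break
            if ok:
                exposed += 1
        out.append(exposed / n_points * 4 * math.pi * r_i**2)
    return np.array(out)


class TestSasa:
    @pytest.mark.parametrize("n_points", [92, 960])
    def test_isolated_atom_is_analytic_sphere(self, n_points):
        area = sasa_per_atom(np.array([[0.0, 0.0, 0.0]]), np.array([1.70]), 1.4, n_points)
        assert area[0] == pytest.approx(4 * math.pi * 3.1**2, rel=1e-12)

    def test_two_distant_atoms_are_both_full_spheres(self):
        area = sasa_per_atom(np.array([[0.0, 0, 0], [100.0, 0, 0]]), np.array([1.7, 1.7]))
        assert np.allclose(area, 4 * math.pi * 3.1**2, rtol=1e-12)

    def test_overlapping_pair_matches_point_count_oracle_exactly(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        radii = np.array([1.70, 1.70])
        ours = sasa_per_atom(coords, radii, 1.4, 240)
        oracle = brute_force_sasa(coords, radii, 1.4, 240)
        assert ours == pytest.approx(oracle.tolist(), abs=0)
        assert ours.sum() < 2 * 4 * math.pi * 3.1**2

    def test_random_cluster_matches_oracle_exactly(self):
        rng = np.random.default_rng(7)
        coords = rng.uniform(0, 6, size=(8, 3))
        radii = np.array([VDW_RADII[e] for e in "CNOS" * 2])
        ours = sasa_per_atom(coords, radii, 1.4, 120)
        oracle = brute_force_sasa(coords, radii, 1.4, 120)
        assert ours == pytest.approx(oracle.tolist(), abs=0)

    def test_per_residue_sum_of_atoms(self):
        res = [
            _res("A", 1, "GLY", [_carbon(1, (0, 0, 0)), _carbon(2, (1.5, 0, 0))]),
            _res("A", 2, "GLY", [_carbon(3, (10.0, 0, 0))]),
        ]
        result = compute_sasa(res)
        assert result.total == pytest.approx(result.per_atom.sum())
        assert result.per_residue[("A", 1, " ")] == pytest.approx(result.per_atom[:2].sum())
        assert result.per_residue[("A", 2, " ")] == pytest.approx(result.per_atom[2])

    def test_unknown_element_is_rejected_by_name(self):
        res = [_res("A", 1, "MSE", [Atom3D(1, "SE", "Se", (0, 0, 0))])]
        with pytest.raises(EpistateError, match="SE"):
            compute_sasa(res)

    def test_mdtraj_cross_check(self, toy_model, tmp_path):
        import mdtraj as md

        from epistate import write_pdb

        chain_a = toy_model.chains["A"]
        path = tmp_path / "chain_a.pdb"
        path.write_text(write_pdb(chain_a, cell=toy_model.cell))
        traj = md.load_pdb(str(path))
        ref = md.shrake_rupley(traj, probe_radius=0.14, n_sphere_points=960).sum() * 100.0
        ours = compute_sasa(chain_a).total
        assert ours == pytest.approx(ref, rel=0.05)


class TestContacts:
    def test_single_pair_within_cutoff(self):
        a = [_res("A", 1, "GLY", [_carbon(1, (0, 0, 0))])]
        b = [_res("B", 1, "GLY", [_carbon(2, (0, 0, 3.5))])]
        pairs = residue_contacts(a, b, cutoff=4.0)
        assert len(pairs) == 1
        assert pairs[0].min_distance == pytest.approx(3.5)
        assert not pairs[0].is_salt_bridge

    def test_tight_cutoff_empty(self):
        a = [_res("A", 1, "GLY", [_carbon(1, (0, 0, 0))])]
        b = [_res("B", 1, "GLY", [_carbon(2, (0, 0, 3.5))])]
        assert residue_contacts(a, b, cutoff=3.0) == []

    def test_nonpositive_cutoff_errors(self):
        a = [_res("A", 1, "GLY", [_carbon(1, (0, 0, 0))])]
        with pytest.raises(GeometryError):
            residue_contacts(a, a, cutoff=0.0)

    def test_random_clouds_match_bruteforce_oracle(self):
        rng = np.random.default_rng(11)
        dom_a = [
            _res("A", i + 1, "GLY", [_carbon(10 * i + k, tuple(rng.uniform(0, 15, 3)))
                                     for k in range(2)])
            for i in range(25)
        ]
        dom_b = [
            _res("B", i + 1, "GLY", [_carbon(1000 + 10 * i + k, tuple(rng.uniform(0, 15, 3)))
                                     for k in range(2)])
            for i in range(25)
        ]
        cutoff = 4.5
        got = {(p.res_a, p.res_b): p.min_distance for p in residue_contacts(dom_a, dom_b, cutoff)}
        expected = {}
        for ra in dom_a:
            for rb in dom_b:
                dmin = min(
                    np.linalg.norm(x.xyz - y.xyz) for x in ra.atoms for y in rb.atoms
                )
                if dmin <= cutoff:
                    expected[(ra.key, rb.key)] = dmin
        assert set(got) == set(expected)
        for key in got:
            assert got[key] == pytest.approx(expected[key])

    @pytest.mark.parametrize("sep, expect_bridge", [(3.9, True), (4.2, False)])
    def test_salt_bridge_distance_rule(self, sep, expect_bridge):
        lys = _res("A", 1, "LYS", [_carbon(1, (0, 0, 0)),
                                   Atom3D(2, "NZ", "N", (0, 0, 1.0))])
        glu = _res("B", 1, "GLU", [Atom3D(3, "OE1", "O", (0, 0, 1.0 + sep))])
        (pair,) = residue_contacts([lys], [glu], cutoff=10.0)
        assert pair.is_salt_bridge is expect_bridge


class TestExposureProfile:
    def test_delta_nonnegative_and_interface_on_top(self, toy_exposure, toy_crystal):
        planted = toy_crystal[1]["interface_pair"]["regulatory"][1]
        deltas = {s.resnum: s.delta_sasa for s in toy_exposure.sites.values()}
        assert all(d >= -1e-6 for d in deltas.values())
        assert max(deltas, key=deltas.get) == planted

    def test_far_residues_have_exactly_zero_delta(self, toy_exposure, toy_crystal):
        planted = toy_crystal[1]["interface_pair"]["regulatory"][1]
        for s in toy_exposure.sites.values():
            if abs(s.resnum - planted) > 3:
                assert s.delta_sasa == 0.0

    def test_delta_sums_to_total_burial(self, toy_exposure):
        total_open = sum(s.sasa_open for s in toy_exposure.sites.values())
        total_closed = sum(s.sasa_closed for s in toy_exposure.sites.values())
        assert toy_exposure.total_delta == pytest.approx(total_open - total_closed, abs=1e-6)

    def test_tsv_export_has_one_row_per_residue(self, toy_exposure):
        lines = toy_exposure.to_tsv().strip().splitlines()
        assert len(lines) == 1 + len(toy_exposure.sites)
        assert lines[0].startswith("chain\tresnum")

    def test_missing_domain_errors(self, toy_assembly):
        from epistate import DomainAnnotation, exposure_profile

        with pytest.raises(GeometryError):
            exposure_profile(toy_assembly, DomainAnnotation("ghost", "Z", 1, 5))
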