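"""Structure stage: parsing, SASA, B-factors, superposition, distances."""

import math

import numpy as np
import pytest

from chainsplit.analyte import DisulphideTopology
from chainsplit.structure import (
    Atom,
    BONDI_RADII,
    ResidueSelection,
    StructureModel,
    atom_radii,
    bfactor_table,
    contact_distance,
    kabsch,
    read_structure,
    sasa_relative_exposure,
    shrake_rupley_sasa,
    sphere_points,
    superpose_rmsd,
    write_pdb,
)
from chainsplit.synthdata import build_toy_structure

TOY_TOPOLOGY = DisulphideTopology(bonds=((("A", 1), ("B", 1)), (("A", 2), ("A", 3))))


def _rotation(axis, angle):
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * K @ K


class TestReadStructure:
    def test_three_atom_snippet_echo(self, tmp_path):
        pdb = tmp_path / "mini.pdb"
        pdb.write_text(
            "ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00 10.00           N\n"
            "ATOM      2  CA  ALA A   1       2.000   2.500   3.000  1.00 12.50           C\n"
            "ATOM      3  C   ALA A   1       3.200   1.800   3.400  1.00 15.00           C\n"
            "END\n"
        )
        model = read_structure(pdb)
        assert len(model) == 3
        ca = model.find_atom("A", 1, "CA")
        assert (ca.x, ca.y, ca.z) == (2.0, 2.5, 3.0)
        assert ca.b_iso == 12.5
        assert ca.element == "C"

    def test_altloc_resolved_to_highest_occupancy(self, tmp_path):
        pdb = tmp_path / "alt.pdb"
        pdb.write_text(
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.60 10.00           C\n"
            "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.40 20.00           C\n"
            "END\n"
        )
        model = read_structure(pdb)
        assert len(model) == 1
        assert model.atoms[0].x == 0.0
        assert model.atoms[0].occupancy == pytest.approx(0.6, abs=1e-6)

    def test_malformed_file_raises(self, tmp_path):
        bad = tmp_path / "bad.cif"
        bad.write_text("this is not a structure\n")
        with pytest.raises(ValueError):
            read_structure(bad)

    def test_toy_structure_roundtrips_through_pdb(self, tmp_path, toy_disulphide_structure):
        path = write_pdb(toy_disulphide_structure, tmp_path / "toy.pdb")
        back = read_structure(path)
        assert len(back) == len(toy_disulphide_structure)
        for a, b in zip(toy_disulphide_structure.atoms, back.atoms):
            assert (a.chain, a.resnum, a.name, a.element.upper()) == (
                b.chain, b.resnum, b.name, b.element.upper()
            )
            assert np.allclose([a.x, a.y, a.z], [b.x, b.y, b.z], atol=1e-3)
            assert a.b_iso == pytest.approx(b.b_iso, abs=1e-2)


class TestSasa:
    def test_isolated_atom_matches_sphere_closed_form(self):
        sasa = shrake_rupley_sasa(np.zeros((1, 3)), np.array([1.7]), 1.4, 960)
        assert sasa[0] == pytest.approx(4 * math.pi * 3.1**2, rel=1e-12)
        assert sasa[0] == pytest.approx(120.76, abs=0.05)

    def test_distant_atoms_keep_full_sasa(self):
        coords = np.array([[0.0, 0, 0], [20.0, 0, 0]])
        radii = np.array([1.7, 1.8])
        sasa = shrake_rupley_sasa(coords, radii, 1.4, 480)
        assert sasa[0] == pytest.approx(4 * math.pi * 3.1**2, rel=1e-12)
        assert sasa[1] == pytest.approx(4 * math.pi * 3.2**2, rel=1e-12)

    def test_burial_monotone_as_neighbour_approaches(self):
        radii = np.array([1.7, 1.7])
        prev = np.inf
        for d in np.linspace(6.0, 1.0, 11):
            sasa = shrake_rupley_sasa(
                np.array([[0.0, 0, 0], [d, 0, 0]]), radii, 1.4, 960
            )
            assert sasa[0] <= prev + 1e-9
            prev = sasa[0]

    def test_total_sasa_invariant_under_rigid_motion(self, toy_disulphide_structure):
        R = _rotation([1, 2, 3], 1.1)
        shift = np.array([5.0, -3.0, 7.0])

        def total(model, n_points):
            atoms = model.atoms
            coords = np.array([[a.x, a.y, a.z] for a in atoms])
            radii = atom_radii([a.element for a in atoms])
            base = shrake_rupley_sasa(coords, radii, 1.4, n_points).sum()
            moved = shrake_rupley_sasa(coords @ R.T + shift, radii, 1.4, n_points).sum()
            return abs(moved - base) / base

        # compact protein-like geometry: < 0.5% wobble at 960 points
        helix = build_toy_structure("helix-with-B", n_res=15)
        assert total(helix, 960) < 0.005
        # hollow-shell assembly with grazing occlusions: looser sanity bound
        assert total(toy_disulphide_structure, 960) < 0.015

    def test_sphere_points_unit_norm(self):
        pts = sphere_points(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)

    def test_buried_vs_exposed_disulphide(self, toy_disulphide_structure):
        res = sasa_relative_exposure(toy_disulphide_structure, TOY_TOPOLOGY)
        exposed = res.disulphides[(("A", 1), ("B", 1))]["relative_exposure"]
        buried = res.disulphides[(("A", 2), ("A", 3))]["relative_exposure"]
        assert exposed > buried
        assert buried < 0.05
        assert exposed > 0.40

    def test_against_independent_sasa_implementation(self, toy_disulphide_structure):
        """biotite's Shrake-Rupley, fed the same Bondi radii, must agree on
        per-atom SASA to within the point-distribution wobble."""
        import biotite.structure as struc

        atoms = [a for a in toy_disulphide_structure.atoms]
        coords = np.array([[a.x, a.y, a.z] for a in atoms])
        radii = atom_radii([a.element for a in atoms])
        ours = shrake_rupley_sasa(coords, radii, 1.4, 960)

        arr = struc.AtomArray(len(atoms))
        arr.coord = coords.astype(np.float32)
        arr.element = np.array([a.element.upper() for a in atoms])
        arr.chain_id = np.array([a.chain for a in atoms])
        arr.res_id = np.array([a.resnum for a in atoms])
        arr.res_name = np.array([a.resname for a in atoms])
        arr.atom_name = np.array([a.name for a in atoms])
        theirs = struc.sasa(arr, probe_radius=1.4, point_number=960, vdw_radii=radii)
        assert np.allclose(ours, theirs, atol=1.5)
        assert ours.sum() == pytest.approx(theirs.sum(), rel=0.01)

    def test_missing_sulphur_flagged(self, toy_disulphide_structure):
        topo = DisulphideTopology(bonds=((("A", 99), ("B", 99)),))
        res = sasa_relative_exposure(toy_disulphide_structure, topo, n_points=120)
        assert res.disulphides[topo.bonds[0]]["missing"]
        assert res.disulphides[topo.bonds[0]]["relative_exposure"] is None


class TestBFactors:
    def test_constant_field_means_and_ratio(self):
        helix = build_toy_structure("helix-with-B", n_res=15)
        rep = bfactor_table(
            helix, ResidueSelection("A", 1, 8), ResidueSelection("A", 9, 15)
        )
        assert rep.helix_mean == pytest.approx(20.0)
        assert rep.loop_mean_all == pytest.approx(20.0)
        assert rep.ratio_all == pytest.approx(1.0)

    def test_ratio_invariant_under_uniform_b_scaling(self):
        b = [10.0 + i for i in range(15)]
        m1 = build_toy_structure("helix-with-B", n_res=15, b_values=b)
        m2 = build_toy_structure("helix-with-B", n_res=15, b_values=[3.0 * x for x in b])
        helix, loop = ResidueSelection("A", 1, 8), ResidueSelection("A", 9, 15)
        r1 = bfactor_table(m1, helix, loop)
        r2 = bfactor_table(m2, helix, loop)
        assert r1.ratio_all == pytest.approx(r2.ratio_all, rel=1e-12)
        assert r2.helix_mean == pytest.approx(3.0 * r1.helix_mean, rel=1e-12)

    def test_backbone_class_excludes_side_chain(self):
        helix = build_toy_structure("helix-with-B", n_res=10)
        sel = ResidueSelection("A", 1, 10, atom_class="backbone")
        picked = sel.pick(helix)
        assert {a.name for a in picked.atoms} == {"N", "CA", "C", "O"}

    def test_empty_selection_raises(self):
        helix = build_toy_structure("helix-with-B", n_res=5)
        with pytest.raises(ValueError, match="empty"):
            bfactor_table(
                helix, ResidueSelection("Z", 1, 5), ResidueSelection("A", 1, 5)
            )

    def test_user_scale_multiplies_ratio(self):
        helix = build_toy_structure("helix-with-B", n_res=10)
        rep = bfactor_table(
            helix, ResidueSelection("A", 1, 5), ResidueSelection("A", 6, 10),
            scale=35.0,
        )
        assert rep.normalised_all == pytest.approx(rep.ratio_all * 35.0)


class TestSuperposition:
    def _points(self, seed=0, n=10):
        rng = np.random.default_rng(seed)
        return rng.normal(size=(n, 3)) * 5.0

    def test_self_superposition_is_zero(self):
        P = self._points()
        assert kabsch(P, P).rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_recovered(self):
        P = self._points(seed=1)
        R = _rotation([1, 0.5, -2], 0.8)
        Q = P @ R.T + np.array([1.0, 2.0, 3.0])
        res = kabsch(P, Q)
        assert res.rmsd < 1e-10
        assert np.allclose(res.rotation @ res.rotation.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_of_rmsd(self):
        P, Q = self._points(seed=2), self._points(seed=3)
        assert kabsch(P, Q).rmsd == pytest.approx(kabsch(Q, P).rmsd, abs=1e-9)

    def test_collinear_points_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch(line, line)

    def test_against_quaternion_brute_force(self):
        """Independent oracle: minimise RMSD over rotations sampled as random
        unit quaternions, polished by Nelder-Mead on the quaternion; the
        SVD solution must agree to 1e-3 A."""
        from scipy.optimize import minimize

        P, Q = self._points(seed=4), self._points(seed=5)
        P0 = P - P.mean(axis=0)
        Q0 = Q - Q.mean(axis=0)

        def quat_to_mat(q):
            q = q / np.linalg.norm(q)
            w, x, y, z = q
            return np.array(
                [
                    [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
                    [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
                    [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
                ]
            )

        def rmsd_of(q):
            R = quat_to_mat(q)
            return float(np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1))))

        rng = np.random.default_rng(0)
        quats = rng.normal(size=(200_000, 4))
        quats /= np.linalg.norm(quats, axis=1, keepdims=True)
        w, x, y, z = quats.T
        R = np.empty((len(quats), 3, 3))
        R[:, 0, 0] = 1 - 2 * (y * y + z * z)
        R[:, 0, 1] = 2 * (x * y - z * w)
        R[:, 0, 2] = 2 * (x * z + y * w)
        R[:, 1, 0] = 2 * (x * y + z * w)
        R[:, 1, 1] = 1 - 2 * (x * x + z * z)
        R[:, 1, 2] = 2 * (y * z - x * w)
        R[:, 2, 0] = 2 * (x * z - y * w)
        R[:, 2, 1] = 2 * (y * z + x * w)
        R[:, 2, 2] = 1 - 2 * (x * x + y * y)
        moved = np.einsum("nij,kj->nki", R, P0)
        rmsds = np.sqrt(np.mean(np.sum((moved - Q0) ** 2, axis=2), axis=1))
        best = quats[np.argmin(rmsds)]
        sol = minimize(rmsd_of, best, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
        assert kabsch(P, Q).rmsd == pytest.approx(sol.fun, abs=1e-3)

    def test_residue_pairing_interface(self, toy_disulphide_structure):
        # shell pseudo-atoms lie on a sphere, so the pairing is non-degenerate
        pairing = [(("A", r), ("A", r)) for r in range(10, 20)]
        res = superpose_rmsd(
            toy_disulphide_structure, toy_disulphide_structure, pairing, atom_name="CA"
        )
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert res.n_atoms == 10


class TestContacts:
    def test_three_four_five(self):
        model = StructureModel(
            atoms=(
                Atom("N", "NH1", 0.0, 0.0, 0.0, chain="B", resnum=22, resname="ARG"),
                Atom("O", "OE1", 3.0, 4.0, 0.0, chain="A", resnum=17, resname="GLU"),
            )
        )
        d = contact_distance(model, [("B", 22, "NH1")], [("A", 17, "OE1")])
        assert d == pytest.approx(5.0)

    def test_group_against_itself_is_zero(self, toy_disulphide_structure):
        group = [("A", 1, "SG"), ("B", 1, "SG")]
        assert contact_distance(toy_disulphide_structure, group, group) == 0.0

    def test_empty_group_raises(self, toy_disulphide_structure):
        with pytest.raises(ValueError, match="empty"):
            contact_distance(toy_disulphide_structure, [("Z", 1, "XX")], [("A", 1, "SG")])
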