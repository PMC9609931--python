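"""Structure I/O and geometry primitives."""

import math

import numpy as np
import pytest

from mutadimer import structio, synthdata
from mutadimer.errors import PairingError, PDBFormatError
from mutadimer.structio import (
    ResidueKey,
    Structure,
    dihedral,
    neighbors_within,
    per_residue_rmsd,
    ramachandran,
    read_pdb,
    substitute_residue,
    superpose,
    write_pdb,
)
from conftest import random_rigid_transform

THREE_ATOM_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
END
"""


def _toy(coords, names=None, res_ids=None, chains=None, res_names=None):
    n = len(coords)
    return Structure(
        list(range(1, n + 1)),
        names or ["CA"] * n,
        ["C"] * n,
        res_names or ["ALA"] * n,
        res_ids if res_ids is not None else list(range(1, n + 1)),
        chains or ["A"] * n,
        np.asarray(coords, dtype=float))


class TestReadWrite:
    def test_reads_hand_written_pdb(self, tmp_path):
        p = tmp_path / "three.pdb"
        p.write_text(THREE_ATOM_PDB)
        s = read_pdb(p)
        assert s.n_atoms == 3
        assert s.chains == ["A"]
        assert np.allclose(s.coords[1], [1.458, 0.0, 0.0])
        assert s.vdw[0] > 0

    def test_multi_model_selects_requested_model(self, tmp_path, helix20):
        models = [helix20.transformed(np.eye(3), [float(i), 0, 0])
                  for i in range(5)]
        p = tmp_path / "multi.pdb"
        write_pdb(models, p)
        s = read_pdb(p, model_index=4)
        assert np.allclose(s.coords, models[4].coords, atol=1e-3)
        with pytest.raises(IndexError):
            read_pdb(p, model_index=5)

    def test_malformed_atom_line_names_the_line(self, tmp_path):
        bad = THREE_ATOM_PDB.replace(
            "ATOM      2  CA  ALA A   1       1.458   0.000   0.000",
            "ATOM      2  CA  ALA A   1       1.458   xxx     0.000")
        p = tmp_path / "bad.pdb"
        p.write_text(bad)
        with pytest.raises(PDBFormatError, match="line 2"):
            read_pdb(p)

    def test_round_trip_preserves_coordinates_to_pdb_precision(
            self, tmp_path, helix20):
        p = tmp_path / "rt.pdb"
        write_pdb(helix20, p)
        back = read_pdb(p)
        assert back.n_atoms == helix20.n_atoms
        assert np.allclose(back.coords, helix20.coords, atol=5.1e-4)


class TestNeighbors:
    def test_two_atoms_straddling_the_radius(self):
        near = _toy([[0, 0, 0], [4.9, 0, 0]])
        far = _toy([[0, 0, 0], [5.1, 0, 0]])
        assert neighbors_within(near, ResidueKey("A", 1), 5.0) == [
            ResidueKey("A", 1), ResidueKey("A", 2)]
        assert neighbors_within(far, ResidueKey("A", 1), 5.0) == [
            ResidueKey("A", 1)]

    def test_matches_brute_force_on_toy_helix(self, helix20):
        center = ResidueKey("A", 10)
        got = neighbors_within(helix20, center, 5.0)
        # oracle: exhaustive double loop over heavy-atom pairs
        heavy = np.nonzero(helix20.heavy_mask)[0]
        cidx = [i for i in heavy
                if helix20.chain[i] == "A" and helix20.res_id[i] == 10]
        expected = {center}
        for i in heavy:
            for j in cidx:
                d = np.linalg.norm(helix20.coords[i] - helix20.coords[j])
                if d <= 5.0:
                    expected.add(ResidueKey(helix20.chain[i],
                                            int(helix20.res_id[i])))
        assert got == sorted(expected, key=lambda k: (k.chain, k.residue_id))

    def test_symmetry(self, helix20):
        r = 6.0
        keys = helix20.residue_keys()
        member = {k: set(neighbors_within(helix20, k, r)) for k in keys}
        for a in keys:
            for b in member[a]:
                assert a in member[b]

    def test_unresolvable_center_raises(self, helix20):
        with pytest.raises(KeyError):
            neighbors_within(helix20, ResidueKey("Z", 1), 5.0)


class TestSuperpose:
    def test_identical_structures_give_zero_rmsd(self, helix20):
        _, _, rmsd = superpose(helix20, helix20)
        assert rmsd <= 1e-10

    def test_rigid_transform_recovered(self, helix20):
        a = math.radians(37.0)
        R = np.array([[math.cos(a), -math.sin(a), 0],
                      [math.sin(a), math.cos(a), 0],
                      [0, 0, 1]])
        moved = helix20.transformed(R, np.array([5.0, -2.0, 1.0]))
        Rhat, t, rmsd = superpose(moved, helix20)
        assert rmsd <= 1e-8
        assert np.linalg.det(Rhat) == pytest.approx(1.0, abs=1e-9)

    def test_matches_quaternion_grid_oracle_on_four_points(self):
        rng = np.random.default_rng(5)
        P = rng.normal(size=(4, 3)) * 3
        Q = P + rng.normal(scale=0.4, size=(4, 3))
        mob = _toy(P)
        ref = _toy(Q)
        _, _, rmsd = superpose(mob, ref)

        # oracle: dense quaternion grid + local refinement by nesting
        def rmsd_for(R):
            Pc = P - P.mean(axis=0)
            Qc = Q - Q.mean(axis=0)
            return np.sqrt((((Pc @ R.T) - Qc) ** 2).sum(axis=1).mean())

        def quat_to_mat(q):
            w, x, y, z = q / np.linalg.norm(q)
            return np.array([
                [1 - 2 * (y * y + z * z), 2 * (x * y - z * w),
                 2 * (x * z + y * w)],
                [2 * (x * y + z * w), 1 - 2 * (x * x + z * z),
                 2 * (y * z - x * w)],
                [2 * (x * z - y * w), 2 * (y * z + x * w),
                 1 - 2 * (x * x + y * y)]])

        grid = np.random.default_rng(0).normal(size=(20000, 4))
        best_q, best = None, np.inf
        for q in grid:
            v = rmsd_for(quat_to_mat(q))
            if v < best:
                best, best_q = v, q
        for scale in (0.3, 0.1, 0.03, 0.01, 0.003):
            local = best_q + np.random.default_rng(1).normal(
                scale=scale, size=(4000, 4))
            for q in local:
                v = rmsd_for(quat_to_mat(q))
                if v < best:
                    best, best_q = v, q
        assert rmsd == pytest.approx(best, abs=1e-4)

    def test_mismatched_selections_raise(self, helix20):
        other = synthdata.make_monomer(20, "helix", seed=7, chain="B")
        with pytest.raises(PairingError):
            superpose(helix20, other)


class TestPerResidueRMSD:
    def test_identical_structures_all_zero(self, helix20):
        table = per_residue_rmsd(helix20, helix20)
        assert all(v <= 1e-10 for v in table.values())

    def test_single_displaced_residue_reports_its_displacement(self):
        # 3x3 grid of single-atom residues, centre point pushed 2 A out of
        # plane.  By symmetry the global fit is a pure translation of
        # 2/9 A, so hand-computed values are 2*8/9 for the displaced
        # residue and 2/9 for every other.
        pts = [[x * 10.0, y * 10.0, 0.0] for x in range(3) for y in range(3)]
        ref = _toy(pts)
        moved_pts = [list(p) for p in pts]
        moved_pts[4][2] += 2.0
        mob = _toy(moved_pts)
        table = per_residue_rmsd(mob, ref)
        assert table[ResidueKey("A", 5)] == pytest.approx(2.0 * 8 / 9,
                                                          abs=1e-9)
        for k, v in table.items():
            if k.residue_id != 5:
                assert v == pytest.approx(2.0 / 9, abs=1e-9)

    def test_gaussian_perturbation_matches_expected_norm(self, helix20):
        # E||eps|| for eps ~ N(0, sigma^2 I_3) = sigma*sqrt(2)*G(2)/G(1.5)
        sigma = 0.3
        rng = np.random.default_rng(11)
        mob = helix20.copy()
        mob.coords = helix20.coords + rng.normal(0, sigma,
                                                 helix20.coords.shape)
        table = per_residue_rmsd(mob, helix20)
        # per-residue RMSD over k atoms concentrates near sigma*sqrt(3)
        mean = np.mean(list(table.values()))
        assert mean == pytest.approx(sigma * np.sqrt(3), rel=0.2)


class TestRamachandran:
    def test_ideal_helix_angles(self, helix20):
        records, violations = ramachandran(helix20)
        defined = [r for r in records if r["defined"]]
        assert len(defined) == 18
        for r in defined:
            assert r["phi"] == pytest.approx(-57.0, abs=2.0)
            assert r["psi"] == pytest.approx(-47.0, abs=2.0)
        assert violations == 0

    def test_three_residue_chain_has_one_defined_pair(self):
        s = synthdata.make_monomer(5, "helix", seed=0)
        sub = s._subset(np.nonzero(s.res_id <= 3)[0])
        records, _ = ramachandran(sub)
        assert sum(r["defined"] for r in records) == 1

    def test_dihedral_matches_direct_arctan_formula(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            p = rng.normal(size=(4, 3)) * 4
            got = dihedral(*p)
            b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
            n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
            y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
            x = np.dot(n1, n2)
            assert got == pytest.approx(math.degrees(math.atan2(y, x)),
                                        abs=1e-9)

    def test_angles_invariant_under_rigid_transform(self, helix20):
        R, t = random_rigid_transform(np.random.default_rng(9))
        moved = helix20.transformed(R, t)
        rec_a, _ = ramachandran(helix20)
        rec_b, _ = ramachandran(moved)
        for a, b in zip(rec_a, rec_b):
            if a["defined"]:
                assert a["phi"] == pytest.approx(b["phi"], abs=1e-6)
                assert a["psi"] == pytest.approx(b["psi"], abs=1e-6)


class TestSubstituteResidue:
    def test_arg_to_trp_keeps_backbone_and_cb(self, receptor_trp, tag_key):
        wt = synthdata.make_monomer(16, "helix", seed=1, site_residue="ARG")
        mut = substitute_residue(wt, tag_key, "TRP")
        assert mut.residue_name_of(tag_key) == "TRP"
        names = {mut.name[i] for i in mut.atom_indices(tag_key)}
        assert names == {"N", "CA", "C", "O", "CB"}
        assert any("ARG->TRP" in note for note in mut.provenance)

    def test_gly_target_loses_cb_without_error(self, helix20):
        key = ResidueKey("A", 10)
        mut = substitute_residue(helix20, key, "GLY")
        names = {mut.name[i] for i in mut.atom_indices(key)}
        assert "CB" not in names

    def test_unknown_code_raises(self, helix20):
        with pytest.raises(ValueError):
            substitute_residue(helix20, ResidueKey("A", 10), "XYZ")

    def test_neighbor_set_recomputed_on_retained_atoms(self, helix20):
        key = ResidueKey("A", 10)
        mut = substitute_residue(helix20, key, "TRP")
        got = neighbors_within(mut, key, 5.0)
        heavy = np.nonzero(mut.heavy_mask)[0]
        cidx = [i for i in heavy if mut.res_id[i] == 10]
        expected = {key}
        for i in heavy:
            if any(np.linalg.norm(mut.coords[i] - mut.coords[j]) <= 5.0
                   for j in cidx):
                expected.add(ResidueKey(mut.chain[i], int(mut.res_id[i])))
        assert got == sorted(expected, key=lambda k: (k.chain, k.residue_id))
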