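import math

import numpy as np
import pytest

from rindock.structure import (
    Atom,
    Residue,
    Structure,
    compute_shape,
    compute_surface,
    read_structure,
    true_interface,
    write_structure,
)

from oracles import interface_oracle, shrake_rupley_oracle


def _chain(ca_positions, chain_id="A", res_type="GLY", extra_atoms=()):
    """Structure of bare-Cα residues at prescribed positions."""
    s = Structure("toy")
    for i, pos in enumerate(ca_positions):
        res = Residue((chain_id, i + 1, ""), res_type)
        res.atoms.append(Atom("CA", "C", np.asarray(pos, dtype=float)))
        for name, element, xyz in extra_atoms:
            res.atoms.append(Atom(name, element, np.asarray(pos) + np.asarray(xyz)))
        s.residues.append(res)
    return s


class TestReadStructure:
    def test_reads_three_residues_with_ca(self, tiny_pdb):
        s = read_structure(tiny_pdb)
        assert len(s) == 3
        assert all(r.ca is not None for r in s)
        assert s.residue_ids() == [("A", 1, ""), ("A", 2, ""), ("A", 3, "")]
        assert s.residues[0].res_type == "ALA"

    def test_reading_is_deterministic(self, tiny_pdb):
        s1, s2 = read_structure(tiny_pdb), read_structure(tiny_pdb)
        assert s1.residue_ids() == s2.residue_ids()
        c1, _ = s1.atom_records()
        c2, _ = s2.atom_records()
        assert np.array_equal(c1, c2)

    def test_gly_cb_aliases_ca(self, tiny_pdb):
        gly = read_structure(tiny_pdb).residues[1]
        assert gly.res_type == "GLY"
        assert gly.cb is gly.ca

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_structure(tmp_path / "absent.pdb")

    def test_hetatm_only_file_rejected(self, tmp_path):
        p = tmp_path / "het.pdb"
        p.write_text(
            "HETATM    1 ZN    ZN A 100      0.000   0.000   0.000  1.00  0.00          ZN\n"
            "END\n"
        )
        with pytest.raises(ValueError, match="no protein atoms"):
            read_structure(p)

    def test_chain_filter(self, tmp_path, tiny_pdb):
        text = tiny_pdb.read_text().replace("TER\n", "").replace("END\n", "")
        text += text.replace(" A ", " B ") + "END\n"
        p = tmp_path / "two_chains.pdb"
        p.write_text(text)
        s = read_structure(p, chain_filter={"B"})
        assert {rid[0] for rid in s.residue_ids()} == {"B"}

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        p = tmp_path / "altloc.pdb"
        p.write_text(
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C\n"
            "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.60  0.00           C\n"
            "ATOM      3  CA  ALA A   2       9.000   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        s = read_structure(p)
        assert s.residues[0].ca.coords[0] == pytest.approx(5.0)

    def test_roundtrip_preserves_coordinates_to_pdb_precision(self, tmp_path, small_complex):
        receptor = small_complex[0]
        out = tmp_path / "rt.pdb"
        write_structure(receptor, out)
        back = read_structure(out)
        assert back.residue_ids() == receptor.residue_ids()
        c1, _ = receptor.atom_records()
        c2, _ = back.atom_records()
        assert np.abs(c1 - c2).max() < 1.5e-3  # PDB stores 3 decimals


class TestSurface:
    def test_isolated_residue_is_surface(self):
        far = _chain([(0, 0, 0), (100, 0, 0), (103.8, 0, 0), (107.6, 0, 0), (111.4, 0, 0)])
        prof = compute_surface(far)
        assert prof.is_surface(("A", 1, ""))

    def test_buried_center_of_dense_ball(self):
        # residues packed on a 3.5 Å grid ball around a central residue
        grid = [
            (x, y, z)
            for x in (-3.5, 0, 3.5)
            for y in (-3.5, 0, 3.5)
            for z in (-3.5, 0, 3.5)
        ]
        center_idx = grid.index((0, 0, 0))
        s = _chain(grid)
        prof = compute_surface(s)
        center_id = ("A", center_idx + 1, "")
        assert not prof.is_surface(center_id)
        # independent sphere-point oracle agrees the center atom is buried
        coords = np.array(grid, dtype=float)
        oracle = shrake_rupley_oracle(coords, ["C"] * len(grid))
        assert oracle[center_idx] / 104.0 < prof.threshold

    def test_threshold_above_max_disables_all(self, small_complex):
        prof = compute_surface(small_complex[0], rel_asa_threshold=1.1)
        assert prof.surface_residues == []

    def test_rigid_motion_invariance(self, small_complex):
        receptor = small_complex[0]
        theta = 0.83
        rot = np.array(
            [
                [math.cos(theta), -math.sin(theta), 0],
                [math.sin(theta), math.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        moved = receptor.transformed(rot, np.array([12.0, -7.0, 3.0]))
        p1 = compute_surface(receptor)
        p2 = compute_surface(moved)
        for rid, v in p1.rel_asa.items():
            assert abs(v - p2.rel_asa[rid]) < 1e-6


class TestShape:
    def test_sphere_points_are_spherical(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(300, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        sd = compute_shape(_chain(20.0 * pts))
        assert sd.shape_class == "spherical"
        assert sd.anisotropy == pytest.approx(1.0, abs=0.1)

    @pytest.mark.parametrize(
        "scales, expected_aniso, expected_class",
        # axis scales split slightly so the principal axes are unambiguous
        [((50.0, 5.2, 4.8), 10.0, "prolate"), ((5.0, 52.0, 48.0), 0.1, "oblate")],
    )
    def test_rod_and_disc(self, scales, expected_aniso, expected_class):
        g = np.linspace(-1.0, 1.0, 6)
        pts = np.stack(np.meshgrid(g, g, g), axis=-1).reshape(-1, 3) * np.array(scales)
        sd = compute_shape(_chain(pts))
        assert sd.shape_class == expected_class
        assert sd.anisotropy == pytest.approx(expected_aniso, rel=0.01)
        # oracle: extents from an independent covariance eigen-decomposition
        c = pts - pts.mean(0)
        _, vecs = np.linalg.eigh(np.cov(c.T))
        proj = c @ vecs
        extents = np.sort(proj.max(0) - proj.min(0))
        assert np.allclose(sorted(sd.axis_lengths), extents, atol=1e-9)

    def test_rotation_translation_invariance(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(-1, 1, size=(100, 3)) * np.array([30.0, 10.0, 4.0])
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        sd1 = compute_shape(_chain(pts))
        sd2 = compute_shape(_chain(pts @ q.T + np.array([5.0, 6.0, 7.0])))
        assert sd1.anisotropy == pytest.approx(sd2.anisotropy, abs=1e-9)

    def test_collinear_cloud_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            compute_shape(_chain([(i * 3.8, 0, 0) for i in range(10)]))


class TestTrueInterface:
    def test_far_apart_is_empty(self):
        a = _chain([(0, 0, 0), (3.8, 0, 0)])
        b = _chain([(200, 0, 0), (203.8, 0, 0)], chain_id="B")
        assert true_interface(a, b, cutoff=10.0) == set()

    def test_superposed_is_everything(self):
        a = _chain([(0, 0, 0), (3.8, 0, 0), (7.6, 0, 0)])
        assert true_interface(a, a, cutoff=10.0) == set(a.residue_ids())

    def test_matches_all_pairs_scan(self):
        a = _chain([(i * 3.8, 0, 0) for i in range(5)])
        b = _chain([(i * 3.8, 24.0 - 4.0 * i, 0) for i in range(5)], chain_id="B")
        got = true_interface(a, b, cutoff=10.0)
        ca, oa = a.atom_records()
        cb, ob = b.atom_records()
        expected, _ = interface_oracle(ca, oa, cb, ob, 10.0)
        assert got == expected
        assert len(got) == 2  # placed so exactly two residues fall within 10 Å

    @pytest.mark.parametrize("c1, c2", [(5.0, 10.0), (10.0, 15.0)])
    def test_monotone_in_cutoff(self, small_complex, c1, c2):
        receptor, ligand, reference, _ = small_complex
        bound = reference.apply(ligand)
        assert true_interface(receptor, bound, c1) <= true_interface(receptor, bound, c2)
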