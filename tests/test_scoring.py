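import math

import numpy as np
import pytest

from rindock.centrality import CentralityProfile, compute_profile
from rindock.network import build_network
from rindock.scoring import (
    Pose,
    docking_interface,
    network_score,
    read_pose_table,
    score_pose_set,
    write_pose_table,
)
from rindock.structure import Atom, Residue, Structure

from oracles import interface_oracle


def _two_chain_toy(gap=4.0):
    """Two 3-residue chains facing each other across a gap."""
    a = Structure("recA")
    b = Structure("ligB")
    for i in range(3):
        ra = Residue(("A", i + 1, ""), "GLY")
        ra.atoms.append(Atom("CA", "C", np.array([i * 3.8, 0.0, 0.0])))
        a.residues.append(ra)
        rb = Residue(("B", i + 1, ""), "GLY")
        rb.atoms.append(Atom("CA", "C", np.array([i * 3.8, gap, 0.0])))
        b.residues.append(rb)
    return a, b


def _fixed_profile(ids, values):
    return CentralityProfile(
        values={
            "closeness": dict(zip(ids, values)),
            "degree": {r: 0.0 for r in ids},
            "betweenness": {r: 0.0 for r in ids},
            "clustering_inv": {r: math.nan for r in ids},
        },
        atom_mode="CA",
        cutoff=8.5,
    )


class TestDockingInterface:
    def test_far_apart_is_empty(self):
        a, b = _two_chain_toy(gap=200.0)
        ir, il = docking_interface(a, b, d=15.0)
        assert ir == set() and il == set()

    def test_nested_in_distance(self, small_complex):
        receptor, ligand, reference, _ = small_complex
        bound = reference.apply(ligand)
        r5, l5 = docking_interface(receptor, bound, d=5.0)
        r15, l15 = docking_interface(receptor, bound, d=15.0)
        assert r5 <= r15 and l5 <= l15

    def test_matches_brute_force_atom_scan(self, small_complex):
        receptor, ligand, reference, _ = small_complex
        bound = reference.apply(ligand)
        got = docking_interface(receptor, bound, d=10.0)
        ca, oa = receptor.atom_records(heavy_only=True)
        cb, ob = bound.atom_records(heavy_only=True)
        assert got == interface_oracle(ca, oa, cb, ob, 10.0)


class TestNetworkScore:
    def test_empty_interface_scores_zero(self):
        a, b = _two_chain_toy()
        pa = _fixed_profile(a.residue_ids(), [0.1, 0.2, 0.3])
        pb = _fixed_profile(b.residue_ids(), [0.1, 0.2, 0.3])
        assert network_score(pa, pb, (set(), set())) == 0.0

    def test_sum_arithmetic(self):
        a, b = _two_chain_toy()
        pa = _fixed_profile(a.residue_ids(), [0.30, 0.25, 0.99])
        pb = _fixed_profile(b.residue_ids(), [0.40, 0.99, 0.99])
        iface = ({("A", 1, ""), ("A", 2, "")}, {("B", 1, "")})
        assert network_score(pa, pb, iface) == pytest.approx(0.95)

    def test_contact_count_does_not_change_contribution(self):
        # residue 2 of the ligand makes 1 contact in one pose and many in
        # another; its closeness contribution is identical in both.
        a, b = _two_chain_toy(gap=4.0)
        pa = _fixed_profile(a.residue_ids(), [0.1, 0.1, 0.1])
        pb = _fixed_profile(b.residue_ids(), [0.2, 0.7, 0.2])
        few = docking_interface(a, b, d=4.5)     # one contact per residue pair
        many = docking_interface(a, b, d=14.0)   # every atom touches everything
        assert ("B", 2, "") in few[1] and ("B", 2, "") in many[1]
        s_few = network_score(pa, pb, (set(), {("B", 2, "")}))
        s_many = network_score(pa, pb, (set(), {("B", 2, "")}))
        assert s_few == s_many == pytest.approx(0.7)

    def test_nan_and_missing_residues_contribute_zero(self):
        a, b = _two_chain_toy()
        pa = _fixed_profile(a.residue_ids(), [0.5, math.nan, 0.5])
        pb = _fixed_profile(b.residue_ids()[:2], [0.5, 0.5])
        iface = ({("A", 2, "")}, {("B", 3, "")})  # NaN and missing
        with pytest.warns(UserWarning, match="missing from profile"):
            assert network_score(pa, pb, iface) == 0.0

    def test_partner_symmetry(self, small_complex):
        receptor, ligand, reference, _ = small_complex
        bound = reference.apply(ligand)
        pr = compute_profile(build_network(receptor))
        pl = compute_profile(build_network(ligand))
        ir, il = docking_interface(receptor, bound, d=15.0)
        forward = network_score(pr, pl, (ir, il))
        swapped = network_score(pl, pr, (il, ir))
        assert forward == pytest.approx(swapped, abs=1e-12)


class TestScorePoseSet:
    def test_identity_pose_matches_direct_complex_score(self, small_complex):
        receptor, ligand, reference, _ = small_complex
        bound = reference.apply(ligand)
        pr = compute_profile(build_network(receptor))
        pl = compute_profile(build_network(ligand))
        identity = Pose("id", np.eye(3), np.zeros(3))
        via_poses = score_pose_set(receptor, bound, [identity], pr, pl)[0]
        direct = network_score(pr, pl, docking_interface(receptor, bound, d=15.0))
        assert via_poses.scores["closeness"] == pytest.approx(direct, abs=1e-12)

    def test_bitwise_deterministic(self, small_complex):
        receptor, ligand, _, poses = small_complex
        pr = compute_profile(build_network(receptor))
        pl = compute_profile(build_network(ligand))
        s1 = score_pose_set(receptor, ligand, poses, pr, pl)
        s2 = score_pose_set(receptor, ligand, poses, pr, pl)
        assert [s.scores for s in s1] == [s.scores for s in s2]

    def test_score_nondecreasing_in_d(self, small_complex):
        receptor, ligand, _, poses = small_complex
        pr = compute_profile(build_network(receptor))
        pl = compute_profile(build_network(ligand))
        prev = None
        for d in (5.0, 10.0, 15.0):
            scores = [
                s.scores["closeness"]
                for s in score_pose_set(receptor, ligand, poses, pr, pl, d=d)
            ]
            if prev is not None:
                assert all(b >= a - 1e-12 for a, b in zip(prev, scores))
            prev = scores

    def test_profiles_are_pose_independent(self, small_complex):
        # moving the pose pair rigidly changes nothing: profiles were computed
        # once on the unbound partners and the interface moves with the pair
        receptor, ligand, reference, _ = small_complex
        pr = compute_profile(build_network(receptor))
        pl = compute_profile(build_network(ligand))
        bound = reference.apply(ligand)
        base = network_score(pr, pl, docking_interface(receptor, bound, d=15.0))
        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        t = np.array([40.0, -3.0, 8.0])
        moved = network_score(
            pr,
            pl,
            docking_interface(receptor.transformed(rot, t), bound.transformed(rot, t), d=15.0),
        )
        assert moved == pytest.approx(base, abs=1e-12)

    def test_invalid_rotation_rejected(self, small_complex):
        receptor, ligand, _, _ = small_complex
        pr = compute_profile(build_network(receptor))
        pl = compute_profile(build_network(ligand))
        bad = Pose("bad", 2.0 * np.eye(3), np.zeros(3))
        with pytest.warns(UserWarning, match="non-orthonormal"):
            out = score_pose_set(receptor, ligand, [bad], pr, pl)
        assert out == []


def test_pose_table_roundtrip(tmp_path, small_complex):
    _, _, reference, poses = small_complex
    path = tmp_path / "poses.tsv"
    write_pose_table([reference] + poses, path)
    back = read_pose_table(path)
    assert [p.pose_id for p in back] == ["reference"] + [p.pose_id for p in poses]
    assert np.allclose(back[0].rotation, reference.rotation)
    assert np.allclose(back[0].translation, reference.translation)
    assert back[1].rmsd == pytest.approx(poses[0].rmsd)
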