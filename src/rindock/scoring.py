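"""Network-based scoring of rigid-body docking poses.

The topology parameters are computed once on the unbound receptor and ligand;
a pose is scored by summing the precomputed values of every residue at the
docking interface — residues of either partner with a heavy atom within d Å
(default 15 Å) of any heavy atom of the other partner — each residue counted
once regardless of how many atomic contacts it makes.  Higher network score is
better; the combination with the (lower-is-better) energy score handles the
sign in one documented place.

Contact-count weighting of the residue values is available behind a flag but
off by default: it degrades rigid-body rescoring, where side chains are not in
their bound conformation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .centrality import CentralityProfile
from .structure import ResidueID, Structure

__all__ = [
    "Pose",
    "PoseScore",
    "docking_interface",
    "network_score",
    "score_pose_set",
    "write_pose_table",
    "read_pose_table",
    "write_score_table",
]

DEFAULT_CONTACT_DISTANCE = 15.0
_ORTHO_TOL = 1e-6


@dataclass
class Pose:
    """A rigid-body placement of the unbound ligand: x' = R x + t."""

    pose_id: str
    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,) in Å
    rmsd: Optional[float] = None  # ligand Cα-RMSD to the reference, if known

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.rmsd is not None and self.rmsd < 0:
            raise ValueError(f"pose {self.pose_id}: negative RMSD")

    @property
    def is_valid_rotation(self) -> bool:
        r = self.rotation
        return (
            np.allclose(r @ r.T, np.eye(3), atol=_ORTHO_TOL)
            and abs(np.linalg.det(r) - 1.0) < 1e-4
        )

    def apply(self, ligand: Structure) -> Structure:
        return ligand.transformed(self.rotation, self.translation)


@dataclass
class PoseScore:
    pose_id: str
    scores: dict[str, float]  # parameter name -> network score
    contact_distance: float
    n_receptor_iface: int
    n_ligand_iface: int


def docking_interface(
    receptor: Structure,
    ligand_pose: Structure,
    d: float = DEFAULT_CONTACT_DISTANCE,
) -> tuple[set[ResidueID], set[ResidueID]]:
    """Docking-interface residues of both partners at contact distance d.

    A residue is at the interface when one of its heavy atoms lies within d Å
    of any heavy atom of the partner; hydrogens are ignored.  Buried and
    surface residues both qualify.
    """
    coords_r, owners_r = receptor.atom_records(heavy_only=True)
    coords_l, owners_l = ligand_pose.atom_records(heavy_only=True)
    if coords_r.shape[0] == 0 or coords_l.shape[0] == 0:
        raise ValueError("docking_interface requires heavy atoms on both partners")
    tree_l = cKDTree(coords_l)
    pairs = cKDTree(coords_r).query_ball_tree(tree_l, r=d)
    iface_r: set[ResidueID] = set()
    iface_l: set[ResidueID] = set()
    for i, hits in enumerate(pairs):
        if hits:
            iface_r.add(owners_r[i])
            for j in hits:
                iface_l.add(owners_l[j])
    return iface_r, iface_l


def _contact_counts(
    receptor: Structure, ligand_pose: Structure, d: float
) -> tuple[dict[ResidueID, int], dict[ResidueID, int]]:
    """Atomic cross-contact counts per residue (contact-weighted mode only)."""
    coords_r, owners_r = receptor.atom_records(heavy_only=True)
    coords_l, owners_l = ligand_pose.atom_records(heavy_only=True)
    pairs = cKDTree(coords_r).query_ball_tree(cKDTree(coords_l), r=d)
    counts_r: dict[ResidueID, int] = {}
    counts_l: dict[ResidueID, int] = {}
    for i, hits in enumerate(pairs):
        if hits:
            counts_r[owners_r[i]] = counts_r.get(owners_r[i], 0) + len(hits)
            for j in hits:
                counts_l[owners_l[j]] = counts_l.get(owners_l[j], 0) + 1
    return counts_r, counts_l


def network_score(
    profile_r: CentralityProfile,
    profile_l: CentralityProfile,
    iface: tuple[set[ResidueID], set[ResidueID]],
    parameter: str = "closeness",
    weights: Optional[tuple[dict[ResidueID, int], dict[ResidueID, int]]] = None,
) -> float:
    """Sum of precomputed parameter values over both interface residue sets.

    Each residue contributes once; undefined (NaN) values contribute 0.  A
    residue at the interface but absent from its profile contributes 0 with a
    warning.  ``weights`` multiplies each residue value by its atomic contact
    count (off by default).
    """
    total = 0.0
    for side, (profile, residues) in enumerate(
        [(profile_r, iface[0]), (profile_l, iface[1])]
    ):
        values = profile.parameter(parameter)
        wmap = weights[side] if weights is not None else None
        for rid in residues:
            if rid not in values:
                warnings.warn(f"interface residue {rid} missing from profile; counts 0")
                continue
            v = values[rid]
            if math.isnan(v):
                continue
            total += v * (wmap.get(rid, 0) if wmap is not None else 1.0)
    return total


def score_pose_set(
    receptor: Structure,
    ligand: Structure,
    poses: Sequence[Pose],
    profile_r: CentralityProfile,
    profile_l: CentralityProfile,
    parameters: Sequence[str] = ("closeness",),
    d: float = DEFAULT_CONTACT_DISTANCE,
    contact_weighted: bool = False,
) -> list[PoseScore]:
    """Score every pose of a decoy set with the pose-independent profiles.

    The ligand profile is computed once on the unbound ligand; a rigid
    transform never changes residue identities, so the same profile scores
    every pose.  Poses with non-orthonormal rotations are rejected with a
    warning and omitted from the output.
    """
    out: list[PoseScore] = []
    for pose in poses:
        if not pose.is_valid_rotation:
            warnings.warn(f"pose {pose.pose_id}: non-orthonormal rotation; rejected")
            continue
        posed = pose.apply(ligand)
        iface = docking_interface(receptor, posed, d=d)
        weights = _contact_counts(receptor, posed, d) if contact_weighted else None
        scores = {
            p: network_score(profile_r, profile_l, iface, p, weights=weights)
            for p in parameters
        }
        out.append(
            PoseScore(
                pose_id=pose.pose_id,
                scores=scores,
                contact_distance=d,
                n_receptor_iface=len(iface[0]),
                n_ligand_iface=len(iface[1]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# pose-table and score-table I/O


def write_pose_table(poses: Sequence[Pose], path: str | Path) -> None:
    """TSV with pose_id, nine row-major rotation entries, translation (Å), rmsd."""
    rows = []
    for p in poses:
        row = {"pose_id": p.pose_id}
        for i in range(3):
            for j in range(3):
                row[f"r{i}{j}"] = p.rotation[i, j]
        for k, ax in enumerate("xyz"):
            row[f"t{ax}"] = p.translation[k]
        row["rmsd"] = p.rmsd if p.rmsd is not None else np.nan
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_pose_table(path: str | Path) -> list[Pose]:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    poses = []
    for _, row in df.iterrows():
        rot = np.array([[row[f"r{i}{j}"] for j in range(3)] for i in range(3)])
        trans = np.array([row["tx"], row["ty"], row["tz"]])
        rmsd = None if "rmsd" not in row or pd.isna(row["rmsd"]) else float(row["rmsd"])
        poses.append(Pose(str(row["pose_id"]), rot, trans, rmsd=rmsd))
    return poses


def write_score_table(scores: Sequence[PoseScore], path: str | Path) -> None:
    rows = [{"pose_id": s.pose_id, **s.scores} for s in scores]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")
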