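"""Simplified three-term rigid-body binding-energy score.

The energy of a docking pose is the sum of:

* **electrostatics** — Coulomb term over inter-molecular heavy-atom pairs with
  a distance-dependent dielectric ε(r) = ε₀·r (ε₀ = 4 by default), each pair's
  contribution truncated to ±1 kcal/mol so overlapping models cannot produce
  artificially extreme scores;
* **desolvation** — atomic solvation parameters applied to the solvent
  accessible surface area buried upon binding, Σ σ(type)·(ASA_complex −
  ASA_isolated);
* **van der Waals** — a 6-12 Lennard-Jones term, each pair truncated above at
  +1 kcal/mol before summation to tolerate rigid-body clashes, and the total
  weighted by 0.1.

Parameters are an embedded, deliberately compact AMBER-style set: per-element
Lennard-Jones radii/well depths, per-atom-name backbone partial charges plus
full/half charges on the standard charged side-chain groups, and
Wesson–Eisenberg-type atomic solvation parameters per element.  Hydrogens are
ignored throughout (united-atom treatment): rigid-body docking inputs
routinely lack them.  Only inter-molecular pairs are ever evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .structure import Atom, Structure, atom_sasa

__all__ = [
    "EnergyScore",
    "electrostatic_energy",
    "vdw_energy",
    "desolvation_energy",
    "total_energy",
    "assign_charges",
    "write_energy_table",
    "read_energy_table",
]

COULOMB_CONSTANT = 332.0636  # kcal·Å/(mol·e²)
VDW_WEIGHT = 0.1
ELEC_CLAMP = 1.0  # kcal/mol, symmetric
VDW_CLAMP = 1.0  # kcal/mol, upper only, before the 0.1 weight

# Lennard-Jones parameters per element: (r_min/2 in Å, well depth in kcal/mol)
LJ_PARAMS: dict[str, tuple[float, float]] = {
    "C": (1.908, 0.086),
    "N": (1.824, 0.170),
    "O": (1.661, 0.210),
    "S": (2.000, 0.250),
}

# Backbone partial charges (e) by atom name; net ~0 per residue.
_BACKBONE_CHARGES: dict[str, float] = {
    "N": -0.42,
    "CA": 0.03,
    "C": 0.60,
    "O": -0.57,
    "OXT": -0.57,
}

# Charged side-chain groups: (res_type, atom_name) -> charge (e).
_SIDECHAIN_CHARGES: dict[tuple[str, str], float] = {
    ("LYS", "NZ"): 1.0,
    ("ARG", "NH1"): 0.5,
    ("ARG", "NH2"): 0.5,
    ("ASP", "OD1"): -0.5,
    ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5,
    ("GLU", "OE2"): -0.5,
}

# Atomic solvation parameters (kcal/mol/Å²) per element, Wesson–Eisenberg style:
# burying carbon is favorable, burying polar nitrogen/oxygen costs energy.
ASP_PARAMS: dict[str, float] = {
    "C": 0.012,
    "N": -0.060,
    "O": -0.060,
    "S": 0.021,
}


class ParameterAssignmentError(KeyError):
    """An atom has no entry in the embedded parameter set."""


def _heavy(structure: Structure) -> tuple[np.ndarray, list[tuple[str, str, str]]]:
    """Heavy-atom coordinates with (res_type, atom_name, element) labels."""
    coords: list[np.ndarray] = []
    labels: list[tuple[str, str, str]] = []
    for res in structure.residues:
        for a in res.heavy_atoms:
            coords.append(a.coords)
            labels.append((res.res_type, a.name, a.element.upper()))
    if not coords:
        raise ValueError("structure has no heavy atoms")
    return np.vstack(coords), labels


def assign_charges(structure: Structure) -> np.ndarray:
    """Per-heavy-atom partial charges from the embedded table.

    Atoms of elements outside the parameterized set (C, N, O, S) raise a
    :class:`ParameterAssignmentError` naming the atom.
    """
    _, labels = _heavy(structure)
    charges = np.zeros(len(labels))
    for i, (res_type, name, element) in enumerate(labels):
        if element not in LJ_PARAMS:
            raise ParameterAssignmentError(
                f"no parameters for atom {name} (element {element}) in {res_type}"
            )
        if (res_type, name) in _SIDECHAIN_CHARGES:
            charges[i] = _SIDECHAIN_CHARGES[(res_type, name)]
        else:
            charges[i] = _BACKBONE_CHARGES.get(name, 0.0)
    return charges


def _pair_distances(receptor: Structure, ligand_pose: Structure):
    coords_r, labels_r = _heavy(receptor)
    coords_l, labels_l = _heavy(ligand_pose)
    diff = coords_r[:, None, :] - coords_l[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    return dist, labels_r, labels_l


def electrostatic_energy(
    receptor: Structure,
    ligand_pose: Structure,
    charges_r: Optional[np.ndarray] = None,
    charges_l: Optional[np.ndarray] = None,
    eps0: float = 4.0,
    clamp: float = ELEC_CLAMP,
) -> float:
    """Truncated distance-dependent-dielectric Coulomb energy (kcal/mol)."""
    if charges_r is None:
        charges_r = assign_charges(receptor)
    if charges_l is None:
        charges_l = assign_charges(ligand_pose)
    dist, _, _ = _pair_distances(receptor, ligand_pose)
    r = np.maximum(dist, 1e-6)
    pair = COULOMB_CONSTANT * np.outer(charges_r, charges_l) / (eps0 * r * r)
    return float(np.clip(pair, -clamp, clamp).sum())


def vdw_energy(
    receptor: Structure,
    ligand_pose: Structure,
    weight: float = VDW_WEIGHT,
    clamp: float = VDW_CLAMP,
) -> float:
    """Truncated, 0.1-weighted 6-12 Lennard-Jones energy (kcal/mol)."""
    dist, labels_r, labels_l = _pair_distances(receptor, ligand_pose)

    def params(labels):
        out = np.empty((len(labels), 2))
        for i, (res_type, name, element) in enumerate(labels):
            if element not in LJ_PARAMS:
                raise ParameterAssignmentError(
                    f"no LJ parameters for atom {name} (element {element}) in {res_type}"
                )
            out[i] = LJ_PARAMS[element]
        return out

    pr, pl = params(labels_r), params(labels_l)
    r_min = pr[:, 0][:, None] + pl[:, 0][None, :]  # Lorentz combination of r_min/2
    eps = np.sqrt(pr[:, 1][:, None] * pl[:, 1][None, :])
    ratio = r_min / np.maximum(dist, 1e-6)
    pair = eps * (ratio**12 - 2.0 * ratio**6)
    return weight * float(np.minimum(pair, clamp).sum())


def desolvation_energy(
    receptor: Structure,
    ligand_pose: Structure,
    point_number: int = 240,
) -> float:
    """ASA-based desolvation: Σ σ(element)·(ASA in complex − ASA isolated)."""
    asa_complex = atom_sasa([receptor, ligand_pose], point_number=point_number)
    asa_r = atom_sasa([receptor], point_number=point_number)
    asa_l = atom_sasa([ligand_pose], point_number=point_number)
    asa_iso = np.concatenate([asa_r, asa_l])
    _, labels_r = _heavy(receptor)
    _, labels_l = _heavy(ligand_pose)
    sigmas = np.empty(len(labels_r) + len(labels_l))
    for i, (res_type, name, element) in enumerate(labels_r + labels_l):
        if element not in ASP_PARAMS:
            raise ParameterAssignmentError(
                f"no solvation parameter for atom {name} (element {element}) in {res_type}"
            )
        sigmas[i] = ASP_PARAMS[element]
    return float((sigmas * (asa_complex - asa_iso)).sum())


@dataclass
class EnergyScore:
    pose_id: str
    electrostatics: float
    desolvation: float
    vdw_weighted: float

    @property
    def total(self) -> float:
        return self.electrostatics + self.desolvation + self.vdw_weighted


def total_energy(
    receptor: Structure,
    ligand_pose: Structure,
    pose_id: str = "",
    eps0: float = 4.0,
    sasa_points: int = 240,
) -> EnergyScore:
    """Compose the three binding-energy terms for one pose (lower is better)."""
    charges_r = assign_charges(receptor)
    charges_l = assign_charges(ligand_pose)
    return EnergyScore(
        pose_id=pose_id,
        electrostatics=electrostatic_energy(
            receptor, ligand_pose, charges_r, charges_l, eps0=eps0
        ),
        desolvation=desolvation_energy(receptor, ligand_pose, point_number=sasa_points),
        vdw_weighted=vdw_energy(receptor, ligand_pose),
    )


def write_energy_table(scores: Sequence[EnergyScore], path: str | Path) -> None:
    rows = [
        {
            "pose_id": s.pose_id,
            "elec": s.electrostatics,
            "desolv": s.desolvation,
            "vdw": s.vdw_weighted,
            "total": s.total,
        }
        for s in scores
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_energy_table(path: str | Path) -> pd.DataFrame:
    """External per-pose energies: TSV with at least pose_id and total columns."""
    df = pd.read_csv(path, sep="\t")
    if "pose_id" not in df.columns:
        raise ValueError(f"{path}: energy table needs a pose_id column")
    if "total" not in df.columns:
        if "energy" in df.columns:
            df = df.rename(columns={"energy": "total"})
        else:
            raise ValueError(f"{path}: energy table needs a total (or energy) column")
    return df
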