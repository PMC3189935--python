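"""Protein structures as residue/atom containers, with surface and shape descriptors.

PDB files are parsed with :mod:`gemmi` into a light-weight residue-centric
container that the network, scoring and energy modules consume.  Residues keep
the author numbering of the source file — a residue is identified everywhere by
the triple ``(chain_id, resseq, icode)`` so that predictions can be reported
against the original coordinates.

Per-atom solvent accessibility is computed with the Shrake–Rupley sphere-point
method as implemented in :func:`biotite.structure.sasa`; relative accessibility
divides the summed residue ASA by an embedded table of per-residue maximal
areas (theoretical Gly-X-Gly values of Tien et al. 2013).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "SurfaceProfile",
    "ShapeDescriptor",
    "ResidueID",
    "STANDARD_AMINO_ACIDS",
    "MAX_ASA",
    "read_structure",
    "write_structure",
    "compute_surface",
    "compute_shape",
    "true_interface",
]

#: residue identifier used throughout the package: (chain id, resseq, icode)
ResidueID = tuple[str, int, str]

STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

# Maximal accessible surface areas (Å²), theoretical values from extended
# Gly-X-Gly tripeptides (Tien et al. 2013).  Used as the denominator of the
# relative ASA; unknown residue types fall back to the GLY value.
MAX_ASA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

_HYDROGEN_ELEMENTS = {"H", "D"}


@dataclass
class Atom:
    """A single atom: label, element symbol and Cartesian coordinates in Å."""

    name: str
    element: str
    coords: np.ndarray  # shape (3,)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in _HYDROGEN_ELEMENTS


@dataclass
class Residue:
    """One residue: identity triple, 3-letter type and its atoms.

    ``cb`` returns the Cβ atom, falling back to Cα for glycine (and any
    residue that simply lacks a Cβ is reported as ``None`` so callers can
    decide how to treat it).
    """

    residue_id: ResidueID
    res_type: str
    atoms: list[Atom] = field(default_factory=list)

    def get_atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Optional[Atom]:
        return self.get_atom("CA")

    @property
    def cb(self) -> Optional[Atom]:
        cb = self.get_atom("CB")
        if cb is None and self.res_type == "GLY":
            return self.ca
        return cb

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]


@dataclass
class Structure:
    """An ordered list of residues read from one model of a PDB file."""

    structure_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def residue_ids(self) -> list[ResidueID]:
        return [r.residue_id for r in self.residues]

    def get_residue(self, residue_id: ResidueID) -> Optional[Residue]:
        for r in self.residues:
            if r.residue_id == residue_id:
                return r
        return None

    def atom_records(self, heavy_only: bool = False) -> tuple[np.ndarray, list[ResidueID]]:
        """All atom coordinates plus the owning residue ID per atom."""
        coords: list[np.ndarray] = []
        owners: list[ResidueID] = []
        for res in self.residues:
            atoms = res.heavy_atoms if heavy_only else res.atoms
            for a in atoms:
                coords.append(a.coords)
                owners.append(res.residue_id)
        if not coords:
            return np.empty((0, 3)), []
        return np.vstack(coords), owners

    def ca_coords(self) -> np.ndarray:
        return np.vstack([r.ca.coords for r in self.residues if r.ca is not None])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a rigidly moved copy: x' = R x + t.  Residue IDs unchanged."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        out = Structure(self.structure_id)
        for res in self.residues:
            new = Residue(res.residue_id, res.res_type)
            for a in res.atoms:
                new.atoms.append(Atom(a.name, a.element, rotation @ a.coords + translation))
            out.residues.append(new)
        return out


@dataclass
class SurfaceProfile:
    """Per-residue relative accessible surface area and surface flags."""

    rel_asa: dict[ResidueID, float]
    threshold: float

    def is_surface(self, residue_id: ResidueID) -> bool:
        return self.rel_asa.get(residue_id, 0.0) > self.threshold

    @property
    def surface_residues(self) -> list[ResidueID]:
        return [rid for rid, v in self.rel_asa.items() if v > self.threshold]

    def to_tsv(self, path: str | Path, structure: Structure) -> None:
        with open(path, "w") as fh:
            fh.write("chain\tresseq\ticode\tres_type\trel_asa\tis_surface\n")
            for res in structure.residues:
                rid = res.residue_id
                v = self.rel_asa.get(rid)
                if v is None:
                    continue
                fh.write(
                    f"{rid[0]}\t{rid[1]}\t{rid[2] or '.'}\t{res.res_type}"
                    f"\t{v:.6f}\t{int(v > self.threshold)}\n"
                )


@dataclass
class ShapeDescriptor:
    """Principal-axis extents (Å, ascending) and the anisotropy class.

    Anisotropy is the extent of the most different principal axis divided by
    the mean extent of the other two; below 0.7 the shape is oblate, above 2.0
    prolate, otherwise spherical.
    """

    axis_lengths: tuple[float, float, float]
    anisotropy: float
    shape_class: str


def read_structure(
    path: str | Path,
    model_index: int = 0,
    chain_filter: Optional[Iterable[str]] = None,
) -> Structure:
    """Read one model of a PDB file into a :class:`Structure`.

    Alternate locations are resolved by keeping, per atom name, the highest
    occupancy copy (ties broken by altloc letter, 'A' first).  Hydrogens are
    retained and flagged non-heavy.  HETATM records are skipped: networks and
    accessibility are defined on polymer residues.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such PDB file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"malformed PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    if model_index >= len(st):
        raise ValueError(f"model index {model_index} out of range ({len(st)} models)")
    model = st[model_index]
    chains = set(chain_filter) if chain_filter is not None else None

    out = Structure(structure_id=path.stem)
    for chain in model:
        if chains is not None and chain.name not in chains:
            continue
        for res in chain:
            if res.het_flag != "A":  # HETATM
                continue
            rid: ResidueID = (chain.name, res.seqid.num, res.seqid.icode.strip())
            # resolve altlocs: highest occupancy per atom name, ties 'A' first
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None or (atom.occ, -ord(atom.altloc or "A")) > (
                    prev.occ,
                    -ord(prev.altloc or "A"),
                ):
                    best[atom.name] = atom
            residue = Residue(rid, res.name)
            for atom in best.values():
                coords = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                if not np.all(np.isfinite(coords)):
                    raise ValueError(
                        f"malformed coordinates for atom {atom.name} of {res.name} {rid}"
                    )
                residue.atoms.append(Atom(atom.name, atom.element.name, coords))
            if residue.atoms:
                out.residues.append(residue)
    if not out.residues:
        raise ValueError(f"no protein atoms in {path} after filtering")
    return out


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a Structure as a single-model PDB file (via gemmi)."""
    st = gemmi.Structure()
    st.name = structure.structure_id
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for res in structure.residues:
        chain_id, resseq, icode = res.residue_id
        chain = chains.get(chain_id)
        if chain is None:
            chain = gemmi.Chain(chain_id)
            chains[chain_id] = chain
        g_res = gemmi.Residue()
        g_res.name = res.res_type
        g_res.seqid = gemmi.SeqId(resseq, icode or " ")
        for a in res.atoms:
            g_atom = gemmi.Atom()
            g_atom.name = a.name
            g_atom.element = gemmi.Element(a.element)
            g_atom.pos = gemmi.Position(*a.coords)
            g_atom.occ = 1.0
            g_res.add_atom(g_atom)
        chain.add_residue(g_res)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def _atom_array(structures: Sequence[Structure]):
    """Heavy atoms of one or more structures as a biotite AtomArray."""
    import biotite.structure as struc

    atoms: list[Atom] = []
    owners: list[tuple[int, ResidueID, str]] = []
    for idx, s in enumerate(structures):
        for res in s.residues:
            for a in res.heavy_atoms:
                atoms.append(a)
                owners.append((idx, res.residue_id, res.res_type))
    n = len(atoms)
    if n == 0:
        raise ValueError("no heavy atoms")
    arr = struc.AtomArray(n)
    arr.coord = np.vstack([a.coords for a in atoms])
    arr.element = np.array([a.element.upper() for a in atoms])
    arr.atom_name = np.array([a.name for a in atoms])
    arr.res_name = np.array([o[2] for o in owners])
    arr.res_id = np.arange(n)  # not used by element-radius SASA
    arr.chain_id = np.array([str(o[0]) for o in owners])
    return arr, owners


def _canonical_coords(coords: np.ndarray) -> np.ndarray:
    """Coordinates in a canonical principal-axis frame.

    The sphere-point SASA sampling is orientation-dependent; evaluating it in
    a frame fixed by the point cloud itself makes the resulting areas exactly
    invariant under rigid motion of the input.  Eigenvector signs are fixed by
    the third moment of the projections (falling back to the largest
    component) and the frame is forced right-handed.
    """
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered
    _, vecs = np.linalg.eigh(cov)
    # sign-fix the two largest-variance axes (the smallest may be degenerate,
    # e.g. planar toys); the remaining axis follows by cross product
    for i in (2, 1):
        proj = centered @ vecs[:, i]
        skew = float((proj**3).sum())
        if abs(skew) > 1e-9:
            if skew < 0:
                vecs[:, i] = -vecs[:, i]
        elif proj[np.argmax(np.abs(proj))] < 0:
            vecs[:, i] = -vecs[:, i]
    vecs[:, 0] = np.cross(vecs[:, 1], vecs[:, 2])
    return centered @ vecs


def atom_sasa(structures: Sequence[Structure], point_number: int = 960) -> np.ndarray:
    """Per-heavy-atom solvent accessible surface area (Å²) of the assembly.

    Computed in a canonical principal-axis frame so the values are invariant
    under rigid motion of the whole assembly.
    """
    import biotite.structure as struc

    arr, _ = _atom_array(structures)
    arr.coord = _canonical_coords(arr.coord)
    vals = struc.sasa(arr, point_number=point_number, vdw_radii="Single")
    return np.nan_to_num(np.asarray(vals, dtype=float))


def compute_surface(
    structure: Structure,
    rel_asa_threshold: float = 0.001,
    point_number: int = 960,
) -> SurfaceProfile:
    """Relative per-residue accessibility and the surface flag.

    Relative ASA is the residue's summed heavy-atom ASA in the context of the
    whole structure, divided by the reference maximal ASA of its residue type.
    A residue is on the surface when relative ASA exceeds the threshold
    (default 0.001, i.e. 0.1% — effectively "any exposure at all").
    """
    _, owners = _atom_array([structure])
    vals = atom_sasa([structure], point_number=point_number)
    per_res: dict[ResidueID, float] = {r.residue_id: 0.0 for r in structure.residues}
    for v, (_, rid, _) in zip(vals, owners):
        per_res[rid] += float(v)
    rel: dict[ResidueID, float] = {}
    for res in structure.residues:
        ref = MAX_ASA.get(res.res_type)
        if ref is None:
            warnings.warn(
                f"unknown residue type {res.res_type} at {res.residue_id}; "
                "using glycine reference area"
            )
            ref = MAX_ASA["GLY"]
        rel[res.residue_id] = per_res[res.residue_id] / ref
    return SurfaceProfile(rel_asa=rel, threshold=rel_asa_threshold)


def compute_shape(structure: Structure) -> ShapeDescriptor:
    """Shape class of the Cα cloud from its principal-axis extents.

    Extents are peak-to-peak lengths along the principal axes of the Cα
    coordinates.  The anisotropy is the extent of the axis most different from
    the other two, divided by the mean of the other two.
    """
    coords = structure.ca_coords()
    if coords.shape[0] < 3:
        raise ValueError("need at least 3 Cα atoms for a shape descriptor")
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / coords.shape[0]
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals[1] <= 1e-9 * max(eigvals[2], 1.0):
        raise ValueError("degenerate (collinear) Cα cloud")
    proj = centered @ eigvecs
    extents = np.sort(proj.max(axis=0) - proj.min(axis=0))

    # "most different" axis: the one whose extent deviates most, multiplicatively,
    # from the mean of the remaining two (a rod's long axis, a disc's short one)
    best_ratio = None
    best_dev = -1.0
    for i in range(3):
        others = [extents[j] for j in range(3) if j != i]
        mean_others = float(np.mean(others))
        ratio = extents[i] / mean_others
        dev = max(ratio, 1.0 / ratio)
        if dev > best_dev:
            best_dev = dev
            best_ratio = ratio
    anisotropy = float(best_ratio)
    if anisotropy < 0.7:
        shape_class = "oblate"
    elif anisotropy > 2.0:
        shape_class = "prolate"
    else:
        shape_class = "spherical"
    return ShapeDescriptor(tuple(float(e) for e in extents), anisotropy, shape_class)


def true_interface(a: Structure, b: Structure, cutoff: float = 10.0) -> set[ResidueID]:
    """Residues of ``a`` with at least one atom within ``cutoff`` Å of ``b``.

    This is the binding-site ground truth used to evaluate interface
    predictions: any-atom contact at 10 Å against the partner in the complex.
    """
    coords_a, owners_a = a.atom_records(heavy_only=False)
    coords_b, _ = b.atom_records(heavy_only=False)
    if coords_a.shape[0] == 0 or coords_b.shape[0] == 0:
        raise ValueError("true_interface requires non-empty structures")
    tree = cKDTree(coords_b)
    hits = tree.query_ball_point(coords_a, r=cutoff)
    return {owners_a[i] for i, lst in enumerate(hits) if lst}
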