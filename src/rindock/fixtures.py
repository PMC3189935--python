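"""Synthetic pseudo-protein structures and decoy ensembles with known truth.

The generator emulates the statistical structure the scoring method relies
on — near-native poses bury a surface patch of high-centrality residues —
without pretending to be physically realistic folds:

* :func:`make_structure` grows a self-avoiding chain of glycine/alanine-like
  pseudo-residues (N, CA, C, O and an optional CB) with ~3.8 Å consecutive
  Cα spacing, confined to an ellipsoid whose aspect ratio controls the shape
  class (sphere, rod, disc, two-domain) at protein-like packing density.
* :func:`make_complex_and_decoys` builds a receptor and a smaller ligand,
  places the "bound" reference pose against a chosen receptor surface patch,
  and surrounds it with rigid-body decoys: a controlled fraction are small
  perturbations of the reference (near-native by construction), the rest are
  random contact placements elsewhere on the receptor.  The network-signal
  strength interpolates the docking site between the centroid of the
  highest-closeness surface residues (signal 1: near-natives bury the
  high-centrality patch) and a random surface site (signal 0).
* :func:`make_benchmark_case` scores the decoys with the real pipeline
  (closeness at 15 Å) and attaches a synthetic energy column whose
  noise level is controlled, yielding BenchmarkCases for weight-fit studies.

All randomness flows from the seed in the spec; the same seed reproduces
every coordinate bit-for-bit.  RMSD labels are computed with
:func:`rindock.evaluation.ligand_rmsd`, so generator and evaluator check each
other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .centrality import compute_profile
from .combine import BenchmarkCase
from .evaluation import ligand_rmsd
from .network import build_network
from .scoring import Pose, docking_interface, network_score, score_pose_set
from .structure import Atom, Residue, ResidueID, Structure

__all__ = [
    "FixtureSpec",
    "make_structure",
    "make_complex_and_decoys",
    "make_benchmark_case",
    "planted_patch",
    "write_fixture_dir",
]

CA_STEP = 3.8  # consecutive Cα spacing, Å
MIN_CA_SEPARATION = 3.6  # self-avoidance for non-consecutive residues, Å
RESIDUE_VOLUME = 150.0  # Å³ per residue: sets the confinement ellipsoid size


@dataclass
class FixtureSpec:
    """Everything that determines one synthetic docking case."""

    n_residues: int = 100
    ligand_residues: int = 24
    shape: str = "disc"  # sphere | rod | disc | two-domain
    aspect: float = 6.0  # axis ratio for rod/disc
    patch_size: int = 8  # residues defining the docking site
    seed: int = 0
    n_decoys: int = 100
    near_native_fraction: float = 0.02
    signal: float = 1.0  # 1: site at the high-closeness patch; 0: random site
    energy_noise: float = 1.0  # sd of the synthetic energy noise (score units)

    def __post_init__(self) -> None:
        if self.n_residues < 5:
            raise ValueError("need at least 5 residues")
        if not 0.0 < self.near_native_fraction < 1.0:
            raise ValueError("near-native fraction must be in (0, 1)")


def _semiaxes(n: int, shape: str, aspect: float) -> tuple[float, float, float]:
    volume = RESIDUE_VOLUME * n
    if shape == "sphere" or shape == "two-domain":
        r = (3 * volume / (4 * math.pi)) ** (1 / 3)
        return (r, r, r)
    if shape == "rod":  # prolate: c = aspect · a
        a = (3 * volume / (4 * math.pi * aspect)) ** (1 / 3)
        return (a, a, aspect * a)
    if shape == "disc":  # oblate: c = a / aspect
        a = (3 * volume * aspect / (4 * math.pi)) ** (1 / 3)
        return (a, a, a / aspect)
    raise ValueError(f"unknown shape {shape!r}")


def _inside(point: np.ndarray, semiaxes: tuple[float, float, float], shape: str) -> bool:
    a, b, c = semiaxes
    if shape == "two-domain":
        # two spheres of radius a·(1/2)^(1/3) with centers 1.2·a apart
        r = a * 0.5 ** (1 / 3)
        offset = np.array([0.6 * a, 0.0, 0.0])
        return (
            np.linalg.norm(point - offset) <= r or np.linalg.norm(point + offset) <= r
        )
    return (point[0] / a) ** 2 + (point[1] / b) ** 2 + (point[2] / c) ** 2 <= 1.0


def _grow_chain(
    rng: np.random.Generator,
    n: int,
    semiaxes: tuple[float, float, float],
    shape: str,
    max_tries: int = 300,
) -> np.ndarray:
    """Self-avoiding random walk of Cα positions inside the confinement body."""
    pts = np.empty((n, 3))
    start = np.zeros(3)
    if shape == "two-domain":
        start = np.array([0.6 * semiaxes[0], 0.0, 0.0])
    pts[0] = start
    for i in range(1, n):
        placed = False
        for _ in range(max_tries):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            cand = pts[i - 1] + CA_STEP * direction
            if not _inside(cand, semiaxes, shape):
                continue
            if i >= 2:
                d = np.linalg.norm(pts[: i - 1] - cand, axis=1)
                if d.min() < MIN_CA_SEPARATION:
                    continue
            pts[i] = cand
            placed = True
            break
        if not placed:
            # relax self-avoidance rather than fail: accept any in-body step
            for _ in range(max_tries):
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                cand = pts[i - 1] + CA_STEP * direction
                if _inside(cand, semiaxes, shape):
                    pts[i] = cand
                    placed = True
                    break
        if not placed:
            raise ValueError(
                f"infeasible geometry: cannot grow a {n}-residue chain in a "
                f"{shape} of semiaxes {semiaxes}"
            )
    return pts


def _residue_from_ca(
    rng: np.random.Generator, rid: ResidueID, ca: np.ndarray, direction: np.ndarray
) -> Residue:
    """Glycine/alanine-like pseudo-residue built around one Cα position."""
    d = direction / np.linalg.norm(direction)
    # an arbitrary unit vector orthogonal to the chain direction
    ref = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    res = Residue(rid, "ALA")
    res.atoms.append(Atom("N", "N", ca - 1.46 * d + 0.3 * u))
    res.atoms.append(Atom("CA", "C", ca))
    res.atoms.append(Atom("C", "C", ca + 1.52 * d + 0.3 * u))
    res.atoms.append(Atom("O", "O", ca + 1.52 * d + 0.3 * u + 1.23 * v))
    res.atoms.append(Atom("CB", "C", ca + 1.53 * u))
    return res


def make_structure(
    n_residues: int = 80,
    shape: str = "sphere",
    aspect: float = 3.0,
    seed: int = 0,
    chain_id: str = "A",
    structure_id: Optional[str] = None,
) -> Structure:
    """Pseudo-protein with backbone-like Cα spacing and a chosen global shape."""
    rng = np.random.default_rng(seed)
    semiaxes = _semiaxes(n_residues, shape, aspect)
    ca = _grow_chain(rng, n_residues, semiaxes, shape)
    s = Structure(structure_id or f"{shape}{n_residues}_s{seed}")
    for i in range(n_residues):
        if i + 1 < n_residues:
            direction = ca[i + 1] - ca[i]
        else:
            direction = ca[i] - ca[i - 1]
        s.residues.append(
            _residue_from_ca(rng, (chain_id, i + 1, ""), ca[i], direction)
        )
    return s


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (deterministic)."""
    i = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det fixed)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] *= -1
    return q


def _small_rotation(rng: np.random.Generator, max_angle_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = math.radians(rng.uniform(0.0, max_angle_deg))
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


def _slide_to_contact(
    receptor: Structure,
    ligand: Structure,
    rotation: np.ndarray,
    direction: np.ndarray,
    anchor: np.ndarray,
    target_gap: float = 4.0,
) -> np.ndarray:
    """Translation putting the rotated ligand in contact along ``direction``.

    The ligand (centered at the origin) is moved outward from ``anchor`` until
    the minimal heavy-atom distance to the receptor is ~``target_gap`` Å.
    """
    from scipy.spatial import cKDTree

    coords_r, _ = receptor.atom_records(heavy_only=True)
    coords_l0, _ = ligand.atom_records(heavy_only=True)
    rotated = coords_l0 @ rotation.T
    tree = cKDTree(coords_r)

    def min_dist(offset: float) -> float:
        t = anchor + offset * direction
        dists, _ = tree.query(rotated + t, k=1)
        return float(dists.min())

    lo, hi = 0.0, 1.0
    while min_dist(hi) < target_gap and hi < 500.0:
        hi *= 2.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if min_dist(mid) < target_gap:
            lo = mid
        else:
            hi = mid
    return anchor + hi * direction


def _center(structure: Structure) -> np.ndarray:
    coords, _ = structure.atom_records(heavy_only=True)
    return coords.mean(axis=0)


def make_complex_and_decoys(
    spec: FixtureSpec,
) -> tuple[Structure, Structure, Pose, list[Pose]]:
    """Receptor, unbound ligand, reference bound pose, and labeled decoys.

    The reference pose buries a receptor surface patch chosen by closeness
    (blended with a random choice according to the signal strength); decoys
    are rigid perturbations with computed ligand Cα-RMSD labels, and at least
    one decoy is guaranteed near-native (< 10 Å).
    """
    rng = np.random.default_rng(spec.seed)
    receptor = make_structure(
        spec.n_residues, spec.shape, spec.aspect, seed=spec.seed, chain_id="A",
        structure_id="receptor",
    )
    ligand = make_structure(
        spec.ligand_residues, "sphere", seed=spec.seed + 1, chain_id="B",
        structure_id="ligand",
    )
    # center the unbound ligand on its heavy-atom centroid
    ligand = ligand.transformed(np.eye(3), -_center(ligand))

    # Docking-site search: slide the ligand to contact along many candidate
    # approach directions and score each site by the summed closeness of the
    # receptor residues it would bury (the quantity the method ranks poses
    # by).  The signal strength blends that ranking with pure noise: at 1 the
    # reference pose buries the highest-closeness site the geometry offers,
    # at 0 a uniformly random contact site.
    net = build_network(receptor, atom_mode="CA", cutoff=8.5)
    profile = compute_profile(net)
    clo = profile.parameter("closeness")
    from .structure import compute_surface, true_interface

    surface = compute_surface(receptor)
    top4 = sorted(
        (rid for rid in surface.surface_residues if rid in clo),
        key=lambda rid: (-clo[rid], rid),
    )[:4]
    anchor = _center(receptor)
    ref_rot = _random_rotation(rng)
    directions = _fibonacci_sphere(48)
    site_scores = np.empty(len(directions))
    translations = []
    for i, direction in enumerate(directions):
        t = _slide_to_contact(receptor, ligand, ref_rot, direction, anchor)
        translations.append(t)
        posed = Pose("cand", ref_rot, t).apply(ligand)
        iface = docking_interface(receptor, posed, d=15.0)
        # primary: how many of the top-closeness surface residues the pose
        # covers at the 10 Å truth cutoff; secondary: closeness content of the
        # docking interface (what the scoring sums)
        covered = len(set(top4) & true_interface(receptor, posed, 10.0))
        site_scores[i] = 1000.0 * covered + network_score(
            profile, profile, (iface[0], set()), "closeness"
        )
    z = (site_scores - site_scores.mean()) / (site_scores.std() + 1e-12)
    blended = spec.signal * z + (1.0 - spec.signal) * rng.normal(size=len(directions))
    best = int(np.argmax(blended))
    out_dir = directions[best]
    ref_trans = translations[best]
    reference = Pose("reference", ref_rot, ref_trans, rmsd=0.0)
    bound_ligand = reference.apply(ligand)

    # Every decoy — near-native or not — goes through the same construction:
    # pick an approach direction and an orientation, slide to contact.  Only
    # the sampling distributions differ, so the two classes share identical
    # contact-geometry statistics and labels carry no construction artifact.
    n_native = max(1, int(round(spec.near_native_fraction * spec.n_decoys)))
    poses: list[Pose] = []
    for i in range(spec.n_decoys):
        pid = f"pose_{i:04d}"
        if i < n_native:
            pose = None
            for attempt in range(30):
                shrink = 1.0 / (1 + attempt)
                rot = _small_rotation(rng, max_angle_deg=15.0 * shrink) @ ref_rot
                direction = out_dir + rng.normal(scale=0.12 * shrink, size=3)
                direction /= np.linalg.norm(direction)
                trans = _slide_to_contact(receptor, ligand, rot, direction, anchor)
                cand = Pose(pid, rot, trans)
                cand.rmsd = ligand_rmsd(bound_ligand, cand.apply(ligand))
                if cand.rmsd < 10.0:
                    pose = cand
                    break
            if pose is None:  # fall back to the reference placement itself
                pose = Pose(pid, ref_rot, ref_trans, rmsd=0.0)
        else:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            rot = _random_rotation(rng)
            trans = _slide_to_contact(receptor, ligand, rot, direction, anchor)
            pose = Pose(pid, rot, trans)
            pose.rmsd = ligand_rmsd(bound_ligand, pose.apply(ligand))
        poses.append(pose)
    return receptor, ligand, reference, poses


def planted_patch(
    receptor: Structure,
    ligand: Structure,
    reference: Pose,
    patch_size: int = 8,
    d: float = 15.0,
) -> list[ResidueID]:
    """The planted interface patch: top-closeness receptor residues buried by
    the reference pose.  On signal-1 fixtures their mean closeness exceeds the
    structure mean — the property the decoy scoring exploits."""
    profile = compute_profile(build_network(receptor, "CA", 8.5))
    iface_r, _ = docking_interface(receptor, reference.apply(ligand), d=d)
    clo = profile.parameter("closeness")
    ranked = sorted(iface_r, key=lambda rid: (-clo.get(rid, 0.0), rid))
    return ranked[:patch_size]


def make_benchmark_case(
    spec: FixtureSpec,
    case_id: Optional[str] = None,
    parameter: str = "closeness",
    d: float = 15.0,
    atom_mode: str = "CA",
    network_cutoff: float = 8.5,
) -> BenchmarkCase:
    """Score one synthetic decoy set into a BenchmarkCase.

    Network scores come from the real pipeline (profiles on the unbound
    partners, docking interfaces at d).  The energy column is synthetic:
    a weak pose-quality term plus Gaussian noise of sd ``energy_noise``, so
    weight-fit studies can dial the informativeness of the energy score.
    """
    rng = np.random.default_rng(spec.seed + 7919)
    receptor, ligand, _, poses = make_complex_and_decoys(spec)
    profile_r = compute_profile(build_network(receptor, atom_mode, network_cutoff))
    profile_l = compute_profile(build_network(ligand, atom_mode, network_cutoff))
    scored = score_pose_set(
        receptor, ligand, poses, profile_r, profile_l, parameters=[parameter], d=d
    )
    network = np.array([s.scores[parameter] for s in scored])
    rmsd = np.array([p.rmsd for p in poses])
    # pose-quality signal (capped RMSD) + controlled noise; lower is better
    energy = 0.1 * np.minimum(rmsd, 30.0) + spec.energy_noise * rng.normal(
        size=len(poses)
    )
    return BenchmarkCase(
        case_id=case_id or f"case_s{spec.seed}",
        pose_ids=[p.pose_id for p in poses],
        energy=energy,
        network=network,
        rmsd=rmsd,
    )


def write_fixture_dir(spec: FixtureSpec, out_dir: str | Path) -> None:
    """Write receptor/ligand PDBs, the pose table and case metadata to a directory."""
    from .scoring import write_pose_table
    from .structure import compute_shape, write_structure

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    receptor, ligand, reference, poses = make_complex_and_decoys(spec)
    write_structure(receptor, out / "receptor.pdb")
    write_structure(ligand, out / "ligand.pdb")
    write_structure(reference.apply(ligand), out / "ligand_bound.pdb")
    write_pose_table([reference] + poses, out / "poses.tsv")
    shape = compute_shape(receptor)
    with open(out / "metadata.tsv", "w") as fh:
        fh.write("case_id\tcomplex_type\tn_decoys\tanisotropy\tshape_class\tseed\n")
        fh.write(
            f"case_s{spec.seed}\tother\t{spec.n_decoys}"
            f"\t{shape.anisotropy:.4f}\t{shape.shape_class}\t{spec.seed}\n"
        )
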