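"""Deterministic synthetic structures for exercising every pipeline stage.

The generators build toy receptor "cages" (closed or cup-shaped shells of
carbon-like pseudo-atoms enclosing a cavity of known center), small ligands
(alkane chains with known rotatable bonds, aromatic rings with known
automorphism groups, rigid asymmetric polyatoms), and complete docking cases
with a planted native pose.  Everything is parameterized from the default
van der Waals table and serializes to valid PDB/MOL2, so the full pipeline
runs with no external input.  A given kind/size/seed always reproduces the
same structure bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .graph_match import Pose
from .io_formats import AtomRecord, Ligand, ParameterTable, Receptor, \
    assign_parameters, detect_rotatable_bonds

__all__ = [
    "FixtureSpec",
    "make_cage",
    "make_cup",
    "make_ligand",
    "make_docking_case",
    "fibonacci_sphere",
]

PSEUDO_RADIUS = 1.908      # Å, carbon-like cage atom radius
PSEUDO_EPS = 0.086         # kcal/mol
CONTACT_OPT = 2 * PSEUDO_RADIUS  # well-minimum receptor-ligand distance
BOND_CC = 1.53             # Å, alkane C-C
BOND_AROMATIC = 1.39       # Å, aromatic C-C
CC_ANGLE = math.radians(111.0)


@dataclass(frozen=True)
class FixtureSpec:
    kind: str          # cage_pocket | cup_pocket | alkane | ring | rigid_polyatom
    size: int
    seed: int


def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately evenly spread unit vectors (golden-spiral lattice)."""
    k = np.arange(n, dtype=float)
    phi = np.arccos(1.0 - 2.0 * (k + 0.5) / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def _receptor_from_points(points: np.ndarray,
                          atoms_per_residue: int = 5) -> Receptor:
    records = []
    for k, xyz in enumerate(points, start=1):
        res = (k - 1) // atoms_per_residue + 1
        within = (k - 1) % atoms_per_residue + 1
        records.append(AtomRecord(
            index=k, element="C", atom_name=f"DU{within}", atom_type="Du",
            coords=np.asarray(xyz, dtype=float),
            residue_id=("A", res, "CAG")))
    return assign_parameters(Receptor(atoms=records))


def make_cage(radius: float = 6.0, n_atoms: int = 60, seed: int = 0,
              center: np.ndarray | None = None
              ) -> tuple[Receptor, np.ndarray]:
    """Closed spherical shell of pseudo-atoms around an empty cavity.

    Returns the receptor and the exact cavity center.  The seed jitters the
    atom placement on the shell (±0.15 Å) without moving the cavity center.
    """
    if radius <= 2 * PSEUDO_RADIUS:
        raise ValueError("radius must exceed the pseudo-atom vdW diameter")
    center = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    rng = np.random.default_rng(seed)
    pts = center + radius * fibonacci_sphere(n_atoms)
    pts = pts + rng.uniform(-0.15, 0.15, size=pts.shape)
    return _receptor_from_points(pts), center


def make_cup(radius: float = 6.0, n_atoms: int = 80, seed: int = 0,
             center: np.ndarray | None = None
             ) -> tuple[Receptor, np.ndarray]:
    """Hemispherical cup open toward +z; from the cup center, 5 of the 6
    axis rays hit the wall."""
    center = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    rng = np.random.default_rng(seed)
    dirs = fibonacci_sphere(n_atoms * 2)
    dirs = dirs[dirs[:, 2] <= 0.05][:n_atoms]
    pts = center + radius * dirs
    pts = pts + rng.uniform(-0.15, 0.15, size=pts.shape)
    return _receptor_from_points(pts), center


def _zero_sum_charges(rng: np.random.Generator, n: int) -> np.ndarray:
    q = rng.uniform(-0.05, 0.05, size=n)
    return q - q.mean()


def _alkane_coords(n: int) -> np.ndarray:
    dx = BOND_CC * math.sin(CC_ANGLE / 2)
    dz = BOND_CC * math.cos(CC_ANGLE / 2)
    return np.array([[k * dx, 0.0, (k % 2) * dz] for k in range(n)])


def _ring_coords(n: int) -> np.ndarray:
    r = BOND_AROMATIC / (2 * math.sin(math.pi / n))
    ang = 2 * math.pi * np.arange(n) / n
    return np.stack([r * np.cos(ang), r * np.sin(ang), np.zeros(n)], axis=1)


def _rigid_polyatom_coords(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random self-avoiding chain: asymmetric rigid cluster, bond 1.53 Å."""
    coords = [np.zeros(3)]
    while len(coords) < n:
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        cand = coords[-1] + BOND_CC * u
        if all(np.linalg.norm(cand - c) > 2.2 for c in coords[:-1]):
            coords.append(cand)
    xyz = np.array(coords)
    return xyz - xyz.mean(axis=0)


def make_ligand(kind: str = "alkane", n_atoms: int = 4,
                seed: int = 0) -> Ligand:
    """Build a connected toy ligand, parameterized and charged.

    Kinds: ``alkane`` (zig-zag united-atom carbon chain; interior C-C bonds
    rotatable), ``ring`` (regular aromatic carbon ring; no rotatable bonds,
    dihedral automorphism group), ``rigid_polyatom`` (random asymmetric
    chain with double bonds, hence rigid).  Charges are small seeded values
    summing to zero.
    """
    if n_atoms < 2:
        raise ValueError("need at least 2 atoms")
    rng = np.random.default_rng(seed)
    if kind == "alkane":
        xyz = _alkane_coords(n_atoms)
        atype, btype = "C.3", "1"
        bonds = [(k, k + 1, btype) for k in range(1, n_atoms)]
    elif kind == "ring":
        if n_atoms < 3:
            raise ValueError("a ring needs at least 3 atoms")
        xyz = _ring_coords(n_atoms)
        atype, btype = "C.ar", "ar"
        bonds = [(k, k % n_atoms + 1, btype) for k in range(1, n_atoms + 1)]
    elif kind == "rigid_polyatom":
        xyz = _rigid_polyatom_coords(n_atoms, rng)
        atype, btype = "C.2", "2"
        bonds = [(k, k + 1, btype) for k in range(1, n_atoms)]
    else:
        raise ValueError(f"unknown ligand kind {kind!r}")

    charges = _zero_sum_charges(rng, n_atoms)
    atoms = [AtomRecord(index=k + 1, element="C", atom_name=f"C{k + 1}",
                        atom_type=atype, coords=xyz[k], charge=charges[k])
             for k in range(n_atoms)]
    lig = Ligand(atoms=atoms, bonds=bonds)
    lig.rotatable_bonds = detect_rotatable_bonds(lig)
    return assign_parameters(lig)


def _molded_shell(lig_xyz: np.ndarray, center: np.ndarray, n_dirs: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Shell points molded to the ligand: along each direction from the
    center, the point where the distance to the nearest ligand atom equals
    the vdW-optimal contact distance."""
    dirs = fibonacci_sphere(n_dirs)
    dirs = dirs + rng.uniform(-0.05, 0.05, size=dirs.shape)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    shell = []
    ts = np.arange(0.5, 15.0, 0.02)
    for u in dirs:
        line = center + ts[:, None] * u
        dmin = np.sqrt(((line[:, None, :] - lig_xyz[None, :, :]) ** 2
                        ).sum(axis=2)).min(axis=1)
        # outermost region where the clearance first reaches the optimum
        beyond = np.flatnonzero(dmin >= CONTACT_OPT)
        k = beyond[0] if len(beyond) else len(ts) - 1
        shell.append(line[k])
    return np.array(shell)


def make_docking_case(seed: int = 0, n_ligand_atoms: int = 8,
                      n_shell: int = 180
                      ) -> tuple[Receptor, Ligand, Pose, np.ndarray]:
    """A complete docking problem with a planted native pose.

    An asymmetric rigid ligand is centred at the origin and a receptor shell
    is molded around it at the van der Waals contact optimum, so the native
    pose sits in a deep, shape-specific energy funnel (negative total energy
    under vdW + Coulomb weights).  Returns (receptor, ligand-in-native-pose,
    native Pose, binding-site center).
    """
    rng = np.random.default_rng(seed)
    ligand = make_ligand("rigid_polyatom", n_ligand_atoms, seed)
    xyz = ligand.coords
    center = xyz.mean(axis=0)
    shell = _molded_shell(xyz, center, n_shell, rng)
    receptor = _receptor_from_points(shell, atoms_per_residue=6)
    native = Pose(coords=xyz.copy(), source="decoy")
    return receptor, ligand, native, center
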