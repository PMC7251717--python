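"""Negative-image binding-pocket construction.

A cubic box (edge 20 Å by default) of lattice points at 2 Å spacing is
centred on the user-supplied binding-site center, and the empty space of the
cavity is carved out by four successive filters:

1. keep points whose distance to the nearest receptor atom is in [2.5, 4.5] Å
   (relaxed mode for predicted receptor structures lowers 2.5 to 2.0 Å);
2. drop singleton points with fewer than 3 adjacent surviving points;
3. drop solvent-exposed points (axis ray casting against receptor atoms);
4. drop points farther from the box center than the ligand radius.

The surviving points negatively image the cavity; they seed graph-matching
pose initialization and act as distance restraints during sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .io_formats import Ligand, Receptor

__all__ = [
    "PocketGrid",
    "PocketError",
    "enumerate_box",
    "filter_by_receptor_distance",
    "filter_singletons",
    "filter_solvent_exposed",
    "filter_by_ligand_radius",
    "build_pocket",
]

DEFAULT_EDGE = 20.0       # Å, box edge
DEFAULT_SPACING = 2.0     # Å, lattice spacing
DEFAULT_LO = 2.5          # Å, filter (1) lower cutoff
RELAXED_LO = 2.0          # Å, lower cutoff for predicted receptor structures
DEFAULT_HI = 4.5          # Å, filter (1) upper cutoff
MIN_RELAXED_POINTS = 10   # below this, relaxed mode skips filters (2)-(4)


class PocketError(RuntimeError):
    """Pocket construction failed (typically: bad binding-site center)."""


@dataclass
class PocketGrid:
    """Grid points that negatively image a binding cavity."""

    center: np.ndarray                 # binding-site center, Å
    spacing: float = DEFAULT_SPACING
    edge: float = DEFAULT_EDGE
    points: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    relaxed: bool = False

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)

    @property
    def n_points(self) -> int:
        return len(self.points)

    def write_xyz(self, path: str | Path) -> None:
        """Plain TSV, one x/y/z row per point."""
        np.savetxt(path, self.points, fmt="%.3f", delimiter="\t")

    def write_pdb(self, path: str | Path) -> None:
        """Dummy HETATM records, one per grid point."""
        with open(path, "w") as fh:
            for k, (x, y, z) in enumerate(self.points, start=1):
                fh.write(f"HETATM{k:5d}  DU  GRD A{k:4d}    "
                         f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          DU\n")
            fh.write("END\n")


def enumerate_box(center: np.ndarray, edge: float = DEFAULT_EDGE,
                  spacing: float = DEFAULT_SPACING) -> np.ndarray:
    """Regular lattice of ``ceil(edge/spacing) + 1`` points per axis.

    The lattice is symmetric about ``center``; with an even number of steps
    per axis (as at the 20 Å / 2 Å defaults, giving 11³ = 1331 points) the
    center itself is a lattice node.  When ``spacing`` does not divide
    ``edge`` the lattice spans the smallest spacing multiple covering the
    requested edge.
    """
    if edge <= 0 or spacing <= 0:
        raise ValueError("edge and spacing must be positive")
    center = np.asarray(center, dtype=float)
    m = int(np.ceil(edge / spacing - 1e-9))
    offsets = spacing * (np.arange(m + 1) - m / 2.0)
    gx, gy, gz = np.meshgrid(offsets, offsets, offsets, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    return pts + center


def filter_by_receptor_distance(points: np.ndarray, receptor: Receptor,
                                lo: float = DEFAULT_LO,
                                hi: float = DEFAULT_HI) -> np.ndarray:
    """Filter (1): keep points at [lo, hi] Å from the nearest receptor atom."""
    if receptor.n_atoms == 0:
        raise ValueError("receptor has no atoms")
    if not lo < hi:
        raise ValueError("need lo < hi")
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) == 0:
        return points
    dmin = cdist(points, receptor.coords).min(axis=1)
    return points[(dmin >= lo) & (dmin <= hi)]


def filter_singletons(points: np.ndarray,
                      spacing: float = DEFAULT_SPACING) -> np.ndarray:
    """Filter (2): drop points with fewer than 3 adjacent surviving points.

    Adjacency is the 26-neighbourhood at one lattice step: two points are
    adjacent when each coordinate differs by at most ``spacing`` (and they
    are distinct).  The neighbour universe is the surviving candidate set
    itself, and the filter is applied in a single pass.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) == 0:
        return points
    diff = np.abs(points[:, None, :] - points[None, :, :])
    adjacent = np.all(diff <= spacing + 1e-6, axis=2)
    np.fill_diagonal(adjacent, False)
    return points[adjacent.sum(axis=1) >= 3]


def filter_solvent_exposed(points: np.ndarray, receptor: Receptor,
                           min_blocked: int = 4,
                           max_range: float = 30.0) -> np.ndarray:
    """Filter (3): drop solvent-exposed points by 6-axis ray casting.

    From each point a ray is cast along each of ±x, ±y, ±z; a ray is blocked
    when it passes within a receptor atom's van der Waals radius (atom ahead
    of the point, within ``max_range`` Å).  Points with fewer than
    ``min_blocked`` of the 6 rays blocked are considered solvent exposed and
    removed.  Buried cavity points block most rays; surface points do not.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) == 0:
        return points
    rcoords = receptor.coords
    radii = receptor.vdw_radii
    keep = np.zeros(len(points), dtype=bool)
    axes = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                     [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float)
    for p_idx, p in enumerate(points):
        rel = rcoords - p                       # (n_atoms, 3)
        blocked = 0
        for u in axes:
            t = rel @ u                         # projection along the ray
            ahead = (t > 0) & (t <= max_range)
            if not np.any(ahead):
                continue
            perp2 = np.einsum("ij,ij->i", rel[ahead], rel[ahead]) - t[ahead] ** 2
            if np.any(perp2 < radii[ahead] ** 2):
                blocked += 1
        keep[p_idx] = blocked >= min_blocked
    return points[keep]


def filter_by_ligand_radius(points: np.ndarray, center: np.ndarray,
                            ligand: Ligand) -> np.ndarray:
    """Filter (4): keep points within the ligand radius of the box center.

    The ligand radius is the distance from the ligand centroid to its
    farthest atom.
    """
    if ligand.n_atoms == 0:
        raise ValueError("ligand has no atoms")
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) == 0:
        return points
    lig = ligand.coords
    r_lig = np.linalg.norm(lig - lig.mean(axis=0), axis=1).max()
    d = np.linalg.norm(points - np.asarray(center, dtype=float), axis=1)
    return points[d <= r_lig + 1e-9]


def build_pocket(receptor: Receptor, ligand: Ligand, center: np.ndarray,
                 relaxed: bool = False, edge: float = DEFAULT_EDGE,
                 spacing: float = DEFAULT_SPACING,
                 min_blocked: int = 4) -> PocketGrid:
    """Compose filters (1)-(4) into the negative-image pocket.

    ``relaxed=True`` is meant for predicted receptor structures whose pockets
    may be distorted: the lower distance cutoff drops to 2.0 Å and, if filter
    (1) already leaves fewer than 10 points, filters (2)-(4) are skipped so
    enough points remain to seed initial poses.
    """
    center = np.asarray(center, dtype=float)
    lo = RELAXED_LO if relaxed else DEFAULT_LO
    pts = enumerate_box(center, edge=edge, spacing=spacing)
    pts = filter_by_receptor_distance(pts, receptor, lo=lo, hi=DEFAULT_HI)
    if relaxed and len(pts) < MIN_RELAXED_POINTS:
        surviving = pts
    else:
        pts = filter_singletons(pts, spacing=spacing)
        pts = filter_solvent_exposed(pts, receptor, min_blocked=min_blocked)
        surviving = filter_by_ligand_radius(pts, center, ligand)
    if len(surviving) == 0:
        raise PocketError(
            "no pocket grid points survive the filters; the binding-site "
            "center is likely outside any cavity — try a different center")
    return PocketGrid(center=center, spacing=spacing, edge=edge,
                      points=surviving, relaxed=relaxed)
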