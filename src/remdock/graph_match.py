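"""Initial pose generation by distance-compatibility graph matching.

A *node* pairs a ligand heavy atom with a pocket grid point.  Two nodes are
*edged* when the intra-ligand distance between their atoms matches the
intra-pocket distance between their grid points within a growing tolerance:

    |d_ligand - d_pocket| < 0.25 * n_edge

where ``n_edge`` counts the edges already accepted while growing the current
clique (1 for the first edge, 2 for the second, ...).  A clique — a set of
nodes in which every pair is edged — defines an atom-to-point correspondence,
and superposing the ligand onto the matched grid points with the Kabsch
rotation yields an initial docking pose.

The growing tolerance makes acceptance order-dependent, so the enumeration
order is fixed: nodes are ordered ligand-atom-major / grid-point-minor, seed
pairs and extensions are scanned in that order, and the edge counter runs per
clique.  This makes the clique set a deterministic function of the inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .io_formats import Ligand
from .pocket import PocketGrid

__all__ = [
    "MatchNode",
    "Clique",
    "Pose",
    "EDGE_TOLERANCE_STEP",
    "edge_test",
    "grow_cliques",
    "kabsch_superpose",
    "pose_from_clique",
    "select_initial_poses",
    "random_unit_axis",
    "rotate_about_centroid",
]

EDGE_TOLERANCE_STEP = 0.25   # Å per accepted edge
ENERGY_CUTOFF = 1e6          # kcal/mol, initial-pose viability cutoff
N_FLIP = 20                  # top poses flipped in predicted mode


@dataclass(frozen=True)
class MatchNode:
    ligand_atom: int   # 1-based ligand atom index
    grid_point: int    # 0-based pocket point index


@dataclass
class Clique:
    """A fully edged node set; ``edge_tolerances[k]`` is the n_edge at which
    the k-th accepted edge passed."""

    nodes: list[MatchNode]
    edge_tolerances: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class Pose:
    """A full-ligand coordinate snapshot."""

    coords: np.ndarray          # (n_atoms, 3), Å
    source: str = "graph_match"  # graph_match | flip | random_rotation | decoy
    energy: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3 \
                or not np.all(np.isfinite(self.coords)):
            raise ValueError("pose coords must be a finite (n, 3) array")

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)


def edge_test(d_ligand: float, d_pocket: float, n_edge: int) -> bool:
    """Accept an edge iff |d_ligand - d_pocket| < 0.25 * n_edge (strict)."""
    if n_edge < 1:
        raise ValueError("n_edge must be >= 1")
    return abs(d_ligand - d_pocket) < EDGE_TOLERANCE_STEP * n_edge


def grow_cliques(ligand: Ligand, grid: PocketGrid,
                 max_nodes: int = 10,
                 max_cliques: int = 2000) -> list[Clique]:
    """Enumerate cliques by deterministic greedy growth.

    Every ordered seed pair of compatible nodes (passing the edge test at
    n_edge = 1) starts a clique, which is then extended one node at a time:
    at each step the first node (in ligand-atom-major order) whose edges to
    every current member pass at the running counter is added, the counter
    advancing by one per accepted edge.  Cliques of size >= 3 are emitted
    (duplicates under node-set equality removed) up to ``max_cliques``.

    Returns an empty list when no clique of size 3 exists; the caller should
    then fall back to random placement.
    """
    heavy = [a.index for a in ligand.atoms if a.is_heavy]
    if len(heavy) < 3:
        raise ValueError("ligand needs at least 3 heavy atoms for matching")
    if grid.n_points == 0:
        raise ValueError("empty pocket grid")

    lig_xyz = ligand.coords[[i - 1 for i in heavy]]
    dl = cdist(lig_xyz, lig_xyz)            # indexed by heavy-atom position
    dp = cdist(grid.points, grid.points)
    pos_of = {a: k for k, a in enumerate(heavy)}

    nodes = [MatchNode(a, g) for a in heavy for g in range(grid.n_points)]
    node_atoms = np.array([pos_of[n.ligand_atom] for n in nodes])
    node_grids = np.array([n.grid_point for n in nodes])

    cliques: list[Clique] = []
    seen: set[frozenset] = set()

    for i, n1 in enumerate(nodes):
        a1, g1 = node_atoms[i], node_grids[i]
        # vectorized seed test against all later nodes
        cand = np.arange(i + 1, len(nodes))
        ok = (node_atoms[cand] != a1) & (node_grids[cand] != g1) & \
             (np.abs(dl[a1, node_atoms[cand]] - dp[g1, node_grids[cand]])
              < EDGE_TOLERANCE_STEP)
        for j in cand[ok]:
            clique = [n1, nodes[j]]
            tolerances = [1]
            n_edge = 1
            used_atoms = {n1.ligand_atom, nodes[j].ligand_atom}
            used_grids = {int(g1), int(node_grids[j])}
            while len(clique) < max_nodes:
                added = False
                for k, nk in enumerate(nodes):
                    if nk.ligand_atom in used_atoms or \
                            nk.grid_point in used_grids:
                        continue
                    ak, gk = node_atoms[k], node_grids[k]
                    step = n_edge
                    accept = True
                    for mem in clique:
                        step += 1
                        if not (abs(dl[pos_of[mem.ligand_atom], ak]
                                    - dp[mem.grid_point, gk])
                                < EDGE_TOLERANCE_STEP * step):
                            accept = False
                            break
                    if accept:
                        clique.append(nk)
                        tolerances.extend(range(n_edge + 1, step + 1))
                        n_edge = step
                        used_atoms.add(nk.ligand_atom)
                        used_grids.add(nk.grid_point)
                        added = True
                        break
                if not added:
                    break
            if len(clique) >= 3:
                key = frozenset((n.ligand_atom, n.grid_point) for n in clique)
                if key not in seen:
                    seen.add(key)
                    cliques.append(Clique(nodes=clique,
                                          edge_tolerances=tolerances))
                    if len(cliques) >= max_cliques:
                        return cliques
    return cliques


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``target``.

    Returns ``(R, t, rmsd)`` with ``R`` a proper rotation (det = +1, the
    reflection branch of the SVD corrected) and ``t`` a translation such
    that ``mobile @ R.T + t`` minimizes the RMSD to ``target``.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    n = len(mobile)
    if n < 3:
        raise ValueError("need at least 3 points for superposition")
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    pm, pt = mobile - cm, target - ct
    if np.linalg.matrix_rank(pm, tol=1e-8) < 2 or \
            np.linalg.matrix_rank(pt, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set")
    h = pm.T @ pt
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = ct - rot @ cm
    moved = mobile @ rot.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return rot, t, rmsd


def pose_from_clique(ligand: Ligand, clique: Clique,
                     grid: PocketGrid) -> Pose | None:
    """Superpose the whole ligand using a clique's atom-to-point map.

    Returns ``None`` (with a warning) when the clique geometry is degenerate
    and no unique rotation exists.
    """
    if len(clique) < 3:
        raise ValueError("clique must have at least 3 nodes")
    mob = ligand.coords[[n.ligand_atom - 1 for n in clique.nodes]]
    tgt = grid.points[[n.grid_point for n in clique.nodes]]
    try:
        rot, t, _ = kabsch_superpose(mob, tgt)
    except ValueError as exc:
        warnings.warn(f"skipping degenerate clique: {exc}")
        return None
    return Pose(coords=ligand.coords @ rot.T + t, source="graph_match")


def random_unit_axis(rng: np.random.Generator) -> np.ndarray:
    """Uniform random unit vector: θ = 2πr₁, φ = arccos(2r₂ − 1)."""
    theta = 2.0 * np.pi * rng.random()
    phi = np.arccos(2.0 * rng.random() - 1.0)
    return np.array([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)])


def rotate_about_centroid(coords: np.ndarray, axis: np.ndarray,
                          angle: float) -> np.ndarray:
    """Rotate coordinates about an axis through their centroid (radians)."""
    c = coords.mean(axis=0)
    rot = Rotation.from_rotvec(np.asarray(axis, dtype=float) * angle)
    return (coords - c) @ rot.as_matrix().T + c


def select_initial_poses(poses: list[Pose], energy_fn, n_needed: int,
                         predicted_mode: bool, rng: np.random.Generator,
                         fallback_coords: np.ndarray | None = None,
                         fallback_center: np.ndarray | None = None
                         ) -> list[Pose]:
    """Pick the replica starting poses from the graph-matching candidates.

    Poses with energy >= 1e6 kcal/mol are discarded and the rest ranked by
    energy.  In predicted mode the 20 best poses are additionally flipped by
    180° about a random axis through their centroid (pocket distortion can
    leave graph matching oriented backwards).  If fewer than ``n_needed``
    poses remain, random rotations of existing poses top the list up; if
    none survive the cutoff, random placements at the pocket centroid are
    used instead (with a warning).
    """
    scored: list[Pose] = []
    for p in poses:
        e = float(energy_fn(p.coords))
        if e < ENERGY_CUTOFF:
            scored.append(Pose(coords=p.coords, source=p.source, energy=e))
    scored.sort(key=lambda p: p.energy)

    if not scored:
        if fallback_coords is None or fallback_center is None:
            raise ValueError("no pose below the energy cutoff and no "
                             "fallback placement available")
        warnings.warn("no initial pose below the energy cutoff; "
                      "falling back to random placements at the pocket center")
        base = np.asarray(fallback_coords, dtype=float)
        base = base - base.mean(axis=0) + np.asarray(fallback_center)
        out = []
        for _ in range(n_needed):
            coords = rotate_about_centroid(
                base, random_unit_axis(rng), rng.uniform(0, 2 * np.pi))
            out.append(Pose(coords=coords, source="random_rotation",
                            energy=float(energy_fn(coords))))
        return out

    pool = list(scored)
    if predicted_mode:
        for p in scored[:N_FLIP]:
            coords = rotate_about_centroid(p.coords, random_unit_axis(rng),
                                           np.pi)
            pool.append(Pose(coords=coords, source="flip",
                             energy=float(energy_fn(coords))))

    if len(pool) >= n_needed:
        return pool[:n_needed]
    out = list(pool)
    while len(out) < n_needed:
        src = pool[rng.integers(len(pool))]
        coords = rotate_about_centroid(src.coords, random_unit_axis(rng),
                                       rng.uniform(0, 2 * np.pi))
        out.append(Pose(coords=coords, source="random_rotation",
                        energy=float(energy_fn(coords))))
    return out
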