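"""The five-term docking force field.

The pose energy is a weighted sum of

1. receptor-ligand 12-6 van der Waals:  A/d¹² − B/d⁶ with A = εR¹²,
   B = 2εR⁶, R = r_i + r_j, ε = √(ε_i ε_j)  (AMBER-style combination);
2. Coulomb electrostatics in the literal distance-dependent-dielectric form
   q_i q_j / (4 d) — no unit-conversion constant is applied, the weights
   were tuned against this literal form;
3. a pocket restraint Σ_k d_k, the sum over pocket grid points of the
   minimum ligand-atom distance to each point (pulls the ligand into the
   negative image);
4. a template distance-profile restraint Σ ½ (d_ij − μ_ij)²/σ_ij²;
5. intra-ligand 12-6 van der Waals over atom pairs excluding 1-2 bonded and
   1-3 angle pairs (which would otherwise sit in the repulsive singularity).

Weights: with an experimental receptor structure only terms 1 and 2 are
active (w1 = w2 = 1, w3 = w4 = 0).  With a predicted receptor model, five
parallel runs use w1 ∈ {0.001, 0.004, 0.02, 0.1, 1}, w2 = 1, w3 = 1 − w1
and w4 = 0.01, trading steric strictness against the pocket restraint to
accommodate different degrees of pocket distortion.  The intra-ligand
weight w5 is 1 in flexible docking and 0 in rigid docking (where the term
is constant anyway).

A 12 Å truncation cutoff is applied to the inter-molecular pair terms for
speed (``cutoff=None`` disables it); at that range the 12-6 and screened
Coulomb contributions are negligible for the charge scales involved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .io_formats import DistanceProfile, Ligand, Receptor
from .pocket import PocketGrid

__all__ = [
    "EnergyWeights",
    "EnergyBreakdown",
    "EnergyModel",
    "DistanceProfile",
    "vdw_pair",
    "coulomb_pair",
    "pocket_restraint",
    "profile_restraint",
    "vdw_intra",
    "intra_exclusions",
    "total_energy",
    "weight_schedule",
    "VDW_WEIGHT_LADDER",
    "DEFAULT_CUTOFF",
]

VDW_WEIGHT_LADDER = (0.001, 0.004, 0.02, 0.1, 1.0)  # w1 per predicted-mode run
PROFILE_WEIGHT = 0.01                                # w4 in predicted mode
DEFAULT_CUTOFF = 12.0                                # Å, inter-term truncation


@dataclass(frozen=True)
class EnergyWeights:
    """Dimensionless weights w1..w5 of the five energy terms."""

    w1: float = 1.0   # receptor-ligand van der Waals
    w2: float = 1.0   # Coulomb
    w3: float = 0.0   # pocket restraint
    w4: float = 0.0   # distance profile
    w5: float = 0.0   # intra-ligand van der Waals

    def __post_init__(self) -> None:
        for name in ("w1", "w2", "w3", "w4", "w5"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class EnergyBreakdown:
    """Unweighted term values plus the weighted total (kcal/mol nominal)."""

    e_vdw_inter: float
    e_coulomb: float
    e_pocket: float
    e_profile: float
    e_vdw_intra: float
    total: float

    def as_dict(self) -> dict[str, float]:
        return dict(e_vdw_inter=self.e_vdw_inter, e_coulomb=self.e_coulomb,
                    e_pocket=self.e_pocket, e_profile=self.e_profile,
                    e_vdw_intra=self.e_vdw_intra, total=self.total)


# ---------------------------------------------------------------------------
# pair primitives
# ---------------------------------------------------------------------------

def vdw_pair(d: float, r_i: float, r_j: float,
             eps_i: float, eps_j: float) -> float:
    """12-6 pair energy A/d¹² − B/d⁶; minimum −ε at d = r_i + r_j."""
    if d <= 0:
        raise ValueError("vdw_pair: distance must be > 0")
    big_r = r_i + r_j
    eps = np.sqrt(eps_i * eps_j)
    a = eps * big_r ** 12
    b = 2.0 * eps * big_r ** 6
    return float(a / d ** 12 - b / d ** 6)


def coulomb_pair(q_i: float, q_j: float, d: float) -> float:
    """Screened Coulomb pair energy q_i q_j / (4 d), literal form."""
    if d <= 0:
        raise ValueError("coulomb_pair: distance must be > 0")
    return float(q_i * q_j / (4.0 * d))


# ---------------------------------------------------------------------------
# term functions
# ---------------------------------------------------------------------------

def pocket_restraint(pose_coords: np.ndarray, grid: PocketGrid) -> float:
    """Σ_k min-distance (Å) from the ligand to each pocket grid point."""
    if grid.n_points == 0:
        warnings.warn("pocket restraint evaluated on an empty grid; term is 0")
        return 0.0
    d = cdist(grid.points, np.asarray(pose_coords, dtype=float))
    return float(d.min(axis=1).sum())


def profile_restraint(pose_coords: np.ndarray, receptor: Receptor,
                      profile: DistanceProfile) -> float:
    """Σ ½ (d_ij − μ_ij)² / σ_ij² over restraint entries (dimensionless)."""
    if len(profile) == 0:
        return 0.0
    pose_coords = np.asarray(pose_coords, dtype=float)
    rec = receptor.coords
    total = 0.0
    for i, j, mu, sigma in profile.entries:
        d = float(np.linalg.norm(rec[i - 1] - pose_coords[j - 1]))
        total += 0.5 * (d - mu) ** 2 / sigma ** 2
    return total


def intra_exclusions(ligand: Ligand) -> set[frozenset[int]]:
    """1-2 bonded and 1-3 angle atom pairs (1-based), excluded from term 5."""
    g = ligand.graph()
    excluded: set[frozenset[int]] = set()
    for n in g:
        lengths = nx.single_source_shortest_path_length(g, n, cutoff=2)
        for m, dist in lengths.items():
            if m != n and dist <= 2:
                excluded.add(frozenset((n, m)))
    return excluded


def vdw_intra(pose_coords: np.ndarray, ligand: Ligand,
              exclusions: set[frozenset[int]] | None = None) -> float:
    """Intra-ligand 12-6 energy over included pairs (kcal/mol)."""
    if exclusions is None:
        exclusions = intra_exclusions(ligand)
    pose_coords = np.asarray(pose_coords, dtype=float)
    radii = ligand.vdw_radii
    eps = ligand.well_depths
    n = ligand.n_atoms
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if frozenset((i + 1, j + 1)) in exclusions:
                continue
            s = float(np.linalg.norm(pose_coords[i] - pose_coords[j]))
            if s <= 0:
                raise ValueError(f"overlapping ligand atoms {i + 1},{j + 1}")
            total += vdw_pair(s, radii[i], radii[j], eps[i], eps[j])
    return total


# ---------------------------------------------------------------------------
# fast evaluator
# ---------------------------------------------------------------------------

class EnergyModel:
    """Precomputed evaluator of the five-term energy for one docking system.

    Pair parameters (A, B, q_iq_j/4; intra C, D and the exclusion mask) are
    assembled once; :meth:`breakdown` and :meth:`total` then evaluate any
    ligand pose in vectorized form.  Both molecules must be parameterized.
    """

    def __init__(self, receptor: Receptor, ligand: Ligand,
                 grid: PocketGrid | None = None,
                 profile: DistanceProfile | None = None,
                 weights: EnergyWeights = EnergyWeights(),
                 cutoff: float | None = DEFAULT_CUTOFF,
                 heavy_only: bool = False):
        self.receptor = receptor
        self.ligand = ligand
        self.grid = grid
        self.profile = profile if profile is not None else DistanceProfile()
        self.weights = weights
        self.cutoff = cutoff

        rmask = receptor.heavy_mask if heavy_only else \
            np.ones(receptor.n_atoms, dtype=bool)
        self._rec_xyz = receptor.coords[rmask]
        rr = receptor.vdw_radii[rmask]
        re = receptor.well_depths[rmask]
        rq = receptor.charges[rmask]
        lr = ligand.vdw_radii
        le = ligand.well_depths
        lq = ligand.charges

        big_r = rr[:, None] + lr[None, :]
        eps = np.sqrt(re[:, None] * le[None, :])
        self._a = eps * big_r ** 12
        self._b = 2.0 * eps * big_r ** 6
        self._qq4 = rq[:, None] * lq[None, :] / 4.0

        excl = intra_exclusions(ligand)
        n = ligand.n_atoms
        ii, jj = np.triu_indices(n, k=1)
        keep = np.array([frozenset((i + 1, j + 1)) not in excl
                         for i, j in zip(ii, jj)])
        self._intra_i, self._intra_j = ii[keep], jj[keep]
        big_rl = lr[self._intra_i] + lr[self._intra_j]
        eps_l = np.sqrt(le[self._intra_i] * le[self._intra_j])
        self._c = eps_l * big_rl ** 12
        self._d = 2.0 * eps_l * big_rl ** 6

        if len(self.profile):
            pi = np.array([e[0] - 1 for e in self.profile.entries])
            self._prof_rec = receptor.coords[pi]
            self._prof_lig = np.array([e[1] - 1
                                       for e in self.profile.entries])
            self._prof_mu = np.array([e[2] for e in self.profile.entries])
            self._prof_sig = np.array([e[3] for e in self.profile.entries])

    def breakdown(self, pose_coords: np.ndarray) -> EnergyBreakdown:
        xyz = np.asarray(pose_coords, dtype=float)
        w = self.weights

        d = cdist(self._rec_xyz, xyz)
        if np.any(d <= 0):
            raise ValueError("receptor and ligand atoms coincide")
        if self.cutoff is not None:
            within = d <= self.cutoff
        else:
            within = np.ones_like(d, dtype=bool)
        d6 = d ** 6
        e_vdw = float(np.sum((self._a / (d6 * d6) - self._b / d6)[within]))
        e_coul = float(np.sum((self._qq4 / d)[within]))

        e_pocket = pocket_restraint(xyz, self.grid) \
            if (self.grid is not None and self.grid.n_points) else 0.0

        if len(self.profile):
            dp = np.linalg.norm(self._prof_rec - xyz[self._prof_lig], axis=1)
            e_prof = float(np.sum(0.5 * (dp - self._prof_mu) ** 2
                                  / self._prof_sig ** 2))
        else:
            e_prof = 0.0

        if len(self._intra_i):
            s = np.linalg.norm(xyz[self._intra_i] - xyz[self._intra_j], axis=1)
            if np.any(s <= 0):
                raise ValueError("overlapping ligand atoms")
            s6 = s ** 6
            e_intra = float(np.sum(self._c / (s6 * s6) - self._d / s6))
        else:
            e_intra = 0.0

        total = (w.w1 * e_vdw + w.w2 * e_coul + w.w3 * e_pocket
                 + w.w4 * e_prof + w.w5 * e_intra)
        return EnergyBreakdown(e_vdw_inter=e_vdw, e_coulomb=e_coul,
                               e_pocket=e_pocket, e_profile=e_prof,
                               e_vdw_intra=e_intra, total=total)

    def total(self, pose_coords: np.ndarray) -> float:
        return self.breakdown(pose_coords).total

    def intra(self, pose_coords: np.ndarray) -> float:
        """Unweighted intra-ligand 12-6 term only (used for clash checks)."""
        if not len(self._intra_i):
            return 0.0
        xyz = np.asarray(pose_coords, dtype=float)
        s = np.linalg.norm(xyz[self._intra_i] - xyz[self._intra_j], axis=1)
        if np.any(s <= 0):
            raise ValueError("overlapping ligand atoms")
        s6 = s ** 6
        return float(np.sum(self._c / (s6 * s6) - self._d / s6))


def total_energy(pose_coords: np.ndarray, receptor: Receptor, ligand: Ligand,
                 grid: PocketGrid | None = None,
                 profile: DistanceProfile | None = None,
                 weights: EnergyWeights = EnergyWeights(),
                 cutoff: float | None = DEFAULT_CUTOFF) -> EnergyBreakdown:
    """One-shot five-term evaluation (see :class:`EnergyModel`)."""
    model = EnergyModel(receptor, ligand, grid=grid, profile=profile,
                        weights=weights, cutoff=cutoff)
    return model.breakdown(pose_coords)


def weight_schedule(predicted_mode: bool,
                    flexible: bool = False) -> list[EnergyWeights]:
    """Per-run weight sets (5 runs).

    Experimental receptors: five identical (1, 1, 0, 0, w5) sets.  Predicted
    receptor models: w1 runs through {0.001, 0.004, 0.02, 0.1, 1} with
    w2 = 1, w3 = 1 − w1, w4 = 0.01.  w5 = 1 when the ligand is flexible,
    else 0.
    """
    w5 = 1.0 if flexible else 0.0
    if not predicted_mode:
        return [EnergyWeights(1.0, 1.0, 0.0, 0.0, w5) for _ in range(5)]
    return [EnergyWeights(w1, 1.0, 1.0 - w1, PROFILE_WEIGHT, w5)
            for w1 in VDW_WEIGHT_LADDER]
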