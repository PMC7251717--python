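"""Replica-exchange Metropolis Monte Carlo refinement of docking poses.

``N`` replicas of the docking system run Metropolis chains in parallel at a
geometric temperature ladder

    T_i = T_min * (T_max / T_min)^((i-1)/(N-1)),   T_min = 1, T_max = 60

(kcal/mol with the Boltzmann constant folded into T).  Local moves translate
the ligand by a uniform vector in [-0.2, 0.2] Å per axis and rotate it about
a uniformly oriented random axis through its centroid by an angle in
[-3°, 3°]; flexible docking additionally twists one randomly chosen
rotatable bond by a uniform angle in [-180°, 180°].  After every 200 local
moves per replica, adjacent replica pairs attempt a pose swap with the
parallel-tempering acceptance rule, letting low-temperature chains escape
local minima.  Decoys are collected every 20 local moves from the four
lowest-temperature replicas; at the default 5 runs x 100 swap epochs this
yields 20,000 decoys (5 x 4 x 100 x 200/20).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy.spatial.transform import Rotation

from .energy import EnergyModel, EnergyWeights
from .graph_match import Pose, random_unit_axis, rotate_about_centroid
from .io_formats import DistanceProfile, Ligand, Receptor
from .pocket import PocketGrid

__all__ = [
    "RunConfig",
    "ReplicaState",
    "Decoy",
    "DecoySet",
    "temperature_ladder",
    "propose_rigid_move",
    "propose_torsion_move",
    "bond_partition",
    "metropolis_accept",
    "attempt_swap",
    "randomize_clashed_ligand",
    "run_remc",
]

CLASH_THRESHOLD = 100.0   # kcal/mol intra-ligand energy triggering relaxation
CLASH_RELAX_STEPS = 500   # torsion-only MC steps used to relax a clash


@dataclass
class RunConfig:
    """Simulation configuration; defaults follow the rigid/experimental
    protocol (predicted receptors use n_replicas=40, flexible docking
    n_swaps=200)."""

    n_replicas: int = 20
    n_swaps: int = 100
    moves_per_swap: int = 200
    decoy_stride: int = 20
    decoy_replicas: int = 4
    n_runs: int = 5
    t_min: float = 1.0
    t_max: float = 60.0
    translation_step: float = 0.2           # Å per axis
    rotation_step: float = math.radians(3.0)
    torsion_step: float = math.radians(180.0)
    flexible: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_replicas", "n_swaps", "moves_per_swap",
                     "decoy_stride", "decoy_replicas", "n_runs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.t_min < self.t_max:
            raise ValueError("need 0 < t_min < t_max")

    def expected_decoy_count(self) -> int:
        """Decoys the collection schedule will record."""
        return (self.n_runs * min(self.decoy_replicas, self.n_replicas)
                * self.n_swaps * (self.moves_per_swap // self.decoy_stride))


@dataclass
class ReplicaState:
    index: int                      # 1-based ladder slot
    temperature: float              # kT, k folded in
    coords: np.ndarray              # current pose coordinates
    energy: float
    rng: np.random.Generator


@dataclass
class Decoy:
    coords: np.ndarray
    energy: float
    run: int
    replica: int
    sweep: int


@dataclass
class DecoySet:
    decoys: list[Decoy] = field(default_factory=list)
    provenance: RunConfig | None = None

    def __len__(self) -> int:
        return len(self.decoys)

    def coords_array(self) -> np.ndarray:
        return np.array([d.coords for d in self.decoys])

    def energies(self) -> np.ndarray:
        return np.array([d.energy for d in self.decoys])


def temperature_ladder(t_min: float, t_max: float, n: int) -> np.ndarray:
    """Geometric ladder T_i = T_min (T_max/T_min)^((i-1)/(N-1)), i = 1..N."""
    if n < 2:
        raise ValueError("need at least 2 replicas for a ladder")
    if not 0 < t_min < t_max:
        raise ValueError("need 0 < t_min < t_max")
    i = np.arange(n, dtype=float)
    return t_min * (t_max / t_min) ** (i / (n - 1))


def propose_rigid_move(coords: np.ndarray, config: RunConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """Random rigid-body move: per-axis uniform translation then a small
    rotation about a uniformly oriented axis through the ligand centroid."""
    ts, rs = config.translation_step, config.rotation_step
    out = coords + rng.uniform(-ts, ts, size=3)
    if rs > 0:
        out = rotate_about_centroid(out, random_unit_axis(rng),
                                    rng.uniform(-rs, rs))
    return out


def bond_partition(ligand: Ligand, bond_index: int) -> np.ndarray:
    """0-based atom indices on the smaller side of a rotatable bond."""
    i, j, _ = ligand.bonds[bond_index]
    g = ligand.graph()
    g.remove_edge(i, j)
    side_i = nx.node_connected_component(g, i)
    side_j = nx.node_connected_component(g, j)
    side = side_j if len(side_j) <= len(side_i) else side_i
    return np.array(sorted(a - 1 for a in side))


def _apply_torsion(coords: np.ndarray, ligand: Ligand, bond_index: int,
                   angle: float,
                   side_cache: dict[int, np.ndarray] | None = None
                   ) -> np.ndarray:
    i, j, _ = ligand.bonds[bond_index]
    if side_cache is not None:
        side = side_cache.setdefault(bond_index,
                                     bond_partition(ligand, bond_index))
    else:
        side = bond_partition(ligand, bond_index)
    axis = coords[j - 1] - coords[i - 1]
    norm = np.linalg.norm(axis)
    if norm == 0:
        return coords
    rot = Rotation.from_rotvec(axis / norm * angle).as_matrix()
    out = coords.copy()
    out[side] = (coords[side] - coords[i - 1]) @ rot.T + coords[i - 1]
    return out


def propose_torsion_move(coords: np.ndarray, ligand: Ligand,
                         config: RunConfig, rng: np.random.Generator,
                         side_cache: dict[int, np.ndarray] | None = None
                         ) -> np.ndarray:
    """Flexible move: the rigid move followed by a twist of one randomly
    selected rotatable bond (smaller side rotates).  Falls back to the rigid
    move when the ligand has no rotatable bonds."""
    out = propose_rigid_move(coords, config, rng)
    if not ligand.rotatable_bonds:
        return out
    b = ligand.rotatable_bonds[rng.integers(len(ligand.rotatable_bonds))]
    angle = rng.uniform(-config.torsion_step, config.torsion_step)
    return _apply_torsion(out, ligand, b, angle, side_cache)


def metropolis_accept(e_new: float, e_old: float, kt: float,
                      rng: np.random.Generator) -> bool:
    """Accept with probability min{1, exp(-(E_new - E_old)/kT)}."""
    if kt <= 0:
        raise ValueError("kT must be > 0")
    de = e_new - e_old
    if de <= 0:
        return True
    return rng.random() < math.exp(-de / kt)


def attempt_swap(rep_i: ReplicaState, rep_j: ReplicaState,
                 rng: np.random.Generator) -> bool:
    """Parallel-tempering swap between contiguous replicas.

    Accepts with p = min{1, exp((E_j - E_i)(1/kT_j - 1/kT_i))}; on success
    the replicas exchange poses and energies (temperatures stay with the
    ladder slots).
    """
    if abs(rep_i.index - rep_j.index) != 1:
        raise ValueError("swaps are only attempted between contiguous replicas")
    arg = (rep_j.energy - rep_i.energy) * \
        (1.0 / rep_j.temperature - 1.0 / rep_i.temperature)
    accept = arg >= 0 or rng.random() < math.exp(arg)
    if accept:
        rep_i.coords, rep_j.coords = rep_j.coords, rep_i.coords
        rep_i.energy, rep_j.energy = rep_j.energy, rep_i.energy
    return accept


def randomize_clashed_ligand(ligand: Ligand, rng: np.random.Generator,
                             model: EnergyModel | None = None,
                             threshold: float = CLASH_THRESHOLD,
                             n_steps: int = CLASH_RELAX_STEPS,
                             kt: float = 60.0) -> Pose:
    """Relax a sterically clashed input conformation by torsion-only MC.

    When the intra-ligand 12-6 energy exceeds ``threshold`` (100 kcal/mol),
    rotatable bonds are twisted for ``n_steps`` Metropolis steps on the
    intra-ligand energy alone (at the top ladder temperature); otherwise the
    input conformation is returned unchanged.
    """
    if model is None:
        from .energy import intra_exclusions, vdw_intra
        intra = lambda xyz: vdw_intra(xyz, ligand)  # noqa: E731
    else:
        intra = model.intra
    coords = ligand.coords
    e = intra(coords)
    if e <= threshold:
        return Pose(coords=coords, source="decoy", energy=e)
    if not ligand.rotatable_bonds:
        warnings.warn("clashed ligand has no rotatable bonds; "
                      "returning it unchanged")
        return Pose(coords=coords, source="decoy", energy=e)
    side_cache: dict[int, np.ndarray] = {}
    for _ in range(n_steps):
        b = ligand.rotatable_bonds[rng.integers(len(ligand.rotatable_bonds))]
        angle = rng.uniform(-math.pi, math.pi)
        cand = _apply_torsion(coords, ligand, b, angle, side_cache)
        try:
            e_cand = intra(cand)
        except ValueError:
            continue
        if metropolis_accept(e_cand, e, kt, rng):
            coords, e = cand, e_cand
    return Pose(coords=coords, source="decoy", energy=e)


def run_remc(receptor: Receptor, ligand: Ligand, grid: PocketGrid,
             profile: DistanceProfile | None,
             initial_poses: list[Pose], config: RunConfig,
             weights_per_run: list[EnergyWeights]) -> DecoySet:
    """Run the full multi-run REMC protocol and collect decoys.

    ``initial_poses`` must hold ``n_runs * n_replicas`` poses (replica ``i``
    of run ``r`` starts from pose ``r * N + i``); ``weights_per_run`` one
    weight set per run.  All randomness derives from ``config.seed`` through
    spawned per-replica streams, so a fixed seed reproduces the decoy set
    bit for bit.
    """
    n = config.n_replicas
    if len(initial_poses) != config.n_runs * n:
        raise ValueError(f"need {config.n_runs * n} initial poses, "
                         f"got {len(initial_poses)}")
    if len(weights_per_run) != config.n_runs:
        raise ValueError("need one weight set per run")

    ladder = temperature_ladder(config.t_min, config.t_max, n)
    n_collect = min(config.decoy_replicas, n)
    master = np.random.SeedSequence(config.seed)
    run_seeds = master.spawn(config.n_runs)
    side_cache: dict[int, np.ndarray] = {}
    flexible = config.flexible and bool(ligand.rotatable_bonds)

    decoys: list[Decoy] = []
    for run in range(config.n_runs):
        model = EnergyModel(receptor, ligand, grid=grid, profile=profile,
                            weights=weights_per_run[run])
        streams = run_seeds[run].spawn(n + 1)
        swap_rng = np.random.default_rng(streams[n])
        replicas = []
        for i in range(n):
            coords = initial_poses[run * n + i].coords.copy()
            replicas.append(ReplicaState(
                index=i + 1, temperature=float(ladder[i]), coords=coords,
                energy=model.total(coords),
                rng=np.random.default_rng(streams[i])))

        for sweep in range(config.n_swaps):
            for rep in replicas:
                for move in range(config.moves_per_swap):
                    if flexible:
                        cand = propose_torsion_move(rep.coords, ligand,
                                                    config, rep.rng,
                                                    side_cache)
                    else:
                        cand = propose_rigid_move(rep.coords, config, rep.rng)
                    try:
                        e_cand = model.total(cand)
                    except ValueError:
                        continue  # singular overlap; reject outright
                    if metropolis_accept(e_cand, rep.energy,
                                         rep.temperature, rep.rng):
                        rep.coords, rep.energy = cand, e_cand
                    if rep.index <= n_collect and \
                            (move + 1) % config.decoy_stride == 0:
                        decoys.append(Decoy(coords=rep.coords.copy(),
                                            energy=rep.energy, run=run,
                                            replica=rep.index, sweep=sweep))
            # alternating even/odd adjacent-pair swap sweep
            for i in range(sweep % 2, n - 1, 2):
                attempt_swap(replicas[i], replicas[i + 1], swap_rng)

    return DecoySet(decoys=decoys, provenance=config)
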