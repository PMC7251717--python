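"""End-to-end blind-docking pipeline.

``dock`` chains the four stages — negative-image pocket construction,
graph-matching pose initialization, replica-exchange Monte Carlo sampling,
and clustering-based model selection — behind one call.  The receptor
quality switch selects the protocol: experimental structures use the plain
vdW + Coulomb energy with standard pocket filters, predicted models use
relaxed pocket filters, flip augmentation of the initial poses, and the
composite van der Waals / pocket-restraint weight schedule.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .energy import EnergyModel, EnergyWeights, weight_schedule
from .graph_match import Pose, grow_cliques, pose_from_clique, \
    select_initial_poses
from .io_formats import DistanceProfile, Ligand, Receptor, assign_parameters
from .pocket import PocketGrid, build_pocket
from .remc import DecoySet, RunConfig, randomize_clashed_ligand, run_remc
from .select import Cluster, cluster_decoys, select_models

__all__ = ["DockingResult", "dock"]


@dataclass
class DockingResult:
    pocket: PocketGrid
    initial_poses: list[Pose]
    decoys: DecoySet
    clusters: list[Cluster]
    models: list[Pose]
    weights_per_run: list[EnergyWeights] = field(default_factory=list)


def _weights_for_runs(predicted: bool, flexible: bool,
                      n_runs: int) -> list[EnergyWeights]:
    schedule = weight_schedule(predicted, flexible=flexible)
    return [schedule[i % len(schedule)] for i in range(n_runs)]


def dock(receptor: Receptor, ligand: Ligand, center: np.ndarray,
         receptor_quality: str = "experimental",
         config: RunConfig | None = None,
         profile: DistanceProfile | None = None,
         n_models: int = 5,
         rmsd_cutoff: float = 2.0,
         scorer=None,
         max_cliques: int = 2000) -> DockingResult:
    """Run the full pipeline and return pocket, decoys, clusters and models.

    ``receptor_quality`` is ``"experimental"`` or ``"predicted"``;
    ``config.flexible`` switches torsional sampling on (requires rotatable
    bonds to have any effect).  All randomness stems from ``config.seed``.
    """
    if receptor_quality not in ("experimental", "predicted"):
        raise ValueError("receptor_quality must be 'experimental' or "
                         "'predicted'")
    predicted = receptor_quality == "predicted"
    config = config if config is not None else RunConfig()
    if not receptor.is_parameterized:
        assign_parameters(receptor)
    if not ligand.is_parameterized:
        assign_parameters(ligand)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    # stage 1: negative-image pocket
    grid = build_pocket(receptor, ligand, center, relaxed=predicted)

    # flexible docking relaxes a clashed input conformation first
    work_ligand = ligand
    if config.flexible:
        relaxed = randomize_clashed_ligand(ligand, rng)
        if not np.array_equal(relaxed.coords, ligand.coords):
            work_ligand = copy.deepcopy(ligand)
            for a, xyz in zip(work_ligand.atoms, relaxed.coords):
                a.coords = np.asarray(xyz, dtype=float)

    # stage 2: graph matching -> initial poses
    cliques = grow_cliques(work_ligand, grid, max_cliques=max_cliques)
    poses = [p for p in (pose_from_clique(work_ligand, c, grid)
                         for c in cliques) if p is not None]

    weights = _weights_for_runs(predicted, config.flexible, config.n_runs)
    rank_model = EnergyModel(receptor, work_ligand, grid=grid,
                             profile=profile, weights=weights[0])
    initial = select_initial_poses(
        poses, rank_model.total, n_needed=config.n_runs * config.n_replicas,
        predicted_mode=predicted, rng=rng,
        fallback_coords=work_ligand.coords,
        fallback_center=grid.points.mean(axis=0))

    # stage 3: REMC sampling
    decoys = run_remc(receptor, work_ligand, grid, profile, initial,
                      config, weights)

    # stage 4: clustering and model selection
    clusters = cluster_decoys(decoys, rmsd_cutoff=rmsd_cutoff,
                              heavy_mask=work_ligand.heavy_mask)
    models = select_models(clusters, decoys, k=n_models, scorer=scorer)

    return DockingResult(pocket=grid, initial_poses=initial, decoys=decoys,
                         clusters=clusters, models=models,
                         weights_per_run=weights)
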