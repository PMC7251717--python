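"""Final model selection from the decoy ensemble.

Decoys are clustered by iterative density peeling in the spirit of
structure-decoy clustering: the decoy with the most neighbours within an
RMSD cutoff seeds the first cluster together with those neighbours, the
cluster is removed, and the procedure repeats on the remainder.  High
multiplicity (cluster size) proxies low free energy, so cluster
representatives ranked by multiplicity are the default models.  Because all
decoys are posed in one receptor frame, the RMSD used here is computed
in-frame, *without* re-superposition.

An optional external scorer hook (a callable mapping pose coordinates to a
score, higher = better — e.g. an empirical binding-affinity function)
replaces the multiplicity ranking when provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .graph_match import Pose
from .remc import DecoySet

__all__ = ["Cluster", "cluster_decoys", "select_models", "pairwise_rmsd"]

DEFAULT_RMSD_CUTOFF = 2.0  # Å


@dataclass
class Cluster:
    member_ids: list[int]          # indices into the decoy list
    representative: int            # decoy id of the medoid
    rmsd_cutoff: float
    representative_energy: float

    @property
    def multiplicity(self) -> int:
        return len(self.member_ids)


def pairwise_rmsd(coords: np.ndarray) -> np.ndarray:
    """In-frame RMSD matrix for an (n_decoys, n_atoms, 3) coordinate stack."""
    coords = np.asarray(coords, dtype=float)
    diff = coords[:, None, :, :] - coords[None, :, :, :]
    return np.sqrt(np.mean(np.sum(diff ** 2, axis=3), axis=2))


def cluster_decoys(decoys: DecoySet, rmsd_cutoff: float = DEFAULT_RMSD_CUTOFF,
                   heavy_mask: np.ndarray | None = None) -> list[Cluster]:
    """Iterative max-neighbour peeling into clusters.

    A decoy is a neighbour of another when their in-frame heavy-atom RMSD is
    <= ``rmsd_cutoff``.  Each round removes the decoy with the most
    remaining neighbours together with those neighbours as one cluster
    (ties broken by lower decoy index), until no decoys remain — so the
    clusters partition the decoy set.  The representative is the cluster
    medoid (minimum summed RMSD to co-members).  Clusters are returned by
    descending multiplicity, ties broken by lower representative energy.
    """
    if len(decoys) == 0:
        raise ValueError("cannot cluster an empty decoy set")
    coords = decoys.coords_array()
    if heavy_mask is not None:
        coords = coords[:, np.asarray(heavy_mask, dtype=bool), :]
    energies = decoys.energies()
    rmsd = pairwise_rmsd(coords)
    neighbour = rmsd <= rmsd_cutoff  # includes self

    active = np.ones(len(decoys), dtype=bool)
    clusters: list[Cluster] = []
    while active.any():
        counts = (neighbour & active[None, :]).sum(axis=1)
        counts[~active] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(neighbour[center] & active)
        sub = rmsd[np.ix_(members, members)]
        medoid = int(members[int(np.argmin(sub.sum(axis=1)))])
        clusters.append(Cluster(member_ids=[int(m) for m in members],
                                representative=medoid,
                                rmsd_cutoff=rmsd_cutoff,
                                representative_energy=float(energies[medoid])))
        active[members] = False

    clusters.sort(key=lambda c: (-c.multiplicity, c.representative_energy))
    return clusters


def select_models(clusters: list[Cluster], decoys: DecoySet, k: int = 1,
                  scorer=None) -> list[Pose]:
    """Return the top-k models as poses.

    Default: the representatives of the k largest clusters.  With a
    ``scorer`` hook (callable: pose coordinates -> score, higher = better)
    the decoys themselves are ranked by score instead and the k best
    returned.  Requests for more models than exist return all, with a
    warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if scorer is not None:
        scores = [float(scorer(d.coords)) for d in decoys.decoys]
        order = sorted(range(len(scores)), key=lambda i: -scores[i])
        chosen = order[:k]
        if k > len(chosen):
            warnings.warn(f"requested {k} models but only "
                          f"{len(chosen)} decoys exist")
        return [Pose(coords=decoys.decoys[i].coords.copy(), source="decoy",
                     energy=decoys.decoys[i].energy) for i in chosen]
    if k > len(clusters):
        warnings.warn(f"requested {k} models but only "
                      f"{len(clusters)} clusters exist; returning all")
    out = []
    for c in clusters[:k]:
        d = decoys.decoys[c.representative]
        out.append(Pose(coords=d.coords.copy(), source="decoy",
                        energy=d.energy))
    return out
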