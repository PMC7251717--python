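"""Docking evaluation metrics.

All metrics operate on heavy atoms and assume the predicted and reference
poses share the receptor coordinate frame (no re-superposition is applied;
evaluating against a differently oriented receptor requires superposing the
receptors first, which is outside this module's scope).

* ligand RMSD — per-atom root-mean-square deviation in the common frame;
* symmetry-corrected RMSD — the minimum RMSD over all element- and
  bond-preserving automorphisms of the ligand graph, correcting the
  artificially high values naive atom ordering gives symmetric ligands
  (e.g. a benzene ring relabelled by rotation);
* center distance — distance between the poses' geometric centers;
* binding-site error — distance between a predicted binding-site center and
  the native ligand's center, deemed acceptable below 8 Å;
* pocket residues / contact scores — the residues in van der Waals contact
  with the ligand (pair distance < r_i + r_j + 0.5 Å), compared between a
  predicted and the native pose as precision, recall and F1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from networkx.algorithms.isomorphism import GraphMatcher
from scipy.spatial.distance import cdist

from .graph_match import Pose
from .io_formats import Ligand, Receptor

__all__ = [
    "ContactComparison",
    "BindingSiteError",
    "ligand_rmsd",
    "symmetry_corrected_rmsd",
    "ligand_automorphisms",
    "center_distance",
    "binding_site_error",
    "pocket_residues",
    "contact_scores",
    "BS_ERROR_CUTOFF",
    "CONTACT_TOLERANCE",
]

BS_ERROR_CUTOFF = 8.0      # Å, acceptable binding-site error (strict <)
CONTACT_TOLERANCE = 0.5    # Å added to the vdW-radius sum for contacts


def _coords(pose) -> np.ndarray:
    if isinstance(pose, Pose):
        return pose.coords
    return np.asarray(pose, dtype=float)


def _heavy_coords(pose, ligand: Ligand | None) -> np.ndarray:
    xyz = _coords(pose)
    if ligand is not None:
        if xyz.shape[0] != ligand.n_atoms:
            raise ValueError("pose / ligand atom-count mismatch")
        xyz = xyz[ligand.heavy_mask]
    return xyz


def ligand_rmsd(pred, ref, ligand: Ligand | None = None) -> float:
    """Heavy-atom RMSD between poses in a common frame (no superposition)."""
    p = _heavy_coords(pred, ligand)
    r = _heavy_coords(ref, ligand)
    if p.shape != r.shape:
        raise ValueError("poses must have the same atom count and order")
    return float(np.sqrt(np.mean(np.sum((p - r) ** 2, axis=1))))


def ligand_automorphisms(ligand: Ligand) -> list[dict[int, int]]:
    """All element- and bond-preserving automorphisms of the heavy-atom
    graph, as dicts mapping 1-based atom index -> equivalent atom index."""
    g = ligand.heavy_graph()
    matcher = GraphMatcher(
        g, g, node_match=lambda a, b: a["element"] == b["element"])
    return [dict(m) for m in matcher.isomorphisms_iter()]


def symmetry_corrected_rmsd(pred, ref, ligand: Ligand) -> float:
    """Minimum heavy-atom RMSD over ligand-graph automorphisms.

    Chemically equivalent atoms (same element, same bonding environment) may
    be relabelled; the reported value is the best RMSD over all such
    relabellings, and always <= the naive :func:`ligand_rmsd`.
    """
    p_all = _coords(pred)
    r_all = _coords(ref)
    if p_all.shape[0] != ligand.n_atoms or r_all.shape[0] != ligand.n_atoms:
        raise ValueError("pose / ligand atom-count mismatch")
    heavy = [a.index for a in ligand.atoms if a.is_heavy]
    pos = {a: k for k, a in enumerate(heavy)}
    p = p_all[[a - 1 for a in heavy]]
    r = r_all[[a - 1 for a in heavy]]
    best = np.inf
    for auto in ligand_automorphisms(ligand):
        perm = [pos[auto[a]] for a in heavy]
        val = float(np.sqrt(np.mean(np.sum((p - r[perm]) ** 2, axis=1))))
        best = min(best, val)
    return best


def center_distance(pred, ref, ligand: Ligand | None = None) -> float:
    """Distance between heavy-atom geometric centers of two poses."""
    p = _heavy_coords(pred, ligand)
    r = _heavy_coords(ref, ligand)
    if len(p) == 0 or len(r) == 0:
        raise ValueError("empty pose")
    return float(np.linalg.norm(p.mean(axis=0) - r.mean(axis=0)))


@dataclass(frozen=True)
class BindingSiteError:
    distance: float
    acceptable: bool  # distance < 8 Å


def binding_site_error(predicted_center: np.ndarray, native_ligand,
                       ligand: Ligand | None = None) -> BindingSiteError:
    """Distance from a predicted binding-site center to the native ligand's
    heavy-atom center; acceptable when strictly below 8 Å."""
    center = np.asarray(predicted_center, dtype=float)
    native = _heavy_coords(native_ligand, ligand)
    d = float(np.linalg.norm(center - native.mean(axis=0)))
    return BindingSiteError(distance=d, acceptable=d < BS_ERROR_CUTOFF)


def pocket_residues(receptor: Receptor, ligand_pose, ligand: Ligand
                    ) -> set[tuple]:
    """Residues with a heavy atom in van der Waals contact with the ligand.

    A contact is a receptor-ligand heavy-atom pair closer than
    r_i + r_j + 0.5 Å (strict inequality).  Both molecules must carry
    assigned van der Waals radii.
    """
    rec_mask = receptor.heavy_mask
    rec_xyz = receptor.coords[rec_mask]
    rec_r = receptor.vdw_radii[rec_mask]
    rec_atoms = [a for a in receptor.atoms if a.is_heavy]

    lig_xyz = _heavy_coords(ligand_pose, ligand)
    lig_r = ligand.vdw_radii[ligand.heavy_mask]

    d = cdist(rec_xyz, lig_xyz)
    threshold = rec_r[:, None] + lig_r[None, :] + CONTACT_TOLERANCE
    in_contact = (d < threshold).any(axis=1)
    return {rec_atoms[i].residue_id for i in np.flatnonzero(in_contact)}


@dataclass
class ContactComparison:
    """Predicted-vs-native binding-residue agreement.

    Metrics with an undefined denominator (no predicted positives, or no
    native positives) are reported as ``None`` rather than 0.
    """

    tp: int
    fp: int
    fn: int
    precision: float | None
    recall: float | None
    f1: float | None


def contact_scores(predicted_residues: set, native_residues: set
                   ) -> ContactComparison:
    """Precision TP/(TP+FP), recall TP/(TP+FN), F1 = 2/(1/prec + 1/rec)."""
    predicted = set(predicted_residues)
    native = set(native_residues)
    tp = len(predicted & native)
    fp = len(predicted - native)
    fn = len(native - predicted)
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    if precision and recall:
        f1 = 2.0 / (1.0 / precision + 1.0 / recall)
    elif precision is None or recall is None:
        f1 = None
    else:
        f1 = 0.0
    return ContactComparison(tp=tp, fp=fp, fn=fn, precision=precision,
                             recall=recall, f1=f1)
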