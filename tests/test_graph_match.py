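"""Graph matching: edge rule, clique growth, Kabsch superposition,
initial-pose selection."""

import math
import warnings

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from remdock.fixtures import make_ligand
from remdock.graph_match import (
    Pose, edge_test, grow_cliques, kabsch_superpose, pose_from_clique,
    random_unit_axis, rotate_about_centroid, select_initial_poses,
)
from remdock.io_formats import AtomRecord, Ligand, assign_parameters
from remdock.pocket import PocketGrid


def _ligand_from_coords(coords, bond_type="1"):
    atoms = [AtomRecord(index=k + 1, element="C", atom_name=f"C{k + 1}",
                        atom_type="C.3", coords=np.asarray(p, float))
             for k, p in enumerate(coords)]
    bonds = [(k, k + 1, bond_type) for k in range(1, len(atoms))]
    return assign_parameters(Ligand(atoms=atoms, bonds=bonds))


def _grid(points):
    points = np.asarray(points, float)
    return PocketGrid(center=points.mean(axis=0), points=points)


def _triangle(d12, d13, d23):
    x = (d13 ** 2 - d23 ** 2 + d12 ** 2) / (2 * d12)
    y = math.sqrt(d13 ** 2 - x ** 2)
    return np.array([[0.0, 0, 0], [d12, 0, 0], [x, y, 0]])


class TestEdgeTest:
    @pytest.mark.parametrize("dl,dp,n,expect", [
        (4.90, 4.90, 1, True),   # first edge of the worked example
        (6.18, 6.63, 2, True),   # 0.45 < 0.50
        (1.40, 2.00, 3, True),   # 0.60 < 0.75
        (6.18, 6.63, 1, False),  # too loose for the first edge
        (0.0, 0.3, 1, False),    # strict inequality at the boundary
        (7.7, 7.7, 1, True),     # zero difference always passes
    ])
    def test_growing_tolerance(self, dl, dp, n, expect):
        assert edge_test(dl, dp, n) is expect

    def test_invalid_order_errors(self):
        with pytest.raises(ValueError):
            edge_test(1.0, 1.0, 0)


class TestGrowCliques:
    def test_worked_three_node_example(self):
        """The printed ligand/pocket distance triple yields exactly one
        3-node clique, its edges accepted at tolerances 1, 2, 3."""
        lig = _ligand_from_coords(_triangle(4.90, 6.18, 1.40))
        grid = _grid(_triangle(4.90, 6.63, 2.00) + np.array([20.0, 0, 0]))
        cliques = grow_cliques(lig, grid)
        assert len(cliques) == 1
        clique = cliques[0]
        assert len(clique) == 3
        assert clique.edge_tolerances == [1, 2, 3]
        assert {(n.ligand_atom, n.grid_point) for n in clique.nodes} == \
            {(1, 0), (2, 1), (3, 2)}

    def test_exact_geometric_copy_matches_all_atoms(self):
        lig = make_ligand("rigid_polyatom", 4, seed=5)
        grid = _grid(lig.coords + np.array([10.0, -3.0, 2.0]))
        cliques = grow_cliques(lig, grid)
        full = [c for c in cliques if len(c) == 4]
        assert full, "expected a clique covering every atom"
        ident = {(n.ligand_atom, n.grid_point) for n in full[0].nodes}
        assert ident == {(k, k - 1) for k in range(1, 5)}

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_oracle(self, seed):
        """On small instances the deterministic growth equals a plain-loop
        re-enumeration of the documented rule."""
        rng = np.random.default_rng(seed)
        lig = make_ligand("rigid_polyatom", 4, seed=seed)
        pts = rng.uniform(-4, 4, size=(10, 3))
        grid = _grid(pts)
        got = [frozenset((n.ligand_atom, n.grid_point) for n in c.nodes)
               for c in grow_cliques(lig, grid, max_cliques=10 ** 6)]
        assert got == _oracle_cliques(lig.coords, pts)


def _oracle_cliques(lig_xyz, grid_pts, max_nodes=10):
    """Naive pure-python clique growth under the documented ordering."""
    def dist(p, q):
        return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))

    na, ng = len(lig_xyz), len(grid_pts)
    dl = [[dist(lig_xyz[i], lig_xyz[j]) for j in range(na)] for i in range(na)]
    dp = [[dist(grid_pts[i], grid_pts[j]) for j in range(ng)]
          for i in range(ng)]
    nodes = [(a, g) for a in range(1, na + 1) for g in range(ng)]
    out, seen = [], set()
    for i, (a1, g1) in enumerate(nodes):
        for (a2, g2) in nodes[i + 1:]:
            if a1 == a2 or g1 == g2:
                continue
            if not abs(dl[a1 - 1][a2 - 1] - dp[g1][g2]) < 0.25:
                continue
            clique = [(a1, g1), (a2, g2)]
            n_edge = 1
            while len(clique) < max_nodes:
                added = False
                for (a, g) in nodes:
                    if a in {c[0] for c in clique} or \
                            g in {c[1] for c in clique}:
                        continue
                    step, ok = n_edge, True
                    for (ma, mg) in clique:
                        step += 1
                        if not abs(dl[ma - 1][a - 1] - dp[mg][g]) \
                                < 0.25 * step:
                            ok = False
                            break
                    if ok:
                        clique.append((a, g))
                        n_edge = step
                        added = True
                        break
                if not added:
                    break
            if len(clique) >= 3:
                key = frozenset(clique)
                if key not in seen:
                    seen.add(key)
                    out.append(key)
    return out


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(5, 3))
        rot, t, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)

    def test_translation_recovered(self):
        pts = np.random.default_rng(1).normal(size=(6, 3))
        shift = np.array([1.0, 2.0, 3.0])
        rot, t, rmsd = kabsch_superpose(pts, pts + shift)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(t, shift, atol=1e-10)

    def test_proper_rotation_even_for_reflection_like_targets(self):
        rng = np.random.default_rng(2)
        m = rng.normal(size=(5, 3))
        t = m.copy()
        t[:, 0] *= -1  # mirrored target tempts the reflection branch
        rot, _, _ = kabsch_superpose(m, t)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_matches_rotation_search_oracle(self):
        """SVD result equals numeric minimization over rotation space."""
        rng = np.random.default_rng(3)
        m = rng.normal(size=(5, 3))
        t = rng.normal(size=(5, 3))
        _, _, rmsd = kabsch_superpose(m, t)

        mc, tc = m - m.mean(0), t - t.mean(0)

        def objective(rotvec):
            r = Rotation.from_rotvec(rotvec).as_matrix()
            return np.sqrt(np.mean(np.sum((mc @ r.T - tc) ** 2, axis=1)))

        best = np.inf
        for seed_vec in Rotation.random(60, rng=rng).as_rotvec():
            res = minimize(objective, seed_vec, method="Nelder-Mead",
                           options={"xatol": 1e-8, "fatol": 1e-12})
            best = min(best, res.fun)
        assert rmsd == pytest.approx(best, abs=1e-3)
        assert rmsd <= best + 1e-9

    def test_degenerate_inputs_error(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(ValueError):
            kabsch_superpose(line, line)
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestPoseFromClique:
    def test_exact_copy_lands_on_grid_points(self):
        lig = make_ligand("rigid_polyatom", 4, seed=7)
        shift = np.array([5.0, 5.0, 5.0])
        grid = _grid(lig.coords + shift)
        cliques = grow_cliques(lig, grid)
        full = next(c for c in cliques if len(c) == 4)
        pose = pose_from_clique(lig, full, grid)
        np.testing.assert_allclose(pose.coords, lig.coords + shift,
                                   atol=1e-9)

    def test_collinear_clique_skipped_with_warning(self):
        lig = _ligand_from_coords([[0.0, 0, 0], [2.0, 0, 0], [4.0, 0, 0]])
        grid = _grid([[0.0, 0, 0], [2.0, 0, 0], [4.0, 0, 0]])
        cliques = grow_cliques(lig, grid)
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            pose = pose_from_clique(lig, cliques[0], grid)
        assert pose is None
        assert any("degenerate" in str(w.message) for w in rec)

    def test_equivariance_under_rigid_transform(self):
        lig = make_ligand("rigid_polyatom", 5, seed=9)
        grid = _grid(lig.coords + np.array([8.0, 0, 0]))
        clique = grow_cliques(lig, grid)[0]
        pose = pose_from_clique(lig, clique, grid)

        rot = Rotation.from_rotvec([0.3, -0.5, 0.7]).as_matrix()
        shift = np.array([2.0, -4.0, 1.0])
        lig2 = _ligand_from_coords(lig.coords @ rot.T + shift)
        grid2 = _grid(grid.points @ rot.T + shift)
        pose2 = pose_from_clique(lig2, clique, grid2)
        np.testing.assert_allclose(pose2.coords,
                                   pose.coords @ rot.T + shift, atol=1e-8)


def _poses_with_energy(values):
    """Poses whose first-atom x encodes the energy read by the test fn."""
    out = []
    for v in values:
        coords = np.array([[v, 0.0, 0.0], [v, 1.0, 0.0], [v, 0.0, 1.0]])
        out.append(Pose(coords=coords))
    return out


def _efn(coords):
    return coords[0, 0]


class TestSelectInitialPoses:
    def test_ranking_keeps_lowest_energy(self):
        rng = np.random.default_rng(0)
        values = list(np.linspace(0, 500, 250)) + [2e6] * 50
        poses = _poses_with_energy(values)
        chosen = select_initial_poses(poses, _efn, n_needed=100,
                                      predicted_mode=False, rng=rng)
        assert len(chosen) == 100
        got = sorted(p.energy for p in chosen)
        np.testing.assert_allclose(got, sorted(values)[:100])

    def test_predicted_mode_flip_and_rotation_bookkeeping(self):
        rng = np.random.default_rng(1)
        poses = _poses_with_energy(np.linspace(0, 19, 20))
        chosen = select_initial_poses(poses, _efn, n_needed=200,
                                      predicted_mode=True, rng=rng)
        assert len(chosen) == 200
        sources = [p.source for p in chosen]
        assert sources.count("graph_match") == 20
        assert sources.count("flip") == 20
        assert sources.count("random_rotation") == 160

    def test_all_above_cutoff_falls_back(self):
        rng = np.random.default_rng(2)
        poses = _poses_with_energy([2e6] * 5)
        base = np.array([[0.0, 0, 0], [1.5, 0, 0], [0, 1.5, 0]])
        with pytest.warns(UserWarning, match="fall"):
            chosen = select_initial_poses(
                poses, _efn, n_needed=12, predicted_mode=False, rng=rng,
                fallback_coords=base, fallback_center=np.array([5.0, 5, 5]))
        assert len(chosen) == 12
        assert all(p.source == "random_rotation" for p in chosen)

    def test_flip_preserves_centroid(self):
        rng = np.random.default_rng(3)
        coords = np.random.default_rng(4).normal(size=(6, 3))
        flipped = rotate_about_centroid(coords, random_unit_axis(rng), np.pi)
        np.testing.assert_allclose(flipped.mean(0), coords.mean(0),
                                   atol=1e-10)
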