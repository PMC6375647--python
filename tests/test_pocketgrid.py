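"""Sphere-grid construction and the three refinement steps, against brute force."""

import numpy as np
import pytest

from voxpocket.pocketgrid import (
    EmptyPocketError,
    PocketGrid,
    build_sphere_grid,
    carve_pocket,
    clip_to_envelope,
    largest_component,
    remove_excluded_volume,
)
from voxpocket.structures import Atom, Ligand, TypedStructure


def _structure(coords, sybyl="C.3"):
    return TypedStructure([
        Atom(i + 1, "CA", "C", "ALA", ("A", i + 1, ""), np.asarray(c, float), sybyl)
        for i, c in enumerate(np.atleast_2d(coords))
    ])


def brute_sphere_count(radius, spacing):
    n = int(np.floor(radius / spacing))
    count = 0
    for x in range(-n, n + 1):
        for y in range(-n, n + 1):
            for z in range(-n, n + 1):
                if (x * x + y * y + z * z) * spacing**2 <= radius**2 + 1e-9:
                    count += 1
    return count


class TestSphereGrid:
    @pytest.mark.parametrize("radius,expected", [(1, 7), (2, 33)])
    def test_small_radii_enumeration(self, radius, expected):
        assert len(build_sphere_grid((0, 0, 0), radius)) == expected

    def test_default_matches_bounding_cube_enumeration(self):
        grid = build_sphere_grid((1.5, -2.0, 0.25))
        assert len(grid) == brute_sphere_count(15.0, 1.0)
        norms = np.linalg.norm(grid.points - grid.center, axis=1)
        assert norms.max() <= 15.0 + 1e-9
        assert len(np.unique(grid.points, axis=0)) == len(grid)

    def test_radius_below_spacing_rejected(self):
        with pytest.raises(ValueError):
            build_sphere_grid((0, 0, 0), radius=0.5, spacing=1.0)


class TestExcludedVolume:
    def test_threshold_inclusive(self):
        grid = build_sphere_grid((0, 0, 0), radius=4)
        out = remove_excluded_volume(grid, _structure([[0, 0, 0]]), cutoff=2.0)
        d = np.linalg.norm(out.points, axis=1)
        assert d.min() > 2.0  # lattice points at exactly 2.0 were removed
        removed = np.linalg.norm(grid.points, axis=1) <= 2.0
        assert out.removal_log["excluded_volume"] == int(removed.sum())

    def test_distant_protein_leaves_grid_unchanged(self):
        grid = build_sphere_grid((0, 0, 0), radius=3)
        out = remove_excluded_volume(grid, _structure([[30, 0, 0]]))
        assert len(out) == len(grid)

    def test_matches_all_pairs_filter(self, rng):
        grid = build_sphere_grid((0, 0, 0), radius=6)
        atoms = rng.uniform(-6, 6, (20, 3))
        out = remove_excluded_volume(grid, _structure(atoms), cutoff=2.0)
        dmin = np.sqrt(((grid.points[:, None] - atoms[None]) ** 2).sum(-1)).min(1)
        np.testing.assert_array_equal(out.points, grid.points[dmin > 2.0])


class TestEnvelopeClip:
    def test_cube_hull_half_space_oracle(self):
        corners = np.array([[sx * 5.0, sy * 5.0, sz * 5.0]
                            for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)])
        grid = build_sphere_grid((0, 0, 0), radius=8)
        out = clip_to_envelope(grid, _structure(corners), mode="hull")
        inside = np.all(np.abs(grid.points) <= 5.0 + 1e-9, axis=1)
        np.testing.assert_array_equal(out.points, grid.points[inside])

    def test_boundary_point_retained(self):
        corners = np.array([[sx * 3.0, sy * 3.0, sz * 3.0]
                            for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)])
        grid = build_sphere_grid((0, 0, 0), radius=3)
        out = clip_to_envelope(grid, _structure(corners), mode="hull")
        assert any(np.allclose(p, [3, 0, 0]) for p in out.points)

    def test_enclosing_shell_keeps_everything(self, sample_record, toy_pot):
        grid = build_sphere_grid((0, 0, 0), radius=2)
        corners = np.array([[sx * 9.0, sy * 9.0, sz * 9.0]
                            for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)])
        out = clip_to_envelope(grid, _structure(corners), mode="hull")
        assert len(out) == len(grid)

    def test_coplanar_protein_falls_back_to_envelope(self):
        coords = [[x, y, 0.0] for x in (-4, 0, 4) for y in (-4, 0, 4)]
        grid = build_sphere_grid((0, 0, 0), radius=5)
        with pytest.warns(UserWarning, match="envelope"):
            out = clip_to_envelope(grid, _structure(coords), mode="hull",
                                   envelope_radius=4.0)
        dmin = np.sqrt(((grid.points[:, None] - np.asarray(coords, float)[None]) ** 2)
                       .sum(-1)).min(1)
        np.testing.assert_array_equal(out.points, grid.points[dmin <= 4.0])


def _grid_from_points(points):
    points = np.asarray(points, float)
    return PocketGrid(points, np.zeros(3), 20.0, 1.0)


def bfs_components(points, connectivity=6):
    """Independent BFS over the lattice graph."""
    pts = {tuple(map(int, p)) for p in points}
    if connectivity == 6:
        moves = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        moves = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
                 for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)]
    seen, comps = set(), []
    for start in pts:
        if start in seen:
            continue
        comp, queue = set(), [start]
        seen.add(start)
        while queue:
            node = queue.pop()
            comp.add(node)
            for m in moves:
                nb = (node[0] + m[0], node[1] + m[1], node[2] + m[2])
                if nb in pts and nb not in seen:
                    seen.add(nb)
                    queue.append(nb)
        comps.append(comp)
    return comps


class TestLargestComponent:
    def test_keeps_biggest_cluster(self):
        big = [(x, 0, 0) for x in range(10)]
        small = [(x, 0, 5) for x in range(3)]
        out = largest_component(_grid_from_points(big + small))
        assert len(out) == 10
        assert out.removal_log["disconnected"] == 3

    def test_single_point_survives(self):
        assert len(largest_component(_grid_from_points([(3, 3, 3)]))) == 1

    def test_tie_broken_toward_center(self):
        near = [(x, 0, 0) for x in range(5)]          # contains (0,0,0)
        far = [(x, 0, 9) for x in range(5)]
        out = largest_component(_grid_from_points(near + far))
        assert {tuple(map(int, p)) for p in out.points} == set(near)

    def test_empty_grid_raises(self):
        with pytest.raises(EmptyPocketError):
            largest_component(_grid_from_points(np.empty((0, 3))))

    def test_matches_bfs_oracle_random(self, rng):
        for _ in range(20):
            pts = np.unique(rng.integers(-4, 5, (60, 3)), axis=0)
            out = largest_component(_grid_from_points(pts))
            comps = bfs_components(pts)
            assert len(out) == max(len(c) for c in comps)

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_result_is_connected(self, rng, connectivity):
        pts = np.unique(rng.integers(-5, 6, (120, 3)), axis=0)
        out = largest_component(_grid_from_points(pts), connectivity)
        assert len(bfs_components(out.points, connectivity)) == 1


class TestCarvePocket:
    def test_equals_stage_composition(self, sample_record):
        from voxpocket.structures import assign_sybyl_types, parse_structure, select_ligand

        st, het = parse_structure(sample_record.pdb_text)
        typed, _ = assign_sybyl_types(st)
        lig = select_ligand(het, "LIG")
        composed = largest_component(
            clip_to_envelope(
                remove_excluded_volume(build_sphere_grid(lig.center), typed), typed))
        direct = carve_pocket(typed, lig)
        np.testing.assert_array_equal(direct.points, composed.points)

    def test_each_step_removes_points_and_log_sums(self, sample_record):
        from voxpocket.structures import parse_structure, select_ligand

        st, het = parse_structure(sample_record.pdb_text)
        lig = select_ligand(het, "LIG")
        grid = carve_pocket(st, lig)
        log = grid.removal_log
        assert log["excluded_volume"] > 0 and log["envelope_clip"] > 0
        initial = brute_sphere_count(15.0, 1.0)
        assert initial - sum(log.values()) == len(grid)
        assert len(bfs_components(grid.lattice_indices)) == 1

    def test_deterministic(self, sample_record):
        from voxpocket.structures import parse_structure, select_ligand

        st, het = parse_structure(sample_record.pdb_text)
        lig = select_ligand(het, "LIG")
        np.testing.assert_array_equal(carve_pocket(st, lig).points,
                                      carve_pocket(st, lig).points)

    def test_vanishing_pocket_raises(self):
        protein = _structure([[40, 0, 0], [44, 0, 0], [40, 4, 0], [40, 0, 4]])
        ligand = Ligand([Atom(1, "C1", "C", "LIG", ("L", 1, ""), np.zeros(3))])
        with pytest.raises(EmptyPocketError):
            carve_pocket(protein, ligand)
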