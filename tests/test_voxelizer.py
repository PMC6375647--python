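"""Principal-axis canonicalization and voxel discretization."""

import numpy as np
import pytest

from voxpocket import synthetic
from voxpocket.pocketgrid import PocketGrid
from voxpocket.potentials import EnergyGrid
from voxpocket.structures import parse_structure, write_pdb
from voxpocket.voxelizer import (
    CanonicalFrame,
    canonicalize,
    load_tensor,
    pool_tensor,
    principal_axes,
    save_tensor,
    to_occupancy,
    to_voxels,
)


def _skewed_cloud(rng, scales=(3.0, 2.0, 1.0), n=400):
    """Anisotropic point cloud with positive skewness along every axis."""
    base = rng.gamma(2.0, 1.0, (n, 3)) - 2.0   # right-skewed, near-zero mean
    return base * np.asarray(scales)


class TestPrincipalAxes:
    def test_eigen_aligned_input_gives_identity(self, rng):
        coords = _skewed_cloud(rng)
        frame = principal_axes(coords, center=(0, 0, 0))
        np.testing.assert_allclose(frame.rotation, np.eye(3), atol=0.05)
        assert np.all(np.diff(frame.axis_lengths) <= 0)

    def test_recovers_known_rotation(self, rng):
        coords = _skewed_cloud(rng)
        frame0 = principal_axes(coords, center=(0, 0, 0))
        theta = 1.1
        r0 = np.array([[np.cos(theta), 0, np.sin(theta)], [0, 1, 0],
                       [-np.sin(theta), 0, np.cos(theta)]])
        frame1 = principal_axes(coords @ r0.T, center=(0, 0, 0))
        # composing the recovered rotation with the applied one reproduces frame0
        np.testing.assert_allclose(frame1.rotation @ r0, frame0.rotation, atol=1e-6)

    def test_rotation_is_proper(self, rng):
        frame = principal_axes(_skewed_cloud(rng), center=(1, 2, 3))
        assert np.isclose(np.linalg.det(frame.rotation), 1.0)

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValueError, match="3"):
            principal_axes(np.array([[0, 0, 0], [1, 0, 0]]), center=(0, 0, 0))

    def test_collinear_atoms_rejected(self):
        coords = np.outer(np.linspace(0, 5, 10), [1.0, 1.0, 0.0])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            principal_axes(coords, center=(0, 0, 0))


def _egrid(points, channels, center=(0, 0, 0)):
    grid = PocketGrid(np.asarray(points, float), np.asarray(center, float), 15.0, 1.0)
    return EnergyGrid(grid, np.asarray(channels, float), ("a", "b")[:np.shape(channels)[1]])


class TestCanonicalize:
    def test_identity_frame_centers_coordinates(self):
        eg = _egrid([[5, 5, 5], [6, 5, 5]], [[1.0], [2.0]][:2], center=(5, 5, 5))
        eg = EnergyGrid(eg.grid, np.array([[1.0], [2.0]]), ("a",))
        out = canonicalize(eg, CanonicalFrame.identity(center=(5, 5, 5)))
        np.testing.assert_allclose(out.grid.points, [[0, 0, 0], [1, 0, 0]])
        np.testing.assert_array_equal(out.channels, eg.channels)

    def test_isometry_preserves_norms(self, rng):
        pts = rng.uniform(-5, 5, (50, 3))
        eg = _egrid(pts, np.ones((50, 2)))
        frame = principal_axes(rng.normal(size=(30, 3)) * [3, 2, 1], center=(0, 0, 0))
        out = canonicalize(eg, frame)
        np.testing.assert_allclose(np.linalg.norm(out.grid.points, axis=1),
                                   np.linalg.norm(pts, axis=1), atol=1e-9)

    def test_identity_frame_idempotent(self):
        eg = _egrid([[1, 2, 3]], [[1.0, 2.0]])
        once = canonicalize(eg, CanonicalFrame.identity())
        twice = canonicalize(once, CanonicalFrame.identity())
        np.testing.assert_allclose(once.grid.points, twice.grid.points)


class TestToVoxels:
    def test_origin_point_lands_in_central_voxel(self):
        eg = _egrid([[0.0, 0.0, 0.0]], np.ones((1, 2)))
        vt = to_voxels(eg)
        nz = np.argwhere(vt.values[..., 0] != 0)
        np.testing.assert_array_equal(nz, [[16, 16, 16]])

    def test_collisions_averaged(self):
        eg = _egrid([[0.1, 0.1, 0.1], [0.4, 0.4, 0.4]], [[1.0, 1.0], [3.0, 3.0]])
        vt = to_voxels(eg)
        assert vt.values[16, 16, 16, 0] == 2.0
        np.testing.assert_array_equal(vt.point_map[(16, 16, 16)], [0, 1])

    def test_per_channel_mass_conserved(self, sample_result):
        vt = sample_result.tensor
        eg = sample_result.energies
        total = np.zeros(vt.values.shape[-1])
        for voxel, pts in vt.point_map.items():
            total += vt.values[voxel] * len(pts)
        np.testing.assert_allclose(total, eg.channels.sum(axis=0), rtol=1e-9)

    def test_out_of_range_coordinates_rejected(self):
        eg = _egrid([[20.0, 0.0, 0.0]], np.ones((1, 2)))
        with pytest.raises(ValueError, match="canonicalize"):
            to_voxels(eg)


class TestOccupancy:
    def test_empty_grid_all_empty(self):
        grid = PocketGrid(np.empty((0, 3)), np.zeros(3), 15.0, 1.0)
        vt = to_occupancy(grid, CanonicalFrame.identity())
        assert np.all(vt.values[..., 0] == 0) and np.all(vt.values[..., 1] == 1)

    def test_channels_are_one_hot(self, sample_result):
        vt = sample_result.occupancy
        np.testing.assert_array_equal(vt.values.sum(axis=-1), np.ones((32, 32, 32)))

    def test_occupied_count_equals_distinct_voxels(self, sample_result):
        vt = sample_result.occupancy
        assert vt.values[..., 0].sum() == len(vt.point_map)


class TestTensorIO:
    def test_hdf5_round_trip_bit_exact(self, tmp_path, sample_result):
        path = tmp_path / "t.h5"
        save_tensor(path, sample_result.tensor)
        loaded = load_tensor(path)
        np.testing.assert_array_equal(loaded.values, sample_result.tensor.values)
        assert loaded.channel_labels == sample_result.tensor.channel_labels
        np.testing.assert_array_equal(loaded.frame.rotation,
                                      sample_result.tensor.frame.rotation)
        assert set(loaded.point_map) == set(sample_result.tensor.point_map)
        for k in loaded.point_map:
            np.testing.assert_array_equal(sorted(loaded.point_map[k]),
                                          sorted(sample_result.tensor.point_map[k]))


def test_pool_tensor_averages_blocks():
    v = np.arange(4**3 * 2, dtype=float).reshape(4, 4, 4, 2)
    pooled = pool_tensor(v, 2)
    assert pooled.shape == (2, 2, 2, 2)
    np.testing.assert_allclose(pooled[0, 0, 0], v[:2, :2, :2].reshape(-1, 2).mean(0))


def rigidly_move_record(record, rotation, shift):
    """Rewrite a synthetic complex's PDB with all coordinates rigidly moved."""
    from dataclasses import replace as dc_replace

    st, het = parse_structure(record.pdb_text)
    moved = type(st)([dc_replace(a, coords=rotation @ a.coords + shift)
                      for a in st.atoms])
    for g in het:
        g.atoms = [dc_replace(a, coords=rotation @ a.coords + shift) for a in g.atoms]
    return write_pdb(moved, het)


def random_lattice_rotation(rng):
    """A random proper rotation of the cubic sampling lattice (signed permutation)."""
    while True:
        perm = rng.permutation(3)
        signs = rng.choice([-1.0, 1.0], 3)
        q = np.zeros((3, 3))
        q[np.arange(3), perm] = signs
        if np.linalg.det(q) > 0:
            return q


def min_mismatch_over_sign_flips(a, b):
    return min(
        np.abs(b[::sx, ::sy, ::sz, :] - a).max()
        for sx in (1, -1) for sy in (1, -1) for sz in (1, -1)
    )


def test_pose_invariance_up_to_sign_convention(sample_record, toy_pot):
    """A lattice-preserving rigid motion leaves the tensor unchanged up to axis flips.

    The sampling lattice is axis-aligned, so exact equality is expected for
    rotations in the cubic point group combined with any translation; the
    canonical orientation step removes the motion, leaving at most the
    documented eigenvector sign ambiguity.
    """
    base = synthetic.process_complex(sample_record, toy_pot)
    rng = np.random.default_rng(3)
    q = random_lattice_rotation(rng)
    shift = np.array([7.25, -3.5, 11.0])   # decimal-exact, survives PDB rounding
    moved_pdb = rigidly_move_record(sample_record, q, shift)
    moved = synthetic.process_complex(
        synthetic.ComplexRecord(moved_pdb, sample_record.label,
                                sample_record.class_name, sample_record.index,
                                sample_record.patch_residues,
                                sample_record.lining_residues,
                                sample_record.cavity_radius), toy_pot)
    assert min_mismatch_over_sign_flips(base.tensor.values, moved.tensor.values) < 1e-6
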