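"""Canonical orientation and voxelization of energy grids.

Pockets are pose-standardized before entering the network: the grid is
translated so the ligand geometric center sits at the origin and rotated so
the longest, middle and shortest principal axes of the binding-residue heavy
atoms align with x, y and z.  Eigenvector sign ambiguity is resolved by
requiring the third central moment (skewness direction) of the binding atoms
along x and y to be non-negative, with z completing a right-handed frame.
The oriented points are then binned into a fixed 32-per-side voxel tensor;
grid points sharing a voxel have their channel vectors averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .pocketgrid import PocketGrid
from .potentials import EnergyGrid
from .structures import ResidueSet

OCCUPANCY_LABELS = ("occupied", "empty")


@dataclass
class CanonicalFrame:
    """Rigid map x -> rotation @ (x + translation) into the canonical pose."""

    rotation: np.ndarray       # (3, 3), rows are the canonical axes
    translation: np.ndarray    # (3,)
    axis_lengths: np.ndarray   # descending eigenvalues of the binding-atom covariance

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, float).reshape(3, 3)
        self.translation = np.asarray(self.translation, float).reshape(3)
        self.axis_lengths = np.asarray(self.axis_lengths, float).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation is improper (determinant -1)")
        if np.any(np.diff(self.axis_lengths) > 1e-9):
            raise ValueError("axis lengths must be descending")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return (np.asarray(coords, float) + self.translation) @ self.rotation.T

    @classmethod
    def identity(cls, center=(0.0, 0.0, 0.0)) -> "CanonicalFrame":
        return cls(np.eye(3), -np.asarray(center, float), np.zeros(3))


def principal_axes(binding: ResidueSet, center) -> CanonicalFrame:
    """Canonical frame from the binding-residue heavy-atom covariance.

    ``center`` (the pocket grid / ligand center) maps to the origin; rotation
    rows are unit eigenvectors ordered by descending eigenvalue with the sign
    convention described in the module docstring.
    """
    coords = binding.coords if isinstance(binding, ResidueSet) else np.asarray(binding, float)
    if len(coords) < 3:
        raise ValueError("axes undefined: need >= 3 binding atoms")
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(centered)
    evals, evecs = np.linalg.eigh(cov)        # ascending
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[1] <= 1e-10 * max(evals[0], 1.0):
        raise ValueError("axes undefined: binding atoms are collinear or degenerate")
    axes = evecs.T.copy()
    for i in (0, 1):  # skewness-non-negative convention for x and y
        if np.sum((centered @ axes[i]) ** 3) < 0:
            axes[i] = -axes[i]
    axes[2] = np.cross(axes[0], axes[1])      # right-handed z
    return CanonicalFrame(axes, -np.asarray(center, float), evals)


def canonicalize(egrid: EnergyGrid, frame: CanonicalFrame) -> EnergyGrid:
    """Map all grid-point coordinates into the canonical frame; channels untouched."""
    new_points = frame.apply(egrid.grid.points)
    new_grid = PocketGrid(new_points, frame.apply(egrid.grid.center),
                          egrid.grid.radius, egrid.grid.spacing,
                          dict(egrid.grid.removal_log))
    return EnergyGrid(new_grid, egrid.channels.copy(), egrid.channel_labels)


@dataclass
class VoxelTensor:
    """Fixed-size voxel image of a pocket: (side, side, side, channels)."""

    values: np.ndarray
    channel_labels: tuple[str, ...]
    frame: CanonicalFrame
    point_map: dict[tuple[int, int, int], np.ndarray]

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        s = self.values.shape
        if len(s) != 4 or not (s[0] == s[1] == s[2]):
            raise ValueError("voxel tensor must be (N, N, N, C)")
        if s[3] != len(self.channel_labels):
            raise ValueError("channel label count mismatch")

    @property
    def side(self) -> int:
        return self.values.shape[0]


def _bin_points(points: np.ndarray, side: int) -> np.ndarray:
    coords = np.asarray(points, float)
    if coords.size and (coords.min() < -side / 2 or coords.max() >= side / 2):
        raise ValueError(
            f"coordinates outside [-{side / 2}, {side / 2}); canonicalize first")
    return np.floor(coords + side / 2).astype(int)


def to_voxels(egrid: EnergyGrid, side: int = 32,
              frame: CanonicalFrame | None = None) -> VoxelTensor:
    """Discretize a canonicalized energy grid into a ``side``^3 x C tensor.

    Voxel index along each axis is floor(coordinate + side/2); channel vectors
    of points landing in the same voxel are averaged.  ``point_map`` records
    which grid points contributed to each voxel for CAM back-mapping.
    """
    idx = _bin_points(egrid.grid.points, side)
    n_ch = egrid.channels.shape[1]
    sums = np.zeros((side, side, side, n_ch))
    counts = np.zeros((side, side, side), dtype=int)
    np.add.at(sums, tuple(idx.T), egrid.channels)
    np.add.at(counts, tuple(idx.T), 1)
    values = np.divide(sums, counts[..., None], out=np.zeros_like(sums),
                       where=counts[..., None] > 0)
    point_map: dict[tuple[int, int, int], list[int]] = {}
    for pi, v in enumerate(map(tuple, idx)):
        point_map.setdefault(v, []).append(pi)
    return VoxelTensor(values, egrid.channel_labels,
                       frame if frame is not None else CanonicalFrame.identity(),
                       {k: np.asarray(v) for k, v in point_map.items()})


def to_occupancy(grid: PocketGrid, frame: CanonicalFrame, side: int = 32) -> VoxelTensor:
    """Shape-only 2-channel variant: one-hot occupied / empty voxels."""
    idx = _bin_points(frame.apply(grid.points), side)
    occupied = np.zeros((side, side, side), dtype=bool)
    point_map: dict[tuple[int, int, int], list[int]] = {}
    for pi, v in enumerate(map(tuple, idx)):
        occupied[v] = True
        point_map.setdefault(v, []).append(pi)
    values = np.stack([occupied.astype(float), (~occupied).astype(float)], axis=-1)
    return VoxelTensor(values, OCCUPANCY_LABELS, frame,
                       {k: np.asarray(v) for k, v in point_map.items()})


def pool_tensor(values: np.ndarray, factor: int = 2) -> np.ndarray:
    """Spatial average pooling of a (N, N, N, C) tensor by an integer factor."""
    n = values.shape[0]
    if n % factor:
        raise ValueError("side not divisible by pooling factor")
    m = n // factor
    return values.reshape(m, factor, m, factor, m, factor, -1).mean(axis=(1, 3, 5))


def save_tensor(path, vt: VoxelTensor) -> None:
    """Write a voxel tensor to HDF5 (bit-exact round trip)."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("values", data=vt.values)
        fh.create_dataset("channel_labels",
                          data=np.array(vt.channel_labels, dtype="S16"))
        fh.create_dataset("frame/rotation", data=vt.frame.rotation)
        fh.create_dataset("frame/translation", data=vt.frame.translation)
        fh.create_dataset("frame/axis_lengths", data=vt.frame.axis_lengths)
        if vt.point_map:
            keys = np.array(sorted(vt.point_map), dtype=int)
            flat = np.concatenate([vt.point_map[tuple(k)] for k in keys])
            lens = np.array([len(vt.point_map[tuple(k)]) for k in keys])
            fh.create_dataset("point_map/voxels", data=keys)
            fh.create_dataset("point_map/points", data=flat)
            fh.create_dataset("point_map/lengths", data=lens)


def load_tensor(path) -> VoxelTensor:
    with h5py.File(path, "r") as fh:
        values = fh["values"][...]
        labels = tuple(s.decode() for s in fh["channel_labels"][...])
        frame = CanonicalFrame(fh["frame/rotation"][...],
                               fh["frame/translation"][...],
                               fh["frame/axis_lengths"][...])
        point_map: dict[tuple[int, int, int], np.ndarray] = {}
        if "point_map" in fh:
            keys = fh["point_map/voxels"][...]
            flat = fh["point_map/points"][...]
            lens = fh["point_map/lengths"][...]
            offset = 0
            for k, ln in zip(keys, lens):
                point_map[tuple(int(x) for x in k)] = flat[offset:offset + ln]
                offset += ln
    return VoxelTensor(values, labels, frame, point_map)
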