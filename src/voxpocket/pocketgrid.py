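"""Ligand-centered spherical grid construction and three-step pocket refinement.

The pocket is represented by points of a 1 A cubic lattice inside a 15 A
sphere centered on the ligand's geometric center.  Refinement removes, in
order: (1) excluded-volume points within 2 A of any protein heavy atom,
(2) points outside the protein (convex hull of heavy-atom centers by default,
or a distance envelope), and (3) points detached from the largest connected
lattice component.  The result is a single connected grid occupying the
cavity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay, QhullError, cKDTree

from .structures import Ligand, TypedStructure


class EmptyPocketError(RuntimeError):
    """Raised when refinement removes every grid point."""


@dataclass
class PocketGrid:
    """Refined pocket lattice points (lexicographic (z, y, x) order)."""

    points: np.ndarray          # (N, 3) absolute coordinates, A
    center: np.ndarray          # sphere center (ligand geometric center)
    radius: float
    spacing: float
    removal_log: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.points = np.asarray(self.points, float).reshape(-1, 3)
        self.center = np.asarray(self.center, float).reshape(3)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def lattice_indices(self) -> np.ndarray:
        """Integer lattice offsets of each point from the center."""
        return np.rint((self.points - self.center) / self.spacing).astype(int)

    def replaced(self, keep: np.ndarray, step: str) -> "PocketGrid":
        """New grid keeping the boolean-masked points, logging removals."""
        log = dict(self.removal_log)
        log[step] = int(len(self.points) - np.count_nonzero(keep))
        return PocketGrid(self.points[keep], self.center, self.radius, self.spacing, log)


def build_sphere_grid(center, radius: float = 15.0, spacing: float = 1.0) -> PocketGrid:
    """Cubic-lattice points within ``radius`` of ``center``.

    Points are ``center + spacing * v`` for integer vectors ``v`` with
    ``|spacing * v| <= radius``, ordered lexicographically by (z, y, x).
    """
    if radius <= 0 or spacing <= 0:
        raise ValueError("radius and spacing must be positive")
    if radius < spacing:
        raise ValueError("radius smaller than spacing produces a single point shell")
    center = np.asarray(center, float).reshape(3)
    n = int(np.floor(radius / spacing))
    axis = np.arange(-n, n + 1)
    zz, yy, xx = np.meshgrid(axis, axis, axis, indexing="ij")
    lattice = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    keep = np.einsum("ij,ij->i", lattice, lattice) * spacing**2 <= radius**2 + 1e-9
    points = center + spacing * lattice[keep]
    return PocketGrid(points, center, radius, spacing, {"initial": 0})


def remove_excluded_volume(
    grid: PocketGrid, protein: TypedStructure, cutoff: float = 2.0
) -> PocketGrid:
    """Drop grid points within ``cutoff`` (inclusive) of any protein heavy atom."""
    if len(protein) == 0:
        raise ValueError("protein structure is empty")
    dmin, _ = cKDTree(protein.coords).query(grid.points)
    return grid.replaced(dmin > cutoff, "excluded_volume")


def clip_to_envelope(
    grid: PocketGrid,
    protein: TypedStructure,
    mode: str = "hull",
    envelope_radius: float = 4.0,
) -> PocketGrid:
    """Drop points outside the protein body.

    ``mode='hull'`` keeps points inside (or on) the convex hull of protein
    heavy-atom centers; ``mode='envelope'`` keeps points within
    ``envelope_radius`` of any protein atom.  A degenerate (coplanar) protein
    in hull mode falls back to envelope mode with a warning.
    """
    coords = protein.coords
    if mode == "hull":
        try:
            tri = Delaunay(coords)
        except (QhullError, ValueError):
            warnings.warn(
                "degenerate protein for convex hull; falling back to envelope mode",
                stacklevel=2,
            )
            return clip_to_envelope(grid, protein, mode="envelope",
                                    envelope_radius=envelope_radius)
        keep = tri.find_simplex(grid.points, tol=1e-9) >= 0
        return grid.replaced(keep, "envelope_clip")
    if mode == "envelope":
        dmin, _ = cKDTree(coords).query(grid.points)
        return grid.replaced(dmin <= envelope_radius, "envelope_clip")
    raise ValueError(f"unknown clip mode {mode!r}")


_STRUCTURES = {6: ndimage.generate_binary_structure(3, 1),
               26: ndimage.generate_binary_structure(3, 3)}


def largest_component(grid: PocketGrid, connectivity: int = 6) -> PocketGrid:
    """Keep only the largest connected lattice component.

    Adjacency is face (6) or face+edge+corner (26) at one lattice step.  Size
    ties are broken in favor of the component containing the point closest to
    the grid center, then by first label.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6 or 26")
    if len(grid) == 0:
        raise EmptyPocketError("pocket vanished during refinement")
    idx = grid.lattice_indices
    lo = idx.min(axis=0)
    shape = idx.max(axis=0) - lo + 1
    occ = np.zeros(shape, dtype=bool)
    occ[tuple((idx - lo).T)] = True
    labels, n = ndimage.label(occ, structure=_STRUCTURES[connectivity])
    point_labels = labels[tuple((idx - lo).T)]
    sizes = np.bincount(point_labels, minlength=n + 1)
    sizes[0] = -1
    best = sizes.max()
    tied = np.flatnonzero(sizes == best)
    if len(tied) > 1:
        # component holding the center-nearest point wins the tie
        center_near = np.argmin(np.einsum("ij,ij->i",
                                          grid.points - grid.center,
                                          grid.points - grid.center))
        center_label = point_labels[center_near]
        winner = center_label if center_label in tied else tied[0]
    else:
        winner = tied[0]
    return grid.replaced(point_labels == winner, "disconnected")


def carve_pocket(
    protein: TypedStructure,
    ligand: Ligand,
    radius: float = 15.0,
    spacing: float = 1.0,
    exclusion_cutoff: float = 2.0,
    clip_mode: str = "hull",
    envelope_radius: float = 4.0,
    connectivity: int = 6,
) -> PocketGrid:
    """Full grid construction: sphere, excluded volume, clip, largest component."""
    grid = build_sphere_grid(ligand.center, radius, spacing)
    grid = remove_excluded_volume(grid, protein, exclusion_cutoff)
    grid = clip_to_envelope(grid, protein, mode=clip_mode, envelope_radius=envelope_radius)
    return largest_component(grid, connectivity)


def grid_to_pdb(grid: PocketGrid, values: np.ndarray | None = None) -> str:
    """Debug dump of grid points as HETATM pseudo-atoms (values in B-factor)."""
    if values is None:
        values = np.zeros(len(grid))
    lines = []
    for i, (p, v) in enumerate(zip(grid.points, values), start=1):
        serial = i % 100000
        lines.append(
            f"HETATM{serial:>5d}  C   GRD A{i % 10000:>4d}    "
            f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}{1.0:6.2f}{min(v, 999.99):6.2f}"
            f"           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
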