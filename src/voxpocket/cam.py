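"""Class-activation mapping from voxels back to binding residues.

The CAM answers "which part of the pocket drove this classification".  The
feature maps of the last convolutional layer are combined with per-map
weights — gradients of the class logit averaged over space (gradient-weighted
CAM, the default, which works with the max-pool + dense head) or the linear
head weights themselves when the model uses a GAP + linear head (plain CAM).
The combined map is rectified at zero and trilinearly upsampled to the voxel
grid.  The top fraction (default 1%) of voxels by CAM value selects pocket
grid points, and each selected point donates its CAM value to the residue of
its nearest protein heavy atom within 5 A; the per-residue sums are the
CAM-scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .classifier import NetworkConfig, TrainedModel
from .nn import Dense, GlobalAvgPool
from .pocketgrid import PocketGrid, grid_to_pdb
from .structures import ResidueId, TypedStructure
from .voxelizer import VoxelTensor


@dataclass
class CamVolume:
    """Spatial CAM values on the voxel grid for one target class."""

    values: np.ndarray
    class_index: int
    method: str

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 3 or len(set(self.values.shape)) != 1:
            raise ValueError("CAM volume must be a cubic 3D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite CAM values")


def activation_map(
    model: TrainedModel, x: VoxelTensor | np.ndarray, class_index: int,
    method: str = "gradcam", out_side: int | None = None,
) -> CamVolume:
    """Voxel-space CAM of ``class_index`` for a single pocket tensor.

    ``method='gradcam'`` weighs feature maps by spatially averaged gradients
    of the contrast target logit_c - mean(other logits) — the shared logit
    component is invisible to softmax, so a plain class-logit target can be
    flat for a class whose evidence the network encodes in the other logits;
    ``method='cam'`` requires a GAP+linear head and uses its class weights
    directly.  Both rectify at zero and trilinearly upsample to ``out_side``
    (default: the model input side) — pass the voxel-grid side here when the
    model consumes pooled inputs.
    """
    values = x.values if isinstance(x, VoxelTensor) else np.asarray(x, float)
    batch = model._prepare(values)
    net = model.network
    layer_index = NetworkConfig.CAM_LAYER_INDEX
    if method == "gradcam":
        acts, grads = net.activation_gradient(batch, class_index, layer_index,
                                              contrast=True)
        weights = grads[0].mean(axis=(0, 1, 2))           # (n_maps,)
        fmap = acts[0]
    elif method == "cam":
        is_gap_head = (len(net.layers) == layer_index + 3
                       and isinstance(net.layers[layer_index + 1], GlobalAvgPool)
                       and isinstance(net.layers[layer_index + 2], Dense))
        if not is_gap_head:
            raise ValueError("plain CAM requires a model built with head='gap'")
        acts, _ = net.activation_gradient(batch, class_index, layer_index)
        weights = net.layers[layer_index + 2].params[0][:, class_index]
        fmap = acts[0]
    else:
        raise ValueError(f"unknown CAM method {method!r}")
    cam = np.maximum(fmap @ weights, 0.0)
    side = out_side if out_side is not None else model.config.input_side
    cam = _upsample_to_input(cam, model.config, side)
    return CamVolume(cam, class_index, method)


def _upsample_to_input(cam: np.ndarray, cfg: NetworkConfig, out_side: int) -> np.ndarray:
    """Trilinearly resample the feature-map CAM onto the voxel grid.

    Valid convolutions shrink the spatial extent: feature-map voxel m is
    centered on input voxel m + margin, with margin = sum(k - 1)/2 over the
    conv kernels.  When the model consumed pooled inputs, output voxel o maps
    to model-input coordinate (o + 0.5)/f - 0.5 for pooling factor f.
    """
    if cam.shape[0] == out_side and cfg.conv_output_side == cfg.input_side:
        return cam
    margin = sum(k - 1 for k in cfg.conv_kernels) / 2.0
    factor = out_side / cfg.input_side
    axis = (np.arange(out_side) + 0.5) / factor - 0.5 - margin
    coords = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"))
    return ndimage.map_coordinates(cam, coords, order=1, mode="nearest")


@dataclass
class SelectedPoints:
    """Grid points retained by the top-fraction CAM cut, with their CAM values."""

    indices: np.ndarray        # pocket grid point indices
    values: np.ndarray         # CAM value of each point's containing voxel
    threshold: float
    n_voxels: int              # voxels at or above the threshold


def select_top(
    cam: CamVolume, point_map: dict[tuple[int, int, int], np.ndarray],
    fraction: float = 0.01,
) -> SelectedPoints:
    """Retain grid points whose voxel CAM value reaches the top ``fraction``.

    The threshold is the (1 - fraction) quantile over *all* voxels; every
    point in a voxel at or above it is kept (ties keep the whole tie group).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    flat = cam.values.ravel()
    threshold = float(np.quantile(flat, 1.0 - fraction)) if fraction < 1 else float(flat.min())
    if np.all(flat == 0):
        warnings.warn("all-zero CAM: empty selection", stacklevel=2)
        return SelectedPoints(np.empty(0, int), np.empty(0), threshold, 0)
    n_voxels = int(np.sum(flat >= threshold))
    idx, vals = [], []
    for voxel, points in point_map.items():
        v = cam.values[voxel]
        if v >= threshold:
            idx.extend(int(p) for p in points)
            vals.extend([float(v)] * len(points))
    order = np.argsort(idx)
    return SelectedPoints(np.asarray(idx, int)[order], np.asarray(vals)[order],
                          threshold, n_voxels)


@dataclass
class ResidueScores:
    """Per-residue CAM-scores plus the mass that mapped to no residue."""

    scores: dict[ResidueId, float]
    n_points: dict[ResidueId, int]
    residue_names: dict[ResidueId, str]
    unassigned_count: int
    unassigned_value: float

    def top_residue(self) -> ResidueId:
        return max(self.scores, key=lambda r: self.scores[r])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (rid[0], rid[1], rid[2], self.residue_names[rid],
             self.scores[rid], self.n_points[rid])
            for rid in sorted(self.scores, key=lambda r: -self.scores[r])
        ]
        return pd.DataFrame(rows, columns=[
            "chain", "residue_number", "insertion_code", "residue_name",
            "cam_score", "n_points"])


def residue_scores(
    selected: SelectedPoints, grid: PocketGrid, structure: TypedStructure,
    cutoff: float = 5.0,
) -> ResidueScores:
    """Aggregate selected-point CAM values onto nearest residues within ``cutoff``.

    ``grid`` and ``structure`` must be expressed in the same (canonical)
    frame.  Nearest-atom ties are broken by lowest residue number, then chain
    id.  Points with no protein atom within the cutoff stay unassigned.
    """
    coords = structure.coords
    if len(coords) == 0:
        raise ValueError("empty structure")
    points = grid.points[selected.indices]
    if len(points):
        dmin, _ = cKDTree(coords).query(points)
        if dmin.min() > grid.radius + cutoff:
            raise ValueError(
                "selected points are far from every atom; frame mismatch between "
                "grid and structure?")
    # order atoms so the nearest-distance tie resolves to lowest resnum, then chain
    atom_order = sorted(
        range(len(structure.atoms)),
        key=lambda i: (structure.atoms[i].residue_id[1], structure.atoms[i].residue_id[0]),
    )
    ordered_coords = coords[atom_order]
    scores: dict[ResidueId, float] = {}
    counts: dict[ResidueId, int] = {}
    names: dict[ResidueId, str] = {}
    unassigned_count, unassigned_value = 0, 0.0
    for p, v in zip(points, selected.values):
        d = np.linalg.norm(ordered_coords - p, axis=1)
        best = int(np.argmin(d))   # argmin takes the first minimum = lowest-resnum tie
        if d[best] <= cutoff:
            atom = structure.atoms[atom_order[best]]
            rid = atom.residue_id
            scores[rid] = scores.get(rid, 0.0) + v
            counts[rid] = counts.get(rid, 0) + 1
            names.setdefault(rid, atom.residue_name)
        else:
            unassigned_count += 1
            unassigned_value += v
    return ResidueScores(scores, counts, names, unassigned_count, unassigned_value)


def selected_points_pdb(selected: SelectedPoints, grid: PocketGrid) -> str:
    """Selected grid points as pseudo-atoms with CAM values in the B-factor column."""
    sub = PocketGrid(grid.points[selected.indices], grid.center, grid.radius,
                     grid.spacing)
    return grid_to_pdb(sub, selected.values)
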