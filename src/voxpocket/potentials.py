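"""Distance-binned pairwise interaction potentials and per-point energy channels.

Each pocket grid point receives a vector of interaction energies, one channel
per probe atom type (the 14 SYBYL ligand-atom types), obtained by summing a
knowledge-based pair potential u(probe, protein_type, r) over all protein
heavy atoms within the cutoff.  The potential is a pluggable distance-binned
lookup table in the style of DFIRE-type statistical potentials; the package
ships no empirical parameter set, only the table format and a synthetic toy
table for testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .pocketgrid import PocketGrid
from .structures import SYBYL_TYPES, TypedStructure

#: Default probe (ligand atom) types, in channel order.
PROBE_TYPES = SYBYL_TYPES


class PotentialFormatError(ValueError):
    """Raised for malformed potential tables (overlapping/gapped bins, etc.)."""


@dataclass
class PairPotential:
    """Distance-binned pair potential u(probe_type, protein_type, bin).

    ``energies`` has shape (n_probe, n_protein_types, n_bins); distances beyond
    the last bin edge contribute zero.
    """

    probe_types: tuple[str, ...]
    protein_types: tuple[str, ...]
    bin_edges: np.ndarray            # length n_bins + 1, strictly increasing
    energies: np.ndarray
    n_missing_pairs: int = 0

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise PotentialFormatError("bin edges must be strictly increasing")
        expected = (len(self.probe_types), len(self.protein_types),
                    len(self.bin_edges) - 1)
        if self.energies.shape != expected:
            raise PotentialFormatError(
                f"energy array shape {self.energies.shape} != {expected}")

    @property
    def cutoff(self) -> float:
        return float(self.bin_edges[-1])

    def lookup(self, probe: str, protein_type: str, distance: float) -> float:
        """Energy for one probe/protein-type pair at a given distance (0 beyond cutoff)."""
        if distance > self.cutoff or distance < self.bin_edges[0]:
            return 0.0
        b = min(np.searchsorted(self.bin_edges, distance, side="right") - 1,
                self.energies.shape[2] - 1)
        try:
            i = self.probe_types.index(probe)
            j = self.protein_types.index(protein_type)
        except ValueError:
            return 0.0
        return float(self.energies[i, j, b])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.probe_types):
            for j, t in enumerate(self.protein_types):
                for b in range(self.energies.shape[2]):
                    rows.append((p, t, self.bin_edges[b], self.bin_edges[b + 1],
                                 self.energies[i, j, b]))
        return pd.DataFrame(
            rows, columns=["probe_type", "protein_type", "bin_low", "bin_high", "energy"])


def save_potential_table(pot: PairPotential, path) -> None:
    pot.to_frame().to_csv(path, sep="\t", index=False)


def load_potential_table(path, probe_types: tuple[str, ...] = PROBE_TYPES) -> PairPotential:
    """Load a tab-separated potential table.

    Columns: probe_type, protein_type, bin_low, bin_high, energy.  All pairs
    must share one contiguous, non-overlapping bin ladder; pairs absent from
    the table default to zero energy (counted and warned about).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"probe_type", "protein_type", "bin_low", "bin_high", "energy"}
    if not required.issubset(df.columns):
        raise PotentialFormatError(f"table must have columns {sorted(required)}")
    if df.empty:
        warnings.warn("empty potential table; all energies zero", stacklevel=2)
        edges = np.array([0.0, 14.5])
        energies = np.zeros((len(probe_types), len(SYBYL_TYPES), 1))
        return PairPotential(tuple(probe_types), SYBYL_TYPES, edges, energies,
                             n_missing_pairs=len(probe_types) * len(SYBYL_TYPES))

    ladders = {
        tuple(map(tuple, g[["bin_low", "bin_high"]].sort_values("bin_low").values))
        for _, g in df.groupby(["probe_type", "protein_type"])
    }
    if len(ladders) != 1:
        raise PotentialFormatError("all pairs must share the same distance bins")
    ladder = next(iter(ladders))
    edges = [ladder[0][0]]
    for low, high in ladder:
        if low != edges[-1]:
            raise PotentialFormatError(
                f"bins must be contiguous and non-overlapping; gap/overlap at {low}")
        if high <= low:
            raise PotentialFormatError(f"empty bin [{low}, {high}]")
        edges.append(high)
    edges = np.asarray(edges)

    extra = sorted(set(df["protein_type"]) - set(SYBYL_TYPES))
    protein_types = SYBYL_TYPES + tuple(extra)
    energies = np.zeros((len(probe_types), len(protein_types), len(edges) - 1))
    present = set()
    p_index = {p: i for i, p in enumerate(probe_types)}
    t_index = {t: j for j, t in enumerate(protein_types)}
    bin_of = {low: b for b, (low, _) in enumerate(ladder)}
    for row in df.itertuples(index=False):
        if row.probe_type not in p_index:
            raise PotentialFormatError(f"unknown probe type {row.probe_type!r}")
        i, j = p_index[row.probe_type], t_index[row.protein_type]
        energies[i, j, bin_of[row.bin_low]] = row.energy
        present.add((row.probe_type, row.protein_type))
    n_missing = len(probe_types) * len(protein_types) - len(present)
    if n_missing:
        warnings.warn(f"{n_missing} (probe, protein_type) pair(s) default to zero",
                      stacklevel=2)
    return PairPotential(tuple(probe_types), protein_types, edges, energies, n_missing)


@dataclass
class EnergyGrid:
    """A pocket grid with one interaction-energy vector per point."""

    grid: PocketGrid
    channels: np.ndarray         # (n_points, n_channels)
    channel_labels: tuple[str, ...]

    def __post_init__(self):
        self.channels = np.asarray(self.channels, float)
        if self.channels.shape != (len(self.grid), len(self.channel_labels)):
            raise ValueError("channel array shape mismatch")
        if not np.all(np.isfinite(self.channels)):
            raise ValueError("non-finite channel energies")


def save_energy_grid(path, egrid: EnergyGrid) -> None:
    """Write an energy grid to HDF5 (points, channels, channel labels, geometry)."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("points", data=egrid.grid.points)
        fh.create_dataset("channels", data=egrid.channels)
        fh.create_dataset("channel_labels",
                          data=np.array(egrid.channel_labels, dtype="S16"))
        fh.create_dataset("center", data=egrid.grid.center)
        fh.attrs["radius"] = egrid.grid.radius
        fh.attrs["spacing"] = egrid.grid.spacing


def load_energy_grid(path) -> EnergyGrid:
    import h5py

    with h5py.File(path, "r") as fh:
        grid = PocketGrid(fh["points"][...], fh["center"][...],
                          float(fh.attrs["radius"]), float(fh.attrs["spacing"]))
        channels = fh["channels"][...]
        labels = tuple(s.decode() for s in fh["channel_labels"][...])
    return EnergyGrid(grid, channels, labels)


def energy_channels(
    grid: PocketGrid, protein: TypedStructure, pot: PairPotential,
    chunk: int = 4096,
) -> EnergyGrid:
    """Sum the pair potential over protein atoms for every grid point.

    channel c at point p = sum over atoms a with d(p, a) <= cutoff of
    u(probe_c, sybyl_type(a), bin(d)).  Distances are point-to-atom-center.
    """
    type_index = {}
    atom_types = np.empty(len(protein), dtype=int)
    for k, atom in enumerate(protein.atoms):
        if atom.sybyl_type == "UNKNOWN":
            raise ValueError(
                f"atom {atom.serial} has no SYBYL type; run assign_sybyl_types first")
        if atom.sybyl_type not in pot.protein_types:
            atom_types[k] = -1  # type absent from table: zero contribution
            continue
        j = type_index.get(atom.sybyl_type)
        if j is None:
            j = pot.protein_types.index(atom.sybyl_type)
            type_index[atom.sybyl_type] = j
        atom_types[k] = j

    coords = protein.coords
    tree = cKDTree(coords)
    n_probe = len(pot.probe_types)
    out = np.zeros((len(grid), n_probe))
    n_bins = pot.energies.shape[2]
    for start in range(0, len(grid), chunk):
        pts = grid.points[start:start + chunk]
        neighbors = tree.query_ball_point(pts, pot.cutoff)
        for local, nbrs in enumerate(neighbors):
            if not nbrs:
                continue
            nbrs = np.asarray(nbrs)
            valid = atom_types[nbrs] >= 0
            nbrs = nbrs[valid]
            if nbrs.size == 0:
                continue
            d = np.linalg.norm(coords[nbrs] - pts[local], axis=1)
            bins = np.searchsorted(pot.bin_edges, d, side="right") - 1
            bins[bins == n_bins] = n_bins - 1  # d exactly at the cutoff: last bin
            ok = bins >= 0
            # energies[:, type, bin] summed over neighbor atoms
            out[start + local] = pot.energies[:, atom_types[nbrs[ok]], bins[ok]].sum(axis=1)
    return EnergyGrid(grid, out, tuple(pot.probe_types))
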