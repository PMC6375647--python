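"""Synthetic protein-ligand complexes with a planted, class-specific lining.

Real pocket benchmarks need thousands of curated PDB complexes; this module
generates small pseudo-complexes that exercise every pipeline stage and carry
a learnable class signal.  Each complex is an ellipsoidal shell of
residue-like atom clusters enclosing a pseudo-ligand.  The class signal is
planted in *atom-type composition*, not shape: a contiguous angular patch of
the cavity lining is built from a class-signature residue species (ASN for an
amide/carbonyl lining, PHE for an aromatic lining, ARG for a guanidinium
lining), while the rest of the lining and an outer shell are leucine-like
(aliphatic carbon).  Shapes are statistically identical across classes, so
interaction-energy channels must outperform occupancy channels — mirroring
the energy-vs-shape comparison the classifier is designed around.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import voxelizer
from .pipeline import PocketResult, voxelize_complex
from .potentials import PROBE_TYPES, PairPotential
from .structures import SYBYL_TYPES, ResidueId

#: Side-chain heavy-atom name sets used to assemble pseudo-residues.  The
#: signature species expose their functional-group atoms only (no CB), so a
#: signature patch is dominated by atom types absent from the LEU background.
RESIDUE_ATOMS = {
    "ASN": ("CG", "OD1", "ND2"),                       # C.2, O.2, N.am
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),   # 6x C.ar
    "ARG": ("NE", "CZ", "NH1", "NH2"),                 # N.pl3, C.2, 2x N.pl3
    "LEU": ("CB", "CG", "CD1", "CD2"),                 # 4x C.3 background
}

DEFAULT_CLASSES = {
    "amide": {"ASN": 0.85, "LEU": 0.15},
    "aromatic": {"PHE": 0.85, "LEU": 0.15},
    "guanidinium": {"ARG": 0.85, "LEU": 0.15},
}


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic benchmark."""

    n_per_class: int = 20
    classes: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLASSES.items()})
    cavity_radius_range: tuple[float, float] = (6.5, 8.5)
    outer_offset: float = 5.5            # outer shell sits this far beyond the lining
    axis_scales: tuple[float, float, float] = (1.25, 1.0, 0.8)
    n_lining_residues: int = 44
    n_outer_residues: int = 28
    patch_half_angle: float = 60.0       # degrees; angular cap of signature residues
    ligand_atoms_range: tuple[int, int] = (10, 30)
    jitter_sigma: float = 0.3            # A, positional noise on residue centers
    seed: int = 0

    def __post_init__(self):
        for name, mixture in self.classes.items():
            if abs(sum(mixture.values()) - 1.0) > 1e-9:
                raise ValueError(f"class {name!r} mixture does not sum to 1")
            unknown = set(mixture) - set(RESIDUE_ATOMS)
            if unknown:
                raise ValueError(f"unknown residue species {unknown} in class {name!r}")

    @property
    def class_names(self) -> list[str]:
        return list(self.classes)


@dataclass
class ComplexRecord:
    """One generated complex: PDB text, label, and planted-region provenance."""

    pdb_text: str
    label: int
    class_name: str
    index: int
    patch_residues: set[ResidueId]
    lining_residues: set[ResidueId]
    cavity_radius: float


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _sphere_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def make_complex(spec: SyntheticSpec, class_name: str, index: int) -> ComplexRecord:
    """Generate one labeled pseudo-complex; deterministic under (seed, class, index)."""
    if class_name not in spec.classes:
        raise ValueError(f"unknown class {class_name!r}")
    label = spec.class_names.index(class_name)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, label, index]))

    r_cavity = rng.uniform(*spec.cavity_radius_range)
    r_outer = r_cavity + spec.outer_offset
    if r_cavity >= r_outer:
        raise ValueError("cavity radius must be smaller than the outer shell radius")
    scales = np.asarray(spec.axis_scales)
    rot = _random_rotation(rng)
    patch_axis = _sphere_directions(1, rng)[0]
    cos_cap = np.cos(np.radians(spec.patch_half_angle))
    mixture = spec.classes[class_name]
    species, probs = zip(*sorted(mixture.items()))

    atoms: list[tuple[str, str, str, int, np.ndarray]] = []  # record fields per atom
    patch_ids: set[ResidueId] = set()
    lining_ids: set[ResidueId] = set()
    resnum = 0

    def add_residue(resname: str, center: np.ndarray) -> ResidueId:
        nonlocal resnum
        resnum += 1
        rid = ("A", resnum, "")
        for atom_name in RESIDUE_ATOMS[resname]:
            offset = rng.normal(0.0, 0.7, 3)
            atoms.append((atom_name, atom_name[0], resname, resnum,
                          rot @ (center + offset)))
        return rid

    for u in _sphere_directions(spec.n_lining_residues, rng):
        center = r_cavity * scales * u + rng.normal(0.0, spec.jitter_sigma, 3)
        if u @ patch_axis >= cos_cap:
            resname = str(rng.choice(species, p=probs))
        else:
            resname = "LEU"
        rid = add_residue(resname, center)
        lining_ids.add(rid)
        if u @ patch_axis >= cos_cap and resname != "LEU":
            patch_ids.add(rid)

    for u in _sphere_directions(spec.n_outer_residues, rng):
        center = r_outer * scales * u + rng.normal(0.0, spec.jitter_sigma, 3)
        add_residue("LEU", center)

    n_lig = int(rng.integers(*spec.ligand_atoms_range, endpoint=True))
    lig_dirs = _sphere_directions(n_lig, rng)
    lig_radii = 0.6 * r_cavity * rng.random(n_lig) ** (1 / 3)
    lig_coords = rot @ (lig_dirs * lig_radii[:, None] * scales).T

    lines = []
    serial = 0
    for atom_name, element, resname, num, xyz in atoms:
        serial += 1
        x, y, z = xyz
        lines.append(
            f"ATOM  {serial:>5d}  {atom_name:<3s} {resname:<3s} A{num:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}")
    for i in range(n_lig):
        serial += 1
        x, y, z = lig_coords[:, i]
        lines.append(
            f"HETATM{serial:>5d}  C{i + 1:<2d} LIG L   1    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}           C")
    lines.append("END")
    return ComplexRecord("\n".join(lines) + "\n", label, class_name, index,
                         patch_ids, lining_ids, r_cavity)


def toy_potential() -> PairPotential:
    """Deterministic synthetic pair potential over bins [0-4, 4-8, 8-14.5] A.

    Every (probe, protein_type) pair gets a distinct nonzero energy in each
    bin, so differences in lining atom-type composition translate into
    separable channel statistics.  Bin magnitudes decay with distance
    (scale 2.0, 1.0, 0.2), mimicking how knowledge-based pair potentials
    approach zero toward their cutoff; this keeps the type signal
    concentrated near the atoms that carry it, so region-level explanations
    have a well-defined ground truth.
    """
    edges = np.array([0.0, 4.0, 8.0, 14.5])
    rng = np.random.default_rng(20190204)
    shape = (len(PROBE_TYPES), len(SYBYL_TYPES), 3)
    energies = np.round(rng.uniform(-1.0, 1.0, shape) * [2.0, 1.0, 0.2], 4)
    energies[energies == 0.0] = 0.01
    return PairPotential(PROBE_TYPES, SYBYL_TYPES, edges, energies)


def process_complex(record: ComplexRecord, pot: PairPotential | None = None,
                    **kwargs) -> PocketResult:
    """Run the full voxelization pipeline on a generated complex."""
    if pot is None:
        pot = toy_potential()
    return voxelize_complex(record.pdb_text, "LIG", pot, **kwargs)


def generate_records(spec: SyntheticSpec) -> list[ComplexRecord]:
    """All ``n_per_class`` x n_classes complexes of the study, in manifest order."""
    return [
        make_complex(spec, name, i)
        for name in spec.class_names
        for i in range(spec.n_per_class)
    ]


def build_arrays(
    spec: SyntheticSpec, pot: PairPotential | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[ComplexRecord], list[PocketResult]]:
    """In-memory dataset: energy tensors, occupancy tensors, labels, provenance."""
    if pot is None:
        pot = toy_potential()
    records = generate_records(spec)
    results = [process_complex(r, pot) for r in records]
    x_energy = np.stack([res.tensor.values for res in results])
    x_occ = np.stack([res.occupancy.values for res in results])
    labels = np.array([r.label for r in records])
    return x_energy, x_occ, labels, records, results


def make_dataset(spec: SyntheticSpec, outdir, pot: PairPotential | None = None) -> pd.DataFrame:
    """Write a self-contained dataset: tensors (HDF5), PDBs, potential, manifest.

    Manifest columns: id, voxel_path, occupancy_path, label, class_name, group.
    Groups tag alternating generation batches within each class so the
    leave-one-group-out protocol has something to hold out.  The PDB text of
    every complex and the potential table are written alongside so CAM
    analysis can re-run the pipeline from the originals.
    """
    from pathlib import Path

    from .potentials import save_potential_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if pot is None:
        pot = toy_potential()
    save_potential_table(pot, outdir / "toy_potential.tsv")
    rows = []
    for record in generate_records(spec):
        result = process_complex(record, pot)
        stem = f"{record.class_name}_{record.index:03d}"
        vox_path = outdir / f"{stem}.h5"
        occ_path = outdir / f"{stem}_occupancy.h5"
        (outdir / f"{stem}.pdb").write_text(record.pdb_text)
        voxelizer.save_tensor(vox_path, result.tensor)
        voxelizer.save_tensor(occ_path, result.occupancy)
        rows.append((stem, str(vox_path), str(occ_path), record.label,
                     record.class_name, f"g{record.index % 2}"))
    manifest = pd.DataFrame(rows, columns=[
        "id", "voxel_path", "occupancy_path", "label", "class_name", "group"])
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
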